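"""Array size estimation, control calibration, group comparisons."""

import numpy as np
import pandas as pd
import pytest

from satkit import arraysize, simdata
from satkit._seq import revcomp


PARAMS = arraysize.SizeParams(rho=0.459, genome_size=5_976_710_698)


def _read(seq, qual=40):
    q = np.full(len(seq), qual) if np.isscalar(qual) else np.asarray(qual)
    return (seq, q)


LIB = {"ACGTACGTACGTACGTACGTACGT"}


class TestCountLibraryHits:
    def test_window_total_without_hits(self):
        m, t = arraysize.count_library_hits([_read("CATTG" * 20)], {"A" * 24}, PARAMS)
        assert (m, t) == (0, 100 - 24 + 1)

    def test_exact_library_read(self):
        kmer = next(iter(LIB))
        m, t = arraysize.count_library_hits([_read(kmer)], LIB, PARAMS)
        assert (m, t) == (1, 1)

    def test_reverse_complement_counted(self):
        kmer = next(iter(LIB))
        m, t = arraysize.count_library_hits([_read(revcomp(kmer))], LIB, PARAMS)
        assert m == 1

    def test_low_quality_windows_skipped(self):
        kmer = next(iter(LIB))
        qual = np.full(24, 40)
        qual[5] = 10
        m, t = arraysize.count_library_hits([_read(kmer, qual)], LIB, PARAMS)
        assert (m, t) == (0, 0)

    def test_streaming_matches_per_read(self):
        rng = np.random.default_rng(0)
        reads = [
            _read("".join(rng.choice(list("ACGT"), size=80))) for _ in range(300)
        ]
        m1, t1 = arraysize.count_library_hits(iter(reads), LIB, PARAMS)
        msum = tsum = 0
        for r in reads:
            m, t = arraysize.count_library_hits([r], LIB, PARAMS)
            msum += m
            tsum += t
        assert (m1, t1) == (msum, tsum)


class TestEstimateSize:
    def test_printed_formula_arithmetic(self):
        # (M/T)/rho * G with M/T = 0.00459, rho = 0.459 -> 1% of the genome
        raw = arraysize.estimate_size(459, 100_000, PARAMS)
        assert raw == pytest.approx(0.00459 / 0.459 * 5_976_710_698)
        assert raw == pytest.approx(59_767_106.98, rel=1e-9)

    def test_zero_hits_zero_size(self):
        assert arraysize.estimate_size(0, 1000, PARAMS) == 0.0

    def test_linearity_in_hits(self):
        a = arraysize.estimate_size(100, 10_000, PARAMS)
        b = arraysize.estimate_size(200, 10_000, PARAMS)
        assert b == pytest.approx(2 * a)

    def test_no_windows_is_error(self):
        with pytest.raises(ValueError):
            arraysize.estimate_size(0, 0, PARAMS)


class TestControlSet:
    def _reference(self, seed=0, n=30_000):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_at_matching_single_stratum(self):
        ref = self._reference()
        target = {k for k in (ref[i : i + 24] for i in range(0, 2000, 24))
                  if arraysize.at_count(k) == 12}
        assert target
        cs = arraysize.build_control_set(ref, target, 20, seed=1)
        assert all(arraysize.at_count(k) == 12 for k in cs.kmers)

    def test_at_histogram_matched_within_rounding(self):
        ref = self._reference(1, 60_000)
        target = {ref[i : i + 24] for i in range(0, 4000, 7)}
        n = 100
        cs = arraysize.build_control_set(ref, target, n, seed=2)
        from collections import Counter

        want = Counter(arraysize.at_count(k) for k in target)
        got = Counter(arraysize.at_count(k) for k in cs.kmers)
        assert len(cs.kmers) == n
        for a, c in got.items():
            expected = n * want.get(a, 0) / sum(want.values())
            assert abs(c - expected) <= 1 + 1e-9

    def test_repeated_kmers_rejected(self):
        ref = self._reference(2, 20_000)
        dup = ref[100:124]
        ref = ref + dup  # second occurrence
        cs = arraysize.build_control_set(ref, {dup}, 1, seed=3)
        assert dup not in cs.kmers

    def test_exclusion_intervals_respected(self):
        ref = self._reference(3, 20_000)
        cs = arraysize.build_control_set(
            ref, {ref[50:74]}, 5, exclusion=[(0, 10_000)], seed=4
        )
        # candidate positions below 10 kb are excluded; harvested controls
        # must come from the second half
        for k in cs.kmers:
            assert ref.find(k) >= 10_000


class TestCalibrateAndCorrect:
    def _setup(self, errors):
        """Control counts engineered so each male's control-size estimate has
        the requested signed relative error."""
        controls = [f"k{i}" for i in range(100)]
        g = 1000.0
        c_true = 50.0
        t = 1000.0
        cols = {}
        for s, err in errors.items():
            target_m = (1 + err) * c_true * t / g
            per = np.full(100, target_m / 100)
            cols[s] = per
        counts = pd.DataFrame(cols, index=controls)
        cs = arraysize.ControlSet(controls, c_true, trim_frac=0.0)
        raw = {s: 2000.0 for s in errors}
        return raw, counts, {s: t for s in errors}, cs, g

    def test_uniform_error_corrected_exactly(self):
        raw, counts, t, cs, g = self._setup({"m1": 0.05, "m2": 0.05})
        df = arraysize.calibrate_and_correct(raw, counts, t, cs, g)
        assert np.allclose(df["corrected_size"], 2000.0 / 1.05)
        assert df.attrs["mean_control_error"] == pytest.approx(0.05)

    def test_outlier_sample_excluded(self):
        raw, counts, t, cs, g = self._setup({"m1": 0.05, "m2": 0.4})
        df = arraysize.calibrate_and_correct(raw, counts, t, cs, g)
        assert bool(df.loc["m2", "excluded"]) is True
        assert bool(df.loc["m1", "excluded"]) is False

    def test_female_filter_drops_kmers(self):
        raw, counts, t, cs, g = self._setup({"m1": 0.0, "m2": 0.0})
        counts["f1"] = 0.0
        counts.loc["k0", "f1"] = 50.0  # grossly over-covered in a female
        df = arraysize.calibrate_and_correct(raw, counts, t, cs, g, female_samples=["f1"])
        assert df.attrs["n_controls_retained"] == 99

    def test_trim_drops_extreme_coverage(self):
        raw, counts, t, cs, g = self._setup({"m1": 0.0, "m2": 0.0})
        cs.trim_frac = 0.02
        counts.loc["k0", ["m1", "m2"]] = 1000.0
        counts.loc["k1", ["m1", "m2"]] = 0.0
        df = arraysize.calibrate_and_correct(raw, counts, t, cs, g)
        assert df.attrs["n_controls_retained"] < 100

    def test_single_male_rejected(self):
        raw, counts, t, cs, g = self._setup({"m1": 0.0, "m2": 0.0})
        with pytest.raises(ValueError):
            arraysize.calibrate_and_correct({"m1": 1.0}, counts, t, cs, g)


class TestGroupComparison:
    def test_exact_wilcoxon_enumeration(self):
        # all 3 smallest in one group: p = 2 * 1/C(6,3) = 0.1
        assert arraysize.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        p = arraysize.wilcoxon_rank_sum([1.0, 2.0, 3.5], [1.5, 2.5, 3.0])
        assert p == pytest.approx(1.0)

    def test_holm_stepdown_by_hand(self):
        adj = arraysize.holm_adjust([0.01, 0.04])
        assert np.allclose(adj, [0.02, 0.04])

    def test_holm_never_decreases_and_is_conservative(self):
        rng = np.random.default_rng(9)
        ps = rng.random(8) * 0.2
        adj = arraysize.holm_adjust(ps)
        assert np.all(adj >= ps - 1e-12)
        alpha = 0.05
        assert set(np.nonzero(adj < alpha)[0]) <= set(np.nonzero(ps < alpha)[0])

    def test_group_summaries_and_pairwise_table(self):
        sizes = [10, 12, 11, 30, 32, 31, 29, 20, 21]
        groups = ["A", "A", "A", "B", "B", "B", "B", "C", "C"]
        summary, tests = arraysize.haplogroup_compare(sizes, groups, alpha=0.05)
        assert summary.loc["A", "n"] == 3
        assert summary.loc["B", "mean"] == pytest.approx(30.5)
        assert len(tests) == 3
        ab = tests[(tests.group_a == "A") & (tests.group_b == "B")].iloc[0]
        assert ab.p_raw == pytest.approx(arraysize.wilcoxon_rank_sum([10, 12, 11], [30, 32, 31, 29]))

    def test_small_groups_kept_in_summary_but_untested(self):
        sizes = [1, 2, 3, 4, 9]
        groups = ["A", "A", "B", "B", "C"]
        summary, tests = arraysize.haplogroup_compare(sizes, groups)
        assert "C" in summary.index
        assert not ((tests.group_a == "C") | (tests.group_b == "C")).any()


class TestSizeTableIO:
    def test_roundtrip_with_header_and_without(self, tmp_path):
        body = "NA001\tGBR\tR\tR1b\t2.1e7\nNA002\tCHB\tO\tO3\t2.9e7\n"
        for header in ("Sample\tPop\tHap\tHapDetail\tSize\n", ""):
            p = tmp_path / f"sd4_{bool(header)}.txt"
            p.write_text(header + body)
            df = arraysize.load_size_table(p)
            assert list(df["sample_id"]) == ["NA001", "NA002"]
            assert df["size_bp"].tolist() == [2.1e7, 2.9e7]

    def test_major_haplogroup_merging(self):
        assert arraysize.major_haplogroup("R1b") == "R"
        assert arraysize.major_haplogroup("Q1a") == "Q/P"
        assert arraysize.major_haplogroup("P") == "Q/P"


def test_estimator_unbiased_on_simulated_reads():
    """On error-free uniform-coverage reads, E[M/T] = rho * array_bp / G."""
    unit = simdata.gen_subfamily_units(1, 1770, 0.1, seed=80)[0]
    array_bp, g_bp = 400_000, 1_000_000
    genome = simdata.build_genome(
        [("c", 200_000, 0, array_bp)], {0: unit}, {"c": g_bp}, seed=80
    )
    dbl = unit + unit
    lib = {dbl[i : i + 24] for i in range(len(unit))}
    cfg_ref = simdata.SimConfig(seed=81, phred_model=simdata.PhredModel(90, 90, 0.0))
    ref_genome = simdata.SimGenome(
        [("arr", genome.seq("c")[200_000 : 200_000 + array_bp])], simdata.SimTruth()
    )
    ref_reads = simdata.sim_illumina_reads(ref_genome, 100, 1.0, cfg_ref)
    rho = arraysize.compute_rho([(r.sequence, r.quality) for r in ref_reads], lib)
    estimates = []
    for seed in range(10):
        cfg = simdata.SimConfig(seed=200 + seed, phred_model=simdata.PhredModel(90, 90, 0.0))
        reads = simdata.sim_illumina_reads(genome, 100, 1.0, cfg)
        params = arraysize.SizeParams(rho=rho, genome_size=g_bp)
        m, t = arraysize.count_library_hits(
            ((r.sequence, r.quality) for r in reads), lib, params
        )
        estimates.append(arraysize.estimate_size(m, t, params))
    estimates = np.array(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - array_bp) < max(3 * se, 0.01 * array_bp)


def test_estimator_monotone_in_array_size():
    unit = simdata.gen_subfamily_units(1, 1770, 0.1, seed=82)[0]
    dbl = unit + unit
    lib = {dbl[i : i + 24] for i in range(len(unit))}
    sizes = []
    for array_bp in (100_000, 200_000, 400_000):
        genome = simdata.build_genome(
            [("c", 100_000, 0, array_bp)], {0: unit}, {"c": 800_000}, seed=83
        )
        cfg = simdata.SimConfig(seed=84, phred_model=simdata.PhredModel(90, 90, 0.0))
        reads = simdata.sim_illumina_reads(genome, 100, 1.0, cfg)
        params = arraysize.SizeParams(rho=0.9, genome_size=800_000)
        m, t = arraysize.count_library_hits(
            ((r.sequence, r.quality) for r in reads), lib, params
        )
        sizes.append(arraysize.estimate_size(m, t, params))
    assert sizes[0] < sizes[1] < sizes[2]
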