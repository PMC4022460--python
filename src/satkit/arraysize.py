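"""Satellite array size estimation from short-read 24-mer hit rates.

For an individual sequenced at arbitrary depth, the fraction of high-quality
24-mer windows matching a subfamily's diagnostic library estimates the
genome fraction occupied by that subfamily's arrays:

    raw_size = (M / T) / rho * G

where M and T are library-matching and total HQ windows, rho is the match
rate observed on the subfamily's own reference reads, and G the genome
size.  Coverage bias is calibrated away with AT-matched single-copy control
24-mers whose true total size is known; group differences (e.g. between Y
haplogroups) are tested with pairwise two-sided Wilcoxon rank-sum tests
under a Holm correction.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import encode, kmer_codes, code_to_kmer, kmer_to_code, revcomp_code


@dataclass
class SizeParams:
    """rho: library match rate on the subfamily's reference reads; G: genome bp."""

    rho: float
    genome_size: float
    kmer_len: int = 24
    phred_min: int = 20

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")


@dataclass
class ControlSet:
    kmers: list
    c_true: float  # known control region size, bp
    trim_frac: float = 0.005
    female_max_reads: int = 10
    outlier_error: float = 0.30


@dataclass
class SizeEstimate:
    sample_id: str
    m: int
    t: int
    raw_size: float
    corrected_size: float | None = None
    control_error: float | None = None
    excluded: bool = False


def _library_code_set(kmers, k):
    codes = set()
    for kmer in kmers:
        c = kmer_to_code(kmer)
        codes.add(c)
        codes.add(revcomp_code(c, k))
    return np.array(sorted(codes), dtype=np.uint64)


def _iter_read_batches(reads, batch=5000):
    it = iter(reads)
    while True:
        chunk = list(itertools.islice(it, batch))
        if not chunk:
            return
        yield chunk


def count_library_hits(reads, library, params: SizeParams):
    """Stream reads and count (M, T): library-matching and total HQ windows.

    ``reads`` yields objects with ``sequence``/``quality`` (or plain
    (sequence, quality) pairs); ``library`` is an iterable of k-mers or a
    KmerLibrary.  Matching is exact, on either strand.  Memory is constant
    in the number of reads.
    """
    kmers = getattr(library, "kmers", library)
    k = params.kmer_len
    lib_codes = _library_code_set(kmers, k)
    if lib_codes.size == 0:
        raise ValueError("library must be non-empty")
    m = t = 0
    for chunk in _iter_read_batches(reads):
        seqs, quals = [], []
        for r in chunk:
            if hasattr(r, "sequence"):
                seqs.append(r.sequence)
                quals.append(np.asarray(r.quality))
            else:
                s, q = r
                seqs.append(s)
                quals.append(np.asarray(q))
        joined = "N".join(seqs)
        qual = np.concatenate(
            [np.concatenate([q, [0]]) for q in quals]
        )[: len(joined)]
        bases = encode(joined)
        hq = qual > params.phred_min
        codes, ok = kmer_codes(bases, k, valid=hq)
        t += int(ok.sum())
        if ok.any():
            hits = np.searchsorted(lib_codes, codes[ok])
            hits = np.clip(hits, 0, lib_codes.size - 1)
            m += int((lib_codes[hits] == codes[ok]).sum())
    return m, t


def per_kmer_hit_counts(reads, kmers, params: SizeParams) -> Counter:
    """Per-control-kmer HQ-window hit counts across a read stream."""
    k = params.kmer_len
    fwd = {kmer_to_code(km): km for km in kmers}
    rev = {revcomp_code(c, k): km for c, km in fwd.items()}
    lookup = {**fwd, **rev}
    keys = np.array(sorted(lookup), dtype=np.uint64)
    out: Counter = Counter()
    for chunk in _iter_read_batches(reads):
        for r in chunk:
            seq = r.sequence if hasattr(r, "sequence") else r[0]
            qual = np.asarray(r.quality if hasattr(r, "quality") else r[1])
            codes, ok = kmer_codes(encode(seq), k, valid=qual > params.phred_min)
            good = codes[ok]
            pos = np.clip(np.searchsorted(keys, good), 0, keys.size - 1)
            for c in good[keys[pos] == good]:
                out[lookup[int(c)]] += 1
    return out


def estimate_size(m: int, t: int, params: SizeParams) -> float:
    """raw array size in bp: (M/T) / rho * G."""
    if t <= 0:
        raise ValueError("no high-quality windows (T = 0)")
    return (m / t) / params.rho * params.genome_size


def compute_rho(reference_reads, library, params_like=None) -> float:
    """Library match rate on the subfamily's own reference reads.

    The analog of the published constant for a synthetic subfamily: the
    proportion of all HQ 24-mers on subfamily-containing reads that match
    the subfamily-specific library.
    """
    p = SizeParams(rho=1.0, genome_size=1.0)
    if params_like is not None:
        p.kmer_len, p.phred_min = params_like.kmer_len, params_like.phred_min
    m, t = count_library_hits(reference_reads, library, p)
    if t == 0:
        raise ValueError("reference reads contain no HQ windows")
    return m / t


def at_count(kmer: str) -> int:
    return sum(1 for c in kmer if c in "AT")


def build_control_set(
    reference: str,
    target_library,
    n_controls: int,
    exclusion=(),
    c_true: float | None = None,
    seed: int = 0,
    kmer_len: int = 24,
) -> ControlSet:
    """Sample single-copy control 24-mers AT-matched to the target library.

    Candidates occur exactly once in the reference (counting both strands)
    and avoid ``exclusion`` intervals (e.g. annotated repeats).  Controls
    are allocated across AT-count strata (0-24) proportionally to the
    target library's AT histogram with largest-remainder rounding; strata
    short of candidates borrow from the nearest stratum with a warning.
    ``c_true`` defaults to the number of controls (one unique 24-mer per
    reference base pair of control region).
    """
    k = kmer_len
    kmers = getattr(target_library, "kmers", target_library)
    bases = encode(reference)
    codes, ok = kmer_codes(bases, k)
    counts: Counter = Counter()
    for c in codes[ok]:
        c = int(c)
        key = min(c, revcomp_code(c, k))
        counts[key] += 1
    excluded_pos = np.zeros(len(reference), dtype=bool)
    for s, e in exclusion:
        excluded_pos[s:e] = True
    cum = np.concatenate([[0], np.cumsum(excluded_pos)])
    candidates_by_at: dict[int, list] = {}
    seen_once = {key for key, n in counts.items() if n == 1}
    for i in np.nonzero(ok)[0]:
        c = int(codes[i])
        key = min(c, revcomp_code(c, k))
        if key not in seen_once:
            continue
        if cum[i + k] - cum[i] > 0:  # overlaps an exclusion interval
            continue
        kmer = code_to_kmer(c, k)
        candidates_by_at.setdefault(at_count(kmer), []).append(kmer)
    hist = Counter(at_count(km) for km in kmers)
    total = sum(hist.values())
    if total == 0:
        raise ValueError("target library is empty")
    # largest-remainder allocation over AT strata
    quotas = {a: n_controls * c / total for a, c in hist.items()}
    alloc = {a: int(q) for a, q in quotas.items()}
    remainder = n_controls - sum(alloc.values())
    for a in sorted(quotas, key=lambda a: quotas[a] - alloc[a], reverse=True)[:remainder]:
        alloc[a] += 1
    rng = np.random.default_rng(seed)
    controls: list[str] = []
    deficit = 0
    for a in sorted(alloc):
        want = alloc[a]
        pool = candidates_by_at.get(a, [])
        take = min(want, len(pool))
        if take < want:
            deficit += want - take
            warnings.warn(f"AT stratum {a}: only {take}/{want} unique candidates")
        if take:
            controls.extend(rng.choice(pool, size=take, replace=False))
    while deficit > 0:
        # borrow from nearest strata with spare candidates
        spare = {
            a: [km for km in pool if km not in set(controls)]
            for a, pool in candidates_by_at.items()
        }
        progressed = False
        for a in sorted(spare, key=lambda a: len(spare[a]), reverse=True):
            if spare[a] and deficit > 0:
                controls.append(spare[a][0])
                deficit -= 1
                progressed = True
        if not progressed:
            break
    if c_true is None:
        c_true = float(len(controls))
    return ControlSet(list(controls), c_true)


def calibrate_and_correct(
    raw_estimates: dict,
    control_counts: pd.DataFrame,
    total_windows: dict,
    control_set: ControlSet,
    genome_size: float,
    female_samples=(),
) -> pd.DataFrame:
    """Calibrate raw size estimates with single-copy control 24-mers.

    ``control_counts`` holds per-control-kmer read/window hit counts
    (rows = control k-mers, columns = samples, females included);
    ``total_windows`` maps sample -> T.  Steps: (1) drop control k-mers in
    the bottom/top ``trim_frac`` of total male coverage or exceeding
    ``female_max_reads`` total hits in female samples; (2) estimate the
    control-region size per male by the same M/T calculation (rho = 1 for
    single-copy 24-mers); (3) the signed mean relative error corrects every
    raw estimate down (or up); (4) samples with |error| above
    ``outlier_error`` are flagged excluded.
    """
    females = [s for s in female_samples if s in control_counts.columns]
    males = [s for s in raw_estimates if s in control_counts.columns]
    if len(males) < 2:
        raise ValueError("need at least 2 male samples with control counts")
    male_cov = control_counts[males].sum(axis=1)
    n_ctl = len(male_cov)
    n_trim = int(control_set.trim_frac * n_ctl)
    order = male_cov.sort_values(kind="stable").index
    trimmed = set(order[:n_trim]) | set(order[n_ctl - n_trim :] if n_trim else [])
    keep = ~control_counts.index.isin(list(trimmed))
    keep = pd.Series(keep, index=control_counts.index)
    if females:
        keep &= control_counts[females].sum(axis=1) <= control_set.female_max_reads
    retained = control_counts.index[keep]
    if len(retained) == 0:
        raise ValueError("all control 24-mers were eliminated")
    errors = {}
    for s in males:
        m_ctl = float(control_counts.loc[retained, s].sum())
        t_s = float(total_windows[s])
        est_c = (m_ctl / t_s) * genome_size
        errors[s] = (est_c - control_set.c_true) / control_set.c_true
    mean_err = float(np.mean(list(errors.values())))
    rows = []
    for s, raw in raw_estimates.items():
        err = errors.get(s)
        corrected = raw / (1.0 + mean_err)
        excluded = err is not None and abs(err) > control_set.outlier_error
        rows.append(
            {
                "sample_id": s,
                "raw_size": raw,
                "corrected_size": corrected,
                "control_error": err,
                "excluded": excluded,
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    df.attrs["mean_control_error"] = mean_err
    df.attrs["n_controls_retained"] = int(len(retained))
    return df


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10):
    """Two-sided two-sample Wilcoxon rank-sum p-value.

    Exact enumeration when the smaller group has at most ``exact_max_n``
    members and there are no ties; otherwise the normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def haplogroup_compare(sizes, groups, alpha: float = 0.001, min_group: int = 2):
    """Group summaries plus pairwise Wilcoxon tests with Holm correction.

    Returns ``(summary, tests)``: a per-group table (n, mean, sd, min, max)
    over all groups, and a pairwise table (raw p, Holm-adjusted p,
    significance at ``alpha``) over groups with at least ``min_group``
    members.
    """
    s = pd.Series(np.asarray(sizes, dtype=float), name="size")
    g = pd.Series(list(groups), name="group")
    df = pd.DataFrame({"size": s.values, "group": g.values})
    summary = (
        df.groupby("group")["size"]
        .agg(n="count", mean="mean", sd="std", min="min", max="max")
        .sort_index()
    )
    eligible = summary.index[summary["n"] >= min_group]
    pairs = list(itertools.combinations(eligible, 2))
    if not pairs:
        raise ValueError("need at least 2 groups with enough members")
    raw = []
    for a, b in pairs:
        raw.append(
            wilcoxon_rank_sum(
                df.loc[df["group"] == a, "size"], df.loc[df["group"] == b, "size"]
            )
        )
    _, adj, _, _ = multipletests(raw, method="holm")
    tests = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_holm": adj,
        }
    )
    tests["significant"] = tests["p_holm"] < alpha
    return summary, tests


def holm_adjust(pvalues):
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    _, adj, _, _ = multipletests(list(pvalues), method="holm")
    return np.asarray(adj)


def load_size_table(path) -> pd.DataFrame:
    """Load a per-sample array-size table.

    Expects whitespace/tab-delimited columns: sample id, population,
    haplogroup, haplogroup detail, array size in bp (header optional).
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    first = df.iloc[0]
    try:
        float(first.iloc[-1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :5]
    df.columns = ["sample_id", "population", "haplogroup", "haplogroup_detail", "size_bp"]
    df["size_bp"] = df["size_bp"].astype(float)
    return df


def major_haplogroup(hap: str, merged=(("Q", "P"),)) -> str:
    """Collapse a haplogroup string to its leading letter; merge listed sets
    (Q and P by default) into a combined label like "Q/P"."""
    h = str(hap).strip()[:1].upper()
    for group in merged:
        if h in group:
            return "/".join(group)
    return h
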