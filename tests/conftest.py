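"""Shared simulated fixtures.

All fixtures are deterministic (fixed seeds) and generated at test time;
the expensive ones are session-scoped so the planted two-subfamily dataset
is simulated once and reused across feature, graph and localization tests.
"""

import numpy as np
import pytest

from satkit import features, readprep, simdata


@pytest.fixture(scope="session")
def two_subfamily_sim():
    """Two planted subfamilies (divergence 0.3 from the ancestral pentamer),
    one 120 kb array each, Sanger-like pairs at 3x coverage."""
    units = dict(enumerate(simdata.gen_subfamily_units(2, 1770, 0.3, seed=42)))
    flank, alen = 25_000, 120_000
    spec = [("chr1", flank, 0, alen), ("chr2", flank, 1, alen)]
    lens = {c: alen + 2 * flank for c in ("chr1", "chr2")}
    genome = simdata.build_genome(spec, units, lens, seed=42)
    config = simdata.SimConfig(seed=42, coverage=3.0)
    reads, pairs = simdata.sim_sanger_pairs(genome, config)
    return genome, reads, pairs, units


@pytest.fixture(scope="session")
def two_subfamily_masked(two_subfamily_sim):
    """Accepted masked reads + surviving pair table for the planted dataset."""
    genome, reads, pairs, _ = two_subfamily_sim
    annos = readprep.annotations_from_records(simdata.truth_annotations(genome, reads))
    masked = [
        readprep.preprocess_read(r, annos[r.read_id]) for r in reads if r.read_id in annos
    ]
    accepted, pairs_kept = readprep.orient_and_dedupe(
        [m for m in masked if m.accepted], pairs
    )
    return accepted, pairs_kept


@pytest.fixture(scope="session")
def two_subfamily_features(two_subfamily_masked):
    accepted, _ = two_subfamily_masked
    return features.standardize_matrix(features.kmer_feature_matrix(accepted, k=5))


@pytest.fixture(scope="session")
def subfamily_truth(two_subfamily_sim, two_subfamily_features):
    """True chromosome (= subfamily) of origin for each featurized read."""
    genome, _, _, _ = two_subfamily_sim
    fm = two_subfamily_features
    return np.array([genome.truth.read_origins[rid][0] for rid in fm.read_ids])
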