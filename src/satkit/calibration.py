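"""Self-mate-pair calibration by paired-read simulation.

The split-acceptance threshold of the recursive clustering (SMP > 0.8) is
justified by simulation: paired reads are drawn from a genome carrying one
contiguous satellite array of known length, the "cluster" is defined as the
reads overlapping the array, and the fraction of mate pairs touching that
cluster with both ends inside it is measured.  SMP grows with array length
(for a fixed insert distribution) and crosses 0.8 near 100 kb with 5 kb
inserts, so accepted clusters correspond to arrays of at least roughly
that size.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .simdata import SimConfig, build_genome, gen_subfamily_units, sim_sanger_pairs


def _overlap(a0, a1, b0, b1):
    return max(0, min(a1, b1) - max(a0, b0))


def smp_for_array(
    array_length: int,
    config: SimConfig | None = None,
    flank: int = 100_000,
    unit_length: int = 1770,
    min_overlap: int = 75,
    seed: int = 0,
) -> float:
    """Simulate one contiguous satellite array and measure cluster SMP.

    A single chromosome carries ``flank`` bp of background, the array, and
    another flank.  Paired Sanger-like reads are simulated (all pairs kept:
    unpaired reads carry no SMP information), the cluster is the set of
    reads with at least ``min_overlap`` bp inside the array, and the
    returned value is (#pairs with both ends in the cluster) / (#pairs with
    at least one end in it).
    """
    if config is None:
        config = SimConfig()
    config = dataclasses.replace(config, seed=seed, unpaired_frac=0.0)
    units = {0: gen_subfamily_units(1, unit_length, 0.1, seed=seed)[0]}
    total = 2 * flank + array_length
    genome = build_genome(
        [("chr1", flank, 0, array_length)], units, {"chr1": total}, seed=seed
    )
    reads, pairs = sim_sanger_pairs(genome, config)
    a0, a1 = flank, flank + array_length
    in_cluster = set()
    for r in reads:
        if _overlap(r.start, r.start + len(r), a0, a1) >= min_overlap:
            in_cluster.add(r.read_id)
    both = touch = 0
    for a, b in pairs:
        ina, inb = a in in_cluster, b in in_cluster
        if ina or inb:
            touch += 1
            if ina and inb:
                both += 1
    if touch == 0:
        return float("nan")
    return both / touch


def smp_curve(array_lengths, config: SimConfig | None = None, seeds=(0,), **kw):
    """Mean SMP per array length over the given seeds (Text-style calibration)."""
    out = []
    for length in array_lengths:
        vals = [smp_for_array(length, config, seed=s, **kw) for s in seeds]
        out.append(float(np.mean(vals)))
    return np.array(out)
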