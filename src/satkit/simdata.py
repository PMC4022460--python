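"""Synthetic satellite genomes and sequencing reads with full ground truth.

Emulates the kind of data the pipeline consumes in practice: pentamer-derived
satellite subfamilies laid out as long tandem arrays inside background
sequence, Sanger-like paired reads (~877 bp), whole-chromosome-shotgun (WCS)
samples with a known chromosome mixing vector, and short Illumina-like reads
for array sizing.  Every generator records its ground truth so downstream
modules can be tested without any external download.

Coordinates are 0-based half-open throughout; strand '+' is the strand
stored in the genome string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._seq import revcomp

PENTAMER = "CATTC"


@dataclass
class PhredModel:
    """Two-level base-quality model: most bases at high_q, a fraction at low_q."""

    high_q: int = 40
    low_q: int = 10
    low_q_rate: float = 0.02


@dataclass
class SimConfig:
    """Sequencing-simulation parameters.

    Defaults follow the study conditions: mean read length 877 bp and 7.8x
    genome coverage for the Sanger-like library.  Insert sizes are a knob
    (mean 5 kb, sd 1 kb by default); read/insert lengths are truncated
    normal, clamped to [50 bp, 5x mean].  About 65% of satellite reads in
    real Sanger libraries have a sequenced mate, hence unpaired_frac 0.35.
    """

    seed: int = 0
    read_len_mean: float = 877.0
    read_len_sd: float = 150.0
    insert_len_mean: float = 5000.0
    insert_len_sd: float = 1000.0
    coverage: float = 7.8
    phred_model: PhredModel = field(default_factory=PhredModel)
    unpaired_frac: float = 0.35

    def __post_init__(self):
        if self.read_len_mean <= 0:
            raise ValueError("read_len_mean must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_len_mean < self.read_len_mean:
            raise ValueError("insert_len_mean must be >= read_len_mean")


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: np.ndarray  # phred per base
    chrom: str
    start: int  # 0-based position of the read's interval on the genome
    strand: str  # '+' or '-'
    mate_id: str | None = None

    def __len__(self):
        return len(self.sequence)


@dataclass
class SimTruth:
    arrays: list = field(default_factory=list)  # (chrom, start, end, subfamily_id, unit_length)
    read_origins: dict = field(default_factory=dict)  # read_id -> (chrom, start, strand)
    true_mixing: dict = field(default_factory=dict)  # sample -> np.ndarray proportions
    true_array_bp: dict = field(default_factory=dict)  # subfamily_id -> total bp

    def arrays_on(self, chrom: str):
        return [a for a in self.arrays if a[0] == chrom]


@dataclass
class SimGenome:
    chromosomes: list  # list of (name, sequence)
    truth: SimTruth

    @property
    def names(self):
        return [n for n, _ in self.chromosomes]

    def seq(self, chrom: str) -> str:
        for n, s in self.chromosomes:
            if n == chrom:
                return s
        raise KeyError(chrom)

    @property
    def total_length(self):
        return sum(len(s) for _, s in self.chromosomes)


def gen_subfamily_units(
    n_subfamilies: int, unit_length: int, divergence: float, seed: int
) -> list[str]:
    """Generate tandem-repeat unit sequences for satellite subfamilies.

    Each unit starts as the ancestral pentamer CATTC concatenated to
    ``unit_length`` and is then mutated i.i.d. per base: with probability
    ``divergence`` a base is substituted by a uniformly chosen different
    base.  Independent draws per subfamily.
    """
    if not (0 <= divergence < 0.75):
        raise ValueError("divergence must be in [0, 0.75)")
    if unit_length % 5 != 0 or unit_length <= 0:
        raise ValueError("unit_length must be a positive multiple of 5")
    rng = np.random.default_rng(seed)
    ancestral = (PENTAMER * (unit_length // 5 + 1))[:unit_length]
    base = np.frombuffer(ancestral.encode(), dtype=np.uint8)
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    units = []
    for _ in range(n_subfamilies):
        arr = base.copy()
        hits = rng.random(unit_length) < divergence
        which = rng.integers(0, 3, size=unit_length)
        for i in np.nonzero(hits)[0]:
            arr[i] = lut[base[i]][which[i]]
        units.append(arr.tobytes().decode())
    return units


def build_genome(
    array_spec: Sequence[tuple],
    units: dict,
    background_length: dict,
    gc: float = 0.4,
    seed: int = 0,
    per_copy_divergence: float = 0.0,
) -> SimGenome:
    """Assemble chromosomes of background sequence with planted tandem arrays.

    ``array_spec`` rows are ``(chrom, position, subfamily_id, array_length)``;
    ``units`` maps subfamily_id -> unit sequence; ``background_length`` maps
    chrom -> total chromosome length.  Arrays are the unit tandemly repeated
    (final copy truncated), optionally with per-copy substitution noise.
    Background is i.i.d. with the given GC fraction.
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    by_chrom: dict[str, list] = {c: [] for c in background_length}
    for chrom, pos, sid, alen in array_spec:
        if chrom not in background_length:
            raise ValueError(f"unknown chromosome {chrom!r}")
        unit = units[sid]
        if alen < len(unit):
            raise ValueError("array_length must be >= unit_length")
        if pos < 0 or pos + alen > background_length[chrom]:
            raise ValueError("array does not fit within chromosome")
        by_chrom[chrom].append((pos, alen, sid, unit))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chromosomes = []
    for chrom, total in background_length.items():
        spans = sorted(by_chrom[chrom])
        for (a0, al, _, _), (b0, bl, _, _) in zip(spans, spans[1:]):
            if a0 + al > b0:
                raise ValueError(f"overlapping arrays on {chrom}")
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=total, p=p)
        for pos, alen, sid, unit in spans:
            ncopies = -(-alen // len(unit))
            copies = []
            for _ in range(ncopies):
                if per_copy_divergence > 0:
                    copy = _mutate(unit, per_copy_divergence, rng)
                else:
                    copy = unit
                copies.append(copy)
            arr = "".join(copies)[:alen]
            bases[pos : pos + alen] = np.frombuffer(arr.encode(), dtype=np.uint8)
            truth.arrays.append((chrom, pos, pos + alen, sid, len(unit)))
            truth.true_array_bp[sid] = truth.true_array_bp.get(sid, 0) + alen
        chromosomes.append((chrom, bases.tobytes().decode()))
    return SimGenome(chromosomes, truth)


def _mutate(seq: str, rate: float, rng) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    alph = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alph[alph != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _trunc_normal(rng, mean, sd, size, lo=50.0):
    hi = 5.0 * mean
    draws = rng.normal(mean, sd, size=size)
    clamped = np.clip(draws, lo, hi)
    return clamped, int(np.sum(draws != clamped))


def _qualities(rng, length, model: PhredModel) -> np.ndarray:
    q = np.full(length, model.high_q, dtype=np.int16)
    q[rng.random(length) < model.low_q_rate] = model.low_q
    return q


def _apply_errors(rng, seq: str, qual: np.ndarray) -> str:
    """Substitution errors at the per-base rate implied by the phred score."""
    err_p = 10.0 ** (-qual / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < err_p)[0]
    if len(hits) == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    alph = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alph[alph != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def sim_sanger_pairs(genome: SimGenome, config: SimConfig):
    """Simulate Sanger-like paired reads from a genome.

    A pair is two reads at the opposite ends of a clone insert: the outer
    read on the forward strand and the inner read reverse-complemented.
    Read and insert lengths are truncated normal; a configurable fraction
    of reads loses its mate.  Returns ``(reads, pairs)`` where ``pairs``
    is a list of ``(read_id, mate_id)``; origins are recorded on
    ``genome.truth.read_origins``.
    """
    rng = np.random.default_rng(config.seed)
    lengths = np.array([len(s) for _, s in genome.chromosomes], dtype=float)
    max_insert = 5.0 * config.insert_len_mean
    if (lengths < max_insert).any():
        raise ValueError("every chromosome must be longer than the maximum insert")
    g = lengths.sum()
    n_pairs = int(round(config.coverage * g / (2.0 * config.read_len_mean)))
    chrom_idx = rng.choice(len(lengths), size=n_pairs, p=lengths / g)
    inserts, _ = _trunc_normal(
        rng, config.insert_len_mean, config.insert_len_sd, n_pairs,
        lo=max(50.0, config.read_len_mean),
    )
    rl1, _ = _trunc_normal(rng, config.read_len_mean, config.read_len_sd, n_pairs)
    rl2, _ = _trunc_normal(rng, config.read_len_mean, config.read_len_sd, n_pairs)
    reads: list[SimRead] = []
    pairs: list[tuple[str, str]] = []
    for i in range(n_pairs):
        ci = chrom_idx[i]
        chrom, seq = genome.chromosomes[ci]
        ins = int(max(inserts[i], rl1[i], rl2[i]))
        start = int(rng.integers(0, len(seq) - ins + 1))
        l1, l2 = int(rl1[i]), int(rl2[i])
        id_a, id_b = f"clone{i:07d}.f", f"clone{i:07d}.r"
        keep_a = keep_b = True
        if rng.random() < config.unpaired_frac:
            if rng.random() < 0.5:
                keep_b = False
            else:
                keep_a = False
        if keep_a:
            fwd = seq[start : start + l1]
            q = _qualities(rng, l1, config.phred_model)
            reads.append(
                SimRead(id_a, _apply_errors(rng, fwd, q), q, chrom, start, "+",
                        id_b if keep_b else None)
            )
            genome.truth.read_origins[id_a] = (chrom, start, "+")
        if keep_b:
            end = start + ins
            rev = revcomp(seq[end - l2 : end])
            q = _qualities(rng, l2, config.phred_model)
            reads.append(
                SimRead(id_b, _apply_errors(rng, rev, q), q, chrom, end - l2, "-",
                        id_a if keep_a else None)
            )
            genome.truth.read_origins[id_b] = (chrom, end - l2, "-")
        if keep_a and keep_b:
            pairs.append((id_a, id_b))
    return reads, pairs


def sim_wcs_sample(
    genome: SimGenome,
    mixing: Sequence[float],
    n_reads: int,
    config: SimConfig,
    sample_id: str = "wcs",
):
    """Simulate a flow-sorted whole-chromosome shotgun sample.

    Each read's chromosome of origin is drawn from ``mixing`` (a proportion
    per genome chromosome, in order); positions are uniform.  The true
    mixing vector is recorded on the genome truth under ``sample_id``.
    """
    mixing = np.asarray(mixing, dtype=float)
    if (mixing < 0).any():
        raise ValueError("mixing proportions must be non-negative")
    if abs(mixing.sum() - 1.0) > 1e-9:
        raise ValueError("mixing must sum to 1")
    if len(mixing) != len(genome.chromosomes):
        raise ValueError("mixing length must equal chromosome count")
    rng = np.random.default_rng(config.seed)
    genome.truth.true_mixing[sample_id] = mixing.copy()
    chrom_idx = rng.choice(len(mixing), size=n_reads, p=mixing)
    rls, _ = _trunc_normal(rng, config.read_len_mean, config.read_len_sd, n_reads)
    reads = []
    for i in range(n_reads):
        chrom, seq = genome.chromosomes[chrom_idx[i]]
        l = int(min(rls[i], len(seq)))
        start = int(rng.integers(0, len(seq) - l + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seq[start : start + l]
        if strand == "-":
            frag = revcomp(frag)
        q = _qualities(rng, l, config.phred_model)
        rid = f"{sample_id}.{i:07d}"
        reads.append(SimRead(rid, _apply_errors(rng, frag, q), q, chrom, start, strand))
        genome.truth.read_origins[rid] = (chrom, start, strand)
    return reads


def sim_illumina_reads(
    genome: SimGenome, read_len: int, coverage: float, config: SimConfig
) -> list[SimRead]:
    """Simulate single-end fixed-length short reads at a given coverage."""
    rng = np.random.default_rng(config.seed)
    lengths = np.array([len(s) for _, s in genome.chromosomes], dtype=float)
    g = lengths.sum()
    n_reads = int(round(coverage * g / read_len))
    chrom_idx = rng.choice(len(lengths), size=n_reads, p=lengths / g)
    reads = []
    for i in range(n_reads):
        chrom, seq = genome.chromosomes[chrom_idx[i]]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seq[start : start + read_len]
        if strand == "-":
            frag = revcomp(frag)
        q = _qualities(rng, read_len, config.phred_model)
        rid = f"sr{i:08d}"
        reads.append(SimRead(rid, _apply_errors(rng, frag, q), q, chrom, start, strand))
        genome.truth.read_origins[rid] = (chrom, start, strand)
    return reads


# ---------------------------------------------------------------------------
# Surrogate annotator: a stand-in for an external repeat annotator, emitting
# records in RepeatMasker .out column layout so that real and surrogate
# annotation files are consumed identically downstream.
# ---------------------------------------------------------------------------

def _motif_coverage(seq: str, motif: str) -> np.ndarray:
    cov = np.zeros(len(seq), dtype=bool)
    for m in (motif, revcomp(motif)):
        start = 0
        while True:
            i = seq.find(m, start)
            if i < 0:
                break
            cov[i : i + len(m)] = True
            start = i + 1
    return cov


def surrogate_annotate(
    reads: Iterable, pentamer: str = PENTAMER, window: int = 25, density_min: float = 0.6
):
    """Annotate satellite segments on reads by pentamer density.

    Marks maximal intervals where the sliding-window density of the pentamer
    (or its reverse complement) is at least ``density_min``.  Defaults are
    chosen so a pure (CATTC)n read scores 1.0 and random sequence ~0.
    Returns a list of record dicts in RepeatMasker .out field layout
    (1-based inclusive query coordinates, strand 'C' for minus).
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    records = []
    for read in reads:
        seq = read.sequence if hasattr(read, "sequence") else str(read)
        rid = read.read_id if hasattr(read, "read_id") else "read"
        n = len(seq)
        if n < window:
            continue
        cov = _motif_coverage(seq, pentamer)
        kernel = np.ones(window)
        dens = np.convolve(cov.astype(float), kernel, mode="valid") / window
        hit = np.zeros(n, dtype=bool)
        for i in np.nonzero(dens >= density_min)[0]:
            hit[i : i + window] = True
        # merge into maximal intervals
        i = 0
        while i < n:
            if hit[i]:
                j = i
                while j < n and hit[j]:
                    j += 1
                sub = seq[i:j]
                fwd = sub.count(pentamer)
                rev = sub.count(revcomp(pentamer))
                name = f"({pentamer})n" if fwd >= rev else f"({revcomp(pentamer)})n"
                div = 100.0 * (1.0 - cov[i:j].mean())
                records.append(
                    {
                        "score": j - i,
                        "div": round(div, 1),
                        "del": 0.0,
                        "ins": 0.0,
                        "query": rid,
                        "qbegin": i + 1,
                        "qend": j,
                        "qleft": f"({n - j})",
                        "strand": "+" if fwd >= rev else "C",
                        "name": name,
                        "family": "Satellite",
                        "rbegin": 1,
                        "rend": j - i,
                        "rleft": "(0)",
                        "id": len(records) + 1,
                    }
                )
                i = j
            else:
                i += 1
    return records


def truth_annotations(genome: SimGenome, reads: Iterable[SimRead]):
    """Annotation records derived from the simulation ground truth.

    Marks, for each read, the parts overlapping a planted satellite array —
    what a repeat annotator with a perfect consensus would report.  Records
    use the same .out field layout as `surrogate_annotate`; strand reflects
    the read's sampling strand ('C' for reads drawn from the reverse
    strand, where the pentamer appears as its reverse complement).
    """
    records = []
    for r in reads:
        arrays = genome.truth.arrays_on(r.chrom)
        n = len(r.sequence)
        g0, g1 = r.start, r.start + n
        for chrom, a0, a1, sid, _unit in arrays:
            s, e = max(g0, a0), min(g1, a1)
            if e - s <= 0:
                continue
            if r.strand == "+":
                q0, q1 = s - g0, e - g0
            else:
                q0, q1 = g1 - e, g1 - s
            records.append(
                {
                    "score": e - s,
                    "div": 0.0,
                    "del": 0.0,
                    "ins": 0.0,
                    "query": r.read_id,
                    "qbegin": q0 + 1,
                    "qend": q1,
                    "qleft": f"({n - q1})",
                    "strand": "+" if r.strand == "+" else "C",
                    "name": f"({PENTAMER})n",
                    "family": "Satellite",
                    "rbegin": 1,
                    "rend": e - s,
                    "rleft": "(0)",
                    "id": len(records) + 1,
                }
            )
    return records


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeatmasker_out(records, path):
    """Write annotation records in RepeatMasker .out layout (3 header lines)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for r in records:
            fh.write(
                f"{r['score']:>5d} {r['div']:>5.1f} {r['del']:>4.1f} {r['ins']:>4.1f}"
                f"  {r['query']}  {r['qbegin']:>7d} {r['qend']:>7d} {r['qleft']:>9}"
                f" {r['strand']} {r['name']:<18} {r['family']:<18}"
                f" {r['rbegin']:>5} {r['rend']:>4} {r['rleft']:>6} {r['id']:>5d}\n"
            )


def write_fastq(reads: Iterable[SimRead], path):
    """Write reads as phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(33 + int(q)) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_pair_table(pairs, path):
    with open(path, "w") as fh:
        fh.write("read_id\tmate_id\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
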