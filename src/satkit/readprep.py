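"""Satellite read identification, masking and orientation.

Two independent screens find satellite-containing reads: annotation records
from a RepeatMasker-style ``.out`` file (real or the surrogate annotator),
and a Poisson model of pentamer (CATTC/GAATG) enrichment per read.  Accepted
reads are reverse-complemented onto the CATTC-dominant strand, and all bases
that are low quality or outside annotated satellite segments are masked;
short high-quality non-satellite islands inside satellite runs are unmasked
so diverged subsequences are not lost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import revcomp
from .simdata import PENTAMER

#: Annotation names treated as satellite matches.
SATELLITE_NAMES = {"HSATII", "(CATTC)n", "(GAATG)n"}


@dataclass
class SatAnnotation:
    read_id: str
    intervals: list = field(default_factory=list)  # (start, end, name, strand)
    percent_identity: list = field(default_factory=list)

    def satellite_intervals(self, names=SATELLITE_NAMES):
        return [iv for iv in self.intervals if iv[2] in names]


@dataclass
class ScreenModel:
    """Poisson background model for per-read pentamer counts.

    The detection threshold t is the smallest count for which the expected
    number of background reads reaching it across the whole dataset does not
    exceed the false-positive budget:
    t = min{t : N * P(X >= t; lambda_bg) <= fp_budget}.
    """

    lambda_bg: float
    dataset_size: int
    fp_budget: float = 1.0
    threshold: int | None = None

    def fit_threshold(self) -> int:
        if self.lambda_bg <= 0:
            raise ValueError("lambda_bg must be positive")
        t = 0
        # sf(t-1) = P(X >= t)
        while self.dataset_size * stats.poisson.sf(t - 1, self.lambda_bg) > self.fp_budget:
            t += 1
        self.threshold = t
        return t


@dataclass
class PreprocessParams:
    phred_min: int = 20
    unmask_max_gap: int = 100
    min_hq_run: int = 75
    min_match_run: int = 20

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class MaskedRead:
    """An oriented read with per-base quality and satellite mask.

    ``mask[i]`` is True where base i is a usable satellite base (annotated
    satellite or rescued island, and phred >= phred_min).  ``sequence`` is
    on the canonical CATTC-dominant strand.
    """

    read_id: str
    sequence: str
    quality: np.ndarray
    mask: np.ndarray
    mate_id: str | None = None
    rejection_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rejection_reason is None


def parse_repeatmasker_out(path) -> dict[str, SatAnnotation]:
    """Parse a RepeatMasker ``.out`` file into per-read annotations.

    Accepts real RepeatMasker output or the surrogate annotator's dialect.
    Query coordinates (1-based inclusive) are converted to 0-based half-open;
    strand 'C' maps to '-'.  Unannotated reads are simply absent.
    """
    annos: dict[str, SatAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("SW", "score")):
                continue
            parts = s.split()
            if len(parts) < 14:
                raise ValueError(f"malformed RepeatMasker line {lineno}: {line!r}")
            try:
                qbegin, qend = int(parts[5]), int(parts[6])
                pid = 100.0 - float(parts[1])
            except ValueError as e:
                raise ValueError(f"malformed RepeatMasker line {lineno}: {e}") from e
            rid = parts[4]
            strand = "-" if parts[8] == "C" else "+"
            name = parts[9]
            anno = annos.setdefault(rid, SatAnnotation(rid))
            anno.intervals.append((qbegin - 1, qend, name, strand))
            anno.percent_identity.append(pid)
    return annos


def annotations_from_records(records) -> dict[str, SatAnnotation]:
    """Build per-read annotations directly from annotator record dicts,
    skipping the .out file round trip."""
    annos: dict[str, SatAnnotation] = {}
    for r in records:
        anno = annos.setdefault(r["query"], SatAnnotation(r["query"]))
        strand = "-" if r["strand"] == "C" else "+"
        anno.intervals.append((r["qbegin"] - 1, r["qend"], r["name"], strand))
        anno.percent_identity.append(100.0 - r["div"])
    return annos


def pentamer_count(seq: str, pentamer: str = PENTAMER) -> int:
    """max(#pentamer, #reverse-complement), non-overlapping left-to-right."""
    return max(seq.count(pentamer), seq.count(revcomp(pentamer)))


def pentamer_screen(reads, pentamer: str = PENTAMER, model: ScreenModel | None = None):
    """Select satellite reads by pentamer enrichment over a Poisson background.

    ``reads`` maps read_id -> sequence (or is an iterable of objects with
    ``read_id``/``sequence``).  If ``model.lambda_bg`` is unset, it is fitted
    as the dataset mean count.  Returns ``(selected_ids, model)``.
    """
    if len(pentamer) != 5:
        raise ValueError("pentamer must have length 5")
    if hasattr(reads, "items"):
        items = list(reads.items())
    else:
        items = [(r.read_id, r.sequence) for r in reads]
    if not items:
        raise ValueError("reads must be non-empty")
    counts = {rid: pentamer_count(seq, pentamer) for rid, seq in items}
    if model is None:
        model = ScreenModel(lambda_bg=0.0, dataset_size=len(items))
    if model.lambda_bg <= 0:
        model.lambda_bg = float(np.mean(list(counts.values())))
    if model.threshold is None:
        model.fit_threshold()
    selected = [rid for rid, c in counts.items() if c >= model.threshold]
    return selected, model


def _runs(flags: np.ndarray):
    """Yield (start, end) for maximal True runs."""
    n = len(flags)
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def _max_run(flags: np.ndarray) -> int:
    return max((e - s for s, e in _runs(flags)), default=0)


def preprocess_read(
    read, annotation: SatAnnotation, params: PreprocessParams = PreprocessParams()
) -> MaskedRead:
    """Apply the masking/orientation/QC pipeline to a satellite read.

    Order of operations:
      1. reject reads with fewer than ``min_match_run`` continuous
         satellite-annotated bases ("short_match");
      2. set aside reads annotated on both strands ("both_strand"), which may
         be inversion breakpoints that would confound clustering;
      3. reverse-complement onto the CATTC-dominant strand;
      4. mask bases outside satellite annotation or with phred < phred_min;
      5. unmask internal high-quality non-satellite islands shorter than
         ``unmask_max_gap``;
      6. reject if no unmasked run reaches ``min_hq_run`` ("short_hq_run").

    Rejections are recorded as reasons on the returned MaskedRead, never
    raised.
    """
    seq = read.sequence
    qual = np.asarray(read.quality)
    mate = getattr(read, "mate_id", None)
    n = len(seq)
    sat = np.zeros(n, dtype=bool)
    by_strand = {"+": np.zeros(n, dtype=bool), "-": np.zeros(n, dtype=bool)}
    for s, e, name, strand in annotation.satellite_intervals():
        sat[s:e] = True
        by_strand[strand][s:e] = True

    def rejected(reason):
        return MaskedRead(read.read_id, seq, qual, np.zeros(n, dtype=bool), mate, reason)

    if _max_run(sat) < params.min_match_run:
        return rejected("short_match")
    if (
        _max_run(by_strand["+"]) >= params.min_match_run
        and _max_run(by_strand["-"]) >= params.min_match_run
    ):
        return rejected("both_strand")

    n_fwd = seq.count(PENTAMER)
    n_rev = seq.count(revcomp(PENTAMER))
    if n_rev > n_fwd:
        seq = revcomp(seq)
        qual = qual[::-1]
        sat = sat[::-1]

    mask = sat & (qual >= params.phred_min)
    # rescue short internal high-quality non-satellite islands
    hq_nonsat = (~sat) & (qual >= params.phred_min)
    for s, e in _runs(hq_nonsat):
        internal = s > 0 and e < n and mask[s - 1] and mask[e]
        if internal and (e - s) < params.unmask_max_gap:
            mask[s:e] = True
    out = MaskedRead(read.read_id, seq, qual, mask, mate, None)
    if _max_run(mask) < params.min_hq_run:
        out.rejection_reason = "short_hq_run"
        out.mask = np.zeros(n, dtype=bool)
    return out


def orient_and_dedupe(masked_reads, pairs, clone_key=None):
    """Remove duplicate reads and restrict the pair table to survivors.

    Duplicates share a read_id or the same clone-end key (``clone_key`` maps
    read_id -> hashable key; when absent, exact sequence identity is the
    fallback key).  First occurrence wins.  Orientation onto the CATTC
    strand has already happened in preprocess_read; reads are re-checked
    and flipped here if needed so the operation is safe standalone.
    """
    seen_ids = set()
    seen_keys = set()
    kept = []
    for mr in masked_reads:
        if mr.read_id in seen_ids:
            continue
        key = clone_key(mr.read_id) if clone_key else mr.sequence
        if key in seen_keys:
            continue
        seen_ids.add(mr.read_id)
        seen_keys.add(key)
        if mr.sequence.count(revcomp(PENTAMER)) > mr.sequence.count(PENTAMER):
            mr = MaskedRead(
                mr.read_id,
                revcomp(mr.sequence),
                np.asarray(mr.quality)[::-1],
                np.asarray(mr.mask)[::-1],
                mr.mate_id,
                mr.rejection_reason,
            )
        kept.append(mr)
    kept_ids = {mr.read_id for mr in kept}
    pairs_kept = [(a, b) for a, b in pairs if a in kept_ids and b in kept_ids]
    return kept, pairs_kept


def write_masked_fasta(masked_reads, path):
    """Masked FASTA: masked-out bases lowercase, usable bases uppercase."""
    with open(path, "w") as fh:
        for mr in masked_reads:
            chars = [
                c.upper() if m else c.lower() for c, m in zip(mr.sequence, mr.mask)
            ]
            fh.write(f">{mr.read_id}\n{''.join(chars)}\n")


def write_rejection_report(masked_reads, path):
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for mr in masked_reads:
            if mr.rejection_reason:
                fh.write(f"{mr.read_id}\t{mr.rejection_reason}\n")
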