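"""Subfamily-diagnostic 24-mer libraries.

From each subfamily's read set, high-quality 24-mer windows (all bases
unmasked and phred above threshold) are collected.  A 24-mer is
subfamily-specific when it appears on more than ``in_frac`` of that
subfamily's reads, on at most ``out_frac`` of reads in every other
subfamily, on no non-satellite read, and on at least ``min_read_support``
reads overall (filtering likely sequencing errors).  Libraries drive both
assembly-sequence classification (perfect matches, both strands) and
array-size estimation from short reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, kmer_codes, code_to_kmer, revcomp


@dataclass
class LibraryParams:
    kmer_len: int = 24
    phred_min: int = 20  # windows require phred strictly above this
    min_read_support: int = 2
    in_frac: float = 0.01
    out_frac: float = 0.001

    def __post_init__(self):
        if not 0 < self.out_frac < self.in_frac <= 1:
            raise ValueError("require 0 < out_frac < in_frac <= 1")


@dataclass
class KmerLibrary:
    subfamily_id: object
    kmers: set
    read_fraction: dict = field(default_factory=dict)
    window_fraction: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.kmers)


def collect_hq_kmers(read, params: LibraryParams = LibraryParams()):
    """All high-quality k-mer windows of a read, in order.

    A window qualifies when every base is A/C/G/T, unmasked (if the read
    carries a mask), and has phred strictly greater than ``phred_min``.
    """
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    k = params.kmer_len
    qual = np.asarray(getattr(read, "quality", np.full(len(seq), 60)))
    mask = getattr(read, "mask", None)
    hq = qual > params.phred_min
    if mask is not None:
        hq = hq & np.asarray(mask)
    codes, ok = kmer_codes(encode(seq), k, valid=hq)
    return [code_to_kmer(int(c), k) for c in codes[ok]]


def _per_subfamily_counts(read_sets, params):
    """Per subfamily: reads-with-windows count, per-kmer read and window counters."""
    stats = {}
    for sid, reads in read_sets.items():
        read_counts: Counter = Counter()
        window_counts: Counter = Counter()
        n_reads = 0
        for r in reads:
            wins = collect_hq_kmers(r, params)
            if not wins:
                continue
            n_reads += 1
            window_counts.update(wins)
            read_counts.update(set(wins))
        stats[sid] = (n_reads, read_counts, window_counts)
    return stats


def build_specific_library(
    subfamily_reads: dict,
    nonsat_reads=(),
    params: LibraryParams = LibraryParams(),
) -> dict:
    """Build a diagnostic 24-mer library for every subfamily.

    ``subfamily_reads`` maps subfamily id -> iterable of masked reads;
    ``nonsat_reads`` is a sample of reads without satellite annotation whose
    k-mers are banned outright.  Read-fraction denominators count reads
    with at least one HQ window.
    """
    if len(subfamily_reads) < 2:
        raise ValueError("need at least 2 subfamilies")
    stats = _per_subfamily_counts(subfamily_reads, params)
    for sid, (n, _, _) in stats.items():
        if n == 0:
            raise ValueError(f"subfamily {sid!r} has no reads with HQ windows")
    banned = set()
    for r in nonsat_reads:
        seq = r.sequence if hasattr(r, "sequence") else str(r)
        for s in (seq, revcomp(seq)):
            codes, ok = kmer_codes(encode(s), params.kmer_len)
            banned.update(code_to_kmer(int(c), params.kmer_len) for c in codes[ok])
    total_read_support: Counter = Counter()
    for _, read_counts, _ in stats.values():
        total_read_support.update(read_counts)
    libraries = {}
    for sid, (n_s, rc_s, wc_s) in stats.items():
        total_windows = sum(wc_s.values())
        kmers = set()
        rfrac, wfrac = {}, {}
        for kmer, c in rc_s.items():
            f_in = c / n_s
            if f_in <= params.in_frac:
                continue
            if total_read_support[kmer] < params.min_read_support:
                continue
            if kmer in banned:
                continue
            if any(
                stats[t][1][kmer] / stats[t][0] > params.out_frac
                for t in stats
                if t != sid
            ):
                continue
            kmers.add(kmer)
            rfrac[kmer] = f_in
            wfrac[kmer] = wc_s[kmer] / total_windows
        libraries[sid] = KmerLibrary(sid, kmers, rfrac, wfrac)
    return libraries


def multiset_overlap(small: Counter, large: Counter) -> float:
    """Containment of the smaller multiset in the larger, without replacement.

    sum_k min(mult_small[k], mult_large[k]) / total_small.
    """
    total = sum(small.values())
    if total == 0:
        return float("nan")
    matched = sum(min(c, large[k]) for k, c in small.items())
    return matched / total


def library_stats(subfamily_reads: dict, params: LibraryParams = LibraryParams()):
    """Fold compression per subfamily and the pairwise window-overlap matrix.

    Fold compression = (total HQ windows) / (distinct 24-mers), a measure of
    self-similarity.  overlap[S, T] is the containment of the smaller of the
    two window multisets in the larger.
    """
    stats = _per_subfamily_counts(subfamily_reads, params)
    sids = list(stats)
    fold = {}
    for sid in sids:
        wc = stats[sid][2]
        total = sum(wc.values())
        fold[sid] = total / len(wc) if wc else float("nan")
    k = len(sids)
    overlap = np.full((k, k), np.nan)
    for i, a in enumerate(sids):
        for j, b in enumerate(sids):
            if i == j:
                continue
            wa, wb = stats[a][2], stats[b][2]
            if sum(wa.values()) <= sum(wb.values()):
                overlap[i, j] = multiset_overlap(wa, wb)
            else:
                overlap[i, j] = multiset_overlap(wb, wa)
    return fold, overlap, sids


def classify_sequence(sequence: str, libraries: dict):
    """Assign a sequence to the subfamily with most perfect 24-mer matches.

    Matches are counted over every window on both strands.  Ties and zero
    hits yield "unassigned".  Returns ``(assignment, hit_counts)``.
    """
    if not libraries:
        raise ValueError("libraries must be non-empty")
    k = next(iter(libraries.values()))
    klen = LibraryParams().kmer_len
    if k.kmers:
        klen = len(next(iter(k.kmers)))
    lookup: dict[str, set] = {}
    for sid, lib in libraries.items():
        for kmer in lib.kmers:
            lookup.setdefault(kmer, set()).add(sid)
            lookup.setdefault(revcomp(kmer), set()).add(sid)
    hits = {sid: 0 for sid in libraries}
    for i in range(len(sequence) - klen + 1):
        w = sequence[i : i + klen]
        for sid in lookup.get(w, ()):
            hits[sid] += 1
    best = max(hits.values(), default=0)
    if best == 0:
        return "unassigned", hits
    top = [sid for sid, c in hits.items() if c == best]
    if len(top) > 1:
        return "unassigned", hits
    return top[0], hits


def write_library_tsv(libraries: dict, path):
    with open(path, "w") as fh:
        fh.write("kmer\tsubfamily\tread_fraction\twindow_fraction\n")
        for sid, lib in libraries.items():
            for kmer in sorted(lib.kmers):
                fh.write(
                    f"{kmer}\t{sid}\t{lib.read_fraction[kmer]:.6g}\t"
                    f"{lib.window_fraction[kmer]:.6g}\n"
                )


def read_library_tsv(path) -> dict:
    libraries: dict = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            kmer, sid, rf, wf = line.rstrip("\n").split("\t")
            lib = libraries.setdefault(sid, KmerLibrary(sid, set()))
            lib.kmers.add(kmer)
            lib.read_fraction[kmer] = float(rf)
            lib.window_fraction[kmer] = float(wf)
    return libraries
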