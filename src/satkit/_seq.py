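"""Low-level sequence encoding helpers shared across modules.

Bases are encoded A=0, C=1, G=2, T=3 (lexicographic); anything else maps
to 4 and is treated as invalid by every k-mer routine.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to a uint8 array (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_codes(bases: np.ndarray, k: int, valid: np.ndarray | None = None):
    """Integer codes for every k-window of an encoded sequence.

    Returns ``(codes, ok)`` where ``codes[i]`` encodes ``bases[i:i+k]`` in
    base 4 (first base most significant) and ``ok[i]`` is True when all k
    bases are A/C/G/T and, if ``valid`` is given, all flagged valid.
    Windows with ``ok == False`` have unspecified codes.
    """
    n = len(bases) - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    good = bases < 4
    if valid is not None:
        good = good & valid
    b = np.where(good, bases, 0).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | b[j : j + n]
    ok = np.ones(n, dtype=bool)
    bad = ~good
    if bad.any():
        # window i is ok iff no bad base in [i, i+k)
        cum = np.concatenate([[0], np.cumsum(bad)])
        ok = (cum[k:] - cum[:-k]) == 0
    return codes, ok


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def kmer_to_code(kmer: str) -> int:
    c = 0
    for ch in kmer:
        c = (c << 2) | int(_ENCODE[ord(ch)])
    return c


def revcomp_code(code: int, k: int) -> int:
    """Code of the reverse complement k-mer."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def count_nonoverlapping(seq: str, motif: str) -> int:
    """Non-overlapping occurrences, left-to-right scan (str.count semantics)."""
    return seq.count(motif)
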