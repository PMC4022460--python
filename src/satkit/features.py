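"""k-mer composition vectors for masked reads.

Each read becomes a row in a reads x 4^k matrix of k-mer frequencies
(default k=5, hence 1,024 columns), counted only inside unmasked segments.
Rows are normalized to sum to 1, then columns are z-scored (population SD)
so that Euclidean distance in the standardized space is the clustering
metric.  PCA projection and circular clone tiling support visual inspection
of tandem-repeat ("ring") topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ._seq import encode, kmer_codes


@dataclass
class FeatureMatrix:
    read_ids: list
    values: np.ndarray
    k: int = 5
    state: str = "raw"  # raw | row_normalized | standardized
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    constant_columns: np.ndarray | None = None

    @property
    def n_reads(self):
        return self.values.shape[0]


def kmer_feature_matrix(masked_reads, k: int = 5) -> FeatureMatrix:
    """Count k-mers within unmasked segments and row-normalize.

    A window contributes only when all k of its bases are unmasked (and
    A/C/G/T).  Reads with zero countable windows are dropped with a warning.
    Column order is lexicographic over A<C<G<T.
    """
    if not 4 <= k <= 7:
        raise ValueError("k must be in [4, 7]")
    ncols = 4 ** k
    rows, ids, dropped = [], [], []
    for mr in masked_reads:
        seq = mr.sequence if hasattr(mr, "sequence") else str(mr)
        rid = getattr(mr, "read_id", f"read{len(ids)}")
        mask = np.asarray(getattr(mr, "mask", np.ones(len(seq), dtype=bool)))
        codes, ok = kmer_codes(encode(seq), k, valid=mask)
        nwin = int(ok.sum())
        if nwin == 0:
            dropped.append(rid)
            continue
        counts = np.bincount(codes[ok].astype(np.int64), minlength=ncols)
        rows.append(counts / nwin)
        ids.append(rid)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} reads with no countable {k}-mer windows")
    values = np.array(rows, dtype=np.float64) if rows else np.empty((0, ncols))
    return FeatureMatrix(ids, values, k=k, state="row_normalized")


def standardize_matrix(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column (population SD); constant columns become zero.

    Column means/SDs are retained so other read sets (e.g. WCS samples) can
    be projected into the same standardized basis.
    """
    if fm.state != "row_normalized":
        raise ValueError(f"expected row_normalized matrix, got state={fm.state!r}")
    means = fm.values.mean(axis=0)
    sds = fm.values.std(axis=0)  # population SD
    constant = sds == 0
    safe = np.where(constant, 1.0, sds)
    vals = (fm.values - means) / safe
    vals[:, constant] = 0.0
    return FeatureMatrix(
        list(fm.read_ids), vals, k=fm.k, state="standardized",
        column_means=means, column_sds=sds, constant_columns=constant,
    )


def standardize_with(fm: FeatureMatrix, means, sds) -> FeatureMatrix:
    """Standardize using a reference matrix's column means/SDs."""
    if fm.state != "row_normalized":
        raise ValueError(f"expected row_normalized matrix, got state={fm.state!r}")
    sds = np.asarray(sds)
    constant = sds == 0
    safe = np.where(constant, 1.0, sds)
    vals = (fm.values - np.asarray(means)) / safe
    vals[:, constant] = 0.0
    return FeatureMatrix(
        list(fm.read_ids), vals, k=fm.k, state="standardized",
        column_means=np.asarray(means), column_sds=sds, constant_columns=constant,
    )


def pca_project(fm: FeatureMatrix, n_components: int):
    """Exact-SVD PCA of a standardized matrix.

    Returns ``(coordinates, explained_variance_fractions)``.  Component signs
    are fixed so each component's largest-magnitude loading is positive,
    making the projection deterministic.
    """
    if fm.state != "standardized":
        raise ValueError("pca_project requires a standardized matrix")
    n, p = fm.values.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds matrix rank bound")
    u, s, vt = linalg.svd(fm.values, full_matrices=False)
    for j in range(len(s)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    coords = u[:, :n_components] * s[:n_components]
    evr = (s ** 2) / np.sum(s ** 2) if s.size else s
    return coords, evr[:n_components]


def tile_clone_reads(clone: str, read_len: int, step: int):
    """Tile fixed-length reads circularly along a clone sequence.

    Start positions are 0, step, 2*step, ... < len(clone); reads spanning the
    end wrap around (the clone is treated as one tandem unit), emulating
    reads sampled across consecutive copies of the repeat.  Returns a list
    of ``(start, sequence)``.
    """
    if not clone:
        raise ValueError("clone must be non-empty")
    if step < 1:
        raise ValueError("step must be >= 1")
    if read_len > 2 * len(clone):
        raise ValueError("read_len must not exceed twice the clone length")
    doubled = clone + clone
    return [(s, doubled[s : s + read_len]) for s in range(0, len(clone), step)]


def save_matrix_tsv(fm: FeatureMatrix, path):
    header = "read_id\t" + "\t".join(str(i) for i in range(fm.values.shape[1]))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for rid, row in zip(fm.read_ids, fm.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
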