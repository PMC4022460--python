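"""Ring topology of a tandem repeat in PCA projection.

Reads tiled circularly along one repeat unit trace a closed curve in the
first two principal components of 5-mer space whenever the unit is longer
than a read: each read covers a different phase of the repeat, and phases
wrap around.
"""

import numpy as np

from satkit import features, simdata

clone = simdata.gen_subfamily_units(1, 1770, 0.35, seed=3)[0]
tiles = features.tile_clone_reads(clone, read_len=600, step=10)
print(f"tiled {len(tiles)} reads of 600 bp along a {len(clone)} bp unit")

fm = features.standardize_matrix(
    features.kmer_feature_matrix([seq for _, seq in tiles], k=5)
)
coords, evr = features.pca_project(fm, 2)
print(f"PC1+PC2 explain {100 * evr.sum():.1f}% of variance")

ring = np.vstack([coords, coords[:1]])
gaps = np.linalg.norm(np.diff(ring, axis=0), axis=1)
print(f"largest gap along the ordered projection = {gaps.max():.2f}, "
      f"median gap = {np.median(gaps):.2f}")
# A closed ring keeps the largest gap comparable to the median gap; a broken
# arc (no tandem structure, or unit shorter than the read) would not.
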