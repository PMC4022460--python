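# Methods

`satkit` characterizes complex satellite DNA — families built from diverged
arrangements of a short ancestral repeat (here the pentamer CATTC) that lack
a consistent repeat-unit reference — directly from whole-genome shotgun
reads, without alignment or assembly. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
does and does not exercise.

## Read screening and masking

Satellite-containing reads are found two ways, which cross-validate each
other:

* **Annotation screen.** Reads carrying repeat-annotation intervals named
  `HSATII`, `(CATTC)n` or `(GAATG)n` (RepeatMasker `.out` layout; the
  package also ships a surrogate annotator that marks maximal intervals
  where the sliding-window density of the pentamer or its reverse
  complement is ≥ 0.6 in 25 bp windows — a pure pentamer run scores 1,
  random sequence ≈ 0).
* **Enrichment screen.** Per read, the count of non-overlapping CATTC
  occurrences (or GAATG, whichever is larger) is compared with a Poisson
  background with mean λ. The detection threshold is the smallest t with
  N·P(X ≥ t; λ) ≤ the false-positive budget (default: one expected false
  positive dataset-wide). λ, N and the budget are parameters; the
  threshold is computed, never hard-coded.

Accepted reads then pass a masking pipeline, in order: reject reads with
fewer than 20 continuous annotated satellite bases; set aside reads
annotated on both strands (candidate inversion breakpoints); reverse
complement onto the CATTC-dominant strand (strictly more CATTC than GAATG;
ties keep the input orientation); mask bases outside satellite annotation
or below phred 20; unmask internal high-quality non-satellite islands
shorter than 100 bp (diverged subsequences the annotator missed); reject
reads without a 75 bp continuous unmasked run. Rejections are recorded
reasons, not exceptions, and the pipeline is idempotent on its own accepted
output.

## Featurization

Each read becomes a row of a reads × 4^k matrix of k-mer frequencies
(default k = 5, 1,024 columns, lexicographic A<C<G<T), counting only
windows whose k bases are all unmasked. Rows are normalized to sum to 1
(window-count normalization; equivalent to length normalization up to a
constant absorbed by the next step), then columns are z-scored with the
population SD; constant columns are zeroed rather than dropped so 4^k
indexing is stable. Other read sets (WCS samples) are projected with the
reference's stored column means/SDs. PCA uses exact SVD with component
signs fixed by the largest-magnitude loading, so projections are
deterministic. Circular clone tiling (reads sampled at a fixed stride along
a doubled unit) reproduces the ring-shaped projection characteristic of a
tandem unit longer than a read.

## Clustering

Reads are vertices of a symmetric 50-nearest-neighbor graph under Euclidean
distance in the standardized space. Distances map to weights by
w = 1 − d/d_max with d_max the largest kNN-edge distance; this keeps
weights in (0, 1] (the single farthest edge is floored at 1e-12 rather
than dropped) and makes the mate-pair overlay weight of 1.0 the graph
maximum. Mate pairs — the two reads of one clone insert — are physical
linkage evidence: an insert shorter than the array it samples has both ends
in the same array.

Each node is split by the normalized-cut criterion: the second-smallest
generalized eigenvector of (D−W)v = μDv (computed via the symmetric
normalized Laplacian; dense eigensolver under 300 vertices, else ARPACK
with shift-invert and a deterministic start vector, falling back to the
smallest-algebraic mode), swept over all n−1 order-statistic thresholds
(512 quantile thresholds above 10,000 vertices) keeping the minimum-ncut
prefix. The sweep's incremental cut/volume update is O(E).

A split is accepted only if both daughters have at least `min_cluster_size`
members (default 2 × k_nn; a kNN graph on fewer points is degenerate) and
both daughters' self-mate-pair frequency exceeds 0.8. SMP of daughter A
against sibling B is (A→A)/(A→A + A→B): the fraction of mate pairs from A
staying in A, among pairs internal to the parent. The published definition
is stated once with a global denominator and once per-division; the
per-division (sibling-restricted) form is used for acceptance because a
cluster should not be penalized for pairs leading to clusters already
separated at a higher level — at the root the two forms coincide. Nodes
with no pairs (undefined SMP) are not split. Leaves are labeled by
decreasing size, ties by smallest member index.

The 0.8 gate is justified by simulation (`calibration.smp_for_array`):
paired reads from a genome with one contiguous array; cluster = reads with
≥ 75 bp inside the array; SMP rises monotonically with array length for a
fixed insert distribution and crosses ~0.9 at 100 kb with 5 kb ± 1 kb
inserts. Accepted clusters therefore correspond to contiguous arrays of
roughly ≥ 100 kb. Insert sizes are a knob: real Sanger libraries mix insert
sizes, and the calibration depends on them.

## Diagnostic 24-mer libraries

High-quality windows are 24-mers with every base unmasked and phred
strictly above 20. A 24-mer is subfamily-specific when present on > 1% of
the subfamily's reads, on ≤ 0.1% of reads of every other subfamily, on no
non-satellite read, and on ≥ 2 reads overall (sequencing-error filter).
Read-fraction denominators count reads with at least one HQ window.
Summary statistics: fold compression = total HQ windows / distinct
24-mers (self-similarity; ≥ 1, = 1 iff all windows distinct), and pairwise
overlap = multiset containment of the smaller subfamily's windows in the
larger's, Σ min(multiplicities)/total_small. Classification of an arbitrary
sequence counts exact matches to each library on both strands and assigns
the argmax; ties and zero hits are "unassigned".

## Chromosomal localization

Flow-sorted chromosome (WCS) libraries are impure, so localization is
inferential. Each WCS read inherits the subfamily of its nearest reference
read (brute-force NN in the shared standardized space; ties to the smallest
reference index). The mixing matrix row X_i is the sample's estimated
read-origin proportions: per-chromosome unique-base coverage × chromosome
size, row-normalized.

Per subfamily, sample counts follow y_i | β ~ Binomial(n_i, X_i·β) where
β_c is the fraction of chromosome c occupied by the subfamily, with
independent truncated-uniform priors on (1e-8, 0.5) — no satellite family
occupies more than half a chromosome; the lower bound avoids log(0). The
posterior is sampled by random-walk Metropolis-within-Gibbs on the logit
scale of the rescaled coordinate (the transform's Jacobian enters the
acceptance ratio; since each β_c ≤ 0.5 and X rows sum to 1, X_i·β is
always a valid probability). Step sizes adapt every 50 iterations during
burn-in (×1.3 above 50% acceptance, ×0.7 below 25%) and are frozen after.
Defaults are 4 chains × 16,000 iterations, 1,000 burn-in, with retained
draws evenly spaced post-burn-in and forced to exactly 3,000 pooled across
chains. Convergence is monitored with split-R̂ (flagged above 1.1, not
fatal). 95% HPD intervals are the shortest windows over the sorted draws.
Abundance in kb is median(β_c) × chromosome size.

Unmapped scaffolds are localized with a Poisson model: under "scaffold on
chromosome c", the sample-i count of reads hitting the scaffold's U unique
24-mers is Poisson(n_i · X_ic · U / L_c), with L_c the chromosome's
mappable length — the rate parameterization is this package's
reconstruction, stated here prominently since the original model
specification is not reproducible from the main text. A uniform prior over
chromosomes gives the posterior by direct normalization; chromosomes with
probability ≥ 0.9 are assigned. Known-discordant assignments can be
removed with a user-supplied blacklist; no biology is hard-coded.

## Array sizing

For an individual's short-read dataset, with M library-matching out of T
total HQ 24-mer windows, the array size is (M/T)/ρ × G, where ρ is the
fraction of HQ windows on the subfamily's own reference reads that match
the library (computed, for synthetic subfamilies, by the same window
counting; the published value for the human Y-chromosome subfamily is
0.459) and G the genome size (5,976,710,698 bp for a diploid male on
hg19). The estimator is unbiased under uniform coverage:
E[M/T] = ρ · array_bp / G.

Coverage bias is calibrated with single-copy control 24-mers drawn from a
reference, AT-matched to the target library (stratified by AT count 0–24,
proportional allocation with largest-remainder rounding; strata short of
unique candidates borrow from others with a warning). Controls in the
bottom/top 0.5% of total male coverage, or with > 10 total hits in female
samples (for Y-linked targets), are dropped. The control-region size is
estimated per male by the same M/T calculation with ρ = 1 (each retained
unique 24-mer contributes one mappable position, so the true size is the
retained-control count unless supplied); the signed mean relative error
rescales all estimates, and samples with |error| > 30% are excluded
(signed error for correction, absolute for exclusion).

Group comparisons use two-sided two-sample Wilcoxon rank-sum tests — exact
enumeration when the smaller group has ≤ 10 members and there are no ties,
else the normal approximation with continuity correction — over all group
pairs with ≥ 2 members, Holm-corrected.

## Synthetic data: what it emulates, and what it does not

The generator plants tandem arrays of pentamer-derived units (ancestral
CATTC concatenated to the unit length, mutated i.i.d. at a chosen
divergence) in i.i.d. background of specified GC, and simulates: Sanger-like
paired reads (truncated-normal lengths, mean 877 bp; truncated-normal
inserts, default mean 5 kb, sd 1 kb; default 7.8× coverage; ~35% of reads
unpaired; two-level phred model with substitution errors at the rate each
phred value implies), WCS samples with an explicit mixing vector, and
fixed-length single-end short reads. Everything is recorded as ground
truth (array intervals, read origins, mixing vectors, array bp) and all
output is byte-deterministic given a seed.

Not emulated: indels and chimeric reads (substitution-only errors keep
k-mer oracles exact), cloning and GC coverage bias (the control-calibration
machinery is therefore exercised with engineered biases, not emergent
ones), 1-away variant repeat arrays (the optional variant-read recovery of
real pipelines is out of scope here), realistic flow-sorting contamination
structure beyond an arbitrary mixing vector, and real subfamily phylogeny
(units are independent draws from the ancestor, not a nested tree, except
where tests build hierarchies explicitly). Passing tests therefore
demonstrate correctness of the algorithms under the stated models, not
performance on real trace archives.

## Problem sizes and numerical choices

Benchmarks are sized for a single CPU: planted-subfamily recovery uses six
420 kb arrays at 7.8× (~18–20k clustered reads); the sizing benchmark
plants a 25 Mb array in a 30 Mb genome read at 0.5×, averaged over 10 read
seeds; posterior-calibration replicates use 2 chains × 4,000 iterations
(the conjugate-oracle comparison runs the full default 4 × 16,000).
Tolerances: row sums to 1 within 1e-9; standardized columns mean 0 ± 1e-9,
variance 1 ± 1e-6; eigensolver tolerance 1e-8; MCMC median vs conjugate
oracle ± 0.002 at 3,000 retained draws. Degenerate inputs: all-identical
points give an all-weight-1 graph; disconnected graphs split along
components at ncut 0; reads with no countable windows are dropped with a
warning; zero-denominator SMP is missing, not 0.

## Known limitations

The 0.8 SMP gate and the ≥ 100 kb array-length interpretation are tied to
the insert-length distribution; libraries with very different inserts need
recalibration via `calibration.smp_curve`. The scaffold-localization rate
model is a documented reconstruction. The Poisson screen threshold for the
published human dataset parameters (λ = 2.37, N = 32M, budget 1) computes
to 16; published analyses have used nearby values, so the threshold is
always reported, never assumed. Exact Wilcoxon switches to the normal
approximation in the presence of ties even for small groups.
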