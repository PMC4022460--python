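"""Chromosomal localization from whole-chromosome shotgun (WCS) samples.

Flow-sorted chromosome libraries are imperfectly pure, so per-sample
subfamily read counts are modeled as binomial draws whose success
probability mixes the per-chromosome satellite proportions (beta) through
the sample's chromosome mixing vector:

    y_i | beta ~ Binomial(n_i, X_i . beta)

with independent truncated-uniform priors beta_c ~ U(1e-8, 0.5).  The
posterior is sampled by random-walk Metropolis-within-Gibbs on the logit
scale (adaptive step during burn-in, frozen afterward).  Unmapped scaffolds
are localized with a Poisson likelihood over their unique-24-mer read
counts and a uniform prior over chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import FeatureMatrix


@dataclass
class MixingMatrix:
    X: np.ndarray  # samples x chromosomes, rows sum to 1
    sample_ids: list
    chrom_names: list
    chrom_sizes: np.ndarray


@dataclass
class CountTable:
    y: np.ndarray  # samples x subfamilies
    n: np.ndarray  # total screened reads per sample
    sample_ids: list
    subfamily_ids: list


@dataclass
class McmcSettings:
    chains: int = 4
    iterations: int = 16000
    burn_in: int = 1000
    retained: int = 3000
    seed: int = 0


@dataclass
class PosteriorSummary:
    samples: np.ndarray  # retained x chromosomes
    median: np.ndarray
    hpd_low: np.ndarray
    hpd_high: np.ndarray
    rhat: np.ndarray
    settings: McmcSettings
    chrom_names: list = field(default_factory=list)

    def kb_estimates(self, chrom_sizes) -> pd.DataFrame:
        """Median and 95% HPD abundance per chromosome, in kb."""
        sizes = np.asarray(chrom_sizes, dtype=float)
        return pd.DataFrame(
            {
                "chrom": self.chrom_names or list(range(len(self.median))),
                "median_kb": self.median * sizes / 1e3,
                "hpd_low_kb": self.hpd_low * sizes / 1e3,
                "hpd_high_kb": self.hpd_high * sizes / 1e3,
            }
        )


def assign_wcs_reads(
    wcs_fm: FeatureMatrix, ref_fm: FeatureMatrix, ref_labels, sample_of_read=None
):
    """Label each WCS read with its nearest reference read's subfamily.

    Both matrices must share k and the reference's standardization basis
    (use ``features.standardize_with`` on the WCS matrix).  Ties go to the
    smallest reference index.  Returns the label array, or a CountTable
    when ``sample_of_read`` maps read ids to sample ids.
    """
    if wcs_fm.k != ref_fm.k:
        raise ValueError("feature matrices must share k")
    nn = NearestNeighbors(n_neighbors=1, algorithm="brute")
    nn.fit(ref_fm.values)
    dist, idx = nn.kneighbors(wcs_fm.values)
    ref_labels = np.asarray(ref_labels)
    labels = ref_labels[idx[:, 0]]
    if sample_of_read is None:
        return labels
    samples = sorted({sample_of_read[r] for r in wcs_fm.read_ids})
    subfams = sorted(set(ref_labels.tolist()))
    y = np.zeros((len(samples), len(subfams)), dtype=int)
    n = np.zeros(len(samples), dtype=int)
    srow = {s: i for i, s in enumerate(samples)}
    scol = {s: j for j, s in enumerate(subfams)}
    for rid, lab in zip(wcs_fm.read_ids, labels):
        i = srow[sample_of_read[rid]]
        n[i] += 1
        y[i, scol[lab]] += 1
    return CountTable(y, n, samples, subfams)


def estimate_mixing_matrix(coverage: pd.DataFrame, chrom_sizes) -> MixingMatrix:
    """Mixing proportions from per-sample per-chromosome unique-base coverage.

    X_ic is proportional to coverage_ic times chromosome size, row-normalized
    — the expected share of the sample's reads per chromosome if every
    chromosome were fully mappable.
    """
    cov = coverage.to_numpy(dtype=float)
    if (cov < 0).any():
        raise ValueError("coverage must be non-negative")
    sizes = np.asarray([chrom_sizes[c] for c in coverage.columns], dtype=float)
    raw = cov * sizes
    totals = raw.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(coverage.index, totals) if t == 0]
        raise ValueError(f"uninformative sample(s) with zero coverage: {bad}")
    return MixingMatrix(
        raw / totals[:, None], list(coverage.index), list(coverage.columns), sizes
    )


def _hpd(samples: np.ndarray, mass: float = 0.95):
    """Shortest interval containing the requested posterior mass."""
    x = np.sort(samples)
    n = len(x)
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        return x[0], x[-1]
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return x[i], x[i + m]


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    half = chains.shape[1] // 2
    if half < 2:
        return float("nan")
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def sample_beta_posterior(
    counts,
    mixing,
    prior=(1e-8, 0.5),
    settings: McmcSettings = McmcSettings(),
    subfamily=None,
) -> PosteriorSummary:
    """Sample the per-chromosome abundance posterior for one subfamily.

    ``counts`` is either a CountTable (with ``subfamily`` choosing a column)
    or a pair ``(y, n)`` of per-sample vectors; ``mixing`` is a MixingMatrix
    or a row-stochastic array.  Returns retained posterior draws pooled
    across chains (exactly ``settings.retained`` of them, split evenly),
    medians, 95% HPD bounds, and a split-R-hat per chromosome.
    """
    if isinstance(counts, CountTable):
        j = counts.subfamily_ids.index(subfamily) if subfamily is not None else 0
        y = counts.y[:, j].astype(float)
        n = counts.n.astype(float)
    else:
        y, n = (np.asarray(v, dtype=float) for v in counts)
    X = mixing.X if isinstance(mixing, MixingMatrix) else np.asarray(mixing, dtype=float)
    chrom_names = mixing.chrom_names if isinstance(mixing, MixingMatrix) else []
    if X.shape[0] != len(y):
        raise ValueError("sample dimension mismatch between counts and mixing")
    lo, hi = prior
    span = hi - lo
    nchains = settings.chains
    iters = settings.iterations
    burn = settings.burn_in
    per_chain = settings.retained // nchains
    extra = settings.retained - per_chain * nchains
    c_dim = X.shape[1]
    rng = np.random.default_rng(settings.seed)
    all_kept = []
    chain_draws = []

    def loglik(p):
        return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))

    for chain in range(nchains):
        crng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        beta = lo + span * crng.uniform(0.01, 0.2, size=c_dim)
        u = np.log((beta - lo) / (hi - beta))
        p = X @ beta
        ll = loglik(p)
        # log prior on u-scale: Jacobian of the logit transform
        ljac = float(np.sum(np.log(beta - lo) + np.log(hi - beta)))
        step = np.full(c_dim, 0.5)
        acc = np.zeros(c_dim)
        tries = np.zeros(c_dim)
        kept = []
        keep_n = per_chain + (1 if chain < extra else 0)
        post = iters - burn
        keep_idx = set((burn + np.linspace(0, post - 1, keep_n).astype(int)).tolist())
        for it in range(iters):
            for c in range(c_dim):
                u_new = u[c] + step[c] * crng.standard_normal()
                b_new = lo + span / (1.0 + math.exp(-u_new))
                p_new = p + X[:, c] * (b_new - beta[c])
                ll_new = float(np.sum(y * np.log(p_new) + (n - y) * np.log1p(-p_new)))
                ljac_c_old = math.log(beta[c] - lo) + math.log(hi - beta[c])
                ljac_c_new = math.log(b_new - lo) + math.log(hi - b_new)
                tries[c] += 1
                if math.log(crng.uniform()) < (ll_new + ljac_c_new) - (ll + ljac_c_old):
                    u[c], beta = u_new, beta.copy()
                    beta[c] = b_new
                    p, ll = p_new, ll_new
                    acc[c] += 1
            if it < burn and (it + 1) % 50 == 0:
                rate = acc / np.maximum(tries, 1)
                step *= np.where(rate > 0.5, 1.3, np.where(rate < 0.25, 0.7, 1.0))
                acc[:] = 0
                tries[:] = 0
            if it in keep_idx:
                kept.append(beta.copy())
        kept = np.array(kept)
        all_kept.append(kept)
        chain_draws.append(kept)
    samples = np.concatenate(all_kept, axis=0)
    assert samples.shape[0] == settings.retained
    min_len = min(c.shape[0] for c in chain_draws)
    stacked = np.stack([c[:min_len] for c in chain_draws])  # chains x draws x dims
    rhat = np.array([_split_rhat(stacked[:, :, c]) for c in range(c_dim)])
    med = np.median(samples, axis=0)
    lo95 = np.empty(c_dim)
    hi95 = np.empty(c_dim)
    for c in range(c_dim):
        lo95[c], hi95[c] = _hpd(samples[:, c])
    return PosteriorSummary(samples, med, lo95, hi95, rhat, settings, chrom_names)


@dataclass
class ScaffoldCall:
    scaffold_id: str
    unique_kmers: int
    probabilities: np.ndarray
    chrom_names: list
    assigned: list


def localize_scaffold(
    counts,
    unique_kmers: int,
    mixing: MixingMatrix,
    sample_totals,
    mappable_lengths,
    scaffold_id: str = "scaffold",
    assign_min_prob: float = 0.9,
) -> ScaffoldCall:
    """Posterior chromosome-of-origin for an unmapped scaffold.

    Under hypothesis "scaffold on chromosome c", the sample-i count of reads
    hitting the scaffold's unique 24-mers is Poisson with rate
    n_i * X_ic * U / L_c, where U is the scaffold's unique-24-mer count and
    L_c the chromosome's mappable length.  A uniform prior over chromosomes
    gives the posterior by direct normalization; chromosomes with posterior
    probability at least ``assign_min_prob`` are assigned.
    """
    if unique_kmers < 1:
        raise ValueError("need at least one unique 24-mer")
    counts = np.asarray(counts, dtype=float)
    n_i = np.asarray(sample_totals, dtype=float)
    L = np.asarray(mappable_lengths, dtype=float)
    X = mixing.X
    logpost = np.empty(X.shape[1])
    for c in range(X.shape[1]):
        lam = n_i * X[:, c] * unique_kmers / L[c]
        lam = np.maximum(lam, 1e-300)
        logpost[c] = float(np.sum(counts * np.log(lam) - lam))
    logpost -= logpost.max()
    probs = np.exp(logpost)
    probs /= probs.sum()
    assigned = [
        mixing.chrom_names[c] for c in range(len(probs)) if probs[c] >= assign_min_prob
    ]
    return ScaffoldCall(scaffold_id, unique_kmers, probs, list(mixing.chrom_names), assigned)


def wcs_coverage_table(read_origins, sample_of_read, chrom_lengths) -> pd.DataFrame:
    """Per-sample per-chromosome coverage from known read origins.

    Convenience for simulated data: coverage_ic = (bases from chromosome c
    in sample i) / length of c.  ``read_origins`` maps read_id ->
    (chrom, start, strand) and read length is not tracked here, so each
    read contributes one unit; with fixed read length this is proportional
    to base coverage, which is all the mixing estimate needs.
    """
    samples = sorted(set(sample_of_read.values()))
    chroms = list(chrom_lengths)
    counts = pd.DataFrame(0.0, index=samples, columns=chroms)
    for rid, sample in sample_of_read.items():
        chrom = read_origins[rid][0]
        counts.loc[sample, chrom] += 1.0
    return counts.div(pd.Series(chrom_lengths), axis=1)
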