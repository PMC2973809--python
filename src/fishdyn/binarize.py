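"""Thresholding count data into burst indicators and estimating moments.

In the bursty regime all usable information in pairwise FISH data is carried
by, per gene, the probability p̂_i that its count exceeds a threshold m_i
(its pooled median by default), and, per gene pair, the covariance ĉ_ij of
the resulting burst indicators.  Same-gene coincidences are never observed,
so the diagonal of ĉ is unavailable; downstream fitting and PCA must work
with the off-diagonal entries plus their sampling variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import PairObservationSet

__all__ = [
    "MomentEstimates",
    "compute_thresholds",
    "binarize",
    "estimate_cov_variance",
    "estimate_moments",
]

#: variance floor, in units of one coincidence count (see
#: :func:`estimate_cov_variance`)
DEFAULT_VARIANCE_EPS = 0.25


@dataclass
class MomentEstimates:
    """Binarized means, pairwise covariances and their uncertainties.

    ``c_hat``/``c_var`` are symmetric with NaN on the diagonal (unobservable
    from pairwise data) and on pairs never probed; ``n_obs_pair[i, j]`` is 0
    for such pairs.  ``var_floored`` marks pairs whose variance hit the
    zero-coincidence floor.
    """

    gene_names: list[str]
    p_hat: np.ndarray
    c_hat: np.ndarray
    c_var: np.ndarray
    n_obs_pair: np.ndarray
    n_obs_gene: np.ndarray
    thresholds: np.ndarray
    var_floored: np.ndarray

    def __post_init__(self):
        self.p_hat = np.asarray(self.p_hat, dtype=float)
        self.c_hat = np.asarray(self.c_hat, dtype=float)
        self.c_var = np.asarray(self.c_var, dtype=float)
        self.n_obs_pair = np.asarray(self.n_obs_pair, dtype=int)
        self.n_obs_gene = np.asarray(self.n_obs_gene, dtype=int)
        self.thresholds = np.asarray(self.thresholds)
        self.var_floored = np.asarray(self.var_floored, dtype=bool)
        off = ~np.eye(self.n_genes, dtype=bool)
        obs = (self.n_obs_pair > 0) & off
        if np.any(np.abs(self.c_hat[obs]) > 1.0 + 1e-12):
            raise ValueError("covariance estimates must lie in [-1, 1]")
        if np.any(self.c_var[obs] <= 0):
            raise ValueError("c_var must be positive where pairs are observed")
        if not np.array_equal(self.n_obs_pair, self.n_obs_pair.T):
            raise ValueError("n_obs_pair must be symmetric")

    @property
    def n_genes(self) -> int:
        return self.p_hat.size

    def observed_pairs(self) -> list[tuple[int, int]]:
        """Upper-triangle pairs with at least one observation."""
        n = self.n_genes
        return [(i, j) for i in range(n) for j in range(i + 1, n)
                if self.n_obs_pair[i, j] > 0]


def compute_thresholds(data: PairObservationSet, policy: str = "median",
                       fixed=None) -> np.ndarray:
    """Per-gene binarization thresholds m_i.

    ``median`` pools each gene's counts across all pairs probing it and takes
    the median, using the *lower* median for even sample sizes (documented
    tie rule); ``fixed`` uses the user-supplied vector.
    """
    if policy == "fixed":
        if fixed is None:
            raise ValueError("fixed policy requires a threshold vector")
        m = np.asarray(fixed)
        if m.size != data.n_genes:
            raise ValueError("fixed thresholds must have length n_genes")
        return m.astype(float)
    if policy != "median":
        raise ValueError(f"unknown threshold policy {policy!r}")
    m = np.empty(data.n_genes)
    for g in range(data.n_genes):
        obs = np.sort(data.gene_observations(g))  # raises if gene unprobed
        m[g] = obs[(obs.size - 1) // 2]  # lower median
    return m


def binarize(data: PairObservationSet, thresholds) -> PairObservationSet:
    """Indicator = 1 iff count is *strictly* larger than the threshold.

    Idempotent on already-binary data with thresholds 0.
    """
    m = np.asarray(thresholds, dtype=float)
    if m.size != data.n_genes:
        raise ValueError("thresholds must have length n_genes")
    counts = [np.stack([c[:, 0] > m[i], c[:, 1] > m[j]], axis=1).astype(float)
              for (i, j), c in zip(data.pairs, data.counts)]
    return PairObservationSet(gene_names=list(data.gene_names),
                              pairs=list(data.pairs), counts=counts,
                              regime="bursty_binary", seed=data.seed)


def estimate_cov_variance(pair_counts: np.ndarray,
                          eps: float = DEFAULT_VARIANCE_EPS
                          ) -> tuple[float, bool]:
    """Sampling variance of one pair's covariance estimate.

    The leading term is Bernoulli-coincidence noise: with coincidence
    frequency r̂ = (1/M) Σ x_i x_j the variance of ĉ is r̂(1−r̂)/M, the
    corrections from estimating the means being subdominant when coincident
    bursts are rare.  Pairs with no observed coincidence would report zero
    variance and an infinite likelihood weight, so r(1−r) is floored at
    ``eps``/M (a quarter of one coincidence count by default).  Returns
    (variance, floor_applied).
    """
    x = np.asarray(pair_counts, dtype=float)
    M = x.shape[0]
    if M < 2:
        raise ValueError("at least 2 observations are required")
    r = float(np.mean(x[:, 0] * x[:, 1]))
    raw = r * (1.0 - r)
    floor = eps / M
    if raw < floor:
        return floor / M, True
    return raw / M, False


def estimate_moments(binary: PairObservationSet,
                     thresholds=None,
                     eps: float = DEFAULT_VARIANCE_EPS) -> MomentEstimates:
    """Measurable moments of a binarized observation set.

    p̂_i pools indicator means over every pair probing gene i (weighted by
    pair sample sizes); ĉ_ij uses the *within-pair* means so each pair's
    covariance estimate is self-contained; duplicate probings of the same
    pair are concatenated.
    """
    if binary.regime != "bursty_binary":
        raise ValueError("estimate_moments requires binarized data")
    n = binary.n_genes
    pooled_sum = np.zeros(n)
    pooled_n = np.zeros(n, dtype=int)
    chunks: dict[tuple[int, int], list[np.ndarray]] = {}
    for (i, j), c in zip(binary.pairs, binary.counts):
        pooled_sum[i] += c[:, 0].sum()
        pooled_sum[j] += c[:, 1].sum()
        pooled_n[i] += c.shape[0]
        pooled_n[j] += c.shape[0]
        key, arr = ((i, j), c) if i < j else ((j, i), c[:, ::-1])
        chunks.setdefault(key, []).append(arr)

    c_hat = np.full((n, n), np.nan)
    c_var = np.full((n, n), np.nan)
    M = np.zeros((n, n), dtype=int)
    floored = np.zeros((n, n), dtype=bool)
    for (i, j), arrs in chunks.items():
        x = np.concatenate(arrs, axis=0)
        m = x.shape[0]
        cij = float(np.mean(x[:, 0] * x[:, 1])
                    - np.mean(x[:, 0]) * np.mean(x[:, 1]))
        vij, fl = estimate_cov_variance(x, eps=eps)
        c_hat[i, j] = c_hat[j, i] = cij
        c_var[i, j] = c_var[j, i] = vij
        M[i, j] = M[j, i] = m
        floored[i, j] = floored[j, i] = fl

    p_hat = np.where(pooled_n > 0, pooled_sum / np.maximum(pooled_n, 1),
                     np.nan)
    if thresholds is None:
        thresholds = np.zeros(n)
    return MomentEstimates(
        gene_names=list(binary.gene_names), p_hat=p_hat, c_hat=c_hat,
        c_var=c_var, n_obs_pair=M, n_obs_gene=pooled_n,
        thresholds=np.asarray(thresholds), var_floored=floored)
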