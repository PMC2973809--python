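"""Synthetic pairwise FISH observation sets for all model families.

Each simulated "cell" is one fixed snapshot probed for a single pair of
genes: an unobserved time t (or switch state s, or global factor G) is drawn,
and the two genes' counts or burst indicators are drawn conditionally
independently given it.  Pairs are mutually independent data sets, as in real
pairwise FISH where every cell is hybridized for one probe pair.

The generator defaults emulate the synthetic ensembles used to benchmark the
reconstruction method; see docs/methods.md for the rationale behind each
range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import (BurstCycleModel, ContinuousCycleModel, SwitchModel,
                     eval_mean_trajectory)

__all__ = [
    "PairObservationSet",
    "all_pairs",
    "sample_cycle_params",
    "sample_bursty_params",
    "sample_switch_params",
    "simulate_continuous",
    "simulate_bursty",
    "simulate_switch",
]

REGIMES = ("continuous", "bursty_binary", "bursty_count")


@dataclass
class PairObservationSet:
    """Raw pairwise snapshot data: counts per cell for each probed gene pair.

    ``counts[k]`` is an (M_k, 2) array for pair ``pairs[k] = (i, j)``; column
    0 holds gene i's counts, column 1 gene j's.  Continuous-regime values may
    be non-integer reals (Gaussian noise, floored at zero).
    """

    gene_names: list[str]
    pairs: list[tuple[int, int]]
    counts: list[np.ndarray]
    regime: str
    seed: int | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if len(self.pairs) != len(self.counts):
            raise ValueError("pairs and counts must have equal length")
        n = len(self.gene_names)
        clean = []
        for (i, j), c in zip(self.pairs, self.counts):
            if i == j:
                raise ValueError("a pair must probe two distinct genes")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"pair ({i}, {j}) out of range")
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] == 0:
                raise ValueError("each pair needs a non-empty (M, 2) array")
            if np.any(c < 0):
                raise ValueError("counts must be non-negative")
            clean.append(c)
        self.counts = clean
        self.pairs = [(int(i), int(j)) for i, j in self.pairs]

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def gene_observations(self, g: int) -> np.ndarray:
        """All counts of gene ``g`` pooled across the pairs probing it."""
        chunks = [c[:, (i, j).index(g)]
                  for (i, j), c in zip(self.pairs, self.counts)
                  if g in (i, j)]
        if not chunks:
            raise ValueError(
                f"gene {self.gene_names[g]!r} has no observations")
        return np.concatenate(chunks)


def all_pairs(n_genes: int) -> list[tuple[int, int]]:
    """Every unordered gene pair (i < j)."""
    return [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _names(n: int) -> list[str]:
    return [f"g{i}" for i in range(n)]


# ---------------------------------------------------------------------------
# random model parameters
# ---------------------------------------------------------------------------

def sample_cycle_params(n_genes: int, noise_max: float = 2.0,
                        rng_seed=None) -> ContinuousCycleModel:
    """Random continuous-regime cycle: A_i = 5(1+u), mu0_i = A_i(1+u').

    The construction guarantees baseline >= amplitude (positive mean
    trajectory) and significant oscillation amplitudes; phases are uniform on
    [0, 2*pi) and noise amplitudes uniform on (0, noise_max].
    """
    if n_genes < 2:
        raise ValueError("n_genes must be at least 2")
    if noise_max <= 0:
        raise ValueError("noise_max must be positive")
    rng = _rng(rng_seed)
    amp = 5.0 * (1.0 + rng.uniform(size=n_genes))
    baseline = amp * (1.0 + rng.uniform(size=n_genes))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_genes)
    noise_sd = noise_max * (1.0 - rng.uniform(size=n_genes))  # in (0, max]
    return ContinuousCycleModel(baseline=baseline, amplitude=amp,
                                phase=phase, noise_sd=noise_sd)


def sample_bursty_params(n_genes: int, rng_seed=None,
                         mean_range: tuple[float, float] = (0.1, 0.4),
                         rel_amp_range: tuple[float, float] = (0.5, 1.0),
                         locked: bool = False,
                         global_noise_sd: float = 0.0) -> BurstCycleModel:
    """Random single-harmonic bursty cycle with significant, positive bursts.

    Amplitudes are drawn as a_i = p̄_i * v with v in ``rel_amp_range`` so the
    burst probability stays positive (a <= p̄) while varying substantially
    over the cycle.  ``locked=True`` returns the amplitude-locked metabolic
    model a_i = p̄_i, for which only the phase is free.
    """
    rng = _rng(rng_seed)
    p = rng.uniform(*mean_range, size=n_genes)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_genes)
    if locked:
        return BurstCycleModel.locked(p, phase,
                                      global_noise_sd=global_noise_sd)
    amp = p * rng.uniform(*rel_amp_range, size=n_genes)
    return BurstCycleModel(mean_prob=p, amp=amp[:, None], phase=phase[:, None],
                           global_noise_sd=global_noise_sd)


def sample_switch_params(n_genes: int, n_states: int = 2, rng_seed=None,
                         state_prob=None,
                         min_separation: float = 0.0) -> SwitchModel:
    """Random switch with burst probabilities uniform on [0, 1].

    ``min_separation > 0`` resamples each gene's row until the spread of its
    per-state probabilities exceeds the floor, so every gene is informative
    about the hidden state (the informative-gene constraint used in the
    synthetic switch benchmarks).
    """
    rng = _rng(rng_seed)
    if state_prob is None:
        state_prob = np.full(n_states, 1.0 / n_states)
    state_prob = np.asarray(state_prob, dtype=float)
    q = np.empty((n_genes, n_states))
    for i in range(n_genes):
        while True:
            row = rng.uniform(size=n_states)
            if row.max() - row.min() >= min_separation:
                q[i] = row
                break
    return SwitchModel(state_prob=state_prob, burst_prob=q)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_continuous(model: ContinuousCycleModel,
                        pairs: Sequence[tuple[int, int]],
                        n_obs_per_pair: int, rng_seed=None,
                        gene_names: Sequence[str] | None = None
                        ) -> PairObservationSet:
    """Continuous-regime snapshots: x = mu(t) + Gaussian noise, floored at 0.

    A fresh uniform time is drawn for every observation of every pair.
    """
    if n_obs_per_pair < 1:
        raise ValueError("n_obs_per_pair must be at least 1")
    rng = _rng(rng_seed)
    counts = []
    for (i, j) in pairs:
        t = rng.uniform(0.0, model.period, size=n_obs_per_pair)
        mu = eval_mean_trajectory(model, t)  # (n_genes, M)
        x = np.stack([
            mu[i] + rng.normal(0.0, model.noise_sd[i], size=n_obs_per_pair),
            mu[j] + rng.normal(0.0, model.noise_sd[j], size=n_obs_per_pair),
        ], axis=1)
        counts.append(np.maximum(x, 0.0))
    names = list(gene_names) if gene_names else _names(model.n_genes)
    return PairObservationSet(gene_names=names, pairs=list(pairs),
                              counts=counts, regime="continuous")


def _global_factors(model: BurstCycleModel, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """One multiplicative factor per cell, shared by both probed genes.

    Gamma-distributed with mean 1 and sd sigma_G (positive by construction);
    the observable moments depend only on its mean and variance.
    """
    sd = model.global_noise_sd
    if sd == 0:
        return np.ones(n)
    shape = 1.0 / sd ** 2
    return rng.gamma(shape, scale=sd ** 2, size=n)


def simulate_bursty(model: BurstCycleModel, pairs: Sequence[tuple[int, int]],
                    n_obs_per_pair: int, rng_seed=None,
                    counts_mode: bool = False, burst_size_mean: float = 8.0,
                    gene_names: Sequence[str] | None = None
                    ) -> PairObservationSet:
    """Bursty-regime snapshots: per-cell time and global factor, then
    conditionally independent Bernoulli burst indicators.

    ``counts_mode=True`` dresses each burst indicator into an mRNA count
    drawn from a geometric distribution (mean ``burst_size_mean``), to
    exercise thresholding; the underlying information remains binary.
    """
    if n_obs_per_pair < 1:
        raise ValueError("n_obs_per_pair must be at least 1")
    rng = _rng(rng_seed)
    counts = []
    for (i, j) in pairs:
        t = rng.uniform(0.0, model.period, size=n_obs_per_pair)
        g = _global_factors(model, n_obs_per_pair, rng)
        pi = np.clip(g * _raw_prob(model, t, i), 0.0, 1.0)
        pj = np.clip(g * _raw_prob(model, t, j), 0.0, 1.0)
        x = np.stack([rng.uniform(size=n_obs_per_pair) < pi,
                      rng.uniform(size=n_obs_per_pair) < pj],
                     axis=1).astype(float)
        if counts_mode:
            size = rng.geometric(1.0 / burst_size_mean, size=x.shape)
            x = x * size
        counts.append(x)
    names = list(gene_names) if gene_names else _names(model.n_genes)
    regime = "bursty_count" if counts_mode else "bursty_binary"
    return PairObservationSet(gene_names=names, pairs=list(pairs),
                              counts=counts, regime=regime)


def _raw_prob(model: BurstCycleModel, t: np.ndarray, gene: int) -> np.ndarray:
    """Unclipped harmonic burst probability of one gene at times t."""
    omega = 2.0 * np.pi / model.period
    h = np.arange(1, model.n_harmonics + 1)
    arg = omega * t[:, None] * h + model.phase[gene]
    return model.mean_prob[gene] + np.sum(model.amp[gene] * np.cos(arg),
                                          axis=1)


def simulate_switch(model: SwitchModel, pairs: Sequence[tuple[int, int]],
                    n_obs_per_pair: int, rng_seed=None,
                    counts_mode: bool = False, burst_size_mean: float = 8.0,
                    gene_names: Sequence[str] | None = None
                    ) -> PairObservationSet:
    """Switch-regime snapshots: one hidden state per cell, shared by both
    probed genes, then conditionally independent Bernoulli bursts."""
    if n_obs_per_pair < 1:
        raise ValueError("n_obs_per_pair must be at least 1")
    rng = _rng(rng_seed)
    counts = []
    for (i, j) in pairs:
        s = rng.choice(model.n_states, size=n_obs_per_pair,
                       p=model.state_prob)
        x = np.stack([
            rng.uniform(size=n_obs_per_pair) < model.burst_prob[i, s],
            rng.uniform(size=n_obs_per_pair) < model.burst_prob[j, s],
        ], axis=1).astype(float)
        if counts_mode:
            size = rng.geometric(1.0 / burst_size_mean, size=x.shape)
            x = x * size
        counts.append(x)
    names = list(gene_names) if gene_names else _names(model.n_genes)
    regime = "bursty_count" if counts_mode else "bursty_binary"
    return PairObservationSet(gene_names=names, pairs=list(pairs),
                              counts=counts, regime=regime)
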