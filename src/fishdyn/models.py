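"""Dynamical models of gene expression and their exact snapshot moments.

Three model families describe how burst probabilities or mean mRNA levels
evolve over the (unobserved) time coordinate of a fixed-cell snapshot:

* :class:`ContinuousCycleModel` -- smooth harmonic oscillation of mean mRNA
  counts with per-gene Gaussian fluctuations (the continuous regime, where
  many transcriptional bursts contribute to each count).
* :class:`BurstCycleModel` -- periodic burst *probabilities* expanded in a
  truncated Fourier series, optionally modulated by a cell-wide global
  transcription factor of mean 1 and standard deviation ``global_noise_sd``
  (the bursty regime, where data are effectively binary).
* :class:`SwitchModel` -- synchronous stochastic switching of all genes among
  ``S`` discrete expression states.

Because cells are fixed, only the time- or state-averaged mean and the
between-gene covariance of burst indicators are observable.  This module
evaluates those moments in closed form, counts identifiable parameters
(degrees-of-freedom bookkeeping), and measures the numerical rank of
covariance matrices -- the quantity that reveals the "complexity" of the
underlying dynamics (2H for a cycle with H harmonics, +1 with global noise,
S-1 for an S-state switch).

Phase convention: cos(2*pi*h*t/T + phi) throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.special import gammaln, roots_genlaguerre

SCHEMA_VERSION = 1

__all__ = [
    "ContinuousCycleModel",
    "BurstCycleModel",
    "SwitchModel",
    "MomentSet",
    "DofReport",
    "eval_mean_trajectory",
    "eval_burst_prob",
    "exact_moments",
    "dof_report",
    "covariance_rank",
    "write_model",
    "read_model",
]


def _as1d(x, name: str, n: int | None = None) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if n is not None and a.size != n:
        raise ValueError(f"{name} has length {a.size}, expected {n}")
    return a


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass
class ContinuousCycleModel:
    """Harmonic mean-mRNA trajectories with per-gene Gaussian noise.

    mu_i(t) = baseline_i + amplitude_i * cos(2*pi*t/period + phase_i),
    observed counts x_i = mu_i(t) + eta_i with eta_i ~ N(0, noise_sd_i).
    """

    baseline: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    noise_sd: np.ndarray
    period: float = 1.0
    strict: bool = True

    def __post_init__(self):
        self.baseline = _as1d(self.baseline, "baseline")
        n = self.baseline.size
        self.amplitude = _as1d(self.amplitude, "amplitude", n)
        self.phase = _as1d(self.phase, "phase", n)
        self.noise_sd = _as1d(self.noise_sd, "noise_sd", n)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")
        # amplitude <= baseline keeps the mean trajectory non-negative; fitted
        # models may violate it, so they are built with strict=False.
        if self.strict and np.any(self.amplitude > self.baseline + 1e-12):
            raise ValueError("amplitude must not exceed baseline")

    @property
    def n_genes(self) -> int:
        return self.baseline.size


@dataclass
class BurstCycleModel:
    """Cyclic burst probabilities as a truncated Fourier series.

    p_i(t) = mean_prob_i + sum_h amp[i,h] * cos(2*pi*(h+1)*t/period + phase[i,h]),
    optionally multiplied by a cell-wide factor G with mean 1 and standard
    deviation ``global_noise_sd`` and clipped to [0, 1] when evaluated.

    ``amplitude_locked`` selects the single-parameter-per-gene metabolic
    model p_i(t) = mean_prob_i * (1 + cos(2*pi*t/period + phi_i)), whose
    expression touches zero once per cycle.
    """

    mean_prob: np.ndarray
    amp: np.ndarray
    phase: np.ndarray
    period: float = 1.0
    global_noise_sd: float = 0.0
    amplitude_locked: bool = False

    def __post_init__(self):
        self.mean_prob = _as1d(self.mean_prob, "mean_prob")
        n = self.mean_prob.size
        self.amp = np.atleast_2d(np.asarray(self.amp, dtype=float))
        self.phase = np.atleast_2d(np.asarray(self.phase, dtype=float))
        if self.amp.shape[0] != n or self.phase.shape != self.amp.shape:
            raise ValueError("amp and phase must be (n_genes, n_harmonics)")
        if self.amp.shape[1] < 1:
            raise ValueError("at least one harmonic is required")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if np.any((self.mean_prob < 0) | (self.mean_prob > 1)):
            raise ValueError("mean_prob must lie in [0, 1]")
        if np.any(self.amp < 0):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.global_noise_sd < 0:
            raise ValueError("global_noise_sd must be non-negative")
        if self.amplitude_locked:
            if self.n_harmonics != 1:
                raise ValueError("amplitude_locked requires a single harmonic")
            if not np.allclose(self.amp[:, 0], self.mean_prob, atol=1e-12):
                raise ValueError(
                    "amplitude_locked requires amp[:, 0] == mean_prob")

    @classmethod
    def locked(cls, mean_prob, phase, period: float = 1.0,
               global_noise_sd: float = 0.0) -> "BurstCycleModel":
        """Build the amplitude-locked (metabolic-cycle) model."""
        mean_prob = _as1d(mean_prob, "mean_prob")
        phase = _as1d(phase, "phase", mean_prob.size)
        return cls(mean_prob=mean_prob, amp=mean_prob[:, None],
                   phase=phase[:, None], period=period,
                   global_noise_sd=global_noise_sd, amplitude_locked=True)

    @property
    def n_genes(self) -> int:
        return self.mean_prob.size

    @property
    def n_harmonics(self) -> int:
        return self.amp.shape[1]


@dataclass
class SwitchModel:
    """Synchronous stochastic switch among S discrete expression states."""

    state_prob: np.ndarray
    burst_prob: np.ndarray  # (n_genes, n_states)

    def __post_init__(self):
        self.state_prob = _as1d(self.state_prob, "state_prob")
        self.burst_prob = np.atleast_2d(np.asarray(self.burst_prob, dtype=float))
        if self.state_prob.size < 2:
            raise ValueError("a switch needs at least 2 states")
        if abs(self.state_prob.sum() - 1.0) > 1e-12:
            raise ValueError("state probabilities must sum to 1")
        if np.any(self.state_prob < 0):
            raise ValueError("state probabilities must be non-negative")
        if self.burst_prob.shape[1] != self.state_prob.size:
            raise ValueError("burst_prob must be (n_genes, n_states)")
        if np.any((self.burst_prob < 0) | (self.burst_prob > 1)):
            raise ValueError("burst probabilities must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.burst_prob.shape[0]

    @property
    def n_states(self) -> int:
        return self.state_prob.size


Model = Union[ContinuousCycleModel, BurstCycleModel, SwitchModel]


@dataclass
class MomentSet:
    """Cycle- or state-averaged mean and between-gene covariance.

    For exact model moments the diagonal carries the model-implied dynamical
    variance (the diagonal a low-rank completion reconstructs), *not* the
    Bernoulli indicator variance: same-gene coincidences are never measured
    by pairwise FISH, so the data-facing estimate in
    :mod:`fishdyn.binarize` flags the diagonal as unobservable instead.
    """

    mean: np.ndarray
    cov: np.ndarray
    diag_observable: bool = True

    def __post_init__(self):
        self.mean = _as1d(self.mean, "mean")
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("cov must be square with side n_genes")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("cov must be symmetric")


@dataclass
class DofReport:
    """Identifiability accounting for one model family.

    ``n_parameters`` counts free model parameters (the overall cycle phase,
    never identifiable from snapshots, is already removed for cycles);
    ``n_constraints`` counts the constraints supplied by the observable
    means plus a rank-r symmetric covariance restricted to the
    ``n_genes*(n_genes-1)/2`` observable off-diagonal entries;
    ``n_unconstrained`` is the number of additional constraints (e.g.
    triplet-FISH data sets) required for full parameter inference.
    """

    model_family: str
    n_genes: int
    n_harmonics_or_states: int
    global_noise: bool
    n_parameters: int
    n_constraints: int
    n_unconstrained: int
    cov_rank: int
    capped: bool = False


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def eval_mean_trajectory(model: ContinuousCycleModel, t) -> np.ndarray:
    """Mean mRNA level per gene at time(s) ``t``.

    Returns shape (n_genes,) for scalar ``t`` and (n_genes, len(t)) for a
    vector of times.
    """
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / model.period
    arg = omega * t[..., None] + model.phase  # (..., n_genes)
    out = model.baseline + model.amplitude * np.cos(arg)
    return np.moveaxis(out, -1, 0) if t.ndim else out


def eval_burst_prob(model: BurstCycleModel, t, global_factor: float = 1.0
                    ) -> np.ndarray:
    """Clipped burst probability per gene at time(s) ``t``.

    clip(global_factor * [p̄_i + Σ_h a_{i,h} cos(2π h t/T + φ_{i,h})], 0, 1).
    The clipping mirrors the simulation rule: when the harmonic expansion
    exceeds one, a burst occurs with probability one.
    """
    if global_factor < 0:
        raise ValueError("global_factor must be non-negative")
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / model.period
    h = np.arange(1, model.n_harmonics + 1)
    # (..., n_genes, n_harmonics)
    arg = omega * t[..., None, None] * h + model.phase
    raw = model.mean_prob + np.sum(model.amp * np.cos(arg), axis=-1)
    out = np.clip(global_factor * raw, 0.0, 1.0)
    return np.moveaxis(out, -1, 0) if t.ndim else out


# ---------------------------------------------------------------------------
# exact moments
# ---------------------------------------------------------------------------

def _harmonic_cov(amp: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """K_ij = 1/2 Σ_h a_{i,h} a_{j,h} cos(φ_{i,h} − φ_{j,h}).

    Equals Σ_h (x_h x_hᵀ + y_h y_hᵀ)/2 with x = a cos φ, y = a sin φ, hence
    has rank 2H for generic parameters.
    """
    x = amp * np.cos(phase)
    y = amp * np.sin(phase)
    return 0.5 * (x @ x.T + y @ y.T)


def _moments_continuous(model: ContinuousCycleModel) -> MomentSet:
    amp = model.amplitude[:, None]
    ph = model.phase[:, None]
    cov = _harmonic_cov(amp, ph)
    cov[np.diag_indices_from(cov)] += model.noise_sd ** 2
    return MomentSet(mean=model.baseline.copy(), cov=cov)


def _moments_bursty_closed(model: BurstCycleModel) -> MomentSet:
    p = model.mean_prob
    K = _harmonic_cov(model.amp, model.phase)
    s2 = model.global_noise_sd ** 2
    cov = s2 * np.outer(p, p) + (1.0 + s2) * K
    return MomentSet(mean=p.copy(), cov=cov)


def _gamma_nodes(sd: float, n_nodes: int = 48):
    """Gauss quadrature nodes/weights for a gamma variable of mean 1, sd."""
    k = 1.0 / sd ** 2          # shape; scale = sd**2
    if k > 150:
        raise ValueError(
            "global_noise_sd < ~0.08 is numerically unstable in the gamma "
            "quadrature; use the closed-form moments instead")
    x, w = roots_genlaguerre(n_nodes, k - 1.0)
    g = x * sd ** 2
    w = w / np.exp(gammaln(k))
    return g, w / w.sum()


def _moments_bursty_quadrature(model: BurstCycleModel, n_time: int = 1024,
                               n_noise: int = 48) -> MomentSet:
    t = np.arange(n_time) * (model.period / n_time)
    if model.global_noise_sd > 0:
        g, wg = _gamma_nodes(model.global_noise_sd, n_noise)
    else:
        g, wg = np.array([1.0]), np.array([1.0])
    mean = np.zeros(model.n_genes)
    second = np.zeros((model.n_genes, model.n_genes))
    for gv, wv in zip(g, wg):
        p = eval_burst_prob(model, t, global_factor=gv)  # (n_genes, n_time)
        mean += wv * p.mean(axis=1)
        second += wv * (p @ p.T) / n_time
    return MomentSet(mean=mean, cov=second - np.outer(mean, mean))


def _moments_continuous_quadrature(model: ContinuousCycleModel,
                                   n_time: int = 1024) -> MomentSet:
    t = np.arange(n_time) * (model.period / n_time)
    mu = eval_mean_trajectory(model, t)  # (n_genes, n_time)
    mean = mu.mean(axis=1)
    cov = mu @ mu.T / n_time - np.outer(mean, mean)
    cov[np.diag_indices_from(cov)] += model.noise_sd ** 2
    return MomentSet(mean=mean, cov=cov)


def _moments_switch(model: SwitchModel) -> MomentSet:
    P = model.state_prob
    q = model.burst_prob
    mean = q @ P
    cov = (q * P) @ q.T - np.outer(mean, mean)
    return MomentSet(mean=mean, cov=cov)


def exact_moments(model: Model, method: str = "closed_form",
                  n_time: int = 1024, n_noise: int = 48) -> MomentSet:
    """Exact cycle- or state-averaged mean and covariance of a model.

    ``method="closed_form"`` uses the analytic expressions (which ignore
    clipping of burst probabilities, as the underlying algebra does);
    ``method="quadrature"`` averages the evaluated model over a fine uniform
    time grid (and Gauss-gamma nodes for global noise), honouring clipping.
    The two agree to ~1e-9 whenever no clipping is active.
    """
    if method not in ("closed_form", "quadrature"):
        raise ValueError(f"unknown method {method!r}")
    if isinstance(model, SwitchModel):
        return _moments_switch(model)  # already exact; no clipping concept
    if isinstance(model, ContinuousCycleModel):
        if method == "closed_form":
            return _moments_continuous(model)
        return _moments_continuous_quadrature(model, n_time)
    if isinstance(model, BurstCycleModel):
        if method == "closed_form":
            return _moments_bursty_closed(model)
        return _moments_bursty_quadrature(model, n_time, n_noise)
    raise TypeError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# identifiability accounting
# ---------------------------------------------------------------------------

def dof_report(family: str, n_genes: int, n_harmonics_or_states: int,
               global_noise: bool = False) -> DofReport:
    """Count parameters, snapshot constraints and unconstrained parameters.

    For a cycle with H harmonics the parameters are (p̄_i, a_{i,h}, φ_{i,h})
    minus one overall phase, i.e. N(1+2H) − 1 (+1 for σ_G with global noise).
    For an S-state switch they are the S−1 free state probabilities plus the
    N·S per-state burst probabilities.  Constraints are the N observed means
    plus the degrees of freedom of a rank-r symmetric covariance,
    rN − r(r−1)/2, capped at the N(N−1)/2 observable off-diagonal entries for
    small gene sets (``capped`` reports whether the cap applied).
    """
    N = int(n_genes)
    k = int(n_harmonics_or_states)
    if N < 2:
        raise ValueError("n_genes must be at least 2")
    if family == "cycle":
        H = k
        if H < 1:
            raise ValueError("n_harmonics must be at least 1")
        n_par = N * (1 + 2 * H) - 1
        r = 2 * H
    elif family == "switch":
        S = k
        if S < 2:
            raise ValueError("n_states must be at least 2")
        n_par = (S - 1) + S * N
        r = S - 1
    else:
        raise ValueError("family must be 'cycle' or 'switch'")
    if global_noise:
        n_par += 1  # sigma_G
        r += 1
    uncapped = r * N - r * (r - 1) // 2
    cap = N * (N - 1) // 2
    cov_constraints = min(uncapped, cap)
    n_constraints = N + cov_constraints
    return DofReport(
        model_family=family, n_genes=N, n_harmonics_or_states=k,
        global_noise=global_noise, n_parameters=n_par,
        n_constraints=n_constraints,
        n_unconstrained=max(0, n_par - n_constraints),
        cov_rank=r, capped=uncapped > cap)


def covariance_rank(cov: np.ndarray, rel_tol: float = 1e-8) -> int:
    """Number of eigenvalues with |λ| > rel_tol × max|λ|; 0 for zero matrix."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance matrix must be square")
    scale = np.max(np.abs(cov))
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, scale)):
        raise ValueError("covariance matrix must be symmetric")
    if scale == 0:
        return 0
    ev = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    return int(np.sum(np.abs(ev) > rel_tol * np.max(np.abs(ev))))


# ---------------------------------------------------------------------------
# model file round trip (JSON, versioned)
# ---------------------------------------------------------------------------

def model_to_dict(model: Model) -> dict:
    d: dict = {"schema_version": SCHEMA_VERSION}
    if isinstance(model, ContinuousCycleModel):
        d.update(family="continuous_cycle", period=model.period,
                 baseline=model.baseline.tolist(),
                 amplitude=model.amplitude.tolist(),
                 phase=model.phase.tolist(),
                 noise_sd=model.noise_sd.tolist())
    elif isinstance(model, BurstCycleModel):
        d.update(family="burst_cycle", period=model.period,
                 mean_prob=model.mean_prob.tolist(),
                 amp=model.amp.tolist(), phase=model.phase.tolist(),
                 global_noise_sd=model.global_noise_sd,
                 amplitude_locked=model.amplitude_locked)
    elif isinstance(model, SwitchModel):
        d.update(family="switch", state_prob=model.state_prob.tolist(),
                 burst_prob=model.burst_prob.tolist())
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return d


def model_from_dict(d: dict) -> Model:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version!r}")
    family = d.get("family")
    if family == "continuous_cycle":
        return ContinuousCycleModel(
            baseline=d["baseline"], amplitude=d["amplitude"],
            phase=d["phase"], noise_sd=d["noise_sd"], period=d["period"])
    if family == "burst_cycle":
        return BurstCycleModel(
            mean_prob=d["mean_prob"], amp=d["amp"], phase=d["phase"],
            period=d["period"], global_noise_sd=d["global_noise_sd"],
            amplitude_locked=d["amplitude_locked"])
    if family == "switch":
        return SwitchModel(state_prob=d["state_prob"],
                           burst_prob=d["burst_prob"])
    raise ValueError(f"unknown model family {family!r}")


def write_model(model: Model, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def read_model(path) -> Model:
    return model_from_dict(json.loads(Path(path).read_text()))
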