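"""Maximum-likelihood reconstruction in the bursty regime.

Binarized pairwise FISH data reduce to per-gene burst frequencies p̂ and
per-pair covariance estimates ĉ_ij with sampling variances σ²_ij.  Because
single bursts are far more frequent than coincidences, the means are pinned
exactly (the fitted model reproduces p̂), and the likelihood is a product of
Gaussians over the independent pairwise covariance estimates:

    log L(θ) = Σ_{pairs} [ −½ log(2π σ²_ij) − (ĉ_ij − c_ij(θ))² / (2σ²_ij) ]

with c_ij(θ) the model's exact cycle- or state-averaged covariance.  The
free parameters are the per-gene phases (plus amplitudes, unless the
amplitude-locked metabolic model is used, plus the global-noise amplitude
σ_G when fitted) for cycles, or one state's burst probabilities for a
2-state switch with known state probability.  Optimization restarts from
random initializations; in this regime the same optimum is reached from
nearly every start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import minimize

from .binarize import MomentEstimates
from .models import BurstCycleModel, MomentSet, SwitchModel, dof_report

__all__ = [
    "BurstyFitResult",
    "cov_loglik",
    "fit_cycle_bursty",
    "fit_switch",
    "reconstruction_error_switch",
    "phase_agreement",
]

#: two restarts count as having reached the same optimum if their
#: log-likelihoods differ by less than this (relative)
RESTART_TOL = 1e-5


@dataclass
class BurstyFitResult:
    model: BurstCycleModel | SwitchModel
    log_likelihood: float
    n_restarts_used: int
    restart_agreement: float
    pinned_means: bool = True
    fitted_global_noise: float | None = None


def cov_loglik(theory_cov, est: MomentEstimates) -> float:
    """Gaussian log-likelihood of the observed pairwise covariances.

    ``theory_cov`` may be a matrix or a :class:`MomentSet`; only the
    observed off-diagonal pairs contribute (missing pairs add 0).
    """
    if isinstance(theory_cov, MomentSet):
        theory_cov = theory_cov.cov
    c = np.asarray(theory_cov, dtype=float)
    ll = 0.0
    for (i, j) in est.observed_pairs():
        v = est.c_var[i, j]
        ll += -0.5 * np.log(2.0 * np.pi * v) \
              - (est.c_hat[i, j] - c[i, j]) ** 2 / (2.0 * v)
    return float(ll)


# ---------------------------------------------------------------------------
# cyclic models
# ---------------------------------------------------------------------------

def _spectral_start(est: MomentEstimates, amax: np.ndarray):
    """Phase/amplitude start from the rank-2 completed covariance.

    For a single-harmonic cycle c = (Z Zᵀ)/2 with rows
    Z_i = a_i (cos φ_i, sin φ_i), so the top-two eigenpairs of the
    diagonal-completed covariance yield a_i and φ_i up to the global
    rotation/reflection symmetry -- an excellent deterministic start.
    """
    from .pca import pca_complete

    try:
        res = pca_complete(est, rank=2)
    except Exception:  # pragma: no cover - degenerate inputs
        return None
    lam = np.maximum(res.eigenvalues[:2], 0.0)
    z = res.eigenvectors[:, :2] * np.sqrt(2.0 * lam)
    phi = np.arctan2(z[:, 1], z[:, 0])
    amp = np.clip(np.hypot(z[:, 0], z[:, 1]), 1e-4, amax)
    return phi, amp


def _cycle_cov(p, amp, phase, sigma_g):
    x = amp * np.cos(phase)
    y = amp * np.sin(phase)
    K = 0.5 * (np.outer(x, x) + np.outer(y, y))
    s2 = sigma_g ** 2
    return s2 * np.outer(p, p) + (1.0 + s2) * K


def _agreement(lls, best):
    scale = max(1.0, abs(best))
    return float(np.mean(np.asarray(lls) >= best - RESTART_TOL * scale))


def fit_cycle_bursty(est: MomentEstimates, n_harmonics: int = 1,
                     global_noise: str = "off",
                     amplitude_locked: bool = False,
                     n_restarts: int = 10, rng_seed=None) -> BurstyFitResult:
    """Fit a cyclic burst-probability model to estimated moments.

    Means are pinned to p̂ exactly.  Free parameters: phases, plus
    amplitudes (bounded to [0, min(p̄, 1−p̄)] so the closed-form moments stay
    consistent with the clipped simulation) unless ``amplitude_locked``, plus
    σ_G on a log scale when ``global_noise="fit"``.  Under-identified
    configurations -- any free-amplitude setting for which the
    degrees-of-freedom report shows unconstrained parameters -- are rejected
    with instructions rather than silently returning one of many optima.
    """
    if global_noise not in ("off", "fit"):
        raise ValueError("global_noise must be 'off' or 'fit'")
    if amplitude_locked and n_harmonics != 1:
        raise ValueError("the amplitude-locked model has a single harmonic")
    p = np.asarray(est.p_hat, dtype=float)
    if np.any(~np.isfinite(p)):
        raise ValueError("p_hat must be finite for all genes")
    n = p.size
    if not amplitude_locked:
        rep = dof_report("cycle", n, n_harmonics,
                         global_noise=(global_noise == "fit"))
        if rep.n_unconstrained > 0:
            raise ValueError(
                f"under-identified: {rep.n_unconstrained} unconstrained "
                "parameters remain; lock the amplitudes (amplitude_locked="
                "True) or supply additional constraints (e.g. triplet data)")
    if n_harmonics != 1:
        raise ValueError("only single-harmonic cyclic fits are supported")

    rng = np.random.default_rng(rng_seed)
    fit_sigma = global_noise == "fit"
    amax = np.minimum(p, 1.0 - p)
    spectral = _spectral_start(est, amax)

    def unpack(theta):
        phi = theta[:n]
        k = n
        if amplitude_locked:
            amp = p
        else:
            amp = theta[k:k + n]
            k += n
        sg = np.exp(theta[k]) if fit_sigma else 0.0
        return phi, amp, sg

    def negloglik(theta):
        phi, amp, sg = unpack(theta)
        return -cov_loglik(_cycle_cov(p, amp, phi, sg), est)

    best = None
    lls = []
    for k in range(max(1, n_restarts)):
        if k == 0 and spectral is not None:
            # deterministic spectral start: phases and amplitudes read off
            # the rank-2 diagonal-completed covariance
            phi0, amp0 = spectral
        else:
            phi0 = rng.uniform(0, 2 * np.pi, size=n)
            amp0 = amax * rng.uniform(0.3, 1.0, size=n)
        theta0 = [phi0]
        bounds: list = [(None, None)] * n
        if not amplitude_locked:
            theta0.append(amp0)
            bounds += [(0.0, a) for a in amax]
        if fit_sigma:
            theta0.append([np.log(0.3) if k == 0
                           else np.log(rng.uniform(0.1, 0.8))])
            bounds += [(-10.0, 1.5)]
        res = minimize(negloglik, np.concatenate(theta0), method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 1000})
        lls.append(-float(res.fun))
        if best is None or lls[-1] > best[0]:
            best = (lls[-1], res.x)

    ll_best, theta = best
    phi, amp, sg = unpack(theta)
    phi = np.mod(phi, 2 * np.pi)
    if amplitude_locked:
        model = BurstCycleModel.locked(p, phi, global_noise_sd=sg)
    else:
        model = BurstCycleModel(mean_prob=p, amp=np.asarray(amp)[:, None],
                                phase=phi[:, None], global_noise_sd=sg)
    return BurstyFitResult(model=model, log_likelihood=ll_best,
                           n_restarts_used=max(1, n_restarts),
                           restart_agreement=_agreement(lls, ll_best),
                           fitted_global_noise=sg if fit_sigma else None)


# ---------------------------------------------------------------------------
# switch models
# ---------------------------------------------------------------------------

def fit_switch(est: MomentEstimates, n_states: int = 2, P1: float = 0.5,
               n_restarts: int = 10, rng_seed=None) -> BurstyFitResult:
    """Fit a 2-state switch with known state probability P1.

    Means are pinned: q_{i,2} = (p̂_i − P1 q_{i,1}) / (1 − P1), with q_{i,1}
    restricted to the interval that keeps q_{i,2} inside [0, 1], so the
    fitted model reproduces p̂ exactly.  The state-swap degeneracy (states
    relabeled together with P1 ↔ 1−P1) is resolved by reporting the labeling
    whose first state has the larger mean burst probability.
    """
    if n_states != 2:
        raise ValueError(
            "only 2-state switches are identifiable from pairwise data with "
            "a known state probability; higher state counts need additional "
            "constraints (see dof_report)")
    if not 0.0 < P1 < 1.0:
        raise ValueError("P1 must lie strictly between 0 and 1")
    p = np.asarray(est.p_hat, dtype=float)
    n = p.size
    for g in range(n):
        if not np.isfinite(p[g]) or not 0.0 <= p[g] <= 1.0:
            raise ValueError(
                f"gene {est.gene_names[g]!r} has infeasible mean burst "
                f"probability {p[g]!r} for P1={P1}")
    P2 = 1.0 - P1
    lo = np.maximum(0.0, (p - P2) / P1)
    hi = np.minimum(1.0, p / P1)

    def q2_of(q1):
        return (p - P1 * q1) / P2

    def negloglik(q1):
        q2 = q2_of(q1)
        c = P1 * np.outer(q1, q1) + P2 * np.outer(q2, q2) - np.outer(p, p)
        return -cov_loglik(c, est)

    rng = np.random.default_rng(rng_seed)
    best = None
    lls = []
    for _ in range(max(1, n_restarts)):
        q0 = rng.uniform(lo, hi)
        res = minimize(negloglik, q0, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)), options={"maxiter": 1000})
        lls.append(-float(res.fun))
        if best is None or lls[-1] > best[0]:
            best = (lls[-1], res.x)

    ll_best, q1 = best
    q2 = q2_of(q1)
    state_prob = np.array([P1, P2])
    q = np.stack([q1, q2], axis=1)
    if q1.mean() < q2.mean():  # canonical labeling: state 1 = high state
        q = q[:, ::-1]
        state_prob = state_prob[::-1]
    model = SwitchModel(state_prob=state_prob,
                        burst_prob=np.clip(q, 0.0, 1.0))
    return BurstyFitResult(model=model, log_likelihood=ll_best,
                           n_restarts_used=max(1, n_restarts),
                           restart_agreement=_agreement(lls, ll_best))


def reconstruction_error_switch(true: SwitchModel, est: SwitchModel) -> float:
    """Switch reconstruction error Δ, quotiented over state relabelings.

    Δ² = (1/N) Σ_i [Σ_s P_s (q̂_{i,s} − q_{i,s})²]
                  / [Σ_s P_s (q_{i,s} − p̄_i)²],
    with P_s and p̄ from the true model, minimized over permutations of the
    estimated states.  Genes with no state-to-state variation carry no
    normalization and are excluded with a warning.
    """
    if true.n_genes != est.n_genes or true.n_states != est.n_states:
        raise ValueError("models must share gene and state counts")
    P = true.state_prob
    q = true.burst_prob
    pbar = q @ P
    den = ((q - pbar[:, None]) ** 2) @ P
    keep = den > 1e-12
    if not np.all(keep):
        warnings.warn(
            "genes with zero state-to-state variation excluded from "
            "reconstruction error", stacklevel=2)
    if not np.any(keep):
        raise ValueError("no gene has state-to-state variation")
    best = np.inf
    for perm in permutations(range(true.n_states)):
        qe = est.burst_prob[:, perm]
        num = ((qe - q) ** 2) @ P
        best = min(best, float(np.mean(num[keep] / den[keep])))
    return float(np.sqrt(best))


def phase_agreement(phase_true, phase_est) -> float:
    """Mean resultant of phase differences after quotienting symmetries.

    Equals 1 iff the estimated phases match the true ones up to a global
    shift and/or time reflection; near 0 for unrelated phases.
    """
    a = np.asarray(phase_true, dtype=float)
    b = np.asarray(phase_est, dtype=float)
    fwd = np.abs(np.mean(np.exp(1j * (b - a))))
    rev = np.abs(np.mean(np.exp(1j * (b + a))))
    return float(max(fwd, rev))
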