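"""PCA of the estimated covariance with iterative diagonal completion.

Pairwise FISH never observes same-gene coincidences, so the diagonal of the
covariance estimate is missing.  Starting from a zero diagonal, the matrix
is eigendecomposed, the diagonal is rebuilt from the top-r rank
reconstruction, and the procedure is iterated to convergence; off-diagonal
entries are never modified.  The spectrum of the completed matrix reveals
the complexity of the dynamics (number of harmonics / switch states), and
for a 2-state switch the principal eigenvector directly yields the vector of
between-state burst-probability differences, giving a full non-iterative
parameter reconstruction to compare against MLE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import MomentEstimates
from .models import SwitchModel

__all__ = [
    "PcaResult",
    "pca_complete",
    "infer_complexity",
    "switch_from_pca",
]

#: an eigenvalue counts as signal when larger than this factor times the
#: median absolute eigenvalue (the "significantly larger than the rest"
#: heuristic)
DEFAULT_NOISE_FACTOR = 5.0

#: dynamics consistent with each covariance rank (rank r: cycle with r/2
#: harmonics for even r, cycle plus global noise for odd r >= 3, and always
#: an (r+1)-state switch)
_RANK_MODELS = {
    0: ["no dynamics (zero covariance)"],
    1: ["2-state switch"],
    2: ["1-harmonic cycle", "3-state switch"],
    3: ["1-harmonic cycle + global noise", "4-state switch"],
    4: ["2-harmonic cycle", "5-state switch"],
    5: ["2-harmonic cycle + global noise", "6-state switch"],
}


@dataclass
class PcaResult:
    completed_cov: np.ndarray
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # orthonormal columns, matching order
    n_iterations: int
    converged: bool
    inferred_rank: int
    imputed_pairs: list[tuple[int, int]]


def _offdiag_matrix(c_hat) -> tuple[np.ndarray, list[tuple[int, int]]]:
    if isinstance(c_hat, MomentEstimates):
        c_hat = c_hat.c_hat
    c = np.array(c_hat, dtype=float)
    n = c.shape[0]
    np.fill_diagonal(c, 0.0)
    imputed = [(i, j) for i in range(n) for j in range(i + 1, n)
               if not np.isfinite(c[i, j])]
    c[~np.isfinite(c)] = 0.0  # missing pairs: unbiased under no signal
    return 0.5 * (c + c.T), imputed


def pca_complete(c_hat, rank: int = 1, tol: float = 1e-10,
                 max_iter: int = 500,
                 noise_factor: float = DEFAULT_NOISE_FACTOR) -> PcaResult:
    """Iteratively complete the missing diagonal from a rank-r reconstruction.

    ``c_hat`` is a covariance matrix (diagonal ignored; NaN allowed for
    missing pairs, imputed as 0 and reported) or a
    :class:`~fishdyn.binarize.MomentEstimates`.  Iterates: eigendecompose,
    keep the top-``rank`` eigenpairs, rebuild the diagonal from the low-rank
    reconstruction; stops when the largest diagonal change is below ``tol``.
    Non-convergence is reported via ``converged=False``, not an exception.
    """
    off, imputed = _offdiag_matrix(c_hat)
    n = off.shape[0]
    c = off.copy()  # zero diagonal start
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        ev, vec = np.linalg.eigh(c)
        order = np.argsort(ev)[::-1]
        top = order[:rank]
        recon_diag = np.einsum("ik,k,ik->i", vec[:, top], ev[top],
                               vec[:, top])
        change = np.max(np.abs(recon_diag - np.diag(c)))
        c = off.copy()
        c[np.diag_indices(n)] = recon_diag
        if change < tol:
            converged = True
            break
    ev, vec = np.linalg.eigh(c)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    return PcaResult(completed_cov=c, eigenvalues=ev, eigenvectors=vec,
                     n_iterations=n_it, converged=converged,
                     inferred_rank=infer_complexity(ev, factor=noise_factor)[0],
                     imputed_pairs=imputed)


def infer_complexity(eigenvalues, noise_scale: float | None = None,
                     factor: float = DEFAULT_NOISE_FACTOR
                     ) -> tuple[int, list[str]]:
    """Infer the dynamical complexity from a descending eigenvalue spectrum.

    The rank is the number of eigenvalues above a noise threshold:
    ``factor * noise_scale`` when an estimated noise level is supplied,
    otherwise ``factor`` times the median absolute eigenvalue of the lower
    half of the spectrum (robust even when the signal eigenvalues are not a
    small minority, as with few genes), plus a machine-precision floor.
    Returns the rank together with the model families consistent with it --
    the ambiguity between cycles and switches of matching rank cannot be
    resolved by pairwise data and needs prior information.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size and np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be sorted in descending order")
    if noise_scale is None:
        lower = np.abs(ev[ev.size // 2:]) if ev.size else np.zeros(1)
        noise_scale = float(np.median(lower)) if lower.size else 0.0
    floor = 1e-10 * float(np.max(np.abs(ev))) if ev.size else 0.0
    rank = int(np.sum(ev > factor * noise_scale + floor))
    models = _RANK_MODELS.get(
        rank, [f"{(rank + 1) // 2}-harmonic cycle family",
               f"{rank + 1}-state switch"])
    return rank, models


def switch_from_pca(pca: PcaResult, p_hat, P1: float) -> SwitchModel:
    """Reconstruct a 2-state switch from the principal eigenpair.

    For a 2-state switch c = P1(1−P1) δ δᵀ with δ the vector of per-gene
    burst-probability differences between the states, so
    δ = v √(λ₁ / (P1(1−P1))) up to sign.  Combined with the pinned means:
    q_{i,1} = p̂_i + (1−P1) δ_i and q_{i,2} = p̂_i − P1 δ_i, clipped to
    [0, 1]; the sign is chosen so state 1 has the larger mean probability.
    """
    if not 0.0 < P1 < 1.0:
        raise ValueError("P1 must lie strictly between 0 and 1")
    lam = float(pca.eigenvalues[0])
    if lam <= 0:
        raise ValueError("leading eigenvalue is not positive: no switch "
                         "signal in the covariance")
    p = np.asarray(p_hat, dtype=float)
    delta = pca.eigenvectors[:, 0] * np.sqrt(lam / (P1 * (1.0 - P1)))
    if delta.mean() < 0:
        delta = -delta
    q1 = p + (1.0 - P1) * delta
    q2 = p - P1 * delta
    q = np.stack([q1, q2], axis=1)
    clip_fraction = float(np.mean((q < 0) | (q > 1)))
    model = SwitchModel(state_prob=np.array([P1, 1.0 - P1]),
                        burst_prob=np.clip(q, 0.0, 1.0))
    model.clip_fraction = clip_fraction  # diagnostic attribute
    return model
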