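"""SO-NMF: synergy analysis of static-optimization activations.

Non-negative matrix factorization decomposes the (f x m) SO activation
matrix into n time-varying synergy activations H (f x n) and n time-invariant
synergy vectors W (n x m),

    a* = H @ W = sum_i H_i W_i

minimizing the Frobenius reconstruction error.  To mirror the synergy-vector
constraint of synergy optimization, each W row is rescaled after every
update to sum to one (L1), with the compensating scale absorbed into the
corresponding H column — a reparameterization that leaves the cost exactly
unchanged.  The reconstructed activations are then pushed back through the
rigid-tendon muscle model to obtain reconstructed forces and joint moments;
because NMF knows nothing about joint moments, those reconstructed moments
generally track the inverse-dynamics moments worse than SO's exact ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .muscle_model import (
    DEFAULT_CURVES,
    HillCurves,
    MuscleParams,
    compute_joint_moments,
    compute_muscle_forces,
)
from .synthetic_data import TrialData

__all__ = ["ReconstructionResult", "fit_nmf_l1", "reconstruct_activations", "reconstructed_moments"]

_EPS = 1e-12


@dataclass
class ReconstructionResult:
    """Synergy factors plus the reconstructed activation/force/moment chain."""

    W: np.ndarray  # (n, m) synergy vectors, rows sum to 1
    H: np.ndarray  # (f, n) synergy activations
    a_star: np.ndarray  # (f, m) = H @ W
    f_star: np.ndarray  # (f, m) reconstructed forces, N
    q_star: np.ndarray  # (f, d) reconstructed joint moments, N*m


def _normalize_rows(W: np.ndarray, H: np.ndarray, norm: str):
    """Rescale W rows to unit sum (or unit L2 norm), absorbing scale into H."""
    if norm == "l1":
        s = W.sum(axis=1)
    elif norm == "l2":
        s = np.linalg.norm(W, axis=1)
    else:
        raise InvalidArgumentError(f"unknown norm {norm!r}")
    s = np.where(s < _EPS, 1.0, s)
    return W / s[:, None], H * s[None, :]


def fit_nmf_l1(
    a: np.ndarray,
    n: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    norm: str = "l1",
):
    """Factor a non-negative activation matrix into n synergies, W rows summing to 1.

    Multiplicative-update minimization of ||a - H W||_F with the row
    normalization applied after every iteration (cost-invariant).  The best
    of ``n_restarts`` seeded random initializations is returned as
    ``(W, H)``; convergence is declared when the relative Frobenius-error
    change drops below ``tol``.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise InvalidArgumentError("activation matrix must be 2-D")
    if np.any(a < 0):
        raise InvalidArgumentError("NMF input must be non-negative")
    f, m = a.shape
    if not 1 <= n <= min(f, m):
        raise InvalidArgumentError(f"n must lie in [1, {min(f, m)}]")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4E]))
    scale = max(a.max(), _EPS)
    best = None
    for _ in range(max(1, n_restarts)):
        H = rng.uniform(0.0, 1.0, (f, n)) * scale
        W = rng.uniform(_EPS, 1.0, (n, m))
        W, H = _normalize_rows(W, H, norm)
        err_prev = np.inf
        for _it in range(max_iter):
            # Lee-Seung multiplicative updates for ||a - H W||_F
            H *= (a @ W.T) / (H @ (W @ W.T) + _EPS)
            W *= (H.T @ a) / ((H.T @ H) @ W + _EPS)
            W, H = _normalize_rows(W, H, norm)
            err = np.linalg.norm(a - H @ W)
            if err_prev - err < tol * max(err_prev, _EPS):
                break
            err_prev = err
        err = np.linalg.norm(a - H @ W)
        if best is None or err < best[0]:
            best = (err, W.copy(), H.copy())
    _, W, H = best
    return W, H


def reconstruct_activations(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Reconstructed activations a* = H @ W (sum of rank-1 synergy terms)."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.ndim != 2 or H.ndim != 2 or H.shape[1] != W.shape[0]:
        raise InvalidArgumentError(
            f"incompatible shapes H {H.shape} x W {W.shape} for reconstruction"
        )
    return H @ W


def reconstructed_moments(
    a_star: np.ndarray,
    trial: TrialData,
    params: MuscleParams,
    curves: HillCurves = DEFAULT_CURVES,
) -> tuple[np.ndarray, np.ndarray]:
    """Forces and joint moments produced by reconstructed activations.

    Delegates to the rigid-tendon muscle model; the reconstructed moments
    ``q_star`` are generally different from the trial's inverse-dynamics
    moments because the factorization optimizes activation reconstruction,
    not moment tracking.
    """
    a_star = np.asarray(a_star, dtype=float)
    if np.any(a_star < 0):
        raise InvalidArgumentError("reconstructed activations must be non-negative")
    f_star = compute_muscle_forces(a_star, trial.lmt, trial.vmt, params, curves)
    q_star = compute_joint_moments(f_star, trial.moment_arms)
    return f_star, q_star


def analyze_so_activations(
    a_so: np.ndarray,
    trial: TrialData,
    params: MuscleParams,
    n: int,
    seed: int = 0,
    n_restarts: int = 10,
    curves: HillCurves = DEFAULT_CURVES,
) -> ReconstructionResult:
    """Full SO-NMF chain for one synergy count: factor, reconstruct, re-derive moments."""
    W, H = fit_nmf_l1(a_so, n, seed=seed, n_restarts=n_restarts)
    a_star = reconstruct_activations(W, H)
    f_star, q_star = reconstructed_moments(a_star, trial, params, curves)
    return ReconstructionResult(W=W, H=H, a_star=a_star, f_star=f_star, q_star=q_star)
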