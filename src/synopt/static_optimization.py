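"""Static optimization (SO) of the muscle redundancy problem.

Each time frame is solved independently: minimize the sum of squared
activations subject to exact reproduction of the inverse-dynamics joint
moments and activation bounds,

    min_a  sum_i a_i^2
    s.t.   Q^MT(a) = Q^ID      (d equality constraints)
           0 <= a_i <= 1

With the rigid-tendon muscle model the force is affine in the activation for
fixed kinematics, so the moment constraints are linear and each frame is a
strictly convex quadratic program with a unique solution.  The first frame is
solved from the best of several seeded random initial guesses; later frames
are warm-started from the previous frame's optimum, which is both fast and —
because the problem is convex — yields the same solution a cold start would.

Because the constraints are equalities, the solved moments match the
inverse-dynamics moments to solver tolerance, i.e. moment-tracking VAF is
100% up to round-off whenever the frame is feasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import InfeasibleFrameError, InvalidArgumentError
from .muscle_model import DEFAULT_CURVES, HillCurves, MuscleParams, force_decomposition
from .synthetic_data import TrialData

__all__ = ["SOConfig", "solve_frame", "solve_trial"]


@dataclass
class SOConfig:
    """Solver settings for static optimization.

    ``constraint_tol`` is relative to the per-DOF maximum |Q^ID| over the
    trial.  ``reserves`` switches to a penalty formulation that adds residual
    torques instead of hard equality constraints (off by default).
    """

    n_multistarts: int = 5
    constraint_tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0
    reserves: bool = False
    reserve_weight: float = 1e4

    def __post_init__(self):
        if self.n_multistarts < 1:
            raise InvalidArgumentError("n_multistarts must be >= 1")


def _frame_qp(q_id_j, r_j, lmt_j, vmt_j, params, curves):
    """Linear constraint data for one frame: G a = b with G (d, m)."""
    gain, passive = force_decomposition(
        np.atleast_2d(lmt_j), np.atleast_2d(vmt_j), params, curves
    )
    G = r_j * gain[0][None, :]
    b = np.asarray(q_id_j, dtype=float) - r_j @ passive[0]
    return G, b


def _solve_qp(G, b, scale, a_init, config):
    """min ||a||^2 s.t. G a = b (rows scaled), 0 <= a <= 1, via SLSQP."""
    m = G.shape[1]
    Gs = G / scale[:, None]
    bs = b / scale
    res = optimize.minimize(
        lambda a: a @ a,
        np.clip(a_init, 0.0, 1.0),
        jac=lambda a: 2.0 * a,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda a: Gs @ a - bs, "jac": lambda a: Gs}],
        options={"ftol": 1e-14, "maxiter": config.max_iter},
    )
    residual = float(np.max(np.abs(Gs @ res.x - bs)))
    return np.clip(res.x, 0.0, 1.0), residual


def solve_frame(
    q_id_j: np.ndarray,
    r_j: np.ndarray,
    lmt_j: np.ndarray,
    vmt_j: np.ndarray,
    params: MuscleParams,
    a_init: np.ndarray | None = None,
    config: SOConfig | None = None,
    curves: HillCurves = DEFAULT_CURVES,
    scale: np.ndarray | None = None,
    frame_index: int = 0,
) -> np.ndarray:
    """Minimum-effort activations for a single frame.

    ``scale`` holds the per-DOF moment normalizers (defaults to
    max(|q_id_j|, 1) when the frame is solved in isolation).  Raises
    :class:`InfeasibleFrameError` with the best residual when no activation
    vector within bounds satisfies the moment constraints to tolerance.
    """
    config = config or SOConfig()
    q_id_j = np.asarray(q_id_j, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    m = r_j.shape[1]
    if a_init is None:
        a_init = np.full(m, 0.1)
    a_init = np.asarray(a_init, dtype=float)
    if np.any(a_init < -1e-12) or np.any(a_init > 1 + 1e-12):
        raise InvalidArgumentError("a_init must lie in [0, 1]")
    G, b = _frame_qp(q_id_j, r_j, lmt_j, vmt_j, params, curves)
    if scale is None:
        scale = np.maximum(np.abs(q_id_j), 1.0)

    if config.reserves:
        Gs, bs = G / scale[:, None], b / scale
        w = config.reserve_weight
        res = optimize.minimize(
            lambda a: a @ a + w * np.sum((Gs @ a - bs) ** 2),
            np.clip(a_init, 0, 1),
            jac=lambda a: 2 * a + 2 * w * Gs.T @ (Gs @ a - bs),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * m,
            options={"maxiter": config.max_iter},
        )
        return np.clip(res.x, 0.0, 1.0)

    a, residual = _solve_qp(G, b, scale, a_init, config)
    if residual > config.constraint_tol:
        # one retry from the minimum-norm least-squares point before giving up
        a0 = np.clip(np.linalg.lstsq(G, b, rcond=None)[0], 0.0, 1.0)
        a2, r2 = _solve_qp(G, b, scale, a0, config)
        if r2 < residual:
            a, residual = a2, r2
    if residual > config.constraint_tol:
        raise InfeasibleFrameError(frame_index, residual, config.constraint_tol)
    return a


def solve_trial(
    trial: TrialData,
    params: MuscleParams,
    config: SOConfig | None = None,
    curves: HillCurves = DEFAULT_CURVES,
) -> np.ndarray:
    """Solve every frame of a trial; returns the (f, m) activation matrix.

    Frame 0 takes the best feasible solution over ``n_multistarts`` seeded
    uniform-random initial guesses; each subsequent frame is warm-started
    from its predecessor (activations vary smoothly during gait, so the
    previous optimum is an excellent initial guess).
    """
    config = config or SOConfig()
    if trial.q_id is None:
        raise InvalidArgumentError("trial has no inverse-dynamics moments (q_id)")
    f, d, m = trial.moment_arms.shape
    scale = np.abs(trial.q_id).max(axis=0)
    zero = scale == 0
    if np.any(zero):
        warnings.warn("all-zero inverse-dynamics moment for some DOF; normalizer set to 1")
        scale = np.where(zero, 1.0, scale)

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x50]))
    a = np.empty((f, m))

    best = None
    errors = []
    for _ in range(config.n_multistarts):
        a0 = rng.uniform(0.0, 1.0, m)
        try:
            cand = solve_frame(
                trial.q_id[0], trial.moment_arms[0], trial.lmt[0], trial.vmt[0],
                params, a0, config, curves, scale, frame_index=0,
            )
        except InfeasibleFrameError as exc:
            errors.append(exc)
            continue
        cost = float(cand @ cand)
        if best is None or cost < best[0]:
            best = (cost, cand)
    if best is None:
        raise errors[-1]
    a[0] = best[1]

    for j in range(1, f):
        a[j] = solve_frame(
            trial.q_id[j], trial.moment_arms[j], trial.lmt[j], trial.vmt[j],
            params, a[j - 1], config, curves, scale, frame_index=j,
        )
    return a
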