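"""Synergy optimization (SynO).

SynO solves the muscle redundancy problem over all time frames at once by
constraining the activation matrix to a low-rank synergy structure

    a (f x m)  =  C(Cp) (f x n_s)  @  V (n_s x m)

where each column of C is a single time-varying synergy activation traced by
a clamped B-spline with p = (f - 1)/5 + 1 (nearest integer) control nodes,
and each row of V is a time-invariant synergy vector of m weights.  The
design vector stacks the spline nodes and the weights, n_s * (p + m)
variables in total.  The cost balances inverse-dynamics moment tracking
against effort with out-of-bounds penalties:

    J = sum_j [ beta * sum_k ((Q^MT_jk - Q^ID_jk) / max_t |Q^ID_k|)^2
                + sum_i (a_ij^2 + lambda_ij (a_ij - 1)^2) ]

with beta = 100 and lambda_ij = 1e5 when a_ij > 1, else 0 (activations are
non-negative by construction, so only the upper bound needs a penalty).
Linear equality constraints fix each V row sum to one — making the C/V split
unique — and all design variables are bounded below by zero.  The problem is
non-convex; it is solved by a gradient-based local method (SLSQP with the
analytic gradient, which is closed-form because forces are affine in the
activations) from several seeded random feasible starts, keeping the
lowest-cost solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline

from .exceptions import InvalidArgumentError, OptimizationFailureError
from .muscle_model import DEFAULT_CURVES, HillCurves, MuscleParams, force_decomposition
from .synthetic_data import TrialData

__all__ = [
    "SynergySet",
    "BSplineControl",
    "SynOConfig",
    "node_count",
    "spline_basis",
    "evaluate_synergy_activations",
    "construct_activations",
    "syno_objective",
    "solve_syno",
    "fit_nodes_to_profiles",
]


@dataclass
class SynergySet:
    """A synergy decomposition: activations C (f x n_s) and vectors V (n_s x m)."""

    C: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.C.ndim != 2 or self.V.ndim != 2 or self.C.shape[1] != self.V.shape[0]:
            raise InvalidArgumentError("C (f, n_s) and V (n_s, m) must be compatible")

    @property
    def n_synergies(self) -> int:
        return self.C.shape[1]

    @property
    def activations(self) -> np.ndarray:
        return self.C @ self.V


@dataclass
class BSplineControl:
    """Clamped B-spline control values for the synergy activation columns."""

    nodes: np.ndarray  # (p, n_s), non-negative
    degree: int = 3
    duration: float = 1.0  # trial duration (f - 1) * dt, seconds

    def __post_init__(self):
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        if np.any(self.nodes < 0):
            raise InvalidArgumentError("spline nodes must be non-negative")
        if self.degree < 0:
            raise InvalidArgumentError("degree must be non-negative")


@dataclass
class SynOConfig:
    """SynO solver settings.

    ``beta`` weights the normalized moment-tracking error against the effort
    term; ``lambda_pen`` is the penalty on activations above one.  Five
    seeded random starts of the gradient solver are used by default, the
    lowest-cost solution winning.
    """

    beta: float = 100.0
    lambda_pen: float = 1e5
    n_multistarts: int = 5
    seed: int = 0
    degree: int = 3
    max_iter: int = 400
    ftol: float = 1e-10

    def __post_init__(self):
        if self.beta <= 0:
            raise InvalidArgumentError("beta must be positive")
        if self.lambda_pen < 0:
            raise InvalidArgumentError("lambda_pen must be non-negative")
        if self.n_multistarts < 1:
            raise InvalidArgumentError("n_multistarts must be >= 1")


def node_count(f: int) -> int:
    """Number of B-spline nodes per synergy activation: (f - 1)/5 + 1, half-up."""
    if f < 1:
        raise InvalidArgumentError("f must be >= 1")
    return int(np.floor((f - 1) / 5 + 1 + 0.5))


def spline_basis(f: int, p: int, degree: int = 3, dt: float = 1.0) -> np.ndarray:
    """Dense (f, p) clamped uniform B-spline basis on the trial time grid.

    The degree is reduced to p - 1 when fewer nodes than degree + 1 are
    available only if p >= 1; with clamped knots the basis is a partition of
    unity, so non-negative nodes yield non-negative activations.
    """
    if p < 1:
        raise InvalidArgumentError("need at least one node")
    if p == 1:
        return np.ones((f, 1))
    k = min(degree, p - 1)
    if k < 1:
        raise InvalidArgumentError("need at least degree + 1 nodes")
    T = (f - 1) * dt
    interior = np.linspace(0.0, T, p - k + 1)[1:-1]
    knots = np.concatenate([np.zeros(k + 1), interior, np.full(k + 1, T)])
    t = np.arange(f) * dt
    t = np.clip(t, 0.0, T)  # guard round-off at the right endpoint
    return BSpline.design_matrix(t, knots, k).toarray()


def evaluate_synergy_activations(ctrl: BSplineControl, f: int, dt: float = 1.0) -> np.ndarray:
    """Evaluate the spline-parameterized synergy activations C (f, n_s)."""
    p = ctrl.nodes.shape[0]
    if p < ctrl.degree + 1 and p > 1:
        raise InvalidArgumentError(
            f"{p} nodes cannot support degree {ctrl.degree}; need degree + 1"
        )
    B = spline_basis(f, p, ctrl.degree, dt)
    return B @ ctrl.nodes


def construct_activations(C: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Activation matrix a = C @ V; non-negative whenever C and V are."""
    C = np.asarray(C, dtype=float)
    V = np.asarray(V, dtype=float)
    if C.ndim != 2 or V.ndim != 2 or C.shape[1] != V.shape[0]:
        raise InvalidArgumentError(
            f"incompatible shapes {C.shape} x {V.shape} for activation construction"
        )
    return C @ V


class _SynOProblem:
    """Precomputed trial quantities and the packed objective/gradient."""

    def __init__(self, trial: TrialData, params: MuscleParams, n_s: int,
                 config: SynOConfig, curves: HillCurves):
        if trial.q_id is None:
            raise InvalidArgumentError("trial has no inverse-dynamics moments (q_id)")
        if n_s < 1:
            raise InvalidArgumentError("n_s must be >= 1")
        self.trial = trial
        self.config = config
        self.n_s = n_s
        f, d, m = trial.moment_arms.shape
        self.f, self.d, self.m = f, d, m
        self.p = node_count(f)
        self.B = spline_basis(f, self.p, config.degree, trial.dt)
        gain, passive = force_decomposition(trial.lmt, trial.vmt, params, curves)
        # moments are affine in a: Q[j,k] = sum_i Rg[j,k,i] a[j,i] + q_pass[j,k]
        self.Rg = trial.moment_arms * gain[:, None, :]
        self.q_pass = np.einsum("jki,ji->jk", trial.moment_arms, passive)
        scale = np.abs(trial.q_id).max(axis=0)
        if np.any(scale == 0):
            warnings.warn(
                "all-zero inverse-dynamics moment for some DOF; normalizer set to 1"
            )
            scale = np.where(scale == 0, 1.0, scale)
        self.scale = scale
        self.n_design = n_s * (self.p + m)

    def unpack(self, x: np.ndarray):
        nodes = x[: self.p * self.n_s].reshape(self.p, self.n_s)
        V = x[self.p * self.n_s:].reshape(self.n_s, self.m)
        return nodes, V

    def cost_grad(self, x: np.ndarray):
        cfg = self.config
        nodes, V = self.unpack(x)
        C = self.B @ nodes
        a = C @ V
        q_mt = np.einsum("jki,ji->jk", self.Rg, a) + self.q_pass
        e = (q_mt - self.trial.q_id) / self.scale[None, :]
        over = np.maximum(a - 1.0, 0.0)
        cost = cfg.beta * np.sum(e**2) + np.sum(a**2) + cfg.lambda_pen * np.sum(over**2)
        # dJ/da, then chain through a = B @ nodes @ V
        da = (
            2.0 * cfg.beta * np.einsum("jk,jki->ji", e / self.scale[None, :], self.Rg)
            + 2.0 * a
            + 2.0 * cfg.lambda_pen * over
        )
        g_nodes = self.B.T @ (da @ V.T)
        g_V = C.T @ da
        return cost, np.concatenate([g_nodes.ravel(), g_V.ravel()])


def syno_objective(
    design: np.ndarray,
    trial: TrialData,
    params: MuscleParams,
    n_s: int,
    config: SynOConfig | None = None,
    curves: HillCurves = DEFAULT_CURVES,
) -> float:
    """Evaluate the SynO cost for a packed design vector (nodes then V)."""
    config = config or SynOConfig()
    prob = _SynOProblem(trial, params, n_s, config, curves)
    design = np.asarray(design, dtype=float)
    if design.shape != (prob.n_design,):
        raise InvalidArgumentError(
            f"design must have {prob.n_design} entries (n_s * (p + m))"
        )
    if np.any(design < 0):
        raise InvalidArgumentError("design variables must be non-negative")
    return float(prob.cost_grad(design)[0])


def fit_nodes_to_profiles(C: np.ndarray, dt: float, degree: int = 3) -> np.ndarray:
    """Least-squares non-negative spline nodes approximating given profiles.

    Used to express a known synergy-activation matrix (e.g. a simulation
    ground truth) in the SynO design space for cost comparisons.
    """
    f = C.shape[0]
    p = node_count(f)
    B = spline_basis(f, p, degree, dt)
    nodes, _, _, _ = np.linalg.lstsq(B, C, rcond=None)
    return np.clip(nodes, 0.0, None)


def solve_syno(
    trial: TrialData,
    params: MuscleParams,
    n_s: int,
    config: SynOConfig | None = None,
    curves: HillCurves = DEFAULT_CURVES,
):
    """Solve SynO with ``n_s`` synergies.

    Runs ``config.n_multistarts`` gradient-based solves from seeded random
    feasible starts (V rows drawn from a flat Dirichlet so each sums to one,
    nodes uniform on [0, 1]) and keeps the lowest-cost converged solution.

    Returns ``(synergies, activations, diagnostics)`` where ``synergies`` is
    a :class:`SynergySet` with V rows summing to one, ``activations`` is the
    (f, m) matrix C @ V, and ``diagnostics`` maps per-start costs, the
    winning start, per-DOF moment VAF, and the final cost.
    """
    config = config or SynOConfig()
    prob = _SynOProblem(trial, params, n_s, config, curves)
    p, m = prob.p, prob.m

    # linear equality: each V row sums to one
    A_eq = np.zeros((n_s, prob.n_design))
    for s in range(n_s):
        A_eq[s, n_s * p + s * m: n_s * p + (s + 1) * m] = 1.0

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5A]))
    starts = []
    for _ in range(config.n_multistarts):
        nodes0 = rng.uniform(0.0, 1.0, (p, n_s))
        V0 = rng.dirichlet(np.ones(m), size=n_s)
        starts.append(np.concatenate([nodes0.ravel(), V0.ravel()]))

    results = []
    for x0 in starts:
        res = optimize.minimize(
            prob.cost_grad,
            x0,
            jac=True,
            method="SLSQP",
            bounds=[(0.0, None)] * prob.n_design,
            constraints=[
                {"type": "eq", "fun": lambda x: A_eq @ x - 1.0, "jac": lambda x: A_eq}
            ],
            options={"ftol": config.ftol, "maxiter": config.max_iter},
        )
        feasible = (
            np.max(np.abs(A_eq @ res.x - 1.0)) < 1e-6 and np.min(res.x) > -1e-8
        )
        results.append((float(res.fun), res, feasible))

    usable = [t for t in results if t[2]]
    if not usable:
        raise OptimizationFailureError(
            "no SynO start produced a feasible converged solution",
            diagnostics=[(c, r.message, r.nit) for c, r, _ in results],
        )
    best_cost, best, _ = min(usable, key=lambda t: t[0])

    x = np.clip(best.x, 0.0, None)
    nodes, V = prob.unpack(x)
    # remove round-off drift in the equality constraint
    V = V / V.sum(axis=1, keepdims=True)
    C = prob.B @ nodes
    a = C @ V
    q_mt = np.einsum("jki,ji->jk", prob.Rg, a) + prob.q_pass
    ss_res = np.sum((q_mt - trial.q_id) ** 2, axis=0)
    ss_ref = np.sum(trial.q_id**2, axis=0)
    vaf = 100.0 * (1.0 - ss_res / np.where(ss_ref == 0, 1.0, ss_ref))

    diagnostics = {
        "start_costs": [c for c, _, _ in results],
        "start_feasible": [feas for _, _, feas in results],
        "best_start": int(np.argmin([c if feas else np.inf for c, _, feas in results])),
        "cost": best_cost,
        "vaf_per_dof": vaf,
        "n_iter": int(best.nit),
        "nodes": nodes,
    }
    return SynergySet(C=C, V=V), a, diagnostics
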