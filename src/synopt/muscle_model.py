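"""Rigid-tendon Hill-type muscle model.

The model maps activations to musculotendon forces and, through the signed
moment-arm Jacobian, to joint moments.  With a rigid tendon the tendon is
fixed at its slack length ``lts``, so the fiber state follows directly from
the musculotendon kinematics: the fiber length projected on the tendon line
is ``lmt - lts`` and the pennation angle follows from the constant-thickness
assumption ``sin(alpha) * l_fiber = sin(alpha0) * l0``.  The force of muscle
*i* at frame *j* is

    F = f_max * (a * fL(l~) * fV(v~) + fPE(l~)) * cos(alpha)

with normalized fiber length ``l~ = l_fiber / l0`` and normalized fiber
velocity ``v~ = (vmt * cos(alpha)) / (vmax * l0)`` (lengthening positive).
The normalized curves fL, fV, fPE are pluggable; the defaults are a Gaussian
active force-length, a smooth asinh force-velocity and an exponential passive
force-length curve, all satisfying fL(1) = 1, fV(0) = 1, fPE >= 0.

For fixed kinematics the force is affine in the activation,
``F = gain * a + passive``; :func:`force_decomposition` exposes that split,
which the optimization modules exploit for linear moment constraints and
closed-form gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "HillCurves",
    "DEFAULT_CURVES",
    "UNIT_CURVES",
    "MuscleParams",
    "force_decomposition",
    "compute_muscle_forces",
    "compute_joint_moments",
]


@dataclass(frozen=True)
class HillCurves:
    """Pluggable normalized Hill curves.

    ``fl`` is the active force-length curve with fl(1) = 1, ``fv`` the
    force-velocity curve with fv(0) = 1 (argument is normalized fiber
    velocity, lengthening positive), ``fpe`` the non-negative passive
    force-length curve.
    """

    fl: Callable[[np.ndarray], np.ndarray]
    fv: Callable[[np.ndarray], np.ndarray]
    fpe: Callable[[np.ndarray], np.ndarray]


def _gaussian_fl(l_norm: np.ndarray) -> np.ndarray:
    return np.exp(-(((l_norm - 1.0) / 0.45) ** 2))


def _asinh_fv(v_norm: np.ndarray) -> np.ndarray:
    # smooth, monotone, fv(0) = 1, ~0.11 at v~ = -1, clamped at 0 beyond
    return np.maximum(0.318 * np.arcsinh(8.149 * v_norm) + 1.0, 0.0)


def _exp_fpe(l_norm: np.ndarray) -> np.ndarray:
    return 0.05 * np.maximum(np.exp(8.0 * (l_norm - 1.0)) - 1.0, 0.0)


DEFAULT_CURVES = HillCurves(fl=_gaussian_fl, fv=_asinh_fv, fpe=_exp_fpe)

#: Constant-one active curves and zero passive curve, for analytic oracles.
UNIT_CURVES = HillCurves(
    fl=lambda l: np.ones_like(l),
    fv=lambda v: np.ones_like(v),
    fpe=lambda l: np.zeros_like(l),
)


@dataclass
class MuscleParams:
    """Per-muscle constants of the rigid-tendon Hill model.

    Attributes
    ----------
    f_max : (m,) maximum isometric force, N
    l0 : (m,) optimal fiber length, m
    lts : (m,) tendon slack length, m
    alpha0 : (m,) pennation angle at optimal fiber length, rad
    vmax : (m,) maximum shortening velocity, optimal fiber lengths / s
    passive_enabled : include the passive force-length contribution
    names : muscle labels (defaults to ``m1..mN``)
    """

    f_max: np.ndarray
    l0: np.ndarray
    lts: np.ndarray
    alpha0: np.ndarray
    vmax: np.ndarray
    passive_enabled: bool = True
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        for attr in ("f_max", "l0", "lts", "alpha0", "vmax"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        m = self.f_max.shape[0]
        for attr in ("l0", "lts", "alpha0", "vmax"):
            if getattr(self, attr).shape != (m,):
                raise InvalidArgumentError(f"{attr} must have shape ({m},)")
        if not self.names:
            self.names = [f"m{i + 1}" for i in range(m)]
        if len(self.names) != m:
            raise InvalidArgumentError("names length must match f_max")
        if np.any(self.f_max <= 0) or np.any(self.l0 <= 0) or np.any(self.vmax <= 0):
            raise InvalidArgumentError("f_max, l0 and vmax must be positive")
        if np.any(self.lts < 0):
            raise InvalidArgumentError("tendon slack length must be non-negative")
        if np.any(self.alpha0 < 0) or np.any(self.alpha0 >= np.pi / 2):
            raise InvalidArgumentError("pennation must lie in [0, pi/2)")

    @property
    def n_muscles(self) -> int:
        return self.f_max.shape[0]

    @classmethod
    def from_csv(cls, path, passive_enabled: bool = True) -> "MuscleParams":
        """Read parameters from a CSV with header name,f_max,l0,lts,alpha0,vmax."""
        df = pd.read_csv(path)
        required = ["name", "f_max", "l0", "lts", "alpha0", "vmax"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"parameter CSV missing columns {missing}")
        return cls(
            f_max=df["f_max"].to_numpy(),
            l0=df["l0"].to_numpy(),
            lts=df["lts"].to_numpy(),
            alpha0=df["alpha0"].to_numpy(),
            vmax=df["vmax"].to_numpy(),
            passive_enabled=passive_enabled,
            names=df["name"].astype(str).tolist(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "name": self.names,
                "f_max": self.f_max,
                "l0": self.l0,
                "lts": self.lts,
                "alpha0": self.alpha0,
                "vmax": self.vmax,
            }
        ).to_csv(path, index=False)


def _fiber_state(lmt: np.ndarray, params: MuscleParams):
    """Normalized fiber length and pennation cosine from musculotendon length.

    Raises :class:`DegenerateGeometryError` naming the first offending
    muscle/frame when ``lmt <= lts`` anywhere.
    """
    lmt = np.atleast_2d(np.asarray(lmt, dtype=float))
    proj = lmt - params.lts[None, :]
    if np.any(proj <= 0):
        j, i = np.argwhere(proj <= 0)[0]
        raise DegenerateGeometryError(
            params.names[i], int(j), float(lmt[j, i]), float(params.lts[i])
        )
    h = params.l0 * np.sin(params.alpha0)  # constant muscle thickness
    l_fiber = np.hypot(proj, h[None, :])
    cos_alpha = proj / l_fiber
    l_norm = l_fiber / params.l0[None, :]
    return l_norm, cos_alpha


def force_decomposition(
    lmt: np.ndarray,
    vmt: np.ndarray,
    params: MuscleParams,
    curves: HillCurves = DEFAULT_CURVES,
):
    """Split the force map into its affine parts: F = gain * a + passive.

    Returns ``(gain, passive)``, both of shape (f, m).  ``gain`` is
    ``f_max * fL * fV * cos(alpha)`` and ``passive`` is
    ``f_max * fPE * cos(alpha)`` (zero when passive force is disabled).
    """
    lmt = np.atleast_2d(np.asarray(lmt, dtype=float))
    vmt = np.atleast_2d(np.asarray(vmt, dtype=float))
    if lmt.shape != vmt.shape:
        raise InvalidArgumentError("lmt and vmt must share a shape")
    if lmt.shape[1] != params.n_muscles:
        raise InvalidArgumentError(
            f"kinematics have {lmt.shape[1]} muscles, params {params.n_muscles}"
        )
    l_norm, cos_alpha = _fiber_state(lmt, params)
    v_fiber = vmt * cos_alpha  # rigid tendon: d l_fiber/dt = cos(alpha) * vmt
    v_norm = v_fiber / (params.vmax * params.l0)[None, :]
    gain = params.f_max[None, :] * curves.fl(l_norm) * curves.fv(v_norm) * cos_alpha
    if params.passive_enabled:
        passive = params.f_max[None, :] * curves.fpe(l_norm) * cos_alpha
    else:
        passive = np.zeros_like(gain)
    return gain, passive


def compute_muscle_forces(
    a: np.ndarray,
    lmt: np.ndarray,
    vmt: np.ndarray,
    params: MuscleParams,
    curves: HillCurves = DEFAULT_CURVES,
) -> np.ndarray:
    """Musculotendon forces (f, m) in N from activations (f, m).

    Stateless: the fiber state depends only on the instantaneous kinematics,
    so repeated calls with the same inputs are idempotent.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError("activations must be finite")
    gain, passive = force_decomposition(lmt, vmt, params, curves)
    if a.shape != gain.shape:
        raise InvalidArgumentError(
            f"activations shape {a.shape} != kinematics shape {gain.shape}"
        )
    return gain * a + passive


def compute_joint_moments(forces: np.ndarray, moment_arms: np.ndarray) -> np.ndarray:
    """Joint moments (f, d) in N*m: Q[j, k] = sum_i r[j, k, i] * F[j, i].

    ``moment_arms`` is the signed (f, d, m) Jacobian; r > 0 means the muscle
    produces a positive moment about that DOF.  Linear in the forces.
    """
    forces = np.atleast_2d(np.asarray(forces, dtype=float))
    moment_arms = np.asarray(moment_arms, dtype=float)
    if moment_arms.ndim != 3:
        raise InvalidArgumentError("moment_arms must be a (f, d, m) tensor")
    f, d, m = moment_arms.shape
    if forces.shape != (f, m):
        raise InvalidArgumentError(
            f"forces shape {forces.shape} incompatible with moment arms {moment_arms.shape}"
        )
    if not (np.all(np.isfinite(forces)) and np.all(np.isfinite(moment_arms))):
        raise InvalidArgumentError("NaN or infinity in moment computation inputs")
    return np.einsum("fdm,fm->fd", moment_arms, forces)
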