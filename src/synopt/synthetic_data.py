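"""Seeded synthetic gait trials with known ground-truth synergy structure.

Real gait-lab inputs to the redundancy solvers are inverse-dynamics joint
moments, a signed moment-arm Jacobian, and musculotendon kinematics derived
from motion capture and a scaled musculoskeletal model.  This module emulates
those inputs with smooth, periodic functions of gait-cycle phase:

* moment arms are low-order (<= 4 harmonics) Fourier series per muscle-DOF
  pair, with a sparse sign pattern (each muscle spans 1-3 DOFs);
* musculotendon lengths oscillate analytically around the optimal-length
  operating point, and velocities are the exact analytic derivative;
* ground-truth activations are the product of burst-like (Gaussian-bump)
  synergy activation profiles and non-negative synergy vectors whose weights
  sum to one, scaled so every activation lies in [0, 1];
* inverse-dynamics moments are produced by pushing the ground-truth
  activations through the rigid-tendon muscle model, which guarantees that a
  feasible exact solution of the moment-matching problem exists;
* synthetic EMG channels are delayed, crosstalk-mixed, noisy, rectified
  images of the true activations (envelope-level noise; raw interference
  signals are not modelled).

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InvalidArgumentError
from .muscle_model import (
    DEFAULT_CURVES,
    HillCurves,
    MuscleParams,
    compute_joint_moments,
    compute_muscle_forces,
    force_decomposition,
)

__all__ = [
    "TrialData",
    "GroundTruth",
    "EMGSet",
    "default_muscle_params",
    "generate_plant",
    "generate_ground_truth",
    "forward_consistent_trial",
    "synthesize_emg",
]

#: Upper bound on any synthetic moment-arm magnitude, m.  Lower-limb moment
#: arms rarely exceed ~8 cm; the generator stays well inside this bound.
MAX_MOMENT_ARM = 0.12

_DOF_NAMES = (
    "hip_abd_add",
    "hip_flex_ext",
    "hip_int_ext_rot",
    "knee_flex_ext",
    "ankle_int_ext_rot",
    "ankle_plantar_dorsi",
)


@dataclass
class TrialData:
    """One trial of solver inputs: the musculoskeletal "plant".

    Arrays share the frame count ``f``; ``q_id`` is ``None`` until
    inverse-dynamics moments are attached (see
    :func:`forward_consistent_trial`).
    """

    dt: float
    dof_labels: list[str]
    muscle_labels: list[str]
    moment_arms: np.ndarray  # (f, d, m), signed, m
    lmt: np.ndarray  # (f, m), m
    vmt: np.ndarray  # (f, m), m/s, lengthening positive
    q_id: np.ndarray | None = None  # (f, d), N*m

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        self.moment_arms = np.asarray(self.moment_arms, dtype=float)
        self.lmt = np.asarray(self.lmt, dtype=float)
        self.vmt = np.asarray(self.vmt, dtype=float)
        f, d, m = self.moment_arms.shape
        if len(self.dof_labels) != d or len(self.muscle_labels) != m:
            raise InvalidArgumentError("label counts must match array shapes")
        if self.lmt.shape != (f, m) or self.vmt.shape != (f, m):
            raise InvalidArgumentError("lmt/vmt shapes must be (f, m)")
        if not np.all(np.isfinite(self.moment_arms)):
            raise InvalidArgumentError("moment arms must be finite")
        if self.q_id is not None:
            self.q_id = np.asarray(self.q_id, dtype=float)
            if self.q_id.shape != (f, d):
                raise InvalidArgumentError("q_id shape must be (f, d)")

    @property
    def n_frames(self) -> int:
        return self.moment_arms.shape[0]

    @property
    def n_dofs(self) -> int:
        return self.moment_arms.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.moment_arms.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class GroundTruth:
    """Known synergy structure behind a synthetic trial (test oracle)."""

    C: np.ndarray  # (f, n_true) non-negative synergy activations
    V: np.ndarray  # (n_true, m) non-negative, rows sum to 1
    true_activations: np.ndarray  # (f, m) == C @ V, in [0, 1]
    seed: int

    @property
    def n_synergies(self) -> int:
        return self.C.shape[1]


@dataclass
class EMGSet:
    """Raw (synthetic) EMG channels plus the metadata used to create them."""

    sample_rate: float
    channels: np.ndarray  # (c, n_samples)
    channel_map: dict[int, str]  # channel index -> muscle label
    delays: np.ndarray  # (c,) seconds, positive = EMG lags activation
    noise_sd: float  # fraction of per-channel amplitude
    crosstalk: np.ndarray  # (c, c) non-negative mixing weights

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        if np.any(self.crosstalk < 0):
            raise InvalidArgumentError("crosstalk weights must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def duration(self) -> float:
        return (self.channels.shape[1] - 1) / self.sample_rate


def default_muscle_params(m: int, seed: int = 0, passive_enabled: bool = True) -> MuscleParams:
    """Plausible lower-limb Hill parameters for ``m`` generic muscles.

    Deterministic in ``seed``; :func:`generate_plant` builds exactly these
    when no explicit parameters are supplied.
    """
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    return MuscleParams(
        f_max=rng.uniform(300.0, 2500.0, m),
        l0=rng.uniform(0.05, 0.13, m),
        lts=rng.uniform(0.12, 0.35, m),
        alpha0=rng.uniform(0.0, 0.35, m),
        vmax=np.full(m, 10.0),
        passive_enabled=passive_enabled,
    )


def _phase(f: int) -> np.ndarray:
    """Gait-cycle phase in [0, 1] for f frames (0% .. 100% of the cycle)."""
    return np.arange(f) / max(f - 1, 1)


def generate_plant(
    m: int,
    d: int,
    f: int,
    dt: float = 0.01,
    seed: int = 0,
    params: MuscleParams | None = None,
    arm_scale: float = 0.06,
) -> TrialData:
    """Generate smooth gait-like geometry and kinematics (no q_id yet).

    Moment arms and musculotendon lengths are band-limited Fourier series in
    cycle phase; velocities are the analytic derivative of the lengths, so
    kinematic consistency is exact up to the band limit.  Each muscle spans
    1-3 DOFs with a fixed sign per pair.  Identical seeds give bit-identical
    output.
    """
    if m < 1 or d < 1 or f < 2 or m < d:
        raise InvalidArgumentError("require m >= d >= 1 and f >= 2")
    if dt <= 0:
        raise InvalidArgumentError("dt must be positive")
    if params is None:
        params = default_muscle_params(m, seed)
    if params.n_muscles != m:
        raise InvalidArgumentError("params size must match m")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A]))
    phi = _phase(f)
    period = (f - 1) * dt
    n_harm = 4

    # sparse DOF spanning: every DOF actuated by several muscles, each muscle 1-3 DOFs
    spans = np.zeros((m, d), dtype=bool)
    for i in range(m):
        k = rng.integers(1, min(3, d) + 1)
        spans[i, rng.choice(d, size=k, replace=False)] = True
    for k in range(d):  # guarantee both signs per DOF so demands are balanceable
        if not spans[:, k].any():
            spans[rng.integers(0, m), k] = True

    moment_arms = np.zeros((f, d, m))
    harm = 2.0 * np.pi * np.arange(1, n_harm + 1)[:, None] * phi[None, :]  # (h, f)
    cos_h, sin_h = np.cos(harm), np.sin(harm)
    for i in range(m):
        for k in range(d):
            if not spans[i, k]:
                continue
            sign = rng.choice([-1.0, 1.0])
            c0 = sign * rng.uniform(0.35, 0.8) * arm_scale
            amps = rng.uniform(-0.15, 0.15, n_harm) * arm_scale / np.arange(1, n_harm + 1)
            bmps = rng.uniform(-0.15, 0.15, n_harm) * arm_scale / np.arange(1, n_harm + 1)
            moment_arms[:, k, i] = c0 + amps @ cos_h + bmps @ sin_h

    # musculotendon length around lts + l0, +-15% of l0, analytic derivative
    lmt = np.zeros((f, m))
    vmt = np.zeros((f, m))
    omega = 2.0 * np.pi * np.arange(1, 3)[:, None] / period  # rad/s per harmonic
    harm2 = 2.0 * np.pi * np.arange(1, 3)[:, None] * phi[None, :]
    cos2, sin2 = np.cos(harm2), np.sin(harm2)
    for i in range(m):
        a_h = rng.uniform(-0.15, 0.15, 2) / np.arange(1, 3)
        b_h = rng.uniform(-0.15, 0.15, 2) / np.arange(1, 3)
        lmt[:, i] = params.lts[i] + params.l0[i] * (1.0 + a_h @ cos2 + b_h @ sin2)
        vmt[:, i] = params.l0[i] * ((-a_h * omega[:, 0]) @ sin2 + (b_h * omega[:, 0]) @ cos2)

    d_labels = [_DOF_NAMES[k] if k < len(_DOF_NAMES) else f"dof{k + 1}" for k in range(d)]
    return TrialData(
        dt=dt,
        dof_labels=d_labels,
        muscle_labels=list(params.names),
        moment_arms=moment_arms,
        lmt=lmt,
        vmt=vmt,
    )


def generate_ground_truth(
    n_true: int,
    f: int,
    m: int,
    seed: int = 0,
    peak_activation: float = 0.85,
    plant: TrialData | None = None,
    params: MuscleParams | None = None,
    curves: HillCurves = DEFAULT_CURVES,
) -> GroundTruth:
    """Ground-truth synergies: Gaussian-bump activations x unit-sum vectors.

    ``C`` holds n_true burst-like non-negative profiles with centers spread
    over the cycle; ``V`` rows are non-negative and sum to one exactly.  The
    product is rescaled so the largest activation equals ``peak_activation``
    (< 1, keeping the bound constraints inactive at the truth).

    When ``plant`` and ``params`` are given, each synergy vector is built as
    the (non-negative part of the) minimum-effort activation pattern for a
    random moment-space demand direction, jittered multiplicatively — muscles
    are weighted by how effectively they produce the synergy's net moment.
    This mimics task-effective muscle groupings and makes the truth lie near
    the optimum of effort-penalized moment tracking, i.e. recoverable by the
    solvers.  Without a plant the rows fall back to flat-Dirichlet-style
    random weights, which are valid activations but generally not
    effort-optimal.
    """
    if n_true < 1 or n_true > m:
        raise InvalidArgumentError("require 1 <= n_true <= m")
    if f < 2:
        raise InvalidArgumentError("require f >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x67]))
    phi = _phase(f)
    C = np.zeros((f, n_true))
    for s in range(n_true):
        center = (s + 0.5) / n_true + rng.uniform(-0.05, 0.05)
        width = rng.uniform(0.08, 0.14)
        amp = rng.uniform(0.7, 1.0)
        C[:, s] = amp * np.exp(-0.5 * ((phi - center) / width) ** 2) + 0.02

    if plant is not None:
        if params is None:
            raise InvalidArgumentError("params are required when a plant is given")
        gain, _ = force_decomposition(plant.lmt, plant.vmt, params, curves)
        G = (plant.moment_arms * gain[:, None, :]).mean(axis=0)  # (d, m) mean gain map
        Gn = G / np.linalg.norm(G, axis=1, keepdims=True)
        d = G.shape[0]
        V = np.zeros((n_true, m))
        for s in range(n_true):
            u = rng.standard_normal(d)
            u /= np.linalg.norm(u)
            w = np.maximum(Gn.T @ u, 0.0)
            if w.sum() < 1e-9:
                w = np.maximum(-(Gn.T @ u), 0.0)
            w = w * rng.uniform(0.5, 1.5, m)
            V[s] = w / w.sum()
    else:
        V = rng.dirichlet(np.full(m, 0.5), size=n_true)

    a = C @ V
    C *= peak_activation / a.max()
    return GroundTruth(C=C, V=V, true_activations=C @ V, seed=int(seed))


def forward_consistent_trial(
    plant: TrialData,
    gt: GroundTruth,
    params: MuscleParams,
    curves: HillCurves = DEFAULT_CURVES,
) -> TrialData:
    """Attach inverse-dynamics moments produced by the ground truth itself.

    ``q_id`` is computed by the same muscle-model code path the solvers use,
    so the ground-truth activations reproduce it exactly and the per-frame
    moment-equality constraints of static optimization are feasible by
    construction.
    """
    f, m = plant.n_frames, plant.n_muscles
    if gt.true_activations.shape != (f, m):
        raise InvalidArgumentError(
            f"ground truth shape {gt.true_activations.shape} != trial ({f}, {m})"
        )
    if params.n_muscles != m:
        raise InvalidArgumentError("params size must match the trial")
    forces = compute_muscle_forces(gt.true_activations, plant.lmt, plant.vmt, params, curves)
    q_id = compute_joint_moments(forces, plant.moment_arms)
    return replace(plant, q_id=q_id)


def synthesize_emg(
    gt: GroundTruth,
    trial: TrialData,
    channel_muscles: Sequence[str],
    sample_rate: float = 1000.0,
    delays: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    crosstalk: np.ndarray | None = None,
    seed: int = 0,
) -> EMGSet:
    """Synthetic EMG: delayed, crosstalk-mixed, noisy images of true activations.

    Each channel c observes muscle ``channel_muscles[c]``.  The channel's
    source signal is its muscle's true activation resampled to
    ``sample_rate`` and shifted by ``delays[c]`` (positive = EMG lags the
    activation); channels are then mixed by the non-negative ``crosstalk``
    matrix (identity = no crosstalk), Gaussian noise with standard deviation
    ``noise_sd`` x channel amplitude is added, and the result is rectified.
    Keeping |delay| <= 100 ms keeps channels inside the evaluation lag window.
    """
    c = len(channel_muscles)
    if c < 1:
        raise InvalidArgumentError("need at least one channel")
    label_to_idx = {lab: i for i, lab in enumerate(trial.muscle_labels)}
    idx = []
    for lab in channel_muscles:
        if lab not in label_to_idx:
            raise InvalidArgumentError(f"unknown muscle {lab!r} in channel map")
        idx.append(label_to_idx[lab])
    delays = np.zeros(c) if delays is None else np.asarray(delays, dtype=float)
    if delays.shape != (c,):
        raise InvalidArgumentError("delays must have one entry per channel")
    crosstalk = np.eye(c) if crosstalk is None else np.asarray(crosstalk, dtype=float)
    if crosstalk.shape != (c, c):
        raise InvalidArgumentError("crosstalk must be (c, c)")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE96]))
    duration = (trial.n_frames - 1) * trial.dt
    n_samples = int(round(duration * sample_rate)) + 1
    t = np.arange(n_samples) / sample_rate
    frame_t = trial.times

    sources = np.empty((c, n_samples))
    for ci, mi in enumerate(idx):
        # positive delay: the EMG at time t reflects activation at t - delay
        sources[ci] = np.interp(t - delays[ci], frame_t, gt.true_activations[:, mi])
    mixed = crosstalk @ sources
    if noise_sd > 0:
        amp = np.abs(mixed).max(axis=1, keepdims=True)
        amp[amp == 0] = 1.0
        mixed = mixed + rng.standard_normal(mixed.shape) * (noise_sd * amp)
    return EMGSet(
        sample_rate=float(sample_rate),
        channels=np.abs(mixed),
        channel_map={ci: lab for ci, lab in enumerate(channel_muscles)},
        delays=delays,
        noise_sd=float(noise_sd),
        crosstalk=crosstalk,
    )
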