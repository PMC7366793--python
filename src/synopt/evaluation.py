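"""Evaluation metrics and comparison reports.

Three quantities score the redundancy solutions:

* VAF — variance accounted for, ``100 * (1 - SSE / SSQ)`` in the uncentered
  form standard in the synergy literature, applied per DOF to joint-moment
  tracking and averaged across DOFs for summaries;
* lagged Pearson correlation — the maximum signed r between an estimated
  activation and an EMG envelope over integer-sample lags within ±100 ms,
  which scores shape agreement while tolerating electromechanical delay;
* activation-similarity r² — the mean over muscles of the squared zero-lag
  Pearson correlation between two activation matrices (used to compare SO
  with its NMF reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emg_processing import EnvelopeSet, resample_to_frames
from .exceptions import InvalidArgumentError, UndefinedMetricError
from .muscle_model import MuscleParams
from .synthetic_data import TrialData

__all__ = [
    "EvaluationReport",
    "vaf",
    "vaf_per_dof",
    "lagged_pearson",
    "activation_similarity_r2",
    "build_comparison_report",
]


@dataclass
class EvaluationReport:
    """Per-method evaluation summary for one synergy count."""

    method: str
    n_s: int | None
    vaf_per_dof: np.ndarray  # %, one per DOF
    vaf_mean: float  # %
    r_per_channel: list[tuple[str, float, float]] = field(default_factory=list)
    # (muscle label, best r, best lag in ms)
    r2_activation_similarity: float | None = None


def vaf(q_ref: np.ndarray, q_est: np.ndarray, centered: bool = False) -> float:
    """Variance accounted for, percent: 100 * (1 - SSE / SSQ).

    Uncentered by default; ``centered=True`` subtracts the reference mean
    from both the residual normalizer and nothing else (classic centered
    variant).  Undefined for an all-zero reference.
    """
    q_ref = np.asarray(q_ref, dtype=float).ravel()
    q_est = np.asarray(q_est, dtype=float).ravel()
    if q_ref.shape != q_est.shape:
        raise InvalidArgumentError("series must share a length")
    if q_ref.size < 2:
        raise InvalidArgumentError("need at least two samples")
    denom = np.sum((q_ref - q_ref.mean()) ** 2) if centered else np.sum(q_ref**2)
    if denom == 0:
        raise UndefinedMetricError("VAF undefined for an all-zero reference")
    return 100.0 * (1.0 - np.sum((q_ref - q_est) ** 2) / denom)


def vaf_per_dof(q_ref: np.ndarray, q_est: np.ndarray, centered: bool = False) -> np.ndarray:
    """Column-wise VAF for (f, d) moment traces."""
    q_ref = np.atleast_2d(np.asarray(q_ref, dtype=float))
    q_est = np.atleast_2d(np.asarray(q_est, dtype=float))
    if q_ref.shape != q_est.shape:
        raise InvalidArgumentError("moment traces must share a shape")
    return np.array([vaf(q_ref[:, k], q_est[:, k], centered) for k in range(q_ref.shape[1])])


def lagged_pearson(
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    max_lag_ms: float = 100.0,
) -> tuple[float, float]:
    """Maximum signed Pearson r between x and y over lags within ±max_lag_ms.

    A positive returned lag means ``y`` lags ``x`` by that many milliseconds
    (y[t] resembles x[t - lag]).  The correlation at each integer-sample lag
    is computed on the overlapping samples only; ties are broken toward the
    smallest |lag|.  Raises when every overlap is constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidArgumentError("series must share a length")
    f = x.size
    max_lag = int(np.floor(max_lag_ms / 1000.0 / dt))
    if f <= max_lag + 2:
        raise InvalidArgumentError("series too short for the requested lag window")

    best_r, best_lag = None, None
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            xs, ys = x[: f - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: f + lag]
        if xs.std() == 0 or ys.std() == 0:
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        if best_r is None or r > best_r + 1e-15:
            best_r, best_lag = r, lag
    if best_r is None:
        raise UndefinedMetricError("correlation undefined: constant overlap at every lag")
    return best_r, best_lag * dt * 1000.0


def activation_similarity_r2(a: np.ndarray, a_star: np.ndarray) -> float:
    """Mean squared zero-lag Pearson correlation over muscle columns.

    Columns constant in either matrix are skipped; raises if none remain.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    a_star = np.atleast_2d(np.asarray(a_star, dtype=float))
    if a.shape != a_star.shape:
        raise InvalidArgumentError("activation matrices must share a shape")
    r2 = []
    for i in range(a.shape[1]):
        if a[:, i].std() == 0 or a_star[:, i].std() == 0:
            continue
        r2.append(float(np.corrcoef(a[:, i], a_star[:, i])[0, 1]) ** 2)
    if not r2:
        raise InvalidArgumentError("no non-constant muscle columns to correlate")
    return float(np.mean(r2))


def _emg_rows(
    method: str,
    n_s: int | None,
    activations: np.ndarray,
    trial: TrialData,
    emg: EnvelopeSet,
    max_lag_ms: float,
) -> list[dict]:
    """Lagged correlation of each mapped EMG channel with its muscle's activation."""
    env = resample_to_frames(emg, trial.n_frames, trial.dt)
    label_to_idx = {lab: i for i, lab in enumerate(trial.muscle_labels)}
    rows = []
    for ch, muscle in emg.channel_map.items():
        if muscle not in label_to_idx:
            raise InvalidArgumentError(f"EMG channel {ch} maps to unknown muscle {muscle!r}")
        a_col = activations[:, label_to_idx[muscle]]
        try:
            r, lag = lagged_pearson(a_col, env[int(ch)], trial.dt, max_lag_ms)
        except UndefinedMetricError:
            r, lag = np.nan, np.nan
        rows.append(
            {"method": method, "n_s": n_s, "channel": int(ch), "muscle": muscle,
             "r": r, "lag_ms": lag}
        )
    return rows


def build_comparison_report(
    trial: TrialData,
    params: MuscleParams,
    so_result: tuple[np.ndarray, np.ndarray],
    syno_results: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
    sonmf_results: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
    emg: EnvelopeSet | None = None,
    max_lag_ms: float = 100.0,
) -> dict[str, pd.DataFrame]:
    """Assemble tidy comparison tables across methods and synergy counts.

    ``so_result`` is ``(activations, moments)``; ``syno_results`` and
    ``sonmf_results`` map synergy counts to the same pair.  Returns three
    long-format frames: ``moment_vaf`` (method x n_s x DOF), ``emg_r``
    (method x n_s x channel, empty without EMG), and
    ``activation_similarity`` (SO vs SO-NMF r² per n).
    """
    if trial.q_id is None:
        raise InvalidArgumentError("trial has no inverse-dynamics moments (q_id)")
    syno_results = syno_results or {}
    sonmf_results = sonmf_results or {}

    vaf_rows, emg_rows, sim_rows = [], [], []

    def add_vaf(method, n_s, q_est):
        v = vaf_per_dof(trial.q_id, q_est)
        for k, lab in enumerate(trial.dof_labels):
            vaf_rows.append({"method": method, "n_s": n_s, "dof": lab, "vaf": v[k]})

    a_so, q_so = so_result
    add_vaf("SO", None, q_so)
    if emg is not None:
        emg_rows += _emg_rows("SO", None, a_so, trial, emg, max_lag_ms)
    for n_s in sorted(syno_results):
        a, q = syno_results[n_s]
        add_vaf("SynO", n_s, q)
        if emg is not None:
            emg_rows += _emg_rows("SynO", n_s, a, trial, emg, max_lag_ms)
    for n in sorted(sonmf_results):
        a_star, q_star = sonmf_results[n]
        add_vaf("SO-NMF", n, q_star)
        if emg is not None:
            emg_rows += _emg_rows("SO-NMF", n, a_star, trial, emg, max_lag_ms)
        sim_rows.append(
            {"n_s": n, "r2": activation_similarity_r2(a_so, a_star)}
        )

    return {
        "moment_vaf": pd.DataFrame(vaf_rows),
        "emg_r": pd.DataFrame(
            emg_rows, columns=["method", "n_s", "channel", "muscle", "r", "lag_ms"]
        ),
        "activation_similarity": pd.DataFrame(sim_rows, columns=["n_s", "r2"]),
    }
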