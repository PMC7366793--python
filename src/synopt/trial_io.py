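"""Trial and result file I/O.

The canonical trial bundle is HDF5 with datasets ``/q_id`` (optional),
``/moment_arms``, ``/lmt``, ``/vmt``, ``/dof_labels``, ``/muscle_labels``
and a scalar ``/dt`` — the 3-D moment-arm tensor needs a real container.
A CSV bundle is provided as a portable fallback: one file per array, with
the moment-arm tensor in long format (frame,dof,muscle,value).  Round trips
are bit-exact in HDF5 and full-precision (repr round-trip) in CSV.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .exceptions import TrialFormatError
from .synthetic_data import GroundTruth, TrialData

__all__ = [
    "write_trial",
    "read_trial",
    "write_trial_csv",
    "read_trial_csv",
    "write_activations",
    "read_activations",
]

_REQUIRED = ("moment_arms", "lmt", "vmt", "dof_labels", "muscle_labels", "dt")


def write_trial(path, trial: TrialData, ground_truth: GroundTruth | None = None,
                attrs: dict | None = None) -> None:
    """Write a trial bundle (and optionally its ground truth) to HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("moment_arms", data=trial.moment_arms)
        h5.create_dataset("lmt", data=trial.lmt)
        h5.create_dataset("vmt", data=trial.vmt)
        h5.create_dataset("dt", data=float(trial.dt))
        str_dt = h5py.string_dtype("utf-8")
        h5.create_dataset("dof_labels", data=np.array(trial.dof_labels, dtype=object), dtype=str_dt)
        h5.create_dataset("muscle_labels", data=np.array(trial.muscle_labels, dtype=object), dtype=str_dt)
        if trial.q_id is not None:
            h5.create_dataset("q_id", data=trial.q_id)
        if ground_truth is not None:
            g = h5.create_group("ground_truth")
            g.create_dataset("C", data=ground_truth.C)
            g.create_dataset("V", data=ground_truth.V)
            g.create_dataset("true_activations", data=ground_truth.true_activations)
            g.attrs["seed"] = int(ground_truth.seed)
        for k, v in (attrs or {}).items():
            h5.attrs[k] = v


def read_trial(path, with_ground_truth: bool = False):
    """Read a trial bundle; returns TrialData or (TrialData, GroundTruth | None)."""
    try:
        with h5py.File(path, "r") as h5:
            missing = [name for name in _REQUIRED if name not in h5]
            if missing:
                raise TrialFormatError(f"trial file {path} missing datasets {missing}")
            trial = TrialData(
                dt=float(h5["dt"][()]),
                dof_labels=[s.decode() if isinstance(s, bytes) else str(s) for s in h5["dof_labels"][()]],
                muscle_labels=[s.decode() if isinstance(s, bytes) else str(s) for s in h5["muscle_labels"][()]],
                moment_arms=h5["moment_arms"][()],
                lmt=h5["lmt"][()],
                vmt=h5["vmt"][()],
                q_id=h5["q_id"][()] if "q_id" in h5 else None,
            )
            gt = None
            if "ground_truth" in h5:
                g = h5["ground_truth"]
                gt = GroundTruth(
                    C=g["C"][()], V=g["V"][()],
                    true_activations=g["true_activations"][()],
                    seed=int(g.attrs.get("seed", 0)),
                )
    except OSError as exc:
        raise TrialFormatError(f"cannot read trial file {path}: {exc}") from exc
    except (KeyError, ValueError) as exc:
        raise TrialFormatError(f"malformed trial file {path}: {exc}") from exc
    return (trial, gt) if with_ground_truth else trial


def write_trial_csv(directory, trial: TrialData) -> None:
    """CSV fallback bundle: one file per array, 3-D tensor in long format."""
    os.makedirs(directory, exist_ok=True)
    f, d, m = trial.moment_arms.shape
    frame, dof, mus = np.meshgrid(np.arange(f), np.arange(d), np.arange(m), indexing="ij")
    pd.DataFrame(
        {"frame": frame.ravel(), "dof": dof.ravel(), "muscle": mus.ravel(),
         "value": trial.moment_arms.ravel()}
    ).to_csv(os.path.join(directory, "moment_arms.csv"), index=False)
    pd.DataFrame(trial.lmt, columns=trial.muscle_labels).to_csv(
        os.path.join(directory, "lmt.csv"), index=False)
    pd.DataFrame(trial.vmt, columns=trial.muscle_labels).to_csv(
        os.path.join(directory, "vmt.csv"), index=False)
    if trial.q_id is not None:
        pd.DataFrame(trial.q_id, columns=trial.dof_labels).to_csv(
            os.path.join(directory, "q_id.csv"), index=False)
    pd.DataFrame({"dt": [trial.dt]}).to_csv(os.path.join(directory, "meta.csv"), index=False)


def read_trial_csv(directory) -> TrialData:
    """Read the CSV fallback bundle written by :func:`write_trial_csv`."""
    try:
        arms_long = pd.read_csv(os.path.join(directory, "moment_arms.csv"))
        lmt_df = pd.read_csv(os.path.join(directory, "lmt.csv"))
        vmt_df = pd.read_csv(os.path.join(directory, "vmt.csv"))
        meta = pd.read_csv(os.path.join(directory, "meta.csv"))
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise TrialFormatError(f"cannot read CSV trial bundle in {directory}: {exc}") from exc
    f = int(arms_long["frame"].max()) + 1
    d = int(arms_long["dof"].max()) + 1
    m = int(arms_long["muscle"].max()) + 1
    if len(arms_long) != f * d * m:
        raise TrialFormatError("moment_arms.csv does not cover a full (frame, dof, muscle) grid")
    arms = np.empty((f, d, m))
    arms[arms_long["frame"], arms_long["dof"], arms_long["muscle"]] = arms_long["value"]
    q_path = os.path.join(directory, "q_id.csv")
    q_df = pd.read_csv(q_path) if os.path.exists(q_path) else None
    return TrialData(
        dt=float(meta["dt"].iloc[0]),
        dof_labels=list(q_df.columns) if q_df is not None else [f"dof{k + 1}" for k in range(d)],
        muscle_labels=list(lmt_df.columns),
        moment_arms=arms,
        lmt=lmt_df.to_numpy(dtype=float),
        vmt=vmt_df.to_numpy(dtype=float),
        q_id=q_df.to_numpy(dtype=float) if q_df is not None else None,
    )


def write_activations(path, activations: np.ndarray, muscle_labels=None,
                      extra: dict[str, np.ndarray] | None = None,
                      attrs: dict | None = None) -> None:
    """Write an (f, m) activation matrix (plus named extras like C/V) to HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("activations", data=np.asarray(activations, dtype=float))
        if muscle_labels is not None:
            h5.create_dataset(
                "muscle_labels", data=np.array(muscle_labels, dtype=object),
                dtype=h5py.string_dtype("utf-8"))
        for name, arr in (extra or {}).items():
            h5.create_dataset(name, data=np.asarray(arr, dtype=float))
        for k, v in (attrs or {}).items():
            h5.attrs[k] = v


def read_activations(path, extra: tuple[str, ...] = ()):
    """Read an activation matrix (and optional named extras) from HDF5."""
    try:
        with h5py.File(path, "r") as h5:
            if "activations" not in h5:
                raise TrialFormatError(f"{path} has no 'activations' dataset")
            a = h5["activations"][()]
            extras = {}
            for name in extra:
                if name not in h5:
                    raise TrialFormatError(f"{path} has no {name!r} dataset")
                extras[name] = h5[name][()]
    except OSError as exc:
        raise TrialFormatError(f"cannot read activations file {path}: {exc}") from exc
    return (a, extras) if extra else a
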