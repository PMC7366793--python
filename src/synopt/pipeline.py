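"""End-to-end orchestration: generate -> solve -> synergy analysis -> evaluate.

A :class:`RunConfig` (loadable from YAML) fixes every dimension, seed and
solver setting; :func:`run_full_comparison` then produces a self-contained
artifact directory with the trial bundle, per-method activation files, tidy
evaluation CSVs and a manifest recording the config hash, seeds and library
versions.  Identical configs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .emg_processing import process_emg
from .evaluation import build_comparison_report
from .exceptions import InvalidArgumentError
from .muscle_model import MuscleParams, compute_joint_moments, compute_muscle_forces
from .nmf_synergies import analyze_so_activations
from .static_optimization import SOConfig, solve_trial
from .synergy_optimization import SynOConfig, solve_syno
from .synthetic_data import (
    default_muscle_params,
    forward_consistent_trial,
    generate_ground_truth,
    generate_plant,
    synthesize_emg,
)
from .trial_io import read_trial, write_activations, write_trial

__all__ = ["RunConfig", "run_full_comparison"]

log = logging.getLogger("synopt")


@dataclass
class RunConfig:
    """Configuration for a full comparison run."""

    out_dir: str = "synopt_run"
    seed: int = 7
    # synthetic trial dimensions
    m: int = 12
    d: int = 3
    f: int = 51
    dt: float = 0.01
    n_true: int = 3
    trial_path: str | None = None  # load instead of generating when set
    params_path: str | None = None
    # synergy counts for SynO and SO-NMF
    n_s: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    # solver settings
    so_multistarts: int = 5
    syno_multistarts: int = 5
    syno_max_iter: int = 400
    nmf_restarts: int = 10
    # synthetic EMG
    emg_channels: int = 6
    emg_rate: float = 1000.0
    emg_delay_ms: float = 20.0
    emg_noise_sd: float = 0.05

    def __post_init__(self):
        if any(n < 1 for n in self.n_s):
            raise InvalidArgumentError("synergy counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml_str(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml_str().encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_full_comparison(config: RunConfig) -> str:
    """Run the whole pipeline; returns the artifact directory path.

    Stages: trial generation (or loading), per-frame SO, SynO for each
    requested synergy count, SO-NMF for the same counts, synthetic-EMG
    processing, and report assembly.  Any stage failure aborts with the
    stage name while keeping the artifacts written so far.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": {"synopt": __version__, "numpy": np.__version__},
        "stages": {},
    }
    stage = "setup"

    def finish_stage(name, t0):
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    def persist_manifest(error=None):
        if error is not None:
            manifest["failed_stage"] = error
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        stage = "generate"
        t0 = time.perf_counter()
        if config.trial_path:
            trial, gt = read_trial(config.trial_path, with_ground_truth=True)
            params = (MuscleParams.from_csv(config.params_path)
                      if config.params_path
                      else default_muscle_params(trial.n_muscles, config.seed))
        else:
            params = default_muscle_params(config.m, config.seed)
            plant = generate_plant(config.m, config.d, config.f, config.dt,
                                   seed=config.seed, params=params)
            gt = generate_ground_truth(config.n_true, config.f, config.m,
                                       seed=config.seed, plant=plant, params=params)
            trial = forward_consistent_trial(plant, gt, params)
        write_trial(os.path.join(config.out_dir, "trial.h5"), trial, gt,
                    attrs={"config_hash": config.config_hash, "seed": config.seed})
        params.to_csv(os.path.join(config.out_dir, "muscles.csv"))
        finish_stage("generate", t0)

        stage = "so"
        t0 = time.perf_counter()
        a_so = solve_trial(trial, params,
                           SOConfig(n_multistarts=config.so_multistarts, seed=config.seed))
        q_so = compute_joint_moments(
            compute_muscle_forces(a_so, trial.lmt, trial.vmt, params), trial.moment_arms)
        write_activations(os.path.join(config.out_dir, "a_so.h5"), a_so,
                          trial.muscle_labels,
                          attrs={"config_hash": config.config_hash, "seed": config.seed})
        finish_stage("so", t0)

        syno_results, sonmf_results = {}, {}
        for n_s in sorted(set(config.n_s)):
            stage = f"syno_{n_s}"
            t0 = time.perf_counter()
            syn, a_syn, diag = solve_syno(
                trial, params, n_s,
                SynOConfig(n_multistarts=config.syno_multistarts, seed=config.seed,
                           max_iter=config.syno_max_iter))
            q_syn = compute_joint_moments(
                compute_muscle_forces(a_syn, trial.lmt, trial.vmt, params),
                trial.moment_arms)
            syno_results[n_s] = (a_syn, q_syn)
            write_activations(
                os.path.join(config.out_dir, f"a_syno_{n_s}.h5"), a_syn,
                trial.muscle_labels, extra={"C": syn.C, "V": syn.V},
                attrs={"config_hash": config.config_hash, "seed": config.seed,
                       "cost": diag["cost"]})
            finish_stage(stage, t0)

            stage = f"sonmf_{n_s}"
            t0 = time.perf_counter()
            rec = analyze_so_activations(a_so, trial, params, n_s,
                                         seed=config.seed, n_restarts=config.nmf_restarts)
            sonmf_results[n_s] = (rec.a_star, rec.q_star)
            write_activations(
                os.path.join(config.out_dir, f"a_sonmf_{n_s}.h5"), rec.a_star,
                trial.muscle_labels, extra={"W": rec.W, "H": rec.H},
                attrs={"config_hash": config.config_hash, "seed": config.seed})
            finish_stage(stage, t0)

        stage = "emg"
        t0 = time.perf_counter()
        envelopes = None
        if config.emg_channels > 0 and gt is not None:
            channels = trial.muscle_labels[: min(config.emg_channels, trial.n_muscles)]
            raw = synthesize_emg(
                gt, trial, channels, sample_rate=config.emg_rate,
                delays=np.full(len(channels), config.emg_delay_ms / 1000.0),
                noise_sd=config.emg_noise_sd, seed=config.seed)
            envelopes = process_emg(raw)
        finish_stage("emg", t0)

        stage = "evaluate"
        t0 = time.perf_counter()
        report = build_comparison_report(
            trial, params, (a_so, q_so), syno_results, sonmf_results, envelopes)
        _write_csv(report["moment_vaf"], os.path.join(config.out_dir, "moment_vaf.csv"))
        _write_csv(report["emg_r"], os.path.join(config.out_dir, "emg_r.csv"))
        _write_csv(report["activation_similarity"],
                   os.path.join(config.out_dir, "activation_similarity.csv"))
        with open(os.path.join(config.out_dir, "summary.txt"), "w") as fh:
            fh.write(f"synopt run {config.config_hash} (seed {config.seed})\n\n")
            mv = report["moment_vaf"]
            for method in mv["method"].unique():
                sub = mv[mv["method"] == method]
                for n_s in sub["n_s"].unique():
                    block = sub[sub["n_s"].isna()] if pd.isna(n_s) else sub[sub["n_s"] == n_s]
                    tag = method if pd.isna(n_s) else f"{method} (n_s={int(n_s)})"
                    fh.write(f"{tag}: mean moment VAF {block['vaf'].mean():.2f}%\n")
        finish_stage("evaluate", t0)
    except Exception:
        persist_manifest(error=stage)
        raise

    persist_manifest()
    return config.out_dir
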