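"""One-shot reproducible pipeline: simulate -> reconstruct -> extract ->
model, with a run manifest recording seeds, parameters and output hashes."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__, io
from .gait import extract_gait
from .reconstruct import detect_stance, reconstruct_trajectory
from .risk import (
    ModelSpec,
    cross_validate,
    cutoff_table,
    describe_cohort,
    fit_model,
    probability_report,
)
from .synthetic import GaitGroundTruth, default_cohort_spec, generate_cohort, generate_gait_imu

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def default_config() -> dict:
    """Demo configuration: a fully synthetic end-to-end run."""
    return {
        "seed": 1,
        "out_dir": "gstride_out",
        "simulate": {
            "imu": {
                "stride_length": 0.94,
                "gait_cycle_time": 1.2,
                "clearance": 0.18,
                "heel_strike_angle": 15.6,
                "toe_off_angle": -53.9,
                "n_strides": 30,
                "sample_rate": 100.0,
                "accel_noise": 0.05,
                "gyro_noise": 0.005,
            },
            "cohort": {"n_fallers": 86, "n_nonfallers": 77, "effect_scale": 1.0},
        },
        "reconstruct": {
            "accel_band": 0.4,
            "gyro_thresh": 0.6,
            "min_duration": 0.1,
            "gravity": 9.81,
        },
        "gait": {"steps_per_stride": 2, "std": "population", "trim_first_last": False},
        "risk": {
            "models": ["conv", "imu", "mix"],
            "n_repeats": 50,
            "train_fraction": 0.7,
            "threshold": 0.5,
            "cutoffs": True,
            "describe": True,
            "figures": False,
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(config: dict) -> None:
    for key in ("imu_path", "cohort_path"):
        p = config.get(key)
        if p is not None and not Path(p).exists():
            raise PipelineError(f"pre-flight: input file does not exist: {p}")


def run_pipeline(config: dict | str | Path, out_dir=None) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    Inputs can be simulated (``simulate`` section) or read from files
    (``imu_path`` / ``cohort_path``).  Every stage error is re-raised as a
    :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _preflight(config)
    out = Path(out_dir or config.get("out_dir", "gstride_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "out_dir"},
        "outputs": {},
    }

    def save(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        manifest["outputs"][name] = _sha256(path)

    sim = config.get("simulate", {})

    # --- stage: IMU input -------------------------------------------------
    try:
        if config.get("imu_path"):
            rec = io.read_imu_csv(config["imu_path"])
        elif "imu" in sim:
            p = dict(sim["imu"])
            gen = {
                k: p.pop(k)
                for k in ("sample_rate", "accel_noise", "gyro_noise")
                if k in p
            }
            rec, truth = generate_gait_imu(GaitGroundTruth(**p), seed=seed, **gen)
            save("imu.csv", io.write_imu_csv, rec)
            truth.to_json(out / "truth.json")
            manifest["outputs"]["truth.json"] = _sha256(out / "truth.json")
        else:
            rec = None
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage 'simulate-imu': {e}") from e

    # --- stage: reconstruct + gait ---------------------------------------
    if rec is not None:
        try:
            rcfg = config.get("reconstruct", {})
            mask = detect_stance(
                rec,
                accel_band=rcfg.get("accel_band", 0.4),
                gyro_thresh=rcfg.get("gyro_thresh", 0.6),
                min_duration=rcfg.get("min_duration", 0.1),
                gravity=rcfg.get("gravity", 9.81),
            )
            traj = reconstruct_trajectory(rec, mask, gravity=rcfg.get("gravity", 9.81))
            save("trajectory.csv", io.write_trajectory_csv, traj)
        except Exception as e:
            raise PipelineError(f"stage 'reconstruct': {e}") from e
        try:
            gcfg = config.get("gait", {})
            strides, summary = extract_gait(
                traj,
                mask,
                steps_per_stride=gcfg.get("steps_per_stride", 2),
                std=gcfg.get("std", "population"),
                trim_first_last=gcfg.get("trim_first_last", False),
            )
            save("strides.csv", io.write_strides_csv, strides)
            io.write_summary(summary, out / "walk_summary.csv", out / "walk_summary.json")
            manifest["outputs"]["walk_summary.csv"] = _sha256(out / "walk_summary.csv")
            manifest["outputs"]["walk_summary.json"] = _sha256(out / "walk_summary.json")
        except Exception as e:
            raise PipelineError(f"stage 'extract-gait': {e}") from e

    # --- stage: cohort ----------------------------------------------------
    cohort = None
    try:
        if config.get("cohort_path"):
            cohort = io.read_cohort_csv(config["cohort_path"])
        elif "cohort" in sim:
            c = dict(sim["cohort"])
            spec = default_cohort_spec(
                n_fallers=c.get("n_fallers", 86),
                n_nonfallers=c.get("n_nonfallers", 77),
                effect_scale=c.get("effect_scale", 1.0),
            )
            cohort = generate_cohort(spec, seed=seed + 1)
            save("cohort.csv", io.write_cohort_csv, cohort)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage 'simulate-cohort': {e}") from e

    # --- stage: risk models ----------------------------------------------
    if cohort is not None:
        kcfg = config.get("risk", {})
        try:
            if kcfg.get("describe", True):
                describe_cohort(cohort).to_csv(out / "cohort_describe.csv", index=False)
                manifest["outputs"]["cohort_describe.csv"] = _sha256(out / "cohort_describe.csv")
            if kcfg.get("cutoffs", True):
                cutoff_table(cohort).to_csv(out / "cutoffs.csv", index=False)
                manifest["outputs"]["cutoffs.csv"] = _sha256(out / "cutoffs.csv")
            evals = {}
            for name in kcfg.get("models", ["conv", "imu", "mix"]):
                spec = ModelSpec.canonical(name)
                fit = fit_model(cohort, spec)
                fit.params.to_csv(out / f"fit_{name}.csv")
                manifest["outputs"][f"fit_{name}.csv"] = _sha256(out / f"fit_{name}.csv")
                ev = cross_validate(
                    cohort,
                    spec,
                    n_repeats=kcfg.get("n_repeats", 50),
                    train_fraction=kcfg.get("train_fraction", 0.7),
                    threshold=kcfg.get("threshold", 0.5),
                    seed=seed + 100,
                )
                evals[name] = ev.as_dict()
                fig = (out / f"prob_{name}.png") if kcfg.get("figures", False) else None
                hist = probability_report(cohort, spec, fit=fit, fig_path=fig)
                hist.to_csv(out / f"prob_hist_{name}.csv", index=False)
                manifest["outputs"][f"prob_hist_{name}.csv"] = _sha256(
                    out / f"prob_hist_{name}.csv"
                )
            with open(out / "crossval.json", "w") as fh:
                json.dump(evals, fh, indent=2)
            manifest["outputs"]["crossval.json"] = _sha256(out / "crossval.json")
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage 'risk-models': {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest
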