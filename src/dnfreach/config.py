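"""Experiment configuration, persistence, seeding and preset pipelines.

An experiment is described by a single YAML document: the model constants,
the session parameters, and a master seed.  All randomness flows from the
master seed through named child streams (model init, trial draws, field
noise, schedule draws), so every component is independently reproducible.
Artifacts are written as CSV (trial logs, analysis tables) and HDF5 (weight
matrices, field snapshots, population traces).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .architecture import ModelConfig, ModelState, init_model
from .learning import LearningRates
from .tasks import (
    OBLIQUES,
    SessionConfig,
    TaskTiming,
    choice_fractions,
    percent_correct,
    run_session,
)
from . import analysis

__all__ = [
    "ExperimentConfig",
    "save_population_trace",
    "load_config",
    "save_config",
    "child_seeds",
    "save_model",
    "load_model",
    "run_experiment",
    "PRESETS",
]


# --------------------------------------------------------------------------
# Configuration document
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """Top-level experiment description (round-trips through YAML)."""

    model: ModelConfig = ModelConfig()
    timing: TaskTiming = TaskTiming()
    rates: LearningRates = LearningRates()
    seed: int = 0
    n_train: int = 1000
    inferred_fraction: float = 0.8

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "timing": dataclasses.asdict(self.timing),
            "rates": dataclasses.asdict(self.rates),
            "seed": self.seed,
            "n_train": self.n_train,
            "inferred_fraction": self.inferred_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {"model", "timing", "rates", "seed", "n_train",
                 "inferred_fraction"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = {}
        if "model" in d:
            kw["model"] = ModelConfig.from_dict(d["model"])
        if "timing" in d:
            kw["timing"] = TaskTiming(**d["timing"])
        if "rates" in d:
            kw["rates"] = LearningRates(**d["rates"])
        for key in ("seed", "n_train", "inferred_fraction"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)

    def session_kwargs(self) -> dict:
        return {"timing": self.timing, "rates": self.rates}


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment config; the model's dynamic-regime
    gates run on first model construction and raise with the failed gate."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return ExperimentConfig.from_dict(doc)


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def child_seeds(master: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % 2 ** 31) for c in ss.spawn(n)]


# --------------------------------------------------------------------------
# Model persistence
# --------------------------------------------------------------------------

def save_model(model: ModelState, path) -> None:
    """Snapshot all field activations and both weight matrices to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(model.config.to_dict())
        f.create_dataset("u/spatial", data=model.spatial.u)
        f.create_dataset("u/context", data=model.ctx.u)
        f.create_dataset("u/assoc", data=model.assoc.u)
        f.create_dataset("u/prep", data=model.prep.u)
        f.create_dataset("u/motor", data=model.motor.u)
        f.create_dataset("W/context_assoc", data=model.ctx_assoc.W)
        f.create_dataset("W/assoc_prep", data=model.assoc_prep.W)


def load_model(path, validate: bool = False) -> ModelState:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig.from_dict(json.loads(f.attrs["config"]))
        model = init_model(cfg, np.random.default_rng(0), validate=validate)
        model.spatial.u[:] = f["u/spatial"][()]
        model.ctx.u[:] = f["u/context"][()]
        model.assoc.u[:] = f["u/assoc"][()]
        model.prep.u[:] = f["u/prep"][()]
        model.motor.u[:] = f["u/motor"][()]
        model.ctx_assoc.W[:] = f["W/context_assoc"][()]
        model.assoc_prep.W[:] = f["W/assoc_prep"][()]
    return model


def save_population_trace(pt, path) -> None:
    """Write a PD-aligned population trace (normalized and raw) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("trace", data=pt.trace)
        f.create_dataset("raw", data=pt.raw)
        f.create_dataset("rel_directions", data=pt.rel_directions)
        for k, v in pt.markers.items():
            f.attrs[k] = v


def export_weights_csv(model: ModelState, outdir) -> None:
    outdir = Path(outdir)
    pd.DataFrame(model.ctx_assoc.W).to_csv(
        outdir / "W_context_assoc.csv", index=False)
    pd.DataFrame(model.weight_difference_map()).to_csv(
        outdir / "weight_difference_map.csv", index=False)
    pd.DataFrame(model.index_shift_map()).to_csv(
        outdir / "index_shift_map.csv", index=False)


# --------------------------------------------------------------------------
# Pipelines
# --------------------------------------------------------------------------

def train_ir(cfg: ExperimentConfig, inferred_fraction: Optional[float] = None
             ) -> tuple[ModelState, list]:
    s1, s2 = child_seeds(cfg.seed, 2)
    model = init_model(cfg.model, np.random.default_rng(s1))
    sess = SessionConfig.ir_training(
        n_trials=cfg.n_train, seed=s2,
        inferred_fraction=cfg.inferred_fraction if inferred_fraction is None
        else inferred_fraction,
        **cfg.session_kwargs())
    return run_session(model, sess)


def _write_log(results, outdir: Path, name: str) -> None:
    analysis.results_to_frame(results).to_csv(outdir / name, index=False)


def _preset_mapping(cfg: ExperimentConfig, outdir: Path) -> dict:
    """IR training + DMG probe (headline mapping performance)."""
    model, tres = train_ir(cfg)
    (s3,) = child_seeds(cfg.seed + 1, 1)
    model, probe = run_session(model, SessionConfig.dmg_probe(
        n_trials=400, seed=s3, **cfg.session_kwargs()))
    _write_log(tres, outdir, "training_log.csv")
    _write_log(probe, outdir, "dmg_probe_log.csv")
    save_model(model, outdir / "model.h5")
    export_weights_csv(model, outdir)
    return {"dmg_percent_correct": percent_correct(probe)}

def _preset_generalization(cfg: ExperimentConfig, outdir: Path) -> dict:
    """IR training + oblique-cue probes + error taxonomy."""
    model, tres = train_ir(cfg)
    s3, s4 = child_seeds(cfg.seed + 1, 2)
    out = {}
    for label, ctx in (("inferred", 1), ("direct", 0)):
        sess = SessionConfig.dmg_probe(n_trials=200, seed=s3 + ctx,
                                       cue_directions=OBLIQUES,
                                       **cfg.session_kwargs())
        # probe a single context: rebuild trials with that context fixed
        from .tasks import make_dmg_trial, run_trial
        ss = np.random.SeedSequence(s4 + ctx)
        tr, nr, dr = (np.random.default_rng(s) for s in ss.spawn(3))
        results = []
        for _ in range(sess.n_trials):
            spec = make_dmg_trial(sess, model.config, tr,
                                  cue=float(tr.choice(OBLIQUES)), context=ctx)
            results.append(run_trial(model, spec, sess, nr, dr))
        cls = analysis.classify_errors(results)
        cls.proportions.to_csv(outdir / f"errors_oblique_{label}.csv")
        _write_log(results, outdir, f"oblique_{label}_log.csv")
        out[f"oblique_{label}"] = cls.proportions["proportion"].to_dict()
    return out

def _preset_schedules(cfg: ExperimentConfig, outdir: Path) -> dict:
    """IR training + EPRS probe + BMRS adaptation."""
    model, _ = train_ir(cfg)
    s3, s4 = child_seeds(cfg.seed + 1, 2)
    model, eres = run_session(model, SessionConfig.pmg_session(
        n_trials=500, seed=s3, schedule="eprs", learning=True,
        store_traces=True, **cfg.session_kwargs()))
    model, bres = run_session(model, SessionConfig.pmg_session(
        n_trials=800, seed=s4, schedule="bmrs", learning=True,
        store_traces=True, **cfg.session_kwargs()))
    _write_log(eres, outdir, "eprs_log.csv")
    _write_log(bres, outdir, "bmrs_log.csv")
    save_model(model, outdir / "model_post_bmrs.h5")
    # PD-aligned population traces for the two schedule phases
    s5, = child_seeds(cfg.seed + 2, 1)
    model, dmg = run_session(model, SessionConfig.dmg_probe(
        n_trials=120, seed=s5, **cfg.session_kwargs()))
    pds = analysis.estimate_pds(dmg)
    nc_e = [r for r in eres if r.spec.kind == "pmg-nc" and not r.aborted]
    nc_b = [r for r in bres[300:] if r.spec.kind == "pmg-nc"
            and not r.aborted]
    save_population_trace(analysis.population_trace(nc_e, pds),
                          outdir / "trace_eprs.h5")
    save_population_trace(analysis.population_trace(nc_b, pds),
                          outdir / "trace_bmrs.h5")
    return {
        "eprs_nc_choices": choice_fractions(eres),
        "bmrs_nc_choices_tail": choice_fractions(bres[300:]),
    }

def _preset_sweep(cfg: ExperimentConfig, outdir: Path) -> dict:
    """Training-ratio sweep with logistic fits."""
    fractions = (0.2, 0.5, 0.65, 0.8, 0.95)
    curve = analysis.sweep_training_ratio(
        fractions, cfg.model, seed=cfg.seed, n_train=cfg.n_train)
    curve.to_frame().to_csv(outdir / "bias_curve.csv", index=False)
    m, beta, mse = analysis.fit_logistic(curve.fractions, curve.nc_inferred)
    return {"logistic_m": m, "logistic_beta": beta, "mse": mse}


PRESETS = {
    "mapping": _preset_mapping,
    "generalization": _preset_generalization,
    "schedules": _preset_schedules,
    "ratio-sweep": _preset_sweep,
}


def run_experiment(name: str, cfg: ExperimentConfig, outdir) -> dict:
    """Run a named preset pipeline; writes config copy, trial logs,
    snapshots and a JSON summary into the output directory."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")
    summary = PRESETS[name](cfg, outdir)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
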