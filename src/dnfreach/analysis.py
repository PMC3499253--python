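"""Behavioral and activity analyses.

Covers the standard summaries of simulated sessions: percent correct and
free-choice fractions, the generalization error taxonomy (correct /
context error at 180 degrees / adjacent-direction error at 45 degrees),
the training-statistics sweep with logistic fits of the resulting
free-choice bias, and pseudo-population traces of the motor preparation
field aligned to each site's preferred direction (PD).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .architecture import ModelConfig, ModelState, init_model
from .dnf_core import circular_distance
from .tasks import (
    CARDINALS,
    OBLIQUES,
    SessionConfig,
    TrialResult,
    choice_fractions,
    run_session,
)

__all__ = [
    "ErrorClassification",
    "BiasCurve",
    "PopulationTrace",
    "classify_errors",
    "results_to_frame",
    "sweep_training_ratio",
    "fit_logistic",
    "fit_scaled_sigmoid",
    "estimate_pds",
    "population_trace",
    "memory_ridge_count",
]

_CLASS_WINDOW = 10.0  # degrees around the 45/180 error modes


# --------------------------------------------------------------------------
# Trial logs and error taxonomy
# --------------------------------------------------------------------------

def results_to_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    """Flatten trial results into the canonical CSV trial log."""
    rows = []
    for k, r in enumerate(results):
        rows.append({
            "trial": k,
            "task": r.spec.kind,
            "cue_dir": r.spec.cue_dir,
            "context": r.spec.context,
            "goal_dirs": "/".join(f"{g:.1f}" for g in r.spec.goals),
            "reach_dir": r.reach,
            "reward": r.reward,
            "aborted": r.aborted,
            "choice": r.choice,
            "realized_goal": r.realized_goal,
            "p_reward_direct": None if r.schedule_probs is None
            else r.schedule_probs["direct"],
        })
    return pd.DataFrame(rows)


@dataclass
class ErrorClassification:
    """Per-condition proportions of reach-error classes and the deviation
    histogram binned on the task's 45-degree grid."""

    proportions: pd.DataFrame       # index: class label; columns: proportion
    histogram: pd.DataFrame         # deviation bin -> proportion
    n_scored: int
    n_aborted: int


def classify_errors(results: Sequence[TrialResult],
                    tolerance: float = 8.0,
                    window: float = _CLASS_WINDOW) -> ErrorClassification:
    """Classify each scored reach by its circular deviation from the
    rewarded goal: correct (within the reward tolerance), context error
    (about 180 degrees, i.e. the direct reach in an inferred trial),
    adjacent-direction error (about 45 degrees, onto a trained direction
    next to the goal), or other."""
    labels = []
    devs = []
    n_ab = 0
    for r in results:
        if r.aborted:
            n_ab += 1
            continue
        dev = float(circular_distance(r.reach, r.spec.goals[0]))
        devs.append(dev)
        if dev <= tolerance:
            labels.append("correct")
        elif abs(dev - 180.0) <= window:
            labels.append("context_error")
        elif abs(dev - 45.0) <= window:
            labels.append("adjacent_direction_error")
        else:
            labels.append("other")
    order = ["correct", "adjacent_direction_error", "context_error", "other"]
    n = max(len(labels), 1)
    props = pd.DataFrame(
        {"proportion": [labels.count(c) / n for c in order]}, index=order)
    bins = np.arange(-22.5, 181.0, 45.0)
    hist, _ = np.histogram(devs, bins=bins)
    histogram = pd.DataFrame({
        "deviation_deg": bins[:-1] + 22.5,
        "proportion": hist / n,
    })
    return ErrorClassification(proportions=props, histogram=histogram,
                               n_scored=len(labels), n_aborted=n_ab)


# --------------------------------------------------------------------------
# Training-statistics sweep and sigmoid fits
# --------------------------------------------------------------------------

@dataclass
class BiasCurve:
    """Free-choice behavior as a function of the training statistics."""

    fractions: np.ndarray            # inferred fraction during IR training
    nc_inferred: np.ndarray          # NC inferred-choice fraction
    activation_diff: np.ndarray      # memory-period PD - OD mean prep output
    n_nc: np.ndarray                 # scored NC trials per grid point

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "train_inferred_fraction": self.fractions,
            "nc_inferred_fraction": self.nc_inferred,
            "memory_activation_diff": self.activation_diff,
            "n_nc": self.n_nc,
        })


def _memory_activation_diff(results: Sequence[TrialResult]) -> float:
    """Mean memory-period preparation output at the inferred goal minus at
    the direct goal, over scored PMG-NC trials (the inferred direction is
    the preferred direction of the dominant choice after biased training)."""
    diffs = []
    for r in results:
        if r.spec.kind != "pmg-nc" or r.prep_memory_mean is None:
            continue
        n = r.prep_memory_mean.shape[0]
        i_dir = int(round(r.spec.goals[0] / (360.0 / n))) % n
        i_inf = int(round(r.spec.goals[1] / (360.0 / n))) % n
        diffs.append(r.prep_memory_mean[i_inf] - r.prep_memory_mean[i_dir])
    return float(np.mean(diffs)) if diffs else float("nan")


def sweep_training_ratio(fractions: Sequence[float],
                         base_config: ModelConfig,
                         seed: int,
                         n_train: int = 1000,
                         n_probe: int = 100) -> BiasCurve:
    """Train a fresh model per grid point at the given inferred-trial
    fraction, then probe free-choice behavior (PMG-NC, learning off)."""
    nc_frac = np.empty(len(fractions))
    act = np.empty(len(fractions))
    n_nc = np.empty(len(fractions), dtype=int)
    ss = np.random.SeedSequence(seed)
    for i, (frac, child) in enumerate(zip(fractions, ss.spawn(len(fractions)))):
        s1, s2, s3 = [int(c.generate_state(1)[0] % 2 ** 31)
                      for c in child.spawn(3)]
        model = init_model(base_config, np.random.default_rng(s1))
        model, _ = run_session(model, SessionConfig.ir_training(
            n_trials=n_train, seed=s2, inferred_fraction=float(frac)))
        model, probe = run_session(model, SessionConfig.pmg_session(
            n_trials=n_probe, seed=s3, learning=False, nc_fraction=1.0))
        cf = choice_fractions(probe)
        nc_frac[i] = cf["inferred"]
        n_nc[i] = cf["n"]
        act[i] = _memory_activation_diff(probe)
    return BiasCurve(fractions=np.asarray(fractions, dtype=float),
                     nc_inferred=nc_frac, activation_diff=act, n_nc=n_nc)


def _logistic(x, m, beta):
    return 1.0 / (1.0 + np.exp(-beta * (x - m)))


def fit_logistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of L(x) = 1/(1+exp(-beta (x - m))).

    Returns (m, beta, mse).  Raises on a degenerate (constant) curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 grid points")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate (constant) curve")
    res = least_squares(
        lambda p: _logistic(x, p[0], p[1]) - y,
        x0=[float(np.median(x)), 10.0],
        bounds=([x.min() - 1.0, 0.01], [x.max() + 1.0, 1000.0]))
    m, beta = res.x
    mse = float(np.mean(res.fun ** 2))
    return float(m), float(beta), mse


def fit_scaled_sigmoid(x: np.ndarray, y: np.ndarray
                       ) -> tuple[float, float, float, float, float]:
    """Least-squares fit of a * L(x) + b (scaled and shifted logistic);
    returns (m, beta, a, b, mse)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 grid points")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate (constant) curve")
    span = float(np.ptp(y))
    res = least_squares(
        lambda p: p[2] * _logistic(x, p[0], p[1]) + p[3] - y,
        x0=[float(np.median(x)), 10.0, span, float(y.min())],
        bounds=([x.min() - 1.0, 0.01, -10 * span - 1e-6, -np.inf],
                [x.max() + 1.0, 1000.0, 10 * span + 1e-6, np.inf]))
    m, beta, a, b = res.x
    mse = float(np.mean(res.fun ** 2))
    return float(m), float(beta), float(a), float(b), mse


# --------------------------------------------------------------------------
# Pseudo-population traces
# --------------------------------------------------------------------------

@dataclass
class PopulationTrace:
    """Trial-averaged, PD-aligned, per-site-normalized preparation-field
    output over (direction relative to PD) x time."""

    trace: np.ndarray                # (n_directions, n_frames) in [0, 1]
    raw: np.ndarray                  # trial-averaged trace, un-normalized
    rel_directions: np.ndarray       # degrees relative to PD
    markers: dict                    # frame indices: cue_on/cue_off/go

    def memory_profile(self) -> np.ndarray:
        """Mean un-normalized output over the memory-period frames, per
        relative direction."""
        lo = self.markers.get("cue_off", 0)
        hi = self.markers.get("memory_end", self.raw.shape[1])
        return self.raw[:, lo:hi].mean(axis=1)


def estimate_pds(dmg_results: Sequence[TrialResult]) -> np.ndarray:
    """Preferred direction per preparation-field site, estimated from DMG
    trials as the rewarded goal direction that maximizes the site's mean
    memory-period output (ties broken by the first maximum)."""
    by_goal: dict = {}
    for r in dmg_results:
        if r.aborted or r.prep_memory_mean is None:
            continue
        g = float(r.spec.goals[0])
        by_goal.setdefault(g, []).append(r.prep_memory_mean)
    if not by_goal:
        raise ValueError("no scored DMG trials with stored activity")
    goals = sorted(by_goal)
    mean_act = np.stack([np.mean(by_goal[g], axis=0) for g in goals])
    return np.asarray(goals, dtype=float)[np.argmax(mean_act, axis=0)]


def population_trace(results: Sequence[TrialResult],
                     pds: np.ndarray) -> PopulationTrace:
    """Average stored preparation-field traces across trials after rotating
    each trial so that sites whose PD equals the trial's inferred goal sit
    at relative direction 0; normalize each site row to its own maximum."""
    traces = []
    markers = None
    for r in results:
        if r.aborted or r.prep_trace is None:
            continue
        n = r.prep_trace.shape[1]
        step = 360.0 / n
        # rotate so the trial's inferred goal maps to index 0
        ref = float(r.spec.goals[-1])
        sites = np.flatnonzero(circular_distance(pds, ref) < step / 2)
        shift = int(sites[0]) if len(sites) else int(round(ref / step)) % n
        traces.append(np.roll(r.prep_trace, -shift, axis=1).T)
        if markers is None:
            markers = dict(r.trace_markers or {})
    if not traces:
        raise ValueError("no stored traces in results")
    n_frames = min(t.shape[1] for t in traces)
    raw = np.mean([t[:, :n_frames] for t in traces], axis=0)
    peak = np.maximum(raw.max(axis=1, keepdims=True), 1e-12)
    avg = raw / peak
    n = avg.shape[0]
    rel = np.arange(n) * (360.0 / n)
    rel[rel > 180.0] -= 360.0
    return PopulationTrace(trace=avg, raw=raw, rel_directions=rel,
                           markers=markers or {})


def memory_ridge_count(trace: PopulationTrace,
                       threshold: float = 0.5) -> int:
    """Number of circularly contiguous above-threshold regions in the
    memory-period profile of a population trace (one sustained ridge for
    biased behavior, two for balanced behavior)."""
    prof = trace.memory_profile()
    prof = prof / max(prof.max(), 1e-12)
    above = prof > threshold
    if above.all():
        return 1
    n = len(above)
    count = 0
    for i in range(n):
        if above[i] and not above[(i - 1) % n]:
            count += 1
    return count
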