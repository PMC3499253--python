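"""Response readout, reward evaluation, and reward-dependent Hebbian rules.

Learning is applied once per trial, after a response has been selected, from
output snapshots averaged over the selection window.  Both plastic
projections use variants of the instar/outstar rules gated by the binary
reward signal R in {+1, -1}:

* instar  (context nodes -> association field): active association sites move
  their incoming weight pattern toward the context-node output pattern on
  reward, and decay weights between co-active pairs on failure.  No
  presynaptic normalization, so many association regions can come to prefer
  the same context (divergent projection).
* outstar (association field -> preparation field): active association sites
  move their outgoing weight pattern toward the preparation-field output (the
  actually executed reach) on reward; on failure the weight to the active
  preparation region is removed and redistributed uniformly over inactive
  targets, so a failed response becomes less likely and alternatives more
  likely on the next identical trial.

Failure updates carry a per-trial normalization so the summed weight change
is comparable to that of a matched rewarded trial (scaled by the smaller
failure learning rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dnf_core import FieldState, circular_distance, sigmoid_output
from .architecture import ModelState, PlasticProjection

__all__ = [
    "LearningRates",
    "RewardSignal",
    "read_response",
    "evaluate_reward",
    "instar_update",
    "outstar_update",
    "apply_trial_learning",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LearningRates:
    """Per-trial learning rates: eps_pos on rewarded trials must exceed
    eps_neg on failed trials (consolidation beats erosion)."""

    eps_pos: float = 0.1
    eps_neg: float = 0.06

    def __post_init__(self):
        if not (self.eps_pos > self.eps_neg > 0):
            raise ValueError("need eps_pos > eps_neg > 0")


@dataclass(frozen=True)
class RewardSignal:
    value: int                      # +1 or -1
    tolerance: float = 8.0          # degrees


# --------------------------------------------------------------------------
# Readout and reward
# --------------------------------------------------------------------------

def _circular_smooth(f: np.ndarray, dx: float, width: float) -> np.ndarray:
    n = f.shape[0]
    off = np.arange(n) * dx
    off = np.minimum(off, n * dx - off)
    k = np.exp(-0.5 * (off / width) ** 2)
    k /= k.sum()
    return np.real(np.fft.ifft(np.fft.fft(f) * np.fft.fft(k)))


def read_response(motor: FieldState, theta: float = 0.5,
                  smoothing: float = 6.0,
                  rng: Optional[np.random.Generator] = None
                  ) -> Optional[float]:
    """Reach direction read from the motor field, or None (aborted trial).

    The field output is circularly smoothed; a response is declared iff the
    smoothed output exceeds ``theta`` somewhere.  The reach direction is the
    circular centroid of the above-threshold region containing the tallest
    peak; an exact tie between separate regions is broken uniformly at
    random (seeded rng).
    """
    f = motor.output()
    dx = motor.lattice.spacing(0)
    sm = _circular_smooth(f, dx, smoothing)
    if sm.max() <= theta:
        return None
    above = sm > theta
    # label circularly connected above-threshold regions
    labels = np.full(f.shape[0], -1, dtype=int)
    n = f.shape[0]
    lab = 0
    for i in range(n):
        if above[i] and labels[i] < 0:
            j = i
            while above[j] and labels[j] < 0:
                labels[j] = lab
                j = (j + 1) % n
            j = (i - 1) % n
            while above[j] and labels[j] < 0:
                labels[j] = lab
                j = (j - 1) % n
            lab += 1
    heights = np.array([sm[labels == k].max() for k in range(lab)])
    best = np.flatnonzero(heights >= heights.max() - 1e-12)
    if len(best) > 1:
        pick = int(best[0]) if rng is None else int(rng.choice(best))
    else:
        pick = int(best[0])
    idx = labels == pick
    ang = np.deg2rad(motor.lattice.coords(0)[idx])
    w = sm[idx]
    c = np.average(np.exp(1j * ang), weights=w)
    return float(np.mod(np.rad2deg(np.angle(c)), 360.0))


def evaluate_reward(reach: float, goal: float,
                    tolerance: float = 8.0) -> RewardSignal:
    """R = +1 iff the reach lies within the (closed) tolerance window of the
    goal, by circular distance; R = -1 otherwise."""
    ok = circular_distance(reach, goal) <= tolerance
    return RewardSignal(value=1 if ok else -1, tolerance=tolerance)


# --------------------------------------------------------------------------
# Weight updates
# --------------------------------------------------------------------------

def instar_update(proj: PlasticProjection, assoc_out: np.ndarray,
                  ctx_out: np.ndarray, reward: int,
                  rates: LearningRates) -> PlasticProjection:
    """Reward-dependent instar rule on W_ca (n_contexts x n_assoc).

    R=+1:  dW[c, x] = eps_pos * f_assoc(x) * (f_ctx(c) - W[c, x])
    R=-1:  dW[c, x] = -eps_neg * N * f_assoc(x) * f_ctx(c) * W[c, x],
           N chosen per trial so the summed |dW| matches the drive of a
           rewarded trial at the same outputs (at rate eps_neg).
    """
    W = proj.W
    fa = assoc_out[None, :]
    fc = ctx_out[:, None]
    if reward > 0:
        W += rates.eps_pos * fa * (fc - W)
    else:
        drive = np.abs(fa * (fc - W)).sum()
        raw = fa * fc * W
        norm = drive / max(raw.sum(), _EPS)
        W -= rates.eps_neg * norm * raw
    proj.clip()
    return proj


def outstar_update(proj: PlasticProjection, assoc_out: np.ndarray,
                   prep_out: np.ndarray, reward: int,
                   rates: LearningRates,
                   active_threshold: float = 0.5) -> PlasticProjection:
    """Reward-dependent outstar rule on W_ap (n_assoc x n_prep).

    R=+1:  dW[x, y] = eps_pos * f_assoc(x) * (f_prep(y) - W[x, y])
    R=-1:  weight from active association sites to the active preparation
           region is removed (normalized as in the instar rule) and the
           removed amount is redistributed over that site's inactive targets
           in proportion to their current weights, preserving each source's
           weight sum.  Proportional (rather than uniform) redistribution
           concentrates the strengthening on the alternative responses the
           site already supports, so a failed response makes the strongest
           competing response more likely next time.
    """
    W = proj.W
    fa = assoc_out[:, None]
    fp = prep_out[None, :]
    if reward > 0:
        W += rates.eps_pos * fa * (fp - W)
    else:
        active = prep_out > active_threshold
        if active.any() and (~active).any():
            drive = np.abs(fa * (fp - W)).sum()
            raw = fa * fp * W
            raw[:, ~active] = 0.0
            norm = drive / max(raw.sum(), _EPS)
            removal = rates.eps_neg * norm * raw
            W -= removal
            inactive_w = W[:, ~active]
            share = inactive_w / np.maximum(
                inactive_w.sum(axis=1, keepdims=True), _EPS)
            W[:, ~active] += removal.sum(axis=1, keepdims=True) * share
    proj.clip()
    return proj


def apply_trial_learning(model: ModelState, assoc_out: np.ndarray,
                         ctx_out: np.ndarray, prep_out: np.ndarray,
                         reward: int, rates: LearningRates) -> ModelState:
    """Apply both rules once, from the trial's stored output snapshots."""
    instar_update(model.ctx_assoc, assoc_out, ctx_out, reward, rates)
    outstar_update(model.assoc_prep, assoc_out, prep_out, reward, rates)
    return model
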