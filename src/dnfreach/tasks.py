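"""Trial construction and session execution.

Task variants (all center-out reach tasks on a circle of directions; the
rewarded goal is the spatial cue rotated by the context's mapping rule,
0 degrees = 'direct', 180 degrees = 'inferred'):

* IR       -- inferred-reach training: spatial + context cue at trial start;
              a target cue at the rewarded goal appears at the end of the
              memory period, with salience fading linearly from 1 to 0 over
              the session; go directly after the target cue.
* DMG      -- definite motor goal: spatial + context cue simultaneously at
              trial start; probe condition, learning off.
* PMG-CI   -- potential motor goal, context instruction: spatial cue first,
              context cue at the end of the memory period resolves the
              ambiguity.
* PMG-NC   -- potential motor goal, no context: free choice between the
              direct and the inferred goal; reward drawn by a schedule.

Reward schedules for PMG-NC trials:

* EPRS -- either potential goal rewarded with probability 50:50,
          independent of the history.
* BMRS -- bias-minimizing: the reward probability of a goal is lowered in
          proportion to its recent choice fraction (sliding window), so only
          balanced choice behavior earns the maximal 50% reward.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np

from .architecture import ModelConfig, ModelState, Stimuli, init_model, \
    set_go_gate, step_model
from .dnf_core import circular_distance, gaussian_input
from .learning import LearningRates, apply_trial_learning, evaluate_reward, \
    read_response

__all__ = [
    "TaskTiming",
    "TrialSpec",
    "TrialResult",
    "SessionConfig",
    "RewardScheduleState",
    "make_ir_trial",
    "make_dmg_trial",
    "make_pmg_trial",
    "eprs_draw",
    "bmrs_update_and_draw",
    "run_trial",
    "run_session",
    "reset_model",
    "fade_salience",
    "CARDINALS",
    "OBLIQUES",
]

CARDINALS = (0.0, 90.0, 180.0, 270.0)
OBLIQUES = (45.0, 135.0, 225.0, 315.0)


# --------------------------------------------------------------------------
# Timing and trial specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskTiming:
    """Epoch durations in model time units.  The behavioral protocol fixes
    only the relative epoch structure; absolute durations are a simulation
    choice."""

    t_cue: float = 100.0       # spatial (and simultaneous context) cue
    t_memory: float = 300.0    # unstimulated memory period
    t_instr: float = 220.0     # late instruction / target-cue window: must
                               # exceed the attractor drift time of the
                               # association peak (~20 tau) for a late
                               # context cue to relocate it
    t_select: float = 120.0    # go -> end of trial (selection window)


@dataclass(frozen=True)
class TrialSpec:
    """One trial's stimulus timeline, context, and rewarded goal(s)."""

    kind: str                          # 'ir' | 'dmg' | 'pmg-ci' | 'pmg-nc'
    cue_dir: float
    context: Optional[int]             # context-node index, None for PMG-NC
    goals: tuple[float, ...]           # rewarded goal / potential goals
    timing: TaskTiming
    target_salience: float = 0.0       # IR target-cue salience in [0, 1]
    # event times (model time units)
    cue_off: float = 0.0
    ctx_on: float = 0.0
    ctx_off: float = 0.0
    target_on: Optional[float] = None
    target_off: Optional[float] = None
    t_go: float = 0.0
    t_end: float = 0.0

    @property
    def target_dir(self) -> Optional[float]:
        return self.goals[0] if self.kind == "ir" else None

    @property
    def memory_end(self) -> float:
        """End of the unstimulated memory period."""
        if self.kind == "ir" and self.target_on is not None:
            return self.target_on
        if self.kind == "pmg-ci":
            return self.ctx_on
        return self.t_go

    def stimuli_at(self, t: float) -> Stimuli:
        stim = Stimuli()
        if t < self.cue_off:
            stim.cue_dir = self.cue_dir
            stim.cue_salience = 1.0
        if self.context is not None and self.ctx_on <= t < self.ctx_off:
            stim.context = self.context
        if (self.target_on is not None and self.target_salience > 0
                and self.target_on <= t < self.target_off):
            stim.target_dir = self.goals[0]
            stim.target_salience = self.target_salience
        return stim


def fade_salience(k: int, n_trials: int) -> float:
    """IR target-cue salience: linear from 1 (trial 0) to 0 (trial n)."""
    return max(0.0, 1.0 - k / n_trials)


def _goal(cue: float, rotation: float) -> float:
    return float(np.mod(cue + rotation, 360.0))


def _draw_context(cfg: ModelConfig, inferred_fraction: float,
                  rng: np.random.Generator) -> int:
    """Direct (rotation-0) context with probability 1 - inferred_fraction;
    the remaining probability split equally over the non-direct contexts."""
    if rng.random() < inferred_fraction:
        return int(rng.integers(1, cfg.n_contexts))
    return 0


def make_ir_trial(k: int, session: "SessionConfig", model_cfg: ModelConfig,
                  rng: np.random.Generator) -> TrialSpec:
    tm = session.timing
    cue = float(rng.choice(session.cue_directions))
    ctx = _draw_context(model_cfg, session.inferred_fraction, rng)
    goal = _goal(cue, model_cfg.context_rotations[ctx])
    mem_end = tm.t_cue + tm.t_memory
    go = mem_end + tm.t_instr
    return TrialSpec(
        kind="ir", cue_dir=cue, context=ctx, goals=(goal,), timing=tm,
        target_salience=fade_salience(k, session.n_trials) if session.fade
        else 1.0,
        cue_off=tm.t_cue, ctx_on=0.0, ctx_off=tm.t_cue,
        target_on=mem_end, target_off=go,
        t_go=go, t_end=go + tm.t_select)


def make_dmg_trial(session: "SessionConfig", model_cfg: ModelConfig,
                   rng: np.random.Generator,
                   cue: Optional[float] = None,
                   context: Optional[int] = None) -> TrialSpec:
    tm = session.timing
    if cue is None:
        cue = float(rng.choice(session.cue_directions))
    if context is None:
        context = int(rng.integers(model_cfg.n_contexts))
    goal = _goal(cue, model_cfg.context_rotations[context])
    go = tm.t_cue + tm.t_memory
    return TrialSpec(
        kind="dmg", cue_dir=cue, context=context, goals=(goal,), timing=tm,
        cue_off=tm.t_cue, ctx_on=0.0, ctx_off=tm.t_cue,
        t_go=go, t_end=go + tm.t_select)


def make_pmg_trial(kind: str, session: "SessionConfig",
                   model_cfg: ModelConfig, rng: np.random.Generator,
                   cue: Optional[float] = None,
                   context: Optional[int] = None) -> TrialSpec:
    if kind not in ("ci", "nc"):
        raise ValueError("PMG kind must be 'ci' or 'nc'")
    tm = session.timing
    if cue is None:
        cue = float(rng.choice(session.cue_directions))
    mem_end = tm.t_cue + tm.t_memory
    go = mem_end + tm.t_instr
    if kind == "ci":
        if context is None:
            context = int(rng.integers(model_cfg.n_contexts))
        goal = _goal(cue, model_cfg.context_rotations[context])
        return TrialSpec(
            kind="pmg-ci", cue_dir=cue, context=context, goals=(goal,),
            timing=tm, cue_off=tm.t_cue,
            ctx_on=mem_end, ctx_off=go,
            t_go=go, t_end=go + tm.t_select)
    return TrialSpec(
        kind="pmg-nc", cue_dir=cue, context=None,
        goals=(_goal(cue, 0.0), _goal(cue, 180.0)), timing=tm,
        cue_off=tm.t_cue, t_go=go, t_end=go + tm.t_select)


# --------------------------------------------------------------------------
# Reward schedules
# --------------------------------------------------------------------------

@dataclass
class RewardScheduleState:
    """Sliding window of recent free-choice labels for the BMRS."""

    window: int = 20
    choices: deque = dc_field(default_factory=deque)  # 'direct' | 'inferred'

    def probabilities(self) -> dict:
        """Current reward probability per potential goal; 50:50 fallback on
        an empty window.  P(reward at g) = 1 - recent fraction of g-choices
        (the raw probabilities already sum to 1 for two goals)."""
        if not self.choices:
            return {"direct": 0.5, "inferred": 0.5}
        frac_direct = sum(c == "direct" for c in self.choices) / \
            len(self.choices)
        return {"direct": 1.0 - frac_direct, "inferred": frac_direct}

    def record(self, choice: str) -> None:
        self.choices.append(choice)
        while len(self.choices) > self.window:
            self.choices.popleft()


def eprs_draw(spec: TrialSpec, rng: np.random.Generator) -> float:
    """Equal-probability schedule: fair coin between the two potential
    goals, independent of history and of the model's choice."""
    return float(spec.goals[int(rng.integers(2))])


def bmrs_update_and_draw(state: RewardScheduleState, spec: TrialSpec,
                         rng: np.random.Generator) -> float:
    """Draw the rewarded goal under the bias-minimizing schedule from the
    current window (the window itself is updated by ``state.record`` once
    the model's choice is known)."""
    p = state.probabilities()
    r = rng.random()
    return float(spec.goals[0]) if r < p["direct"] else float(spec.goals[1])


# --------------------------------------------------------------------------
# Session configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionConfig:
    """One block of trials with a fixed mixture and schedule."""

    kind: str                               # 'ir' | 'dmg' | 'pmg'
    n_trials: int
    seed: int = 0
    timing: TaskTiming = TaskTiming()
    rates: LearningRates = LearningRates()
    learning: bool = True
    inferred_fraction: float = 0.8          # IR mixture
    fade: bool = True                       # IR target-cue fade on/off
    nc_fraction: float = 0.4                # PMG mixture: P(NC) vs CI
    schedule: str = "eprs"                  # 'eprs' | 'bmrs' for NC trials
    bmrs_window: int = 20
    cue_directions: tuple[float, ...] = CARDINALS
    theta: float = 0.5                      # response threshold
    smoothing: float = 6.0                  # readout smoothing width (deg)
    tolerance: float = 8.0                  # reward window (deg)
    store_traces: bool = False
    trace_stride: int = 10                  # steps between stored frames
    engine: str = "auto"                    # 'auto' | 'reference'

    def __post_init__(self):
        if not (0.0 <= self.inferred_fraction <= 1.0):
            raise ValueError("inferred_fraction must be in [0, 1]")
        if not (0.0 <= self.nc_fraction <= 1.0):
            raise ValueError("nc_fraction must be in [0, 1]")
        if self.schedule not in ("eprs", "bmrs"):
            raise ValueError("schedule must be 'eprs' or 'bmrs'")
        if self.kind not in ("ir", "dmg", "pmg"):
            raise ValueError("session kind must be 'ir', 'dmg' or 'pmg'")

    # common presets ------------------------------------------------------
    @classmethod
    def ir_training(cls, n_trials: int = 1000, seed: int = 0,
                    inferred_fraction: float = 0.8, **kw) -> "SessionConfig":
        return cls(kind="ir", n_trials=n_trials, seed=seed,
                   inferred_fraction=inferred_fraction, **kw)

    @classmethod
    def dmg_probe(cls, n_trials: int = 400, seed: int = 0,
                  **kw) -> "SessionConfig":
        return cls(kind="dmg", n_trials=n_trials, seed=seed, learning=False,
                   **kw)

    @classmethod
    def pmg_session(cls, n_trials: int = 500, seed: int = 0,
                    schedule: str = "eprs", learning: bool = False,
                    **kw) -> "SessionConfig":
        return cls(kind="pmg", n_trials=n_trials, seed=seed,
                   schedule=schedule, learning=learning, **kw)


# --------------------------------------------------------------------------
# Trial and session execution
# --------------------------------------------------------------------------

@dataclass
class TrialResult:
    """Outcome of one executed trial."""

    spec: TrialSpec
    reach: Optional[float]                 # degrees, or None if aborted
    reward: Optional[int]                  # +1 / -1, None if aborted
    realized_goal: Optional[float]         # goal that was rewarded
    choice: Optional[str] = None           # PMG-NC: 'direct' | 'inferred'
    aborted: bool = False
    schedule_probs: Optional[dict] = None
    prep_memory_mean: Optional[np.ndarray] = None  # mean f_prep over memory
    prep_trace: Optional[np.ndarray] = None        # (frames x n_dirs)
    trace_markers: Optional[dict] = None           # frame indices of events


def reset_model(model: ModelState) -> ModelState:
    """Return all fields and nodes to their resting levels (between trials);
    weights are untouched."""
    model.spatial.u[:] = model.spatial.params.h
    model.assoc.u[:] = model.assoc.params.h
    model.prep.u[:] = model.prep.params.h
    model.motor.u[:] = model.motor.params.h
    model.ctx.u[:] = model.ctx.params.h
    model.spatial.s[:] = 0.0
    set_go_gate(model, False)
    return model


def _engine_arrays(model: ModelState) -> Optional[dict]:
    """Collapse the model's kernels into the compiled engine's matrix form,
    or return None if the configuration is outside the engine's envelope."""
    if model.engine_cache is not None:
        return model.engine_cache
    from . import _engine
    if not _engine.HAVE_NUMBA:
        return None
    if model.assoc.kernel.inh_mats is not None:
        return None  # separable local inhibition: reference path only

    def collapse(field):
        k = field.kernel
        K = k.params.exc_amp * k.exc_mats[0]
        if k.inh_mats is not None:
            K = K - k.params.inh_amp * k.inh_mats[0]
        return np.ascontiguousarray(K), k.global_inh

    K_sp, glob_sp = collapse(model.spatial)
    K_pr, glob_pr = collapse(model.prep)
    K_mo, glob_mo = collapse(model.motor)
    ka = model.assoc.kernel
    K_as_sp = np.ascontiguousarray(ka.params.exc_amp * ka.exc_mats[0])
    K_as_ctx = np.ascontiguousarray(ka.exc_mats[1].T)

    def par(p):
        return np.array([p.tau, p.h, p.q, p.beta])

    model.engine_cache = dict(
        K_sp=K_sp, glob_sp=glob_sp, K_as_sp=K_as_sp, K_as_ctx=K_as_ctx,
        glob_as=ka.global_inh, K_pr=K_pr, glob_pr=glob_pr, K_mo=K_mo,
        glob_mo=glob_mo,
        par_sp=par(model.spatial.params), par_nd=par(model.ctx.params),
        par_as=par(model.assoc.params), par_pr=par(model.prep.params),
        par_mo=par(model.motor.params),
    )
    return model.engine_cache


def _spatial_series(model: ModelState, spec: TrialSpec,
                    n_steps: int) -> np.ndarray:
    cfg = model.config
    lat = model.spatial.lattice
    dt = cfg.dt
    s = np.zeros((n_steps, cfg.n_spatial))
    cue = gaussian_input(lat, spec.cue_dir, cfg.stim_amp, cfg.stim_width)
    s[: int(round(spec.cue_off / dt))] += cue
    if spec.target_on is not None and spec.target_salience > 0:
        tgt = gaussian_input(lat, spec.goals[0],
                             cfg.stim_amp * spec.target_salience,
                             cfg.stim_width)
        s[int(round(spec.target_on / dt)):
          int(round(spec.target_off / dt))] += tgt
    return s


def run_trial(model: ModelState, spec: TrialSpec, session: SessionConfig,
              noise_rng: np.random.Generator,
              draw_rng: np.random.Generator,
              schedule_state: Optional[RewardScheduleState] = None
              ) -> TrialResult:
    """Step the model through one trial's timeline, read the response,
    realize the reward and (if enabled) apply the per-trial learning."""
    cfg = model.config
    dt = cfg.dt
    reset_model(model)

    n_steps = int(round(spec.t_end / dt))
    mem_lo = spec.cue_off
    mem_hi = spec.memory_end

    snap_assoc = np.zeros(model.assoc.u.shape)
    snap_ctx = np.zeros(cfg.n_contexts)
    snap_prep = np.zeros(cfg.n_spatial)
    n_snap = 0
    mem_prep = np.zeros(cfg.n_spatial)
    n_mem = 0

    markers = {"cue_on": 0}
    stride = session.trace_stride
    trace = None

    eng = _engine_arrays(model) if session.engine == "auto" else None
    if eng is not None:
        from ._engine import run_trial_core
        go_step = int(round(spec.t_go / dt))
        snap_step = go_step + (n_steps - go_step) // 3
        n_frames_max = (n_steps + stride - 1) // stride
        trace_buf = np.zeros((n_frames_max if session.store_traces else 1,
                              cfg.n_spatial))
        if spec.context is not None:
            ctx_idx = spec.context
            ctx_on = int(round(spec.ctx_on / dt))
            ctx_off = int(round(spec.ctx_off / dt))
        else:
            ctx_idx, ctx_on, ctx_off = -1, 0, 0
        def noise_for(q, shape):
            if q <= 0:
                return np.empty((0,) + shape)
            return noise_rng.standard_normal((n_steps,) + shape)

        noise_sp = noise_for(cfg.spatial_q, (cfg.n_spatial,))
        noise_ctx = noise_for(cfg.node_q, (cfg.n_contexts,))
        noise_as = noise_for(cfg.assoc_q,
                             (cfg.n_spatial, cfg.n_ctx_samples))
        noise_pr = noise_for(cfg.prep_q, (cfg.n_spatial,))
        noise_mo = noise_for(cfg.motor_q, (cfg.n_spatial,))
        n_snap, n_mem, n_frames = run_trial_core(
            model.spatial.u, model.ctx.u, model.assoc.u, model.prep.u,
            model.motor.u,
            eng["K_sp"], eng["glob_sp"], eng["K_as_sp"], eng["K_as_ctx"],
            eng["glob_as"], eng["K_pr"], eng["glob_pr"], eng["K_mo"],
            eng["glob_mo"],
            cfg.node_self, cfg.node_inh,
            model.blur_sp,
            model.ctx_assoc.W, model.assoc_prep.W,
            cfg.g_ctx_assoc,
            model.assoc_prep.gain * model.assoc_prep.volume,
            cfg.g_spatial_assoc, cfg.g_spatial_prep, cfg.g_prep_motor,
            cfg.g_motor_prep,
            cfg.c_motor_prep * model.motor.lattice.spacing(0),
            cfg.go_amp,
            eng["par_sp"], eng["par_nd"], eng["par_as"], eng["par_pr"],
            eng["par_mo"],
            dt,
            _spatial_series(model, spec, n_steps),
            ctx_idx, cfg.ctx_stim_amp, ctx_on, ctx_off,
            go_step, n_steps,
            noise_sp, noise_ctx, noise_as, noise_pr, noise_mo,
            snap_assoc, snap_ctx, snap_prep, mem_prep,
            int(round(mem_lo / dt)), int(round(mem_hi / dt)),
            trace_buf, stride, session.store_traces, snap_step,
        )
        set_go_gate(model, True)
        if session.store_traces:
            trace = trace_buf[:n_frames]
    else:
        frames = []
        snap_t = spec.t_go + (spec.t_end - spec.t_go) / 3.0
        for i in range(n_steps):
            t = i * dt
            if t >= spec.t_go and not model.go:
                set_go_gate(model, True)
            step_model(model, spec.stimuli_at(t), dt, noise_rng)
            if t >= snap_t:
                snap_assoc += model.assoc.output()
                snap_ctx += model.ctx.output()
                snap_prep += model.prep.output()
                n_snap += 1
            if mem_lo <= t < mem_hi:
                mem_prep += model.prep.output()
                n_mem += 1
            if session.store_traces and i % stride == 0:
                frames.append(model.prep.output().copy())
        if session.store_traces:
            trace = np.array(frames)
    if session.store_traces:
        markers["cue_off"] = int(spec.cue_off / dt) // stride
        markers["memory_end"] = int(mem_hi / dt) // stride
        markers["go"] = int(spec.t_go / dt) // stride

    reach = read_response(model.motor, session.theta, session.smoothing,
                          draw_rng)

    mem_mean = mem_prep / max(n_mem, 1)

    if reach is None:
        return TrialResult(spec=spec, reach=None, reward=None,
                           realized_goal=None, aborted=True,
                           prep_memory_mean=mem_mean, prep_trace=trace,
                           trace_markers=markers if session.store_traces
                           else None)

    # choice label and realized reward
    choice = None
    probs = None
    if spec.kind == "pmg-nc":
        d_direct = circular_distance(reach, spec.goals[0])
        d_inf = circular_distance(reach, spec.goals[1])
        choice = "direct" if d_direct <= d_inf else "inferred"
        if session.schedule == "bmrs":
            if schedule_state is None:
                raise ValueError("BMRS requires a RewardScheduleState")
            probs = schedule_state.probabilities()
            realized = bmrs_update_and_draw(schedule_state, spec, draw_rng)
            schedule_state.record(choice)
        else:
            realized = eprs_draw(spec, draw_rng)
    else:
        realized = spec.goals[0]

    reward = evaluate_reward(reach, realized, session.tolerance).value

    if session.learning and n_snap > 0:
        apply_trial_learning(model, (snap_assoc / n_snap).ravel(),
                             snap_ctx / n_snap, snap_prep / n_snap,
                             reward, session.rates)

    return TrialResult(spec=spec, reach=reach, reward=reward,
                       realized_goal=realized, choice=choice,
                       schedule_probs=probs, prep_memory_mean=mem_mean,
                       prep_trace=trace,
                       trace_markers=markers if session.store_traces
                       else None)


def run_session(model: ModelState, session: SessionConfig
                ) -> tuple[ModelState, list[TrialResult]]:
    """Run a block of trials with persistent model and schedule state.

    All randomness flows from the session seed through named child streams
    (trial draws, field noise, schedule draws), so a session is reproducible
    from (config, seed).
    """
    ss = np.random.SeedSequence(session.seed)
    trial_rng, noise_rng, draw_rng = \
        (np.random.default_rng(s) for s in ss.spawn(3))
    schedule_state = RewardScheduleState(window=session.bmrs_window) \
        if session.schedule == "bmrs" else None

    results: list[TrialResult] = []
    for k in range(session.n_trials):
        if session.kind == "ir":
            spec = make_ir_trial(k, session, model.config, trial_rng)
        elif session.kind == "dmg":
            spec = make_dmg_trial(session, model.config, trial_rng)
        else:
            nc = trial_rng.random() < session.nc_fraction
            spec = make_pmg_trial("nc" if nc else "ci", session,
                                  model.config, trial_rng)
        results.append(run_trial(model, spec, session, noise_rng, draw_rng,
                                 schedule_state))
    return model, results


# --------------------------------------------------------------------------
# Summaries
# --------------------------------------------------------------------------

def percent_correct(results: Sequence[TrialResult]) -> float:
    """Percent rewarded among non-aborted trials (aborted trials are logged
    but excluded from the denominator)."""
    scored = [r for r in results if not r.aborted]
    if not scored:
        return float("nan")
    return 100.0 * sum(r.reward > 0 for r in scored) / len(scored)


def choice_fractions(results: Sequence[TrialResult]) -> dict:
    """Fractions of direct / inferred choices among scored PMG-NC trials."""
    nc = [r for r in results
          if r.spec.kind == "pmg-nc" and not r.aborted]
    if not nc:
        return {"direct": float("nan"), "inferred": float("nan"), "n": 0}
    n_direct = sum(r.choice == "direct" for r in nc)
    return {"direct": n_direct / len(nc),
            "inferred": 1.0 - n_direct / len(nc), "n": len(nc)}
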