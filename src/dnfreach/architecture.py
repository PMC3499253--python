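"""The five-component reach-selection model.

Components (all feature dimensions in degrees of reach/cue direction unless
stated otherwise):

* spatial input field   -- 1-D circular; input-driven regime; represents the
                           currently visible spatial cue(s).
* context nodes         -- discrete nodes with self-excitation and mutual
                           inhibition; latch the trial's context cue.
* association field     -- 2-D (direction x abstract context dimension);
                           memory + selection regime; a single self-sustained
                           peak stores the cue conjunction over the memory
                           period and is the substrate of all learning.
* motor preparation field -- 1-D; soft competition (local excitation, global
                           inhibition); integrates the direct pathway, the
                           learned associative pathway and motor feedback.
* motor field           -- 1-D; strong winner-take-all; held at a low resting
                           level until the go signal disinhibits it.

Fixed projections are topological (Gaussian-blurred, normalized so a
saturated localized source peak delivers roughly its gain at the target
center).  Two projections are plastic: context nodes -> association field
(W_ca, instar-trained) and association field -> motor preparation field
(W_ap, outstar-trained, initialized as a wrapped-Gaussian topological map
with zero index shift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict, replace
from typing import Optional

import numpy as np

from .dnf_core import (
    FeatureLattice,
    FieldParams,
    FieldState,
    InteractionKernel,
    NodeGroup,
    build_kernel,
    circular_distance,
    field_step,
    gaussian_input,
    node_step,
    sigmoid_output,
)

__all__ = [
    "ModelConfig",
    "TopologicalProjection",
    "PlasticProjection",
    "Stimuli",
    "ModelState",
    "init_model",
    "step_model",
    "set_go_gate",
    "motor_feedback",
    "validate_regimes",
    "RegimeError",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """All model constants, with units.

    Field parameters are (tau, h, q, beta) per field; kernel parameters are
    amplitude densities (per degree, and per context unit for the 2-D field)
    and Gaussian widths.  Projection gains are the approximate input
    amplitude delivered by a saturated source peak.
    """

    # lattices
    n_spatial: int = 72                 # samples on the 360-degree circle
    n_ctx_samples: int = 10             # samples along the context dimension
    ctx_extent: float = 10.0            # context-dimension extent (units)
    ctx_circular: bool = False          # bounded by default (see methods)
    assoc_boundary_norm: float = 0.5    # border-support exponent, bounded dim
    n_contexts: int = 2                 # context nodes
    context_rotations: tuple[float, ...] = (0.0, 180.0)  # goal = cue + rot

    dt: float = 1.0                     # Euler step (model time units)

    # spatial input field (input-driven)
    spatial_tau: float = 10.0
    spatial_h: float = -2.0
    spatial_q: float = 0.05
    spatial_beta: float = 1.5  # graded: the cue representation decays as a
                               # smooth sensory trace after stimulus offset
    spatial_kexc: float = 0.15
    spatial_kexc_width: float = 8.0
    spatial_kglob: float = 0.001

    # context nodes (latching)
    node_tau: float = 10.0
    node_h: float = -2.0
    node_q: float = 0.05
    node_beta: float = 4.0
    node_self: float = 3.5
    node_inh: float = 2.0

    # association field (memory + selection)
    assoc_tau: float = 10.0
    assoc_h: float = -3.0
    assoc_q: float = 0.15  # placement of the peak along the context
                           # dimension explores under this noise
    assoc_beta: float = 2.0  # graded peak: movable by late context input
    assoc_kexc: float = 0.22
    assoc_kexc_width_sp: float = 10.0   # degrees
    assoc_kexc_width_ctx: float = 3.0   # context units
    assoc_kglob: float = 0.07

    # motor preparation field (soft competition)
    prep_tau: float = 10.0
    prep_h: float = -2.0
    prep_q: float = 0.05
    prep_beta: float = 1.5   # graded output: input differences must survive
                             # into the selection stage
    prep_kexc: float = 0.05
    prep_kexc_width: float = 8.0
    prep_kglob: float = 0.05

    # motor field (gated winner-take-all)
    motor_tau: float = 10.0
    motor_h: float = -4.0
    motor_q: float = 0.05
    motor_beta: float = 4.0
    motor_kexc: float = 0.30
    motor_kexc_width: float = 8.0
    motor_kglob: float = 0.15

    # stimuli
    stim_amp: float = 5.0               # spatial / target cue input amplitude
    stim_width: float = 8.0             # degrees
    ctx_stim_amp: float = 5.0           # context-node input while cue is on

    # fixed projections
    proj_width: float = 6.0             # blur of topological projections (deg)
    g_spatial_prep: float = 3.5         # direct pathway gain
    g_spatial_assoc: float = 3.0        # ridge input gain
    g_ctx_assoc: float = 2.5            # context-node -> association gain
    g_assoc_prep: float = 0.02          # gain on integral-weighted W_ap input
    g_prep_motor: float = 3.0
    g_motor_prep: float = 2.5           # topological motor feedback
    c_motor_prep: float = 0.06          # global feedback suppression (per deg)
    go_amp: float = 3.5                 # uniform motor disinhibition when on

    # plastic projections
    w_ca_init: float = 0.05             # upper bound of uniform W_ca init
    w_ap_amp: float = 1.0               # initial topological W_ap amplitude
    w_ap_width: float = 10.0            # its wrapped-Gaussian width (deg)
    w_max: float = 1.5                  # hard weight bound, both projections

    def __post_init__(self):
        if len(self.context_rotations) != self.n_contexts:
            raise ValueError("need one rotation per context node")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    # convenience constructors -------------------------------------------
    def spatial_lattice(self) -> FeatureLattice:
        return FeatureLattice.direction_circle(self.n_spatial)

    def assoc_lattice(self) -> FeatureLattice:
        return FeatureLattice(
            extents=(360.0, self.ctx_extent),
            shape=(self.n_spatial, self.n_ctx_samples),
            circular=(True, self.ctx_circular),
        )

    def with_contexts(self, rotations: tuple[float, ...],
                      scale_context_dim: bool = True) -> "ModelConfig":
        """Configuration for a different set of mapping rules.

        By default the context dimension grows in proportion to the number
        of contexts, keeping per-context territory constant -- the analogue
        of recruiting more neurons for a harder association task.
        """
        new = replace(self, n_contexts=len(rotations),
                      context_rotations=tuple(float(r) for r in rotations))
        if scale_context_dim and len(rotations) != self.n_contexts:
            per_ctx = self.ctx_extent / self.n_contexts
            extent = per_ctx * len(rotations)
            samples = int(round(self.n_ctx_samples *
                                len(rotations) / self.n_contexts))
            new = replace(new, ctx_extent=extent, n_ctx_samples=samples)
        return new

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "context_rotations" in d:
            d["context_rotations"] = tuple(d["context_rotations"])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model config keys: {sorted(unknown)}")
        return cls(**d)


# --------------------------------------------------------------------------
# Projections
# --------------------------------------------------------------------------

def _normalized_blur(lattice: FeatureLattice, width: float) -> np.ndarray:
    """Circular Gaussian blur matrix normalized so that a saturated localized
    peak (f ~ 1 over a few kernel widths) maps to ~1 at its center."""
    from .dnf_core import _offset_matrix, _gauss
    off = _offset_matrix(lattice, 0)
    m = _gauss(off, width)
    dx = lattice.spacing(0)
    return m * (dx / (width * np.sqrt(2.0 * np.pi)))


@dataclass
class TopologicalProjection:
    """Fixed, topologically organized projection between 1-D fields (or from
    a 1-D field into the spatial dimension of the 2-D association field, in
    which case the input is a ridge, homogeneous along the context axis)."""

    gain: float
    blur: np.ndarray  # (n_target x n_source) normalized matrix
    ridge: bool = False

    def __call__(self, f_source: np.ndarray) -> np.ndarray:
        v = self.gain * (self.blur @ f_source)
        return v[:, None] if self.ridge else v


@dataclass
class PlasticProjection:
    """A learnable weight matrix with hard bounds [0, w_max].

    ``W`` has shape (n_source_samples, n_target_samples); the delivered input
    is ``gain * volume * (f_source @ W)`` where ``volume`` is the source
    lattice's sample volume (integral weighting).
    """

    W: np.ndarray
    gain: float
    volume: float
    w_max: float

    def __call__(self, f_source: np.ndarray) -> np.ndarray:
        return (self.gain * self.volume) * (f_source @ self.W)

    def clip(self) -> None:
        np.clip(self.W, 0.0, self.w_max, out=self.W)


# --------------------------------------------------------------------------
# Model state
# --------------------------------------------------------------------------

@dataclass
class Stimuli:
    """External input specification for one time step."""

    cue_dir: Optional[float] = None       # spatial cue direction (deg)
    cue_salience: float = 1.0             # scales the spatial-cue amplitude
    target_dir: Optional[float] = None    # IR target cue direction (deg)
    target_salience: float = 0.0
    context: Optional[int] = None         # index of the cued context node
    go: bool = False


@dataclass
class ModelState:
    config: ModelConfig
    spatial: FieldState
    ctx: NodeGroup
    assoc: FieldState
    prep: FieldState
    motor: FieldState
    ctx_assoc: PlasticProjection          # W_ca: (n_contexts, n_assoc_flat)
    assoc_prep: PlasticProjection         # W_ap: (n_assoc_flat, n_spatial)
    blur_sp: np.ndarray                   # shared topological blur matrix
    go: bool = False
    engine_cache: Optional[dict] = None   # compiled-path matrices (lazy)

    def directions(self) -> np.ndarray:
        return self.spatial.lattice.coords(0)

    def assoc_output_flat(self) -> np.ndarray:
        return self.assoc.output().ravel()

    def weight_difference_map(self) -> np.ndarray:
        """Fig-3-style diagnostic: per association-field site, the difference
        between the incoming weight from the last ('inferred') and the first
        ('direct') context node (2-contexts) or max-minus-direct otherwise."""
        W = self.ctx_assoc.W
        shape = self.assoc.lattice.shape
        if W.shape[0] == 2:
            return (W[1] - W[0]).reshape(shape)
        return (W[1:].max(axis=0) - W[0]).reshape(shape)

    def index_shift_map(self) -> np.ndarray:
        """Per association-field site, the circular difference (deg) between
        the direction its outgoing weights target most strongly and its own
        spatial position (0 for the initial topological map)."""
        dirs = self.directions()
        tgt = dirs[np.argmax(self.assoc_prep.W, axis=1)]
        own = np.repeat(dirs, self.config.n_ctx_samples)
        shift = np.mod(tgt - own, 360.0)
        return shift.reshape(self.assoc.lattice.shape)


class RegimeError(ValueError):
    """A field's parameters fail its required dynamic-regime gate."""


# --------------------------------------------------------------------------
# Construction
# --------------------------------------------------------------------------

def _field(lat, tau, h, q, beta, kernel) -> FieldState:
    return FieldState.at_rest(lat, FieldParams(tau=tau, h=h, q=q, beta=beta),
                              kernel)


def build_fields(cfg: ModelConfig) -> tuple:
    lat1 = cfg.spatial_lattice()
    lat2 = cfg.assoc_lattice()
    spatial = _field(lat1, cfg.spatial_tau, cfg.spatial_h, cfg.spatial_q,
                     cfg.spatial_beta,
                     InteractionKernel(exc_amp=cfg.spatial_kexc,
                                       exc_width=(cfg.spatial_kexc_width,),
                                       global_inh=cfg.spatial_kglob))
    assoc = _field(lat2, cfg.assoc_tau, cfg.assoc_h, cfg.assoc_q,
                   cfg.assoc_beta,
                   InteractionKernel(
                       exc_amp=cfg.assoc_kexc,
                       exc_width=(cfg.assoc_kexc_width_sp,
                                  cfg.assoc_kexc_width_ctx),
                       global_inh=cfg.assoc_kglob,
                       boundary_norm=cfg.assoc_boundary_norm))
    prep = _field(lat1, cfg.prep_tau, cfg.prep_h, cfg.prep_q, cfg.prep_beta,
                  InteractionKernel(exc_amp=cfg.prep_kexc,
                                    exc_width=(cfg.prep_kexc_width,),
                                    global_inh=cfg.prep_kglob))
    motor = _field(lat1, cfg.motor_tau, cfg.motor_h, cfg.motor_q,
                   cfg.motor_beta,
                   InteractionKernel(exc_amp=cfg.motor_kexc,
                                     exc_width=(cfg.motor_kexc_width,),
                                     global_inh=cfg.motor_kglob))
    ctx = NodeGroup.at_rest(
        cfg.n_contexts,
        FieldParams(tau=cfg.node_tau, h=cfg.node_h, q=cfg.node_q,
                    beta=cfg.node_beta),
        w_self=cfg.node_self, w_inh=cfg.node_inh)
    return spatial, ctx, assoc, prep, motor


def init_model(cfg: ModelConfig, rng: np.random.Generator,
               validate: bool = True) -> ModelState:
    """Build a model at rest with pre-learning weights.

    W_ca starts as small i.i.d. uniform values (no spatial structure); W_ap
    starts as a wrapped-Gaussian topological map along the spatial dimension
    (index shift 0 degrees for every association-field column).
    """
    if validate:
        validate_regimes(cfg)
    spatial, ctx, assoc, prep, motor = build_fields(cfg)
    n_flat = cfg.n_spatial * cfg.n_ctx_samples
    vol_a = assoc.lattice.spacing(0) * assoc.lattice.spacing(1)

    W_ca = rng.uniform(0.0, cfg.w_ca_init, size=(cfg.n_contexts, n_flat))
    ctx_assoc = PlasticProjection(W=W_ca, gain=cfg.g_ctx_assoc, volume=1.0,
                                  w_max=cfg.w_max)

    dirs = spatial.lattice.coords(0)
    d = circular_distance(dirs[:, None], dirs[None, :])
    topo = cfg.w_ap_amp * np.exp(-0.5 * (d / cfg.w_ap_width) ** 2)
    W_ap = np.repeat(topo, cfg.n_ctx_samples, axis=0).astype(float).copy()
    assoc_prep = PlasticProjection(W=W_ap, gain=cfg.g_assoc_prep,
                                   volume=vol_a, w_max=cfg.w_max)

    blur = _normalized_blur(spatial.lattice, cfg.proj_width)
    return ModelState(config=cfg, spatial=spatial, ctx=ctx, assoc=assoc,
                      prep=prep, motor=motor, ctx_assoc=ctx_assoc,
                      assoc_prep=assoc_prep, blur_sp=blur)


# --------------------------------------------------------------------------
# Stepping
# --------------------------------------------------------------------------

def external_spatial_input(model: ModelState, stim: Stimuli) -> np.ndarray:
    cfg = model.config
    lat = model.spatial.lattice
    s = np.zeros(lat.shape)
    if stim.cue_dir is not None and stim.cue_salience > 0:
        s += gaussian_input(lat, stim.cue_dir, cfg.stim_amp *
                            stim.cue_salience, cfg.stim_width)
    if stim.target_dir is not None and stim.target_salience > 0:
        s += gaussian_input(lat, stim.target_dir, cfg.stim_amp *
                            stim.target_salience, cfg.stim_width)
    return s


def motor_feedback(model: ModelState,
                   f_m: Optional[np.ndarray] = None) -> np.ndarray:
    """Input the motor field sends back to the preparation field: topological
    excitation at the selected direction plus global suppression, so the
    selected plan is reinforced and alternatives are quenched."""
    cfg = model.config
    if f_m is None:
        f_m = model.motor.output()
    dx = model.motor.lattice.spacing(0)
    return (cfg.g_motor_prep * (model.blur_sp @ f_m)
            - cfg.c_motor_prep * dx * f_m.sum())


def step_model(model: ModelState, stim: Stimuli, dt: float,
               rng: Optional[np.random.Generator] = None) -> ModelState:
    """One synchronous update: every field's input is computed from the
    previous step's outputs, then all fields step together."""
    cfg = model.config

    f_sp = model.spatial.output()
    f_ctx = model.ctx.output()
    f_as = model.assoc.output()
    f_pr = model.prep.output()
    f_mo = model.motor.output()

    # -- inputs -----------------------------------------------------------
    s_spatial = external_spatial_input(model, stim)

    s_nodes = np.zeros(cfg.n_contexts)
    if stim.context is not None:
        s_nodes[stim.context] = cfg.ctx_stim_amp

    ridge = cfg.g_spatial_assoc * (model.blur_sp @ f_sp)
    s_assoc = np.broadcast_to(ridge[:, None], f_as.shape).copy()
    s_assoc += model.ctx_assoc(f_ctx).reshape(f_as.shape)

    s_prep = cfg.g_spatial_prep * (model.blur_sp @ f_sp)
    s_prep = s_prep + model.assoc_prep(f_as.ravel())
    s_prep = s_prep + motor_feedback(model, f_mo)

    s_motor = cfg.g_prep_motor * (model.blur_sp @ f_pr)
    if model.go or stim.go:
        s_motor = s_motor + cfg.go_amp

    # -- synchronous step -------------------------------------------------
    field_step(model.spatial, s_spatial, dt, rng, out=f_sp)
    node_step(model.ctx, s_nodes, dt, rng)
    field_step(model.assoc, s_assoc, dt, rng, out=f_as)
    field_step(model.prep, s_prep, dt, rng, out=f_pr)
    field_step(model.motor, s_motor, dt, rng, out=f_mo)
    return model


def set_go_gate(model: ModelState, on: bool) -> ModelState:
    """Latch the go signal: while off the motor field rests too low to form a
    peak from preparation input; when on it is uniformly disinhibited."""
    model.go = bool(on)
    return model


# --------------------------------------------------------------------------
# Regime gates
# --------------------------------------------------------------------------

def _settle(field: FieldState, s, steps: int, dt: float) -> None:
    for _ in range(steps):
        field_step(field, s, dt, None)


_VALIDATED: set = set()


def validate_regimes(cfg: ModelConfig) -> None:
    """Noise-free checks that each component operates in its required
    dynamic regime; raises RegimeError naming the failed gate."""
    key = tuple(sorted((k, str(v)) for k, v in cfg.to_dict().items()))
    if key in _VALIDATED:
        return
    dt = cfg.dt
    spatial, ctx, assoc, prep, motor = build_fields(cfg)
    lat1 = spatial.lattice

    # gate: spatial field is input-driven
    s = gaussian_input(lat1, 90.0, cfg.stim_amp, cfg.stim_width)
    _settle(spatial, s, int(100 / dt), dt)
    if spatial.output().max() < 0.8:
        raise RegimeError("spatial-field gate: cue input does not drive a peak")
    _settle(spatial, np.zeros(lat1.shape), int(150 / dt), dt)
    if spatial.output().max() > 0.1:
        raise RegimeError("spatial-field gate: peak fails to decay "
                          "(field is not input-driven)")

    # gate: context nodes latch
    s_on = np.zeros(cfg.n_contexts); s_on[0] = cfg.ctx_stim_amp
    for _ in range(int(100 / dt)):
        node_step(ctx, s_on, dt, None)
    for _ in range(int(300 / dt)):
        node_step(ctx, np.zeros(cfg.n_contexts), dt, None)
    f = ctx.output()
    if f[0] < 0.5:
        raise RegimeError("context-node gate: activated node does not latch")
    if cfg.n_contexts > 1 and f[1:].max() > 0.1:
        raise RegimeError("context-node gate: latched node fails to suppress "
                          "the others")

    # gate: association field sustains a single peak (memory + selection)
    lat2 = assoc.lattice
    ridge = gaussian_input(lat1, 90.0, cfg.g_spatial_assoc, cfg.proj_width)
    s2 = np.broadcast_to(ridge[:, None], lat2.shape).copy()
    yc = lat2.coords(1)
    bias = 0.3 * np.exp(-0.5 * ((yc - yc[len(yc) // 2])
                                / cfg.assoc_kexc_width_ctx) ** 2)
    s2 += bias[None, :]
    _settle(assoc, s2, int(150 / dt), dt)
    if assoc.output().max() < 0.8:
        raise RegimeError("association-field gate: ridge input does not "
                          "ignite a peak")
    _settle(assoc, np.zeros(lat2.shape), int(300 / dt), dt)
    f2 = assoc.output()
    if f2.max() < 0.8:
        raise RegimeError("association-field gate: peak is not self-sustained "
                          "(no memory regime)")
    # localized in both dimensions, and unique
    act_cols = np.where(f2.max(axis=1) > 0.5)[0]
    act_rows = np.where(f2.max(axis=0) > 0.5)[0]
    if len(act_cols) > cfg.n_spatial // 3 or len(act_rows) > (
            2 * cfg.n_ctx_samples) // 3:
        raise RegimeError("association-field gate: sustained activation is "
                          "not localized")

    # gate: association field selects one peak from two equal inputs
    spatial2, _, assoc_b, _, _ = build_fields(cfg)
    r2 = (gaussian_input(lat1, 0.0, cfg.g_spatial_assoc, cfg.proj_width)
          + gaussian_input(lat1, 180.0, cfg.g_spatial_assoc, cfg.proj_width))
    s2b = np.broadcast_to(r2[:, None], lat2.shape).copy()
    s2b += 1e-3 * np.cos(np.deg2rad(lat2.coords(0)))[:, None]  # tiny tilt
    _settle(assoc_b, s2b, int(200 / dt), dt)
    fb = assoc_b.output()
    on0 = fb[lat2.index_of(0.0), :].max() > 0.5
    on180 = fb[lat2.index_of(180.0), :].max() > 0.5
    if on0 and on180:
        raise RegimeError("association-field gate: two peaks coexist "
                          "(no selection regime)")

    # gate: preparation field is input-driven (memory support is exogenous)
    sp = gaussian_input(lat1, 90.0, cfg.g_spatial_prep, cfg.stim_width)
    _settle(prep, sp, int(100 / dt), dt)
    if prep.output().max() < 0.5:
        raise RegimeError("preparation-field gate: projection input does not "
                          "drive a peak")
    _settle(prep, np.zeros(lat1.shape), int(150 / dt), dt)
    if prep.output().max() > 0.1:
        raise RegimeError("preparation-field gate: peak fails to decay "
                          "(field is not input-driven)")

    # gate: motor field is silent until go, then winner-take-all.  The drive
    # level mirrors operation: preparation output is graded, so competing
    # motor inputs arrive at a fraction of the nominal projection gain.
    drive = 0.6 * cfg.g_prep_motor
    sm = (gaussian_input(lat1, 0.0, drive, cfg.stim_width)
          + gaussian_input(lat1, 180.0, drive, cfg.stim_width))
    _settle(motor, sm, int(200 / dt), dt)
    if motor.output().max() > 0.1:
        raise RegimeError("motor-field gate: peak forms before the go signal")
    sm_go = sm + cfg.go_amp
    sm_go = sm_go + 1e-3 * np.cos(np.deg2rad(lat1.coords(0)))
    _settle(motor, sm_go, int(200 / dt), dt)
    fm = motor.output()
    n0 = fm[lat1.index_of(0.0)] > 0.5
    n180 = fm[lat1.index_of(180.0)] > 0.5
    if not (n0 or n180):
        raise RegimeError("motor-field gate: go signal does not allow a peak")
    if n0 and n180:
        raise RegimeError("motor-field gate: two peaks survive "
                          "(no winner-take-all)")
    # a single weak (memory-driven) preparation peak must still ignite
    _, _, _, _, motor_b = build_fields(cfg)
    s1 = gaussian_input(lat1, 90.0, 0.45 * cfg.g_prep_motor,
                        cfg.stim_width) + cfg.go_amp
    _settle(motor_b, s1, int(200 / dt), dt)
    if motor_b.output().max() < 0.5:
        raise RegimeError("motor-field gate: weak single peak fails to "
                          "ignite after go")

    _VALIDATED.add(key)
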