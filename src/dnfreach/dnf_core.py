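"""Amari-type dynamic neural fields on discrete feature lattices.

A dynamic neural field (DNF) describes the activation u(x, t) of a neural
population over a continuous feature dimension (here: reach/cue direction in
degrees, and an abstract context dimension).  The activation evolves under a
leaky integrator with lateral interactions,

    tau * du/dt = -u + h + s(x, t) + [k * f(u)](x) + noise,

where h < 0 is the resting level, s is the external input, k is an
interaction kernel with local excitation and longer-range (or global)
inhibition, and f is a logistic output nonlinearity with soft threshold at
zero.  Depending on the interaction strengths the field operates in an
input-driven regime (peaks decay once input is removed), a memory regime
(self-sustained peaks), or a selection regime (global inhibition lets only a
single peak survive).

Fields are sampled on uniform lattices; convolution with the kernel is
applied with integral (grid-spacing) weighting so the dynamic regime is
approximately invariant under resampling.  Integration is explicit Euler with
additive Gaussian noise scaled by sqrt(dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FeatureLattice",
    "FieldParams",
    "InteractionKernel",
    "SampledKernel",
    "FieldState",
    "NodeGroup",
    "sigmoid_output",
    "build_kernel",
    "lateral_input",
    "field_step",
    "node_step",
    "circular_distance",
]


# --------------------------------------------------------------------------
# Lattices
# --------------------------------------------------------------------------

def circular_distance(a, b, period: float = 360.0):
    """Shortest angular distance between directions ``a`` and ``b`` (degrees)."""
    d = np.mod(np.asarray(a) - np.asarray(b), period)
    return np.minimum(d, period - d)


@dataclass(frozen=True)
class FeatureLattice:
    """Uniformly sampled feature space of one or two dimensions.

    ``extents[d]`` is the total length of dimension ``d`` (360 degrees for the
    circular direction dimension; abstract units for the context dimension),
    ``shape[d]`` the number of samples, and ``circular[d]`` whether the
    dimension wraps.
    """

    extents: tuple[float, ...]
    shape: tuple[int, ...]
    circular: tuple[bool, ...]

    def __post_init__(self):
        if not (1 <= len(self.shape) <= 2):
            raise ValueError("only 1-D and 2-D lattices are supported")
        if not (len(self.extents) == len(self.shape) == len(self.circular)):
            raise ValueError("per-dimension field lengths disagree")
        if any(n < 2 for n in self.shape):
            raise ValueError("need at least 2 samples per dimension")
        if any(e <= 0 for e in self.extents):
            raise ValueError("extents must be positive")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def spacing(self, dim: int = 0) -> float:
        """Sample spacing along ``dim`` (extent / n for circular, extent/(n-1)
        for bounded dimensions, so bounded samples include both ends)."""
        n, e = self.shape[dim], self.extents[dim]
        return e / n if self.circular[dim] else e / (n - 1)

    def coords(self, dim: int = 0) -> np.ndarray:
        """Sample positions along ``dim`` (circular: [0, extent))."""
        return np.arange(self.shape[dim]) * self.spacing(dim)

    def index_of(self, position: float, dim: int = 0) -> int:
        """Nearest lattice index to a position along ``dim``."""
        n = self.shape[dim]
        i = int(round(position / self.spacing(dim)))
        if self.circular[dim]:
            return i % n
        return min(max(i, 0), n - 1)

    @classmethod
    def direction_circle(cls, n: int = 72) -> "FeatureLattice":
        """The canonical 1-D circular direction lattice (extent 360 degrees)."""
        return cls(extents=(360.0,), shape=(n,), circular=(True,))


# --------------------------------------------------------------------------
# Parameters and kernels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldParams:
    """Leaky-integrator parameters of one field.

    tau   -- time constant (model time units), > 0
    h     -- global resting level (activation units), < 0
    q     -- additive noise amplitude per sqrt(time unit), >= 0
    beta  -- steepness of the logistic output, > 0 (threshold fixed at 0)
    """

    tau: float
    h: float
    q: float
    beta: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("time constant tau must be positive")
        if self.h >= 0:
            raise ValueError("resting level h must be negative")
        if self.q < 0:
            raise ValueError("noise amplitude q must be non-negative")
        if self.beta <= 0:
            raise ValueError("sigmoid steepness beta must be positive")


@dataclass(frozen=True)
class InteractionKernel:
    """Lateral-interaction profile: local Gaussian excitation minus either a
    surround Gaussian or a global (offset-independent) inhibition constant.

    For 2-D fields the local components are separable products of
    per-dimension Gaussian profiles; ``exc_width``/``inh_width`` then hold one
    width per dimension.  Amplitudes are densities per unit feature volume
    (the convolution is grid-spacing weighted).
    """

    exc_amp: float
    exc_width: tuple[float, ...]
    inh_amp: float = 0.0
    inh_width: tuple[float, ...] = ()
    global_inh: float = 0.0
    boundary_norm: float = 0.5  # border-support renormalization exponent
                                # for bounded dimensions (see _dim_matrix)

    def __post_init__(self):
        if self.exc_amp < 0 or self.inh_amp < 0 or self.global_inh < 0:
            raise ValueError("kernel amplitudes must be non-negative")
        if self.exc_amp > 0 and any(w <= 0 for w in self.exc_width):
            raise ValueError("excitatory widths must be positive")
        if self.inh_amp > 0:
            if not self.inh_width or any(w <= 0 for w in self.inh_width):
                raise ValueError("inhibitory widths must be positive")
            if any(wi <= we for we, wi in zip(self.exc_width, self.inh_width)):
                raise ValueError(
                    "local inhibition must be wider than excitation")


def _gauss(d: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (d / sigma) ** 2)


def _offset_matrix(lattice: FeatureLattice, dim: int) -> np.ndarray:
    """|offset| between every pair of samples along one dimension."""
    x = lattice.coords(dim)
    d = np.abs(x[:, None] - x[None, :])
    if lattice.circular[dim]:
        d = np.minimum(d, lattice.extents[dim] - d)
    return d


def _dim_matrix(lattice: FeatureLattice, dim: int, sigma: float,
                boundary_norm: float = 0.5) -> np.ndarray:
    """Spacing-weighted Gaussian interaction matrix along one dimension.

    Circular dimensions use the wrapped distance.  On bounded dimensions the
    kernel is truncated at the borders, which leaves border sites with less
    recurrent support; rows are then renormalized toward the infinite-line
    kernel mass with exponent ``boundary_norm``.  0 keeps the full border
    penalty (boundaries repel activation peaks), 1 removes it entirely
    (boundaries attract, because support concentrates on fewer neighbors);
    intermediate values leave a mild penalty, so peaks forming without
    localized input settle away from the borders but localized drive can
    still place a peak there.
    """
    x = lattice.coords(dim)
    dx = lattice.spacing(dim)
    if lattice.circular[dim]:
        d = np.abs(x[:, None] - x[None, :])
        d = np.minimum(d, lattice.extents[dim] - d)
        return _gauss(d, sigma) * dx
    m = _gauss(np.abs(x[:, None] - x[None, :]), sigma) * dx
    target = sigma * np.sqrt(2.0 * np.pi)
    m *= (target / m.sum(axis=1, keepdims=True)) ** boundary_norm
    return m


@dataclass
class SampledKernel:
    """Kernel sampled on a lattice, stored as per-dimension interaction
    matrices so the lateral input reduces to small dense matrix products."""

    lattice: FeatureLattice
    params: InteractionKernel
    exc_mats: list  # per-dim (n_d x n_d) matrices, spacing-weighted
    inh_mats: Optional[list]
    global_inh: float  # spacing-weighted global constant

    def as_array(self) -> np.ndarray:
        """Dense kernel k(offset) sampled at all pairwise offsets relative to
        sample 0 (without spacing weights), mainly for inspection and tests."""
        p = self.params
        prof_e = np.ones(self.lattice.shape)
        prof_i = np.ones(self.lattice.shape)
        for d in range(self.lattice.ndim):
            off = _offset_matrix(self.lattice, d)[0]
            shape = [1] * self.lattice.ndim
            shape[d] = -1
            prof_e = prof_e * _gauss(off, p.exc_width[d]).reshape(shape)
            if p.inh_amp > 0:
                prof_i = prof_i * _gauss(off, p.inh_width[d]).reshape(shape)
        k = p.exc_amp * prof_e - p.global_inh
        if p.inh_amp > 0:
            k = k - p.inh_amp * prof_i
        return k


def build_kernel(lattice: FeatureLattice,
                 params: InteractionKernel) -> SampledKernel:
    """Sample an interaction kernel on a lattice.

    Raises if a local component is wider than a bounded dimension's extent
    (the surround would be truncated into something qualitatively different).
    """
    widths = list(params.exc_width)
    if params.inh_amp > 0:
        widths += list(params.inh_width)
    for d in range(lattice.ndim):
        if not lattice.circular[d]:
            for w_tuple in (params.exc_width,
                            params.inh_width if params.inh_amp > 0 else ()):
                if w_tuple and w_tuple[d] >= lattice.extents[d]:
                    raise ValueError(
                        f"kernel width {w_tuple[d]} exceeds bounded extent "
                        f"{lattice.extents[d]} on dimension {d}")

    vol = 1.0
    exc_mats, inh_mats = [], []
    for d in range(lattice.ndim):
        dx = lattice.spacing(d)
        vol *= dx
        exc_mats.append(
            _dim_matrix(lattice, d, params.exc_width[d],
                        params.boundary_norm)
            if params.exc_amp > 0
            else np.zeros((lattice.shape[d], lattice.shape[d])))
        if params.inh_amp > 0:
            inh_mats.append(_dim_matrix(lattice, d, params.inh_width[d],
                                        params.boundary_norm))
    return SampledKernel(
        lattice=lattice,
        params=params,
        exc_mats=exc_mats,
        inh_mats=inh_mats if params.inh_amp > 0 else None,
        global_inh=params.global_inh * vol,
    )


# --------------------------------------------------------------------------
# Field and node state
# --------------------------------------------------------------------------

@dataclass
class FieldState:
    """One DNF: lattice, parameters, kernel, and the current activation."""

    lattice: FeatureLattice
    params: FieldParams
    kernel: SampledKernel
    u: np.ndarray
    s: np.ndarray

    @classmethod
    def at_rest(cls, lattice: FeatureLattice, params: FieldParams,
                kernel_params: InteractionKernel) -> "FieldState":
        u = np.full(lattice.shape, params.h, dtype=float)
        return cls(lattice=lattice, params=params,
                   kernel=build_kernel(lattice, kernel_params),
                   u=u, s=np.zeros(lattice.shape))

    def output(self) -> np.ndarray:
        return _sigmoid(self.u, self.params.beta)


@dataclass
class NodeGroup:
    """Discrete dynamic nodes with self-excitation and mutual inhibition.

    A node driven above threshold latches (stays active after input removal)
    and suppresses the others -- a discrete analogue of the selection regime.
    """

    params: FieldParams
    w_self: float
    w_inh: float
    u: np.ndarray

    @classmethod
    def at_rest(cls, n: int, params: FieldParams, w_self: float,
                w_inh: float) -> "NodeGroup":
        return cls(params=params, w_self=w_self, w_inh=w_inh,
                   u=np.full(n, params.h, dtype=float))

    @property
    def n(self) -> int:
        return self.u.shape[0]

    def output(self) -> np.ndarray:
        return _sigmoid(self.u, self.params.beta)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def _sigmoid(u: np.ndarray, beta: float) -> np.ndarray:
    """Fast logistic without validation (hot path: called every step)."""
    x = u * (-beta)
    np.clip(x, -60.0, 60.0, out=x)
    np.exp(x, out=x)
    x += 1.0
    np.reciprocal(x, out=x)
    return x


def sigmoid_output(u: np.ndarray, beta: float) -> np.ndarray:
    """Logistic output f(u) = 1 / (1 + exp(-beta u)), elementwise in (0, 1)."""
    if beta <= 0:
        raise ValueError("sigmoid steepness beta must be positive")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite activation values")
    # Numerically stable two-branch evaluation.
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-beta * u[pos]))
    eu = np.exp(beta * u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def lateral_input(state: FieldState, out: Optional[np.ndarray] = None
                  ) -> np.ndarray:
    """Convolution of the field output with the interaction kernel.

    Circular dimensions use wrapped offsets; bounded dimensions truncate at
    the borders (zero padding).  For 2-D fields the local components are
    applied separably.
    """
    f = state.output() if out is None else out
    if f.shape != tuple(state.lattice.shape):
        raise ValueError("output shape does not match lattice")
    k = state.kernel
    p = k.params
    lat = None
    if p.exc_amp > 0:
        lat = k.exc_mats[0] @ f if state.lattice.ndim == 1 else \
            k.exc_mats[0] @ f @ k.exc_mats[1].T
        if p.exc_amp != 1.0:
            lat *= p.exc_amp
    if k.inh_mats is not None:
        inh = k.inh_mats[0] @ f if state.lattice.ndim == 1 else \
            k.inh_mats[0] @ f @ k.inh_mats[1].T
        inh *= p.inh_amp
        lat = -inh if lat is None else np.subtract(lat, inh, out=lat)
    if lat is None:
        lat = np.zeros_like(f)
    if k.global_inh:
        lat -= k.global_inh * f.sum()
    return lat


def field_step(state: FieldState, s: np.ndarray, dt: float,
               rng: Optional[np.random.Generator] = None,
               out: Optional[np.ndarray] = None) -> FieldState:
    """One explicit-Euler step of the field equation (in place).

    du = (dt/tau) * (-u + h + s + lateral) + q * sqrt(dt) * xi,
    with xi i.i.d. standard normal per sample, so the injected noise variance
    per unit time is independent of the step size.  ``out`` may pass the
    pre-computed sigmoid output of the current state (synchronous updates
    compute every field's output once before stepping).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(s, dtype=float)
    if s.shape != state.u.shape:
        raise ValueError("input shape does not match field")
    p = state.params
    lat = lateral_input(state, out=out)
    # in-place: du = (dt/tau) * (-u + h + s + lat) reusing the lat buffer
    lat += s
    lat += p.h
    lat -= state.u
    lat *= dt / p.tau
    if p.q > 0 and rng is not None:
        lat += (p.q * np.sqrt(dt)) * rng.standard_normal(state.u.shape)
    state.u += lat
    state.s = s
    return state


def node_step(nodes: NodeGroup, inputs: np.ndarray, dt: float,
              rng: Optional[np.random.Generator] = None) -> NodeGroup:
    """Euler step for a node group; interaction matrix has the
    self-excitation on the diagonal and -mutual_inhibition off it."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape != nodes.u.shape:
        raise ValueError("input shape does not match node group")
    p = nodes.params
    f = nodes.output()
    lat = nodes.w_self * f - nodes.w_inh * (f.sum() - f)
    du = (dt / p.tau) * (-nodes.u + p.h + inputs + lat)
    if p.q > 0 and rng is not None:
        du += p.q * np.sqrt(dt) * rng.standard_normal(nodes.u.shape)
    nodes.u += du
    return nodes


def gaussian_input(lattice: FeatureLattice, center: float, amplitude: float,
                   width: float, dim: int = 0) -> np.ndarray:
    """Localized (wrapped) Gaussian stimulus profile along one dimension."""
    x = lattice.coords(dim)
    if lattice.circular[dim]:
        d = circular_distance(x, center, lattice.extents[dim])
    else:
        d = np.abs(x - center)
    return amplitude * _gauss(d, width)
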