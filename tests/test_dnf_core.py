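import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnfreach.dnf_core import (
    FeatureLattice,
    FieldParams,
    FieldState,
    InteractionKernel,
    NodeGroup,
    build_kernel,
    circular_distance,
    field_step,
    gaussian_input,
    lateral_input,
    node_step,
    sigmoid_output,
)


# --------------------------------------------------------------------------
# sigmoid output
# --------------------------------------------------------------------------

def test_sigmoid_threshold_and_saturation():
    assert sigmoid_output(np.array([0.0]), beta=2.0)[0] == pytest.approx(0.5)
    assert sigmoid_output(np.array([200.0]), beta=4.0)[0] == pytest.approx(1.0)
    assert sigmoid_output(np.array([-200.0]), beta=4.0)[0] == pytest.approx(0.0)


def test_sigmoid_matches_scalar_logistic_elementwise():
    u = np.array([-1.0, 0.0, 1.0])
    out = sigmoid_output(u, beta=4.0)
    for ui, oi in zip(u, out):
        assert oi == pytest.approx(1.0 / (1.0 + math.exp(-4.0 * ui)),
                                   abs=1e-12)


@given(st.lists(st.floats(-40, 40), min_size=1, max_size=50),
       st.floats(0.1, 10.0))
@settings(max_examples=50, deadline=None)
def test_sigmoid_bounds_and_monotonicity(values, beta):
    u = np.sort(np.array(values))
    out = sigmoid_output(u, beta)
    assert np.all((out >= 0.0) & (out <= 1.0))
    interior = np.abs(beta * u) < 30  # saturation underflows in float64
    assert np.all((out[interior] > 0.0) & (out[interior] < 1.0))
    assert np.all(np.diff(out) >= -1e-15)


def test_sigmoid_rejects_bad_inputs():
    with pytest.raises(ValueError):
        sigmoid_output(np.array([np.nan]), beta=1.0)
    with pytest.raises(ValueError):
        sigmoid_output(np.array([0.0]), beta=0.0)


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

def test_zero_amplitude_kernel_gives_zero_lateral_input():
    lat = FeatureLattice.direction_circle(12)
    k = InteractionKernel(exc_amp=0.0, exc_width=(10.0,))
    state = FieldState.at_rest(lat, FieldParams(10, -2, 0, 2), k)
    state.u[:] = 1.0
    assert np.allclose(lateral_input(state), 0.0)


def test_global_inhibition_is_offset_independent():
    lat = FeatureLattice.direction_circle(12)
    k = build_kernel(lat, InteractionKernel(exc_amp=0.0, exc_width=(10.0,),
                                            global_inh=0.7))
    arr = k.as_array()
    assert np.allclose(arr, -0.7)


def test_circular_kernel_uses_wrapped_distance():
    lat = FeatureLattice.direction_circle(36)  # 10-degree spacing
    k = build_kernel(lat, InteractionKernel(exc_amp=1.0, exc_width=(15.0,)))
    arr = k.as_array()
    # offset between 350 and 10 degrees is 20 degrees
    i350, i10 = lat.index_of(350.0), lat.index_of(10.0)
    i20 = lat.index_of(20.0)
    assert k.exc_mats[0][i350, i10] == pytest.approx(
        k.exc_mats[0][0, i20], abs=1e-12)
    assert arr[i20] == pytest.approx(np.exp(-0.5 * (20.0 / 15.0) ** 2),
                                     abs=1e-12)


def test_kernel_wider_than_bounded_extent_is_rejected():
    lat = FeatureLattice(extents=(10.0,), shape=(10,), circular=(False,))
    with pytest.raises(ValueError, match="exceeds bounded extent"):
        build_kernel(lat, InteractionKernel(exc_amp=1.0, exc_width=(12.0,)))


def test_inhibition_must_be_wider_than_excitation():
    with pytest.raises(ValueError):
        InteractionKernel(exc_amp=1.0, exc_width=(10.0,), inh_amp=0.5,
                          inh_width=(8.0,))


# --------------------------------------------------------------------------
# lateral input: O(N^2) oracle
# --------------------------------------------------------------------------

def _brute_force_lateral_1d(lat, params, f):
    n = lat.shape[0]
    dx = lat.spacing(0)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            d = circular_distance(lat.coords(0)[i], lat.coords(0)[j])
            k = params.exc_amp * np.exp(-0.5 * (d / params.exc_width[0]) ** 2)
            if params.inh_amp > 0:
                k -= params.inh_amp * np.exp(
                    -0.5 * (d / params.inh_width[0]) ** 2)
            out[i] += k * f[j] * dx
        out[i] -= params.global_inh * dx * f.sum()
    return out


def test_lateral_input_matches_brute_force_1d():
    lat = FeatureLattice.direction_circle(12)
    params = InteractionKernel(exc_amp=1.3, exc_width=(25.0,), inh_amp=0.4,
                               inh_width=(60.0,), global_inh=0.05)
    state = FieldState.at_rest(lat, FieldParams(10, -2, 0, 2), params)
    rng = np.random.default_rng(3)
    state.u[:] = rng.normal(0, 1, lat.shape)
    f = state.output()
    expected = _brute_force_lateral_1d(lat, params, f)
    assert np.max(np.abs(lateral_input(state) - expected)) < 1e-10


def test_lateral_input_matches_brute_force_2d_circular():
    lat = FeatureLattice(extents=(360.0, 8.0), shape=(8, 4),
                         circular=(True, True))
    params = InteractionKernel(exc_amp=0.9, exc_width=(60.0, 2.0),
                               global_inh=0.02)
    state = FieldState.at_rest(lat, FieldParams(10, -2, 0, 2), params)
    rng = np.random.default_rng(5)
    state.u[:] = rng.normal(0, 1, lat.shape)
    f = state.output()
    expected = np.zeros(lat.shape)
    dv = lat.spacing(0) * lat.spacing(1)
    for i in range(8):
        for j in range(4):
            for a in range(8):
                for b in range(4):
                    d0 = circular_distance(lat.coords(0)[i], lat.coords(0)[a])
                    d1 = circular_distance(lat.coords(1)[j], lat.coords(1)[b],
                                           period=8.0)
                    k = params.exc_amp * np.exp(
                        -0.5 * ((d0 / 60.0) ** 2 + (d1 / 2.0) ** 2))
                    expected[i, j] += (k - params.global_inh) * f[a, b] * dv
    assert np.max(np.abs(lateral_input(state) - expected)) < 1e-10


def test_bounded_dimension_rows_are_support_normalized():
    """On a bounded dimension, truncation-induced loss of recurrent support
    at the borders is partially compensated (exponent 0.5 by default)."""
    lat = FeatureLattice(extents=(10.0,), shape=(11,), circular=(False,))
    k = build_kernel(lat, InteractionKernel(exc_amp=1.0, exc_width=(3.0,),
                                            boundary_norm=0.5))
    m = k.exc_mats[0]
    target = 3.0 * np.sqrt(2 * np.pi)
    border, center = m[0].sum(), m[5].sum()
    assert border < center  # a mild penalty remains
    raw = np.exp(-0.5 * (np.abs(np.arange(11.0)[:, None]
                                - np.arange(11.0)[None, :]) / 3.0) ** 2)
    raw_border = raw[0].sum()
    assert border == pytest.approx(raw_border * (target / raw_border) ** 0.5)


def test_lateral_input_shape_mismatch_raises():
    lat = FeatureLattice.direction_circle(12)
    state = FieldState.at_rest(lat, FieldParams(10, -2, 0, 2),
                               InteractionKernel(exc_amp=1.0,
                                                 exc_width=(20.0,)))
    with pytest.raises(ValueError):
        lateral_input(state, out=np.zeros(5))


# --------------------------------------------------------------------------
# field dynamics
# --------------------------------------------------------------------------

def _rest_field(n=24, q=0.0, tau=10.0, h=-2.0, beta=2.0, exc=0.0):
    lat = FeatureLattice.direction_circle(n)
    return FieldState.at_rest(
        lat, FieldParams(tau, h, q, beta),
        InteractionKernel(exc_amp=exc, exc_width=(20.0,)))


def test_resting_level_is_attracting_fixed_point():
    state = _rest_field()
    state.u[:] = 3.0
    z = np.zeros(state.u.shape)
    for _ in range(200):
        field_step(state, z, 1.0)
    assert np.max(np.abs(state.u - state.params.h)) < 1e-6


def test_euler_convergence_under_step_halving():
    def endpoint(dt):
        state = _rest_field(exc=0.1)
        s = gaussian_input(state.lattice, 90.0, 3.0, 20.0)
        for _ in range(int(100 / dt)):
            field_step(state, s, dt)
        return state.u.copy()
    u1, u2 = endpoint(1.0), endpoint(0.5)
    assert np.max(np.abs(u1 - u2)) < 0.01 * np.ptp(u1)


def test_noise_variance_scales_with_sqrt_dt():
    """Summed noise variance per unit model time is step-size invariant."""
    def terminal_std(dt, seed):
        state = _rest_field(q=0.3, tau=1e9)  # pure noise accumulation
        z = np.zeros(state.u.shape)
        rng = np.random.default_rng(seed)
        for _ in range(int(round(50 / dt))):
            field_step(state, z, dt, rng)
        return np.std(state.u - state.params.h)
    s1 = np.mean([terminal_std(1.0, s) for s in range(5)])
    s2 = np.mean([terminal_std(0.25, s) for s in range(5)])
    assert s1 == pytest.approx(s2, rel=0.15)


def test_translation_equivariance_on_circle():
    shift = 5
    state_a = _rest_field(n=36, exc=0.2)
    state_b = _rest_field(n=36, exc=0.2)
    s = gaussian_input(state_a.lattice, 40.0, 3.0, 20.0)
    s_shifted = np.roll(s, shift)
    for _ in range(80):
        field_step(state_a, s, 1.0)
        field_step(state_b, s_shifted, 1.0)
    assert np.allclose(np.roll(state_a.u, shift), state_b.u, atol=1e-10)


# --------------------------------------------------------------------------
# node dynamics
# --------------------------------------------------------------------------

def _nodes(n=2, q=0.0):
    return NodeGroup.at_rest(n, FieldParams(10.0, -2.0, q, 4.0),
                             w_self=3.5, w_inh=2.0)


def test_nodes_stay_at_rest_without_input():
    # the resting state sits within one baseline-output quantum of h
    nodes = _nodes()
    z = np.zeros(2)
    for _ in range(200):
        node_step(nodes, z, 1.0)
    assert np.allclose(nodes.u, -2.0, atol=1e-3)
    assert np.all(nodes.output() < 1e-3)


def test_node_latches_and_suppresses_competitor():
    nodes = _nodes()
    drive = np.array([5.0, 0.0])
    for _ in range(100):
        node_step(nodes, drive, 1.0)
    for _ in range(400):
        node_step(nodes, np.zeros(2), 1.0)
    f = nodes.output()
    assert f[0] > 0.5
    assert f[1] < 0.1


def test_symmetric_nodes_without_inhibition_evolve_identically():
    nodes = NodeGroup.at_rest(2, FieldParams(10.0, -2.0, 0.0, 4.0),
                              w_self=3.5, w_inh=0.0)
    drive = np.array([2.0, 2.0])
    for _ in range(100):
        node_step(nodes, drive, 1.0)
    assert nodes.u[0] == pytest.approx(nodes.u[1], abs=1e-12)


# --------------------------------------------------------------------------
# lattice helpers
# --------------------------------------------------------------------------

def test_circular_distance_wraps():
    assert circular_distance(350.0, 10.0) == pytest.approx(20.0)
    assert circular_distance(2.0, 358.0) == pytest.approx(4.0)


def test_invalid_field_params_rejected():
    with pytest.raises(ValueError):
        FieldParams(tau=0.0, h=-1.0, q=0.0, beta=1.0)
    with pytest.raises(ValueError):
        FieldParams(tau=1.0, h=0.5, q=0.0, beta=1.0)
    with pytest.raises(ValueError):
        FieldParams(tau=1.0, h=-1.0, q=-0.1, beta=1.0)
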