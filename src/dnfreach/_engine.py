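"""Compiled (numba) inner loop for trial simulation.

This is a performance specialization of the reference dynamics in
``architecture.step_model`` / ``dnf_core.field_step`` for the standard model
layout: 1-D fields with Gaussian(+global) kernels collapsible into a single
interaction matrix, and a 2-D association field with separable excitation
plus global inhibition.  ``tasks.run_trial`` falls back to the reference
path for configurations outside this envelope, and the test suite asserts
noise-free equivalence of the two paths.

Noise is pregenerated per trial from the session's noise stream (the draw
order differs from the reference path's per-step draws, so noisy
trajectories are deterministic given the seed but not sample-for-sample
identical across the two paths; they agree exactly at q = 0).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _sig_inplace(u, beta, out):
    for i in range(u.size):
        x = beta * u.flat[i]
        if x > 60.0:
            x = 60.0
        elif x < -60.0:
            x = -60.0
        out.flat[i] = 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def run_trial_core(
    u_sp, u_ctx, u_as, u_pr, u_mo,
    K_sp, glob_sp,
    K_as_sp, K_as_ctx, glob_as,
    K_pr, glob_pr,
    K_mo, glob_mo,
    node_self, node_inh,
    blur,
    W_ca, W_ap,
    g_ca, gv_ap, g_sa, g_sp_pr, g_pr_mo, g_mo_pr, c_mo_pr, go_amp,
    par_sp, par_nd, par_as, par_pr, par_mo,   # each: (tau, h, q, beta)
    dt,
    s_sp_series,                 # (n_steps, n) external spatial input
    ctx_idx, ctx_amp, ctx_on, ctx_off,        # steps
    go_step, n_steps,
    noise_sp, noise_ctx, noise_as, noise_pr, noise_mo,  # (n_steps, ...) or size-0
    snap_as, snap_ctx, snap_pr, mem_pr,       # accumulators (in place)
    mem_lo, mem_hi,                           # steps
    trace, trace_stride, store_trace, snap_step,
):
    n = u_sp.shape[0]
    nc = u_ctx.shape[0]
    ny = u_as.shape[1]
    sqdt = np.sqrt(dt)

    f_sp = np.empty(n)
    f_ctx = np.empty(nc)
    f_as = np.empty((n, ny))
    f_pr = np.empty(n)
    f_mo = np.empty(n)
    n_snap = 0
    n_mem = 0
    n_frames = 0

    for step in range(n_steps):
        # outputs of the previous state (synchronous update)
        _sig_inplace(u_sp, par_sp[3], f_sp)
        _sig_inplace(u_ctx, par_nd[3], f_ctx)
        _sig_inplace(u_as, par_as[3], f_as)
        _sig_inplace(u_pr, par_pr[3], f_pr)
        _sig_inplace(u_mo, par_mo[3], f_mo)

        blur_sp = blur @ f_sp
        blur_pr = blur @ f_pr
        blur_mo = blur @ f_mo
        sum_mo = f_mo.sum()

        # ---- spatial field ------------------------------------------------
        lat = K_sp @ f_sp
        g = glob_sp * f_sp.sum()
        r = dt / par_sp[0]
        for i in range(n):
            u_sp[i] += r * (-u_sp[i] + par_sp[1] + s_sp_series[step, i]
                            + lat[i] - g)
        if par_sp[2] > 0.0:
            u_sp += (par_sp[2] * sqdt) * noise_sp[step]

        # ---- context nodes ------------------------------------------------
        sum_fc = f_ctx.sum()
        r = dt / par_nd[0]
        for c in range(nc):
            s_in = ctx_amp if (c == ctx_idx and ctx_on <= step < ctx_off) \
                else 0.0
            lat_c = node_self * f_ctx[c] - node_inh * (sum_fc - f_ctx[c])
            u_ctx[c] += r * (-u_ctx[c] + par_nd[1] + s_in + lat_c)
        if par_nd[2] > 0.0:
            u_ctx += (par_nd[2] * sqdt) * noise_ctx[step]

        # ---- association field --------------------------------------------
        lat2 = K_as_sp @ f_as @ K_as_ctx
        g2 = glob_as * f_as.sum()
        ctx_in = g_ca * (f_ctx @ W_ca)   # (n*ny,)
        r = dt / par_as[0]
        k = 0
        for i in range(n):
            ridge = g_sa * blur_sp[i]
            for j in range(ny):
                u_as[i, j] += r * (-u_as[i, j] + par_as[1] + ridge
                                   + ctx_in[k] + lat2[i, j] - g2)
                k += 1
        if par_as[2] > 0.0:
            u_as += (par_as[2] * sqdt) * noise_as[step]

        # ---- motor preparation field --------------------------------------
        ap_in = gv_ap * (f_as.reshape(n * ny) @ W_ap)
        lat = K_pr @ f_pr
        g = glob_pr * f_pr.sum()
        fb_glob = c_mo_pr * sum_mo
        r = dt / par_pr[0]
        for i in range(n):
            u_pr[i] += r * (-u_pr[i] + par_pr[1]
                            + g_sp_pr * blur_sp[i] + ap_in[i]
                            + g_mo_pr * blur_mo[i] - fb_glob
                            + lat[i] - g)
        if par_pr[2] > 0.0:
            u_pr += (par_pr[2] * sqdt) * noise_pr[step]

        # ---- motor field --------------------------------------------------
        lat = K_mo @ f_mo
        g = glob_mo * f_mo.sum()
        go = go_amp if step >= go_step else 0.0
        r = dt / par_mo[0]
        for i in range(n):
            u_mo[i] += r * (-u_mo[i] + par_mo[1] + g_pr_mo * blur_pr[i]
                            + go + lat[i] - g)
        if par_mo[2] > 0.0:
            u_mo += (par_mo[2] * sqdt) * noise_mo[step]

        # ---- accumulators (outputs of the *new* state next loop) ----------
        if step >= snap_step:
            _sig_inplace(u_as, par_as[3], f_as)
            _sig_inplace(u_ctx, par_nd[3], f_ctx)
            _sig_inplace(u_pr, par_pr[3], f_pr)
            snap_as += f_as
            snap_ctx += f_ctx
            snap_pr += f_pr
            n_snap += 1
        if mem_lo <= step < mem_hi:
            _sig_inplace(u_pr, par_pr[3], f_pr)
            mem_pr += f_pr
            n_mem += 1
        if store_trace and step % trace_stride == 0:
            _sig_inplace(u_pr, par_pr[3], f_pr)
            for i in range(n):
                trace[n_frames, i] = f_pr[i]
            n_frames += 1

    return n_snap, n_mem, n_frames
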