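"""Numba kernels for spin transport through a capillary flow field.

Spins advance along directed (flow-oriented) segments at the plug-flow speed;
at a node the next segment is drawn with probability proportional to the
outgoing volumetric flow rate, and spins reaching the outlet are re-injected
at the inlet with their residual step time conserved. Segments carrying no
flow leave spins stationary (stagnant blood).

The phase kernel never stores trajectories: for each spin it accumulates, per
gradient "shape" profile u_k(t), the running moment
``M_k = sum_t u_k(t) * (p(t) + p(t+dt))/2 * dt`` (trapezoid rule, exact for
the piecewise-linear paths of plug flow), from which the phase for any
measurement of amplitude G along direction n is ``gamma * G * (n . M_k)``.
"""

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _pick_edge(out_off, out_edge, out_cum, node):
    lo = out_off[node]
    hi = out_off[node + 1]
    r = np.random.random()
    e = out_edge[hi - 1]
    for k in range(lo, hi):
        if r <= out_cum[k]:
            e = out_edge[k]
            break
    return e


@numba.njit(cache=True, inline="always")
def _advance(
    e, s, t_rem, e_src, e_dst, e_len, e_speed,
    out_off, out_edge, out_cum, inlet, outlet,
):
    """Advance one spin by t_rem seconds; returns (edge, arclength)."""
    while t_rem > 0.0:
        v = e_speed[e]
        if v <= 0.0:
            break
        t_seg = (e_len[e] - s) / v
        if t_seg > t_rem:
            s += v * t_rem
            t_rem = 0.0
        else:
            t_rem -= t_seg
            node = e_dst[e]
            if node == outlet:
                node = inlet  # re-injection, residual time conserved
            if out_off[node + 1] == out_off[node]:
                # dead end (numerically zero outflow): route via the inlet
                node = inlet
            e = _pick_edge(out_off, out_edge, out_cum, node)
            s = 0.0
    return e, s


@numba.njit(cache=True)
def propagate_phase_moments(
    node_pos, e_src, e_dst, e_len, e_speed, e_u,
    out_off, out_edge, out_cum,
    inlet, outlet,
    spin_edge, spin_s,
    shapes, dt, seed,
):
    """Accumulate per-spin, per-shape phase moment vectors (um * s).

    shapes: (K, T) unit-amplitude gradient profiles sampled at dt.
    Returns moments (N, K, 3).
    """
    np.random.seed(seed)
    n_spins = spin_edge.shape[0]
    n_shapes = shapes.shape[0]
    n_steps = shapes.shape[1]
    moments = np.zeros((n_spins, n_shapes, 3))
    for n in range(n_spins):
        e = spin_edge[n]
        s = spin_s[n]
        px = node_pos[e_src[e], 0] + e_u[e, 0] * s
        py = node_pos[e_src[e], 1] + e_u[e, 1] * s
        pz = node_pos[e_src[e], 2] + e_u[e, 2] * s
        for t in range(n_steps):
            e, s = _advance(
                e, s, dt, e_src, e_dst, e_len, e_speed,
                out_off, out_edge, out_cum, inlet, outlet,
            )
            qx = node_pos[e_src[e], 0] + e_u[e, 0] * s
            qy = node_pos[e_src[e], 1] + e_u[e, 1] * s
            qz = node_pos[e_src[e], 2] + e_u[e, 2] * s
            mx = 0.5 * (px + qx) * dt
            my = 0.5 * (py + qy) * dt
            mz = 0.5 * (pz + qz) * dt
            for k in range(n_shapes):
                u = shapes[k, t]
                if u != 0.0:
                    moments[n, k, 0] += u * mx
                    moments[n, k, 1] += u * my
                    moments[n, k, 2] += u * mz
            px = qx
            py = qy
            pz = qz
    return moments


@numba.njit(cache=True)
def propagate_positions(
    node_pos, e_src, e_dst, e_len, e_speed, e_u,
    out_off, out_edge, out_cum,
    inlet, outlet,
    spin_edge, spin_s,
    n_steps, dt, seed,
):
    """Record full trajectories sampled at dt. Returns (N, n_steps+1, 3)."""
    np.random.seed(seed)
    n_spins = spin_edge.shape[0]
    traj = np.zeros((n_spins, n_steps + 1, 3))
    for n in range(n_spins):
        e = spin_edge[n]
        s = spin_s[n]
        for t in range(n_steps + 1):
            traj[n, t, 0] = node_pos[e_src[e], 0] + e_u[e, 0] * s
            traj[n, t, 1] = node_pos[e_src[e], 1] + e_u[e, 1] * s
            traj[n, t, 2] = node_pos[e_src[e], 2] + e_u[e, 2] * s
            if t < n_steps:
                e, s = _advance(
                    e, s, dt, e_src, e_dst, e_len, e_speed,
                    out_off, out_edge, out_cum, inlet, outlet,
                )
    return traj


@numba.njit(cache=True)
def count_segment_entries(
    e_src, e_dst, e_len, e_speed,
    out_off, out_edge, out_cum,
    inlet, outlet,
    spin_edge, spin_s,
    t_ref, seed,
):
    """Event-driven count of segment entries per spin over t_ref seconds."""
    np.random.seed(seed)
    n_spins = spin_edge.shape[0]
    counts = np.zeros(n_spins)
    for n in range(n_spins):
        e = spin_edge[n]
        s = spin_s[n]
        t = 0.0
        while True:
            v = e_speed[e]
            if v <= 0.0:
                break
            t_seg = (e_len[e] - s) / v
            if t + t_seg >= t_ref:
                break
            t += t_seg
            node = e_dst[e]
            if node == outlet:
                node = inlet
            if out_off[node + 1] == out_off[node]:
                node = inlet
            e = _pick_edge(out_off, out_edge, out_cum, node)
            s = 0.0
            counts[n] += 1.0
    return counts
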