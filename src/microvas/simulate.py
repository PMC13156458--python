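"""Spin seeding, transport through the flow field, and dMRI signal synthesis.

Spins are seeded uniformly over the vessel volume (segment selection
probability proportional to pi r^2 L, position uniform along the segment) and
advected through the flow-oriented network at the plug-flow speed, branching
at nodes with probability proportional to the outgoing volumetric flow rate.
The complex signal of a measurement is

    s = | (1/N) sum_n exp(-i gamma int_0^TE p_n(t) . G(t) dt) |,

discretised at dt = 10 us. Production runs accumulate per-spin phase moments
on the fly (no trajectory storage); full sampled trajectories are available
for validation via :func:`propagate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .flow import FlowSolution
from .protocols import DT_S, GAMMA_RAD_S_T, ProtocolSpec, Waveform

__all__ = [
    "SpinState",
    "SpinTrajectories",
    "seed_spins",
    "propagate",
    "synthesize_signal",
    "simulate_protocol_signals",
    "ensemble_signal_matrices",
    "average_directions",
    "add_rician",
    "DEFAULT_N_SPINS",
]

#: Default number of spins per network realisation.
DEFAULT_N_SPINS = 5000

_UM_TO_M = 1e-6


# -- routing arrays ---------------------------------------------------------

@dataclass(frozen=True)
class _Routing:
    """Flow-directed segment arrays in kernel-ready form (um, um/s)."""

    node_pos: np.ndarray
    e_src: np.ndarray
    e_dst: np.ndarray
    e_len: np.ndarray
    e_speed: np.ndarray
    e_u: np.ndarray
    out_off: np.ndarray
    out_edge: np.ndarray
    out_cum: np.ndarray
    inlet: int
    outlet: int


def _build_routing(flow: FlowSolution) -> _Routing:
    net = flow.network
    segs = flow.directed_segments
    src = segs[:, 0].astype(np.int64)
    dst = segs[:, 1].astype(np.int64)
    vec = net.nodes[dst] - net.nodes[src]
    length = np.linalg.norm(vec, axis=1)
    unit = vec / length[:, None]
    speed_um_s = flow.speed * 1e3  # mm/s -> um/s
    speed_um_s = np.where(flow.transit_mask, speed_um_s, 0.0)

    n = net.n_nodes
    qa = np.abs(flow.q)
    order = np.argsort(src, kind="stable")
    out_off = np.zeros(n + 1, dtype=np.int64)
    counts = np.bincount(src[flow.transit_mask], minlength=n)
    out_off[1:] = np.cumsum(counts)
    out_edge = np.empty(int(counts.sum()), dtype=np.int64)
    out_cum = np.empty_like(out_edge, dtype=np.float64)
    fill = out_off[:-1].copy()
    for e in order:
        if not flow.transit_mask[e]:
            continue
        node = src[e]
        out_edge[fill[node]] = e
        fill[node] += 1
    for node in range(n):
        lo, hi = out_off[node], out_off[node + 1]
        if hi > lo:
            w = qa[out_edge[lo:hi]]
            out_cum[lo:hi] = np.cumsum(w) / w.sum()
    return _Routing(
        node_pos=np.ascontiguousarray(net.nodes),
        e_src=src,
        e_dst=dst,
        e_len=length,
        e_speed=speed_um_s,
        e_u=np.ascontiguousarray(unit),
        out_off=out_off,
        out_edge=out_edge,
        out_cum=out_cum,
        inlet=int(net.inlet),
        outlet=int(net.outlet),
    )


# -- spin state and trajectories -------------------------------------------

@dataclass(frozen=True)
class SpinState:
    """Initial spin placement: per-spin segment index and arclength (um)."""

    flow: FlowSolution
    edge: np.ndarray
    arclength: np.ndarray
    seed: int | None = None

    @property
    def n_spins(self) -> int:
        return len(self.edge)

    def positions(self) -> np.ndarray:
        r = _build_routing(self.flow)
        return r.node_pos[r.e_src[self.edge]] + r.e_u[self.edge] * self.arclength[:, None]


@dataclass(frozen=True)
class SpinTrajectories:
    """Sampled spin paths: positions (N, T+1, 3) in um at interval dt."""

    positions: np.ndarray
    dt: float
    flow: FlowSolution
    seed: int | None = None

    @property
    def n_spins(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1] - 1

    def max_offsegment_distance(self) -> float:
        """Largest distance of any sampled position from the nearest segment
        (validation helper, um)."""
        net = self.flow.network
        a = net.nodes[net.segments[:, 0]]
        b = net.nodes[net.segments[:, 1]]
        ab = b - a
        ab2 = (ab * ab).sum(axis=1)
        pts = self.positions.reshape(-1, 3)
        worst = 0.0
        for chunk in np.array_split(pts, max(1, len(pts) // 2000)):
            t = ((chunk[:, None, :] - a[None]) * ab[None]).sum(axis=2) / ab2[None]
            t = np.clip(t, 0.0, 1.0)
            proj = a[None] + t[..., None] * ab[None]
            d = np.linalg.norm(chunk[:, None, :] - proj, axis=2).min(axis=1)
            worst = max(worst, float(d.max()))
        return worst


def seed_spins(
    flow: FlowSolution, n_spins: int = DEFAULT_N_SPINS, seed: int | None = None
) -> SpinState:
    """Seed spins uniformly over the total vessel volume."""
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    net = flow.network
    if net.n_segments == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    vol = net.volumes
    edge = rng.choice(net.n_segments, size=n_spins, p=vol / vol.sum())
    arclength = rng.uniform(0.0, net.lengths[edge])
    return SpinState(flow=flow, edge=edge.astype(np.int64),
                     arclength=arclength, seed=seed)


def _kernel_seed(seed: int | None) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


def propagate(
    state: SpinState,
    duration_ms: float,
    dt: float = DT_S,
    seed: int | None = None,
) -> SpinTrajectories:
    """Advect spins for ``duration_ms`` and record sampled trajectories.

    Intended for validation and small runs; production signal synthesis goes
    through :func:`simulate_protocol_signals`, which accumulates phase moments
    without storing paths.
    """
    r = _build_routing(state.flow)
    n_steps = int(round(duration_ms * 1e-3 / dt))
    traj = _kernels.propagate_positions(
        r.node_pos, r.e_src, r.e_dst, r.e_len, r.e_speed, r.e_u,
        r.out_off, r.out_edge, r.out_cum, r.inlet, r.outlet,
        state.edge, state.arclength, n_steps, dt, _kernel_seed(seed),
    )
    return SpinTrajectories(positions=traj, dt=dt, flow=state.flow, seed=seed)


def synthesize_signal(
    traj: SpinTrajectories, waveform: Waveform, direction: np.ndarray
) -> float:
    """Magnitude signal of one measurement from sampled trajectories."""
    direction = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(direction), 1.0):
        raise ValueError("direction must be unit norm")
    if traj.n_steps < waveform.n_samples:
        raise ValueError("trajectory window does not cover the waveform")
    if not np.isclose(traj.dt, waveform.dt):
        raise ValueError("mismatched time bases")
    prof = waveform.profile
    t_idx = np.flatnonzero(prof)
    mid = 0.5 * (traj.positions[:, t_idx, :] + traj.positions[:, t_idx + 1, :])
    proj = mid @ direction  # (N, nt), um
    phase = GAMMA_RAD_S_T * waveform.G * _UM_TO_M * traj.dt * (proj @ prof[t_idx])
    return float(np.abs(np.mean(np.exp(-1j * phase))))


# -- production path: phase moments ----------------------------------------

def _shape_table(protocols: list[ProtocolSpec]):
    """Unique gradient shapes across protocols, padded to a common length.

    Returns (shapes (K, T) array, per-protocol list of per-waveform shape
    indices)."""
    keys: dict[tuple, int] = {}
    profiles: list[np.ndarray] = []
    index_map: list[list[int]] = []
    for prot in protocols:
        idxs = []
        for w in prot.waveforms:
            key = (w.kind, w.delta_ms, w.Delta_ms, w.tau_ms, w.n_samples)
            if key not in keys:
                keys[key] = len(profiles)
                profiles.append(w.profile)
            idxs.append(keys[key])
        index_map.append(idxs)
    n_t = max(len(p) for p in profiles)
    shapes = np.zeros((len(profiles), n_t))
    for k, p in enumerate(profiles):
        shapes[k, : len(p)] = p
    return shapes, index_map


def simulate_protocol_signals(
    flow: FlowSolution,
    protocols: list[ProtocolSpec],
    n_spins: int = DEFAULT_N_SPINS,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Noise-free per-measurement signals for one network under several
    protocols, reusing a single trajectory realisation (one simulation per
    synthetic voxel)."""
    state = seed_spins(flow, n_spins, seed)
    r = _build_routing(flow)
    shapes, index_map = _shape_table(protocols)
    moments = _kernels.propagate_phase_moments(
        r.node_pos, r.e_src, r.e_dst, r.e_len, r.e_speed, r.e_u,
        r.out_off, r.out_edge, r.out_cum, r.inlet, r.outlet,
        state.edge, state.arclength, shapes, DT_S, _kernel_seed(seed),
    )  # (N, K, 3) um*s
    out = []
    for prot, idxs in zip(protocols, index_map):
        sig = np.empty(prot.n_measurements)
        for m, (wi, di) in enumerate(prot.measurements):
            w = prot.waveforms[wi]
            proj = moments[:, idxs[wi], :] @ prot.directions[di]  # um*s
            phase = GAMMA_RAD_S_T * w.G * _UM_TO_M * proj
            sig[m] = np.abs(np.mean(np.exp(-1j * phase)))
        out.append(sig)
    return out


def ensemble_signal_matrices(
    ensemble,
    protocols: list[ProtocolSpec],
    n_spins: int = DEFAULT_N_SPINS,
    seed: int | None = None,
    solve=None,
    progress: bool = False,
) -> list[np.ndarray]:
    """Stack noise-free signals for every (network, qin) pair of an ensemble.

    Returns one (Q, M) matrix per protocol, rows in ensemble order. ``solve``
    may inject a pre-computed flow solution lookup; by default flows are
    solved here.
    """
    from .flow import solve_flow

    ss = np.random.SeedSequence(seed)
    rows: list[list[np.ndarray]] = [[] for _ in protocols]
    iterator = enumerate(ensemble)
    if progress:
        from tqdm import tqdm

        iterator = enumerate(tqdm(list(ensemble)))
    for i, (net, qin) in iterator:
        flow = solve(net, qin) if solve is not None else solve_flow(net, qin)
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        sigs = simulate_protocol_signals(flow, protocols, n_spins, sub)
        for k, s in enumerate(sigs):
            rows[k].append(s)
    return [np.vstack(r) for r in rows]


# -- averaging and noise ----------------------------------------------------

def average_directions(signals: np.ndarray, protocol: ProtocolSpec) -> np.ndarray:
    """Arithmetic mean over the gradient directions at fixed waveform.

    ``signals`` has the per-measurement axis last; returns one value per
    waveform (b-value) in protocol order.
    """
    signals = np.asarray(signals)
    groups = protocol.averaging_groups()
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty direction group")
    return np.stack([signals[..., g].mean(axis=-1) for g in groups], axis=-1)


def add_rician(
    signal: np.ndarray, snr: float, seed=None
) -> np.ndarray:
    """Corrupt normalised magnitude signals with Rician noise.

    sigma = 1/SNR relative to the b=0 signal of 1:
    s_noisy = sqrt((s + n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2).
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal = np.asarray(signal, dtype=float)
    sigma = 1.0 / snr
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)
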