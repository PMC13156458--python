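"""The 12 ground-truth microvascular descriptors of a network realisation.

Segment-moment metrics (unweighted over capillary segments): mean/SD of the
blood speed (vm, vs; mm/s), of the volumetric flow rate (qm, qs; mm^3/s),
mean radius rm (um) and mean segment length Lm (um).

Path metrics (over directed inlet-to-outlet paths of the flow-oriented
graph): the path-weighted means vw, qw, rw (line integrals along a path
normalised by its length, then averaged uniformly across paths), the mean
path length Lmp (um) and the exact number of paths Npaths (dynamic
programming on the DAG; enumeration is capped and falls back to uniform
path sampling).

ANB (apparent network branching): mean number of capillary segments a
flowing spin traverses in a 100 ms reference window, estimated by probe-spin
trajectory counting with outlet-to-inlet re-injection.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from . import _kernels
from .flow import FlowSolution
from .simulate import _build_routing, seed_spins, _kernel_seed

__all__ = [
    "VascularMetrics",
    "moment_metrics",
    "path_metrics",
    "compute_anb",
    "compute_metrics",
    "metrics_table",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "vm", "vs", "vw", "qm", "qs", "qw",
    "rm", "rw", "Lm", "Lmp", "Npaths", "ANB",
)


@dataclass(frozen=True)
class VascularMetrics:
    """The 12 descriptors plus the input flow qin (mm^3/s)."""

    vm: float
    vs: float
    vw: float
    qm: float
    qs: float
    qw: float
    rm: float
    rw: float
    Lm: float
    Lmp: float
    Npaths: float
    ANB: float
    qin: float

    def as_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        d = self.as_dict()
        if not all(np.isfinite(v) for v in d.values()):
            raise ValueError("non-finite metric value")
        if self.vs < 0 or self.qs < 0 or self.ANB < 0:
            raise ValueError("negative spread/branching metric")
        if self.Npaths < 1:
            raise ValueError("Npaths must be >= 1")


def moment_metrics(flow: FlowSolution) -> dict:
    """Unweighted per-segment means and population SDs of |v|, |q|, r, L."""
    net = flow.network
    speed = flow.speed  # mm/s
    qabs = np.abs(flow.q)
    return {
        "vm": float(speed.mean()),
        "vs": float(speed.std()),  # population SD
        "qm": float(qabs.mean()),
        "qs": float(qabs.std()),
        "rm": float(net.radii.mean()),
        "Lm": float(net.lengths.mean()),
    }


def _transit_digraph(flow: FlowSolution) -> nx.DiGraph:
    net = flow.network
    segs = flow.directed_segments
    g = nx.DiGraph()
    for e in np.flatnonzero(flow.transit_mask):
        a, b = map(int, segs[e])
        g.add_edge(a, b, index=int(e))
    return g


def count_paths(flow: FlowSolution) -> tuple[int, dict]:
    """Exact number of directed inlet->outlet paths and the per-node
    downstream path counts (DAG dynamic programming, exact integers)."""
    g = _transit_digraph(flow)
    net = flow.network
    if net.outlet not in g or net.inlet not in g:
        raise ValueError("no inlet->outlet path carries flow")
    counts: dict[int, int] = {net.outlet: 1}
    for node in reversed(list(nx.topological_sort(g))):
        if node == net.outlet:
            continue
        counts[node] = sum(counts.get(v, 0) for v in g.successors(node))
    if counts.get(net.inlet, 0) == 0:
        raise ValueError("no inlet->outlet path carries flow")
    return counts[net.inlet], counts


def _iter_paths(flow: FlowSolution, max_paths: int, n_sample: int, rng):
    """Yield inlet->outlet paths as lists of segment indices: exhaustively if
    the path count fits in max_paths, else n_sample uniform draws."""
    g = _transit_digraph(flow)
    net = flow.network
    n_paths, counts = count_paths(flow)
    if n_paths <= max_paths:
        for nodes in nx.all_simple_paths(g, net.inlet, net.outlet):
            yield [g.edges[u, v]["index"] for u, v in zip(nodes[:-1], nodes[1:])]
    else:
        for _ in range(n_sample):
            node = net.inlet
            path = []
            while node != net.outlet:
                succ = [v for v in g.successors(node) if counts.get(v, 0) > 0]
                w = np.array([counts[v] for v in succ], dtype=float)
                v = succ[rng.choice(len(succ), p=w / w.sum())]
                path.append(g.edges[node, v]["index"])
                node = v
            yield path


def path_metrics(
    flow: FlowSolution,
    max_paths: int = 2_000,
    n_sample: int = 2_000,
    seed: int | None = None,
) -> dict:
    """Path-weighted means vw, qw, rw, mean path length Lmp, exact Npaths."""
    net = flow.network
    rng = np.random.default_rng(seed)
    n_paths, _ = count_paths(flow)
    length = net.lengths
    speed = flow.speed
    qabs = np.abs(flow.q)
    radii = net.radii
    vws, qws, rws, lps = [], [], [], []
    for segs in _iter_paths(flow, max_paths, n_sample, rng):
        idx = np.asarray(segs)
        L = length[idx]
        lp = L.sum()
        vws.append(float((L * speed[idx]).sum() / lp))
        qws.append(float((L * qabs[idx]).sum() / lp))
        rws.append(float((L * radii[idx]).sum() / lp))
        lps.append(float(lp))
    return {
        "vw": float(np.mean(vws)),
        "qw": float(np.mean(qws)),
        "rw": float(np.mean(rws)),
        "Lmp": float(np.mean(lps)),
        "Npaths": float(n_paths),
    }


def compute_anb(
    flow: FlowSolution,
    t_ref_ms: float = 100.0,
    n_probe_spins: int = 1000,
    seed: int | None = None,
) -> float:
    """Apparent network branching: mean segment entries per probe spin over
    the reference window (100 ms)."""
    state = seed_spins(flow, n_probe_spins, seed)
    r = _build_routing(flow)
    counts = _kernels.count_segment_entries(
        r.e_src, r.e_dst, r.e_len, r.e_speed,
        r.out_off, r.out_edge, r.out_cum, r.inlet, r.outlet,
        state.edge, state.arclength, t_ref_ms * 1e-3, _kernel_seed(seed),
    )
    return float(counts.mean())


def compute_metrics(
    flow: FlowSolution,
    max_paths: int = 100_000,
    n_probe_spins: int = 1000,
    seed: int | None = None,
) -> VascularMetrics:
    """All 12 descriptors for one solved network realisation."""
    vals = moment_metrics(flow)
    vals.update(path_metrics(flow, max_paths=max_paths, seed=seed))
    vals["ANB"] = compute_anb(flow, n_probe_spins=n_probe_spins, seed=seed)
    m = VascularMetrics(**vals, qin=flow.qin)
    m.validate()
    return m


def metrics_table(
    ensemble,
    solve=None,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Metrics for every (network, qin) pair, keyed by base network and
    realisation indices from the network provenance."""
    from .flow import solve_flow

    ss = np.random.SeedSequence(seed)
    rows = []
    for net, qin in ensemble:
        flow = solve(net, qin) if solve is not None else solve_flow(net, qin)
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        m = compute_metrics(flow, seed=sub, **kwargs)
        rows.append(
            {
                "base_index": net.provenance.get("base_index"),
                "realisation": net.provenance.get("realisation"),
                **m.as_dict(),
            }
        )
    return pd.DataFrame(rows)
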