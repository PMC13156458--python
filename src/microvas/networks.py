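"""Synthetic capillary networks and their perturbed 3D realisations.

Networks are geometric graphs: nodes carry positions in micrometres, segments
carry radii, and exactly one inlet and one outlet sit on the network boundary.
Base networks are planar (z = 0) Delaunay-style graphs emulating
histology-derived capillary beds of in-plane size 240-600 um; an ensemble of
realisations is produced by jittering node positions, rescaling radii,
removing a small fraction of segments, reassigning the inlet/outlet, and
embedding the plane in 3D with an exponentially decaying depth profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, Delaunay

__all__ = [
    "CapillaryNetwork",
    "PerturbationConfig",
    "generate_base_network",
    "perturb_realisation",
    "assign_depth",
    "build_ensemble",
    "QIN_GRID",
]

#: Input volumetric flow rates probed across the ensemble, mm^3/s:
#: 10 equally spaced values spanning [1.5e-4, 2.75e-3].
QIN_GRID = np.linspace(1.5e-4, 2.75e-3, 10)


class NetworkGeometryError(ValueError):
    """Raised when a network cannot be built or perturbed as requested."""


@dataclass(frozen=True)
class CapillaryNetwork:
    """Geometric graph of capillary segments with one inlet and one outlet.

    Attributes
    ----------
    nodes : (n, 3) float array
        Node positions in micrometres.
    segments : (m, 2) int array
        Node-index pairs (unordered endpoints).
    radii : (m,) float array
        Segment radii in micrometres.
    inlet, outlet : int
        Node indices of the single inlet and outlet.
    provenance : dict
        Base-network id, realisation seed, and generation parameters.
    """

    nodes: np.ndarray
    segments: np.ndarray
    radii: np.ndarray
    inlet: int
    outlet: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "segments", np.asarray(self.segments, dtype=int))
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))

    # -- derived geometry ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def lengths(self) -> np.ndarray:
        """Segment lengths in micrometres."""
        a, b = self.segments.T
        return np.linalg.norm(self.nodes[a] - self.nodes[b], axis=1)

    @property
    def volumes(self) -> np.ndarray:
        """Segment lumen volumes, um^3 (cylinders)."""
        return np.pi * self.radii**2 * self.lengths

    def bounding_box_diagonal(self) -> float:
        span = self.nodes.max(axis=0) - self.nodes.min(axis=0)
        return float(np.linalg.norm(span))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, (a, b) in enumerate(self.segments):
            g.add_edge(int(a), int(b), index=i, radius=float(self.radii[i]))
        return g

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("non-finite node coordinates")
        if self.n_segments == 0:
            raise ValueError("network has no segments")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")
        if np.any(self.lengths <= 0):
            raise ValueError("all segment lengths must be positive")
        if self.inlet == self.outlet:
            raise ValueError("inlet and outlet must differ")
        g = self.to_graph()
        if not nx.has_path(g, self.inlet, self.outlet):
            raise ValueError("inlet and outlet are not connected")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": "um",
            "inlet": int(self.inlet),
            "outlet": int(self.outlet),
            "nodes": self.nodes.tolist(),
            "segments": self.segments.tolist(),
            "radii": self.radii.tolist(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CapillaryNetwork":
        return cls(
            nodes=np.array(d["nodes"], dtype=float),
            segments=np.array(d["segments"], dtype=int),
            radii=np.array(d["radii"], dtype=float),
            inlet=int(d["inlet"]),
            outlet=int(d["outlet"]),
            provenance=d.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "CapillaryNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_edge_list(
        cls,
        node_table: np.ndarray,
        segment_table: np.ndarray,
        inlet: int,
        outlet: int,
    ) -> "CapillaryNetwork":
        """Build from tabular data: node rows (id, x, y, z), segment rows
        (a, b, radius). Coordinates in micrometres. Accepts externally traced
        networks exported in this edge-list dialect."""
        node_table = np.asarray(node_table, dtype=float)
        segment_table = np.asarray(segment_table, dtype=float)
        order = np.argsort(node_table[:, 0])
        node_table = node_table[order]
        ids = node_table[:, 0].astype(int)
        remap = {int(i): k for k, i in enumerate(ids)}
        segs = np.array(
            [[remap[int(a)], remap[int(b)]] for a, b in segment_table[:, :2]], dtype=int
        )
        return cls(
            nodes=node_table[:, 1:4],
            segments=segs,
            radii=segment_table[:, 2],
            inlet=remap[int(inlet)],
            outlet=remap[int(outlet)],
        )


@dataclass(frozen=True)
class PerturbationConfig:
    """Amplitudes of the per-realisation perturbations.

    radius_fraction: multiplicative radius factors drawn uniform in
    [1 - f, 1 + f] (default +/-40%); xy_jitter: uniform in-plane node shifts,
    um (default +/-2); zmax: maximum out-of-plane depth, um (default 150,
    i.e. a total depth excursion of 300 um); removal_fraction: fraction of
    segments removed at random (default 3%), rejecting removals that would
    disconnect the graph.
    """

    radius_fraction: float = 0.40
    xy_jitter: float = 2.0
    zmax: float = 150.0
    removal_fraction: float = 0.03
    reassign_endpoints: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.radius_fraction < 0 or self.xy_jitter < 0 or self.zmax < 0:
            raise ValueError("perturbation amplitudes must be >= 0")
        if not 0 <= self.removal_fraction < 1:
            raise ValueError("removal_fraction must lie in [0, 1)")


# -- base-network synthesis ------------------------------------------------

def _hull_nodes(xy: np.ndarray) -> np.ndarray:
    if len(xy) < 4:
        return np.arange(len(xy))
    return np.unique(ConvexHull(xy).vertices)


#: Discrete base radii (um) from which segment radii are drawn before the
#: +/-40% perturbation smears them into a roughly uniform distribution.
#: Capillary-scale calibres (2-5.5 um): together with the standard qin grid
#: these give plug-flow speeds of order 1-10 mm/s and vascular
#: pseudo-diffusion coefficients in the range observed in abdominal IVIM.
BASE_RADII_UM = np.linspace(2.0, 5.5, 8)


def generate_base_network(
    size_um: float,
    mean_segment_length_um: float = 60.0,
    seed: int | None = None,
    aspect_ratio: float = 1.0,
    rotation_deg: float = 0.0,
) -> CapillaryNetwork:
    """Generate a planar base capillary network of target diagonal ``size_um``.

    Points are placed on a jittered grid with spacing ``mean_segment_length_um``
    and triangulated (Delaunay); overlong edges are pruned while preserving
    connectivity. Radii are drawn from a discrete set spanning 4-10 um. The
    inlet and outlet are the most distant pair of convex-hull nodes. The node
    cloud is rescaled so that the bounding-box diagonal equals ``size_um``.

    Histology-derived capillary beds are irregular patches rather than
    isotropic meshes; ``aspect_ratio`` stretches the lattice along one axis
    (rotated by ``rotation_deg``) so that a base set can span a range of
    orientation biases and segment-length scales.
    """
    if not 240.0 <= size_um <= 600.0:
        raise NetworkGeometryError(
            f"size_um={size_um} outside the supported 240-600 um envelope"
        )
    if aspect_ratio < 1.0:
        raise NetworkGeometryError("aspect_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    side = size_um / np.sqrt(2.0)
    spacing = float(mean_segment_length_um)
    n_side = max(3, int(round(side / spacing)) + 1)
    if n_side < 3:
        raise NetworkGeometryError("too few nodes for a connected network")
    g1 = np.arange(n_side) * spacing
    xx, yy = np.meshgrid(g1, g1)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts = pts + rng.uniform(-0.35 * spacing, 0.35 * spacing, size=pts.shape)
    if aspect_ratio != 1.0:
        pts[:, 0] *= np.sqrt(aspect_ratio)
        pts[:, 1] /= np.sqrt(aspect_ratio)
    if rotation_deg:
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = pts @ rot.T

    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)

    # prune the longest edges (Delaunay slivers) but keep the graph connected
    keep = lengths <= 1.7 * spacing * np.sqrt(aspect_ratio)
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    g.add_edges_from(edges[keep])
    if not nx.is_connected(g):
        order = np.argsort(lengths)
        for idx in order:
            if keep[idx]:
                continue
            a, b = edges[idx]
            if not nx.has_path(g, a, b):
                g.add_edge(a, b)
                keep[idx] = True
        if not nx.is_connected(g):  # pragma: no cover - Delaunay is connected
            raise NetworkGeometryError("could not build a connected network")
    edges = np.array(sorted(g.edges()))

    hull = _hull_nodes(pts)
    d2 = np.linalg.norm(pts[hull][:, None] - pts[hull][None, :], axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    inlet, outlet = int(hull[i]), int(hull[j])

    # rescale to the exact target diagonal
    span = pts.max(axis=0) - pts.min(axis=0)
    pts = pts * (size_um / float(np.linalg.norm(span)))

    # Radii are assigned through a smooth random field sampled at segment
    # midpoints and quantile-mapped onto the discrete base set: vessels are
    # continuous tubes, so neighbouring segments share calibre, and the r^4
    # conductance then concentrates flow along wide preferential channels as
    # in real capillary beds. The marginal radius distribution stays uniform
    # over the base set.
    mids = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
    k_waves = rng.uniform(-1.0, 1.0, size=(6, 2))
    k_waves *= (2 * np.pi / rng.uniform(1.5 * spacing, 4.0 * spacing, size=(6, 1)))
    phases = rng.uniform(0, 2 * np.pi, size=6)
    fld = np.cos(mids @ k_waves.T + phases).sum(axis=1)
    ranks = np.argsort(np.argsort(fld))
    radii = BASE_RADII_UM[(ranks * len(BASE_RADII_UM)) // len(edges)]
    net = CapillaryNetwork(
        nodes=np.column_stack([pts, np.zeros(len(pts))]),
        segments=edges,
        radii=radii,
        inlet=inlet,
        outlet=outlet,
        provenance={
            "kind": "base",
            "size_um": float(size_um),
            "mean_segment_length_um": spacing,
            "seed": seed,
        },
    )
    net.validate()
    return net


# -- perturbed realisations -------------------------------------------------

def perturb_realisation(
    net: CapillaryNetwork,
    cfg: PerturbationConfig,
    max_retries: int = 200,
) -> CapillaryNetwork:
    """Produce one perturbed realisation of ``net``.

    Radii are scaled by factors uniform in [1-f, 1+f], in-plane positions
    jittered uniformly within +/-xy_jitter um, a ``removal_fraction`` share of
    segments is removed (rejecting, with bounded retries, removals that would
    disconnect the graph), and the inlet/outlet are reassigned among
    convex-hull boundary nodes. All draws are uniform. Depth is not assigned
    here; see :func:`assign_depth`.
    """
    net.validate()
    rng = np.random.default_rng(cfg.seed)
    nodes = net.nodes.copy()
    nodes[:, :2] += rng.uniform(-cfg.xy_jitter, cfg.xy_jitter, size=(len(nodes), 2))
    radii = net.radii * rng.uniform(
        1.0 - cfg.radius_fraction, 1.0 + cfg.radius_fraction, size=net.n_segments
    )

    n_remove = int(np.floor(cfg.removal_fraction * net.n_segments))
    g = net.to_graph()
    removed: list[int] = []
    if n_remove > 0:
        candidates = rng.permutation(net.n_segments)
        tries = 0
        for idx in candidates:
            if len(removed) == n_remove:
                break
            a, b = map(int, net.segments[idx])
            g.remove_edge(a, b)
            ok = nx.has_path(g, a, b) or (g.degree(a) == 0) or (g.degree(b) == 0)
            # a removal may strand a node entirely; only allow it if the
            # remainder of the graph (ignoring newly isolated nodes) stays
            # connected, so the flow system remains solvable
            if ok:
                sub = [n for n in g.nodes if g.degree(n) > 0]
                ok = len(sub) > 0 and nx.is_connected(g.subgraph(sub))
                ok = ok and net.inlet in sub and net.outlet in sub
            if ok:
                removed.append(int(idx))
            else:
                g.add_edge(a, b)
                tries += 1
                if tries > max_retries:
                    raise NetworkGeometryError(
                        "segment removal kept disconnecting the network"
                    )
    keep = np.setdiff1d(np.arange(net.n_segments), removed)
    segments = net.segments[keep]
    radii = radii[keep]

    inlet, outlet = net.inlet, net.outlet
    if cfg.reassign_endpoints:
        used = np.unique(segments)
        hull = _hull_nodes(nodes[used][:, :2])
        hull = used[hull]
        span = net.bounding_box_diagonal()
        for _ in range(max_retries):
            a, b = rng.choice(hull, size=2, replace=False)
            far = np.linalg.norm(nodes[a, :2] - nodes[b, :2]) >= 0.4 * span
            gg = nx.Graph(list(map(tuple, segments)))
            if far and nx.has_path(gg, int(a), int(b)):
                inlet, outlet = int(a), int(b)
                break

    out = CapillaryNetwork(
        nodes=nodes,
        segments=segments,
        radii=radii,
        inlet=inlet,
        outlet=outlet,
        provenance={
            **net.provenance,
            "kind": "realisation",
            "perturbation_seed": cfg.seed,
            "removed_segments": removed,
        },
    )
    out.validate()
    return out


def assign_depth(
    net: CapillaryNetwork,
    zmax: float = 150.0,
    sign: int | None = None,
    seed: int | None = None,
) -> CapillaryNetwork:
    """Embed a planar network in 3D with an exponential depth profile.

    Depth decays with in-plane distance ``d`` from the centroid,
    ``z = s * zmax * exp(-(d - d_min) / d0)`` with ``d0`` a quarter of the
    network extent (bounding-box diagonal), so the centroid-nearest node
    attains ``|z| = zmax`` and the maximum depth sits at the network centre.
    The sign ``s`` is drawn uniformly in {+1, -1} per realisation unless given.
    """
    if zmax < 0:
        raise ValueError("zmax must be >= 0")
    rng = np.random.default_rng(seed)
    s = sign if sign is not None else int(rng.choice([-1, 1]))
    nodes = net.nodes.copy()
    if zmax == 0:
        nodes[:, 2] = 0.0
    else:
        xy = nodes[:, :2]
        centroid = xy.mean(axis=0)
        d = np.linalg.norm(xy - centroid, axis=1)
        span = xy.max(axis=0) - xy.min(axis=0)
        d0 = max(float(np.linalg.norm(span)) / 4.0, 1e-9)
        nodes[:, 2] = s * zmax * np.exp(-(d - d.min()) / d0)
    return replace(
        net,
        nodes=nodes,
        provenance={**net.provenance, "zmax": float(zmax), "depth_sign": s},
    )


def default_base_set(
    n_bases: int = 15, seed: int | None = 0
) -> list[CapillaryNetwork]:
    """The standard set of base networks emulating a histology-derived panel.

    The bases span the 240-600 um in-plane size envelope, segment-length
    scales of roughly 35-90 um, and varied in-plane anisotropy (aspect ratios
    up to ~2.2 with random orientation), so that the ensemble covers a broad,
    roughly uniform range of capillary lengths and morphologies rather than
    replicating a single isotropic mesh.
    """
    rng = np.random.default_rng(seed)
    sizes = np.linspace(240.0, 600.0, n_bases)
    lengths = 35.0 + (np.arange(n_bases) * 55.0 / max(n_bases - 1, 1))
    rng.shuffle(lengths)
    bases = []
    for i in range(n_bases):
        bases.append(
            generate_base_network(
                float(sizes[i]),
                mean_segment_length_um=float(lengths[i]),
                seed=int(rng.integers(2**31)),
                aspect_ratio=float(rng.uniform(1.0, 2.2)),
                rotation_deg=float(rng.uniform(0.0, 180.0)),
            )
        )
    return bases


def build_ensemble(
    base_networks: list[CapillaryNetwork],
    realisations_per_network: int = 100,
    qin_values: np.ndarray | None = None,
    seed: int | None = None,
    cfg: PerturbationConfig | None = None,
) -> list[tuple[CapillaryNetwork, float]]:
    """Build the study ensemble of perturbed 3D realisations with input flows.

    Each base network spawns ``realisations_per_network`` perturbed 3D
    realisations; the input volumetric flow rate is assigned by cycling the
    ``qin_values`` grid (default: 10 equally spaced values in
    [1.5e-4, 2.75e-3] mm^3/s) so every value is used equally often per base
    network. Returns ``(network, qin)`` pairs, base-major order.
    """
    if realisations_per_network < 1:
        raise ValueError("realisations_per_network must be >= 1")
    qin_values = QIN_GRID if qin_values is None else np.asarray(qin_values, float)
    if len(qin_values) == 0:
        raise ValueError("qin_values must be nonempty")
    base_cfg = cfg or PerturbationConfig()
    ss = np.random.SeedSequence(seed)
    out: list[tuple[CapillaryNetwork, float]] = []
    for b, base in enumerate(base_networks):
        for r in range(realisations_per_network):
            sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            real = perturb_realisation(base, replace(base_cfg, seed=sub))
            real = assign_depth(real, base_cfg.zmax, seed=sub + 1)
            real = replace(
                real,
                provenance={**real.provenance, "base_index": b, "realisation": r},
            )
            out.append((real, float(qin_values[r % len(qin_values)])))
    return out
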