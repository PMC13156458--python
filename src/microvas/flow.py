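"""Steady Poiseuille flow through a capillary network.

The network is solved by the electric-hydraulic analogy: node pressures play
the role of voltages, per-segment volumetric flow rates (VFR) of currents, and
the Poiseuille resistance 8*mu*L/(pi*r^4) of Ohmic resistances. With the inlet
injecting qin and the outlet draining it, Kirchhoff conservation at every
interior node gives a sparse linear system in the node pressures. Spins are
modelled as experiencing plug flow, so the mean speed of a segment is simply
v = q / (pi r^2), uniform over the cross-section.

Because the total inflow qin is prescribed (not a pressure difference), the
absolute blood viscosity cancels from the flow split; it is kept as a single
configurable constant only so that pressures have consistent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .networks import CapillaryNetwork

__all__ = ["FlowSolution", "solve_flow"]

#: Default dynamic viscosity of blood, Pa*s (affects pressures only).
BLOOD_VISCOSITY_PA_S = 1.2e-3

#: Segments with |q| below EPS_FLOW * qin are treated as carrying no transit.
EPS_FLOW = 1e-9


class FlowSolverError(RuntimeError):
    """Raised when the hydraulic system cannot be solved."""


@dataclass(frozen=True)
class FlowSolution:
    """Per-segment flow through a :class:`CapillaryNetwork`.

    q is the signed VFR (mm^3/s) with respect to the segment's stored
    (node_a -> node_b) orientation; v the plug-flow mean speed (mm/s, signed
    the same way); pressure the node pressures (Pa up to the viscosity
    constant). ``directed_segments`` re-orients every segment along the flow,
    which yields an acyclic inlet-to-outlet routing graph.
    """

    network: CapillaryNetwork
    q: np.ndarray
    v: np.ndarray
    pressure: np.ndarray
    qin: float
    viscosity: float = BLOOD_VISCOSITY_PA_S
    provenance: dict = field(default_factory=dict)

    @property
    def speed(self) -> np.ndarray:
        """Unsigned mean speeds, mm/s."""
        return np.abs(self.v)

    @property
    def directed_segments(self) -> np.ndarray:
        """(m, 2) segments re-oriented so flow runs a -> b."""
        segs = self.network.segments.copy()
        flip = self.q < 0
        segs[flip] = segs[flip][:, ::-1]
        return segs

    @property
    def transit_mask(self) -> np.ndarray:
        """Segments that carry appreciable flow (|q| >= EPS_FLOW * qin)."""
        return np.abs(self.q) >= EPS_FLOW * self.qin

    def segment_table(self) -> "np.ndarray":
        """Tabular serialisation alongside the network: columns
        (node_a, node_b, radius_um, q_mm3_s, v_mm_s)."""
        return np.column_stack(
            [self.network.segments, self.network.radii, self.q, self.v]
        )

    def node_imbalance(self) -> np.ndarray:
        """Signed flow imbalance at every node (should vanish except at the
        inlet (+qin) and outlet (-qin))."""
        net = self.network
        out = np.zeros(net.n_nodes)
        a, b = net.segments.T
        np.add.at(out, a, -self.q)
        np.add.at(out, b, self.q)
        out[net.inlet] += self.qin
        out[net.outlet] -= self.qin
        return out


def solve_flow(net: CapillaryNetwork, qin: float) -> FlowSolution:
    """Solve steady flow with total inflow ``qin`` (mm^3/s) at the inlet.

    Returns per-segment signed VFR and plug-flow mean speed. Raises
    :class:`FlowSolverError` if the hydraulic system is singular (network not
    connected) and ``ValueError`` for nonpositive radii or qin <= 0.
    """
    net.validate()
    if qin <= 0:
        raise ValueError("qin must be positive")
    lengths_mm = net.lengths * 1e-3
    radii_mm = net.radii * 1e-3
    if np.any(radii_mm <= 0):
        raise ValueError("all radii must be positive")

    # hydraulic conductance per segment, mm^3 / (s * Pa)
    mu = BLOOD_VISCOSITY_PA_S
    g = np.pi * radii_mm**4 / (8.0 * mu * lengths_mm)

    n = net.n_nodes
    a, b = net.segments.T
    lap = sp.coo_matrix(
        (
            np.concatenate([g, g, -g, -g]),
            (
                np.concatenate([a, b, a, b]),
                np.concatenate([a, b, b, a]),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    rhs = np.zeros(n)
    rhs[net.inlet] = qin
    rhs[net.outlet] = -qin

    # ground the outlet to remove the pressure gauge freedom
    keep = np.ones(n, dtype=bool)
    keep[net.outlet] = False
    lap_red = lap[keep][:, keep].tocsc()
    try:
        p_red = spla.spsolve(lap_red, rhs[keep])
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise FlowSolverError(f"hydraulic system could not be solved: {exc}")
    if not np.all(np.isfinite(p_red)):
        raise FlowSolverError("singular hydraulic system (disconnected network?)")
    pressure = np.zeros(n)
    pressure[keep] = p_red

    q = g * (pressure[a] - pressure[b])  # mm^3/s, signed a -> b
    area_mm2 = np.pi * (net.radii * 1e-3) ** 2
    v = q / area_mm2  # mm/s
    return FlowSolution(network=net, q=q, v=v, pressure=pressure, qin=float(qin))
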