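"""Shared fixtures: toy networks with hand-solvable flow, and a small
simulated ensemble reused across analysis tests."""

import numpy as np
import pytest

from microvas.flow import solve_flow
from microvas.metrics import metrics_table
from microvas.networks import CapillaryNetwork, build_ensemble, default_base_set
from microvas.protocols import build_protocol
from microvas.simulate import ensemble_signal_matrices


def straight_pipe(length=100.0, radius=5.0, n_mid=0):
    """Inlet -> outlet chain along +x (optionally subdivided)."""
    n = n_mid + 2
    xs = np.linspace(0.0, length, n)
    nodes = np.column_stack([xs, np.zeros(n), np.zeros(n)])
    segs = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return CapillaryNetwork(
        nodes=nodes, segments=segs, radii=np.full(n - 1, radius),
        inlet=0, outlet=n - 1,
    )


def parallel_pipes(radii=(5.0, 5.0), length=100.0):
    """Two segments joining the same inlet/outlet pair."""
    nodes = np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0], [length / 2, 30.0, 0.0],
                      [length / 2, -30.0, 0.0]])
    segs = np.array([[0, 2], [2, 1], [0, 3], [3, 1]])
    r = np.array([radii[0], radii[0], radii[1], radii[1]])
    return CapillaryNetwork(nodes=nodes, segments=segs, radii=r, inlet=0, outlet=1)


def y_network(r1=5.0, r2=5.0 * 2 ** 0.25, length=100.0):
    """Single stem splitting into two branches that rejoin at the outlet."""
    nodes = np.array(
        [[0.0, 0.0, 0.0], [length, 0.0, 0.0], [2 * length, 40.0, 0.0],
         [2 * length, -40.0, 0.0], [3 * length, 0.0, 0.0]]
    )
    segs = np.array([[0, 1], [1, 2], [2, 4], [1, 3], [3, 4]])
    radii = np.array([8.0, r1, r1, r2, r2])
    return CapillaryNetwork(nodes=nodes, segments=segs, radii=radii, inlet=0, outlet=4)


@pytest.fixture(scope="session")
def pipe_flow():
    net = straight_pipe()
    return solve_flow(net, 1e-3)


@pytest.fixture(scope="session")
def mini_ensemble():
    """24 perturbed 3D realisations (8 bases x 3) with cycled qin values."""
    bases = default_base_set(8, seed=5)
    return build_ensemble(bases, realisations_per_network=3, seed=17)


@pytest.fixture(scope="session")
def mini_protocols():
    return {
        "NC30": build_protocol("NC", Delta_ms=30.0),
        "NC50": build_protocol("NC", Delta_ms=50.0),
        "FC10": build_protocol("FC", tau_ms=10.0),
        "richNC": build_protocol("richNC"),
        "in-vivo": build_protocol("in-vivo"),
    }


@pytest.fixture(scope="session")
def mini_signals(mini_ensemble, mini_protocols):
    """Noise-free per-measurement signal matrices for the mini ensemble."""
    names = list(mini_protocols)
    mats = ensemble_signal_matrices(
        mini_ensemble, [mini_protocols[n] for n in names], n_spins=1500, seed=23
    )
    return dict(zip(names, mats))


@pytest.fixture(scope="session")
def mini_metrics(mini_ensemble):
    return metrics_table(mini_ensemble, seed=29)


@pytest.fixture(scope="session")
def study_ensemble():
    """Desk-scale replicate of the study ensemble: 15 bases x 20 realisations."""
    bases = default_base_set(15, seed=0)
    return build_ensemble(bases, realisations_per_network=20, seed=7)


@pytest.fixture(scope="session")
def study_protocols():
    return {
        "NC": build_protocol("NC"),
        "FC": build_protocol("FC"),
        "richNC": build_protocol("richNC"),
        "richFC": build_protocol("richFC"),
    }


@pytest.fixture(scope="session")
def study_signals(study_ensemble, study_protocols):
    names = list(study_protocols)
    mats = ensemble_signal_matrices(
        study_ensemble, [study_protocols[n] for n in names], n_spins=2000, seed=11
    )
    return dict(zip(names, mats))


@pytest.fixture(scope="session")
def study_metrics(study_ensemble):
    return metrics_table(study_ensemble, seed=3)
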