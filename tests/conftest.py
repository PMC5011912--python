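"""Shared fixtures: worked-example networks and benchmark replicates.

The two small fixture networks are synthetic reconstructions: the
published figures are not available as edge lists, so these graphs were
found by constraint search to match every printed summary statistic of
the worked examples (node/edge counts, set degrees, cross-set link
counts, and hence the p-values).
"""

from dataclasses import replace

import pytest

from neat import DESIGNS, NodeSet, build_network, run_design
from neat.simulation import SimulationDesign, PowerLawDegrees

# Directed worked example: 8 nodes, 15 arrows; with A={1,4}, B={3,5,7},
# C={2,5} it has o_A=5, i_B=4, i_C=4, o_B=4, n_AB=2, n_BC=3, i_V=15.
DIRECTED_EXAMPLE_ARCS = [
    (1, 2), (1, 7), (2, 1), (2, 4), (2, 6), (2, 7), (2, 8), (3, 2),
    (4, 1), (4, 6), (4, 7), (5, 8), (6, 1), (7, 2), (7, 5),
]

# Undirected worked example: 12 nodes, 18 edges (d_V=36); with A={1,5},
# B={2,4,7}, C={6,8} it has d_A=4, d_B=15, d_C=6, n_AB=4, n_AC=0, n_BC=5.
UNDIRECTED_EXAMPLE_EDGES = [
    (1, 2), (1, 4), (2, 4), (2, 5), (2, 6), (2, 8), (2, 11), (3, 12),
    (4, 6), (4, 8), (4, 9), (5, 7), (7, 8), (7, 9), (8, 9), (7, 10),
    (9, 12), (11, 12),
]

SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def directed_example_net():
    return build_network(DIRECTED_EXAMPLE_ARCS, "directed")


@pytest.fixture(scope="session")
def directed_example_sets():
    return {
        "A": NodeSet("A", ["1", "4"]),
        "B": NodeSet("B", ["3", "5", "7"]),
        "C": NodeSet("C", ["2", "5"]),
    }


@pytest.fixture(scope="session")
def undirected_example_net():
    return build_network(UNDIRECTED_EXAMPLE_EDGES, "undirected")


@pytest.fixture(scope="session")
def undirected_example_sets():
    return {
        "A": NodeSet("A", ["1", "5"]),
        "B": NodeSet("B", ["2", "4", "7"]),
        "C": NodeSet("C", ["6", "8"]),
    }


@pytest.fixture(scope="session")
def design_reports():
    """Three full-scale replicates of each planted-enrichment design."""
    return {
        d: [run_design(d, s) for s in SEEDS]
        for d in ("S1", "S2", "S4", "S5")
    }


@pytest.fixture(scope="session")
def h0_only_reports():
    """Full-scale S1-style replicates with no planted enrichments."""
    design = replace(DESIGNS["S1"], n_planted=0)
    return [run_design(design, s) for s in SEEDS]


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down design for fast unit-level checks."""
    return SimulationDesign(
        "small", "directed", PowerLawDegrees(exponent=4, min_degree=5),
        n_nodes=200, n_sets=10, set_size=(15, 25), n_planted=8,
    )
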