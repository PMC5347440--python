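import numpy as np
import pandas as pd
import pytest

from mvnflow.network import VascularNetwork
from mvnflow.solver import BoundaryCondition


def make_network(node_rows, vessel_rows):
    """node_rows: (id, x, y, z, boundary); vessel_rows: (id, n1, n2, d, L, type)."""
    nodes = pd.DataFrame(
        node_rows, columns=["id", "x", "y", "z", "boundary"]
    ).set_index("id")
    vessels = pd.DataFrame(
        vessel_rows, columns=["id", "n1", "n2", "diameter", "length", "type"]
    ).set_index("id")
    return VascularNetwork(nodes, vessels)


@pytest.fixture
def single_pipe():
    return make_network(
        [(0, 0, 0, 0, "pial_inflow"), (1, 100, 0, 0, "pial_outflow")],
        [(0, 0, 1, 10.0, 100.0, "C")],
    )


@pytest.fixture
def series_pipes():
    return make_network(
        [
            (0, 0, 0, 0, "pial_inflow"),
            (1, 50, 0, 0, "interior"),
            (2, 100, 0, 0, "pial_outflow"),
        ],
        [(0, 0, 1, 10.0, 50.0, "C"), (1, 1, 2, 10.0, 50.0, "C")],
    )


@pytest.fixture
def y_network():
    """Arteriole feeding two identical capillary daughters."""
    return make_network(
        [
            (0, 0, 0, 0, "pial_inflow"),
            (1, 200, 0, 0, "interior"),
            (2, 400, 100, 0, "pial_outflow"),
            (3, 400, -100, 0, "pial_outflow"),
        ],
        [
            (0, 0, 1, 10.0, 200.0, "DA"),
            (1, 1, 2, 8.0, 250.0, "C"),
            (2, 1, 3, 8.0, 250.0, "C"),
        ],
    )


@pytest.fixture
def y_bcs():
    return [
        BoundaryCondition(0, 60.0),
        BoundaryCondition(2, 10.0),
        BoundaryCondition(3, 10.0),
    ]


def random_network(rng, n_nodes=50):
    """Random connected network with two boundary nodes."""
    import networkx as nx

    g = nx.gnm_random_graph(n_nodes, int(2.2 * n_nodes), seed=int(rng.integers(2**31)))
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    nodes = sorted(g.nodes())
    relabel = {n: i for i, n in enumerate(nodes)}
    pos = rng.uniform(0, 500, size=(len(nodes), 3))
    node_rows = []
    for n in nodes:
        i = relabel[n]
        kind = "pial_inflow" if i == 0 else ("pial_outflow" if i == 1 else "interior")
        node_rows.append((i, *pos[i], kind))
    vessel_rows = []
    for vid, (u, v) in enumerate(sorted(g.edges())):
        vessel_rows.append(
            (vid, relabel[u], relabel[v], rng.uniform(3, 20), rng.uniform(20, 200), "C")
        )
    return make_network(node_rows, vessel_rows)
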