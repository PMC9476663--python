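"""Shared fixtures: deterministic alkane geometries and their group graphs."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from lssmf import (
    AlkaneSpec,
    GroupGraph,
    generate_branched_alkane,
    generate_linear_alkane,
    perceive_and_group,
)


@pytest.fixture(scope="session")
def heptane():
    return generate_linear_alkane(7)


@pytest.fixture(scope="session")
def heptane_graph(heptane):
    return perceive_and_group(heptane)


@pytest.fixture(scope="session")
def dmp24():
    return generate_branched_alkane(AlkaneSpec.two_four_dimethylpentane())


@pytest.fixture(scope="session")
def dmp24_graph(dmp24):
    return perceive_and_group(dmp24)


@pytest.fixture(scope="session")
def ttbm_graph():
    with pytest.warns(UserWarning):  # strained fixture: close H-H contacts
        return perceive_and_group(
            generate_branched_alkane(AlkaneSpec.tetra_tert_butylmethane())
        )


def path_graph(n: int) -> GroupGraph:
    """Abstract n-group chain (no geometry)."""
    return GroupGraph.from_edges(n, [(i, i + 1) for i in range(n - 1)])


def brute_force_connected_subsets(graph: GroupGraph, size: int) -> set[frozenset[int]]:
    """Independent oracle: exhaustive enumeration of connected induced
    group subsets via itertools + networkx connectivity."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_groups))
    g.add_edges_from(graph.edges)
    out = set()
    for combo in itertools.combinations(range(graph.n_groups), size):
        if nx.is_connected(g.subgraph(combo)):
            out.add(frozenset(combo))
    return out
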