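"""Shared fixtures and brute-force oracles for the test suite.

Abstract classifier/path tests use graphs whose nodes all carry the same
period-4 sequence ("ACGT" * 3, k=12) with every edge at overhang 4: any
suffix/prefix pair then agrees, so arbitrary topologies stay
overlap-consistent and reconstructible while frequencies drive ordering.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from levelasm import AssemblyGraph, AssemblyParams, GraphEdge, GraphNode

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

UNIFORM_SEQ = "ACGT" * 3  # length 12, period 4
UNIFORM_PARAMS = AssemblyParams(k=12, max_overhang=4)


def uniform_graph(
    edges: list[tuple[int, int]],
    n_nodes: int | None = None,
    freqs: dict[int, int] | None = None,
) -> AssemblyGraph:
    """Build an overlap-consistent abstract graph from an edge list."""
    ids = sorted({i for e in edges for i in e} | set(range(n_nodes or 0)))
    freqs = freqs or {}
    nodes = {
        i: GraphNode(i, UNIFORM_SEQ, freqs.get(i, 1)) for i in ids
    }
    return AssemblyGraph(
        graph_id=0,
        nodes=nodes,
        edges=[GraphEdge(s, d, 4) for s, d in edges],
    )


def component_count(node_ids: set[int], edges: list[tuple[int, int]]) -> int:
    """Hand-rolled union-find component counter (oracle)."""
    parent = {i: i for i in node_ids}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    return len({find(i) for i in node_ids})


def brute_force_paths(
    adj: dict[int, set[int]], start: int, targets: set[int]
) -> list[list[int]]:
    """Exhaustively enumerate simple paths from start; paths end at a
    target node (or at dead ends when no targets are given)."""
    results: list[list[int]] = []

    def walk(node: int, path: list[int]) -> None:
        ended = node in targets if targets else not (adj[node] - set(path))
        if ended and len(path) > 1:
            results.append(list(path))
            return
        for nxt in sorted(adj[node]):
            if nxt not in path:
                walk(nxt, path + [nxt])

    walk(start, [start])
    return results


def brute_force_ambiguous(adj: dict[int, set[int]], starts: set[int]) -> bool:
    """Oracle for cycle-or-reconvergence: some simple path from a start
    can be extended back onto itself, or some node is the endpoint of two
    distinct simple paths from the starts."""
    seen_paths_to: dict[int, int] = {}
    cycle = False

    def walk(node: int, path: list[int]) -> None:
        nonlocal cycle
        seen_paths_to[node] = seen_paths_to.get(node, 0) + 1
        for nxt in sorted(adj[node]):
            if nxt in path:
                cycle = True
                continue
            walk(nxt, path + [nxt])

    for s in sorted(starts):
        walk(s, [s])
    reconverge = any(v > 1 for k, v in seen_paths_to.items() if k not in starts)
    return cycle or reconverge


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params() -> AssemblyParams:
    return AssemblyParams(k=15, min_contig_len=100)
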