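"""Graph refinement and three-level classification.

Each connected component is refined by collapsing local cycles between
sibling nodes, its nodes are partitioned into periphery (E), junction (J)
and interior (I) sets, a cornerstone node is sought among the interior
nodes, the end sets E1/E2 are populated from the two sub-graphs its removal
produces, and the graph is assigned one of three complexity levels:

* level 1 — no cycles, |E1| = |E2| = 1: a single non-chimeric path;
* level 2 — no cycles, |E1| = 1, |E2| >= 2: one path per end node, each
  with a unique end point and hence non-chimeric;
* level 3 — everything else (multiple starts, reconvergent routes or
  cycles): paths may be chimeric.

"Cycles" are detected by tracing paths outward from E1: a path that can
double back on itself (directed cycle) or reconverge with an alternative
route (a node reachable two different ways) makes path choice ambiguous,
so either condition forces level 3.
"""
from __future__ import annotations

from itertools import combinations

import networkx as nx

from .kmer_graph import boundary_overhang
from .params import AssemblyParams
from .records import AssemblyGraph, GraphEdge


def _undirected(graph: AssemblyGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e.src, e.dst) for e in graph.edges)
    return g


def _out_adj(graph: AssemblyGraph) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in graph.nodes}
    for e in graph.edges:
        adj[e.src].add(e.dst)
    return adj


def _in_adj(graph: AssemblyGraph) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in graph.nodes}
    for e in graph.edges:
        adj[e.dst].add(e.src)
    return adj


def collapse_local_cycles(
    graph: AssemblyGraph, params: AssemblyParams
) -> AssemblyGraph:
    """Merge sibling pairs (nodes sharing a parent) joined by a direct edge.

    The higher-frequency sibling's sequence and coverage are kept and all
    in/out edges of both siblings are united on it.  After every merge all
    edges incident to the merged node are re-validated against the overhang
    criterion — merges can stretch implied distances beyond it — and
    invalid ones dropped.  Repeats until no mergeable sibling pair remains;
    non-local cycles passing through several junctions are untouched.
    """
    while True:
        pair = _find_sibling_pair(graph)
        if pair is None:
            return graph
        _merge_pair(graph, pair, params)


def _find_sibling_pair(graph: AssemblyGraph) -> tuple[int, int] | None:
    out = _out_adj(graph)
    linked = {(e.src, e.dst) for e in graph.edges}
    for parent in sorted(out):
        children = sorted(out[parent])
        for a, b in combinations(children, 2):
            if (a, b) in linked or (b, a) in linked:
                return (a, b)
    return None


def _merge_pair(
    graph: AssemblyGraph, pair: tuple[int, int], params: AssemblyParams
) -> None:
    a, b = (
        graph.nodes[pair[0]],
        graph.nodes[pair[1]],
    )
    keep, drop = sorted(
        (a, b), key=lambda n: (-n.frequency, n.sequence, n.node_id)
    )
    new_edges: dict[tuple[int, int], int] = {}
    for e in graph.edges:
        src = keep.node_id if e.src == drop.node_id else e.src
        dst = keep.node_id if e.dst == drop.node_id else e.dst
        if src == dst:
            continue
        key = (src, dst)
        if key not in new_edges or e.overhang < new_edges[key]:
            new_edges[key] = e.overhang
    del graph.nodes[drop.node_id]
    edges: list[GraphEdge] = []
    for (src, dst), overhang in sorted(new_edges.items()):
        if src == keep.node_id or dst == keep.node_id:
            d = boundary_overhang(graph.nodes[src], graph.nodes[dst], params)
            if d is None:
                continue
            overhang = d
        edges.append(GraphEdge(src, dst, overhang))
    graph.edges = edges


def partition_nodes(graph: AssemblyGraph) -> tuple[set[int], set[int], set[int]]:
    """Partition node ids into periphery/junction/interior sets by
    undirected degree: 1 -> E, >2 -> J, otherwise (0 or 2) -> I."""
    g = _undirected(graph)
    set_E, set_J, set_I = set(), set(), set()
    for node_id in graph.nodes:
        degree = g.degree(node_id)
        if degree == 1:
            set_E.add(node_id)
        elif degree > 2:
            set_J.add(node_id)
        else:
            set_I.add(node_id)
    graph.set_E, graph.set_J, graph.set_I = set_E, set_J, set_I
    return set_E, set_J, set_I


def select_cornerstone(graph: AssemblyGraph) -> int | None:
    """Pick the highest-frequency interior node whose removal splits the
    graph into exactly two connected sub-graphs.

    Candidates are interior (set I) nodes sorted by representative
    frequency descending, ties broken by lexicographic sequence.  A node
    with a circumventing path (removal leaves one component) or whose
    removal shatters the graph into more than two pieces is skipped.
    Returns None when no candidate qualifies (the graph then falls back to
    level 3).
    """
    g = _undirected(graph)
    candidates = sorted(
        graph.set_I,
        key=lambda i: (-graph.nodes[i].frequency, graph.nodes[i].sequence, i),
    )
    for cand in candidates:
        rest = [n for n in g.nodes if n != cand]
        if not rest:
            continue
        if nx.number_connected_components(g.subgraph(rest)) == 2:
            graph.cornerstone = cand
            return cand
    graph.cornerstone = None
    return None


def populate_end_sets(
    graph: AssemblyGraph, cornerstone: int
) -> tuple[set[int], set[int]]:
    """Split off the two sub-graphs left by cornerstone removal and collect
    their periphery (set E) members: the smaller sub-graph's become E1, the
    larger's E2.  Equal sizes are resolved deterministically — the
    sub-graph containing the smallest node id becomes E1."""
    g = _undirected(graph)
    rest = [n for n in g.nodes if n != cornerstone]
    comps = [set(c) for c in nx.connected_components(g.subgraph(rest))]
    if len(comps) != 2:
        raise ValueError("cornerstone removal must yield exactly two sub-graphs")
    comps.sort(key=lambda c: (len(c), min(c)))
    e1 = graph.set_E & comps[0]
    e2 = graph.set_E & comps[1]
    graph.E1, graph.E2 = e1, e2
    return e1, e2


def _oriented_out(graph: AssemblyGraph, starts: set[int]) -> dict[int, set[int]]:
    """Forward adjacency, or the reversed one when every start is a sink.

    The orientation each component is kept in is an arbitrary strand
    choice; when the E1 side happens to sit at the downstream end, paths
    are traced against edge direction so classification and enumeration do
    not depend on strand."""
    out = _out_adj(graph)
    if starts and all(not out[s] for s in starts):
        inn = _in_adj(graph)
        if any(inn[s] for s in starts):
            return inn
    return out


def detect_cycles(graph: AssemblyGraph, e1: set[int]) -> bool:
    """True iff tracing paths from E1 can double back or reconverge:
    a directed cycle is reachable from E1, or some node is reachable from
    E1 along two distinct routes."""
    if not e1:
        raise ValueError("E1 must be non-empty")
    adj = _oriented_out(graph, e1)
    reachable: set[int] = set()
    stack = sorted(e1)
    while stack:
        node = stack.pop()
        if node in reachable:
            continue
        reachable.add(node)
        stack.extend(adj[node] - reachable)
    # reconvergence: >1 predecessor within the reachable sub-graph
    indeg = {n: 0 for n in reachable}
    for src in reachable:
        for dst in adj[src]:
            if dst in reachable:
                indeg[dst] += 1
    if any(count > 1 for count in indeg.values()):
        return True
    # directed cycle within the reachable sub-graph
    sub = nx.DiGraph()
    sub.add_nodes_from(reachable)
    for src in reachable:
        sub.add_edges_from((src, d) for d in adj[src] if d in reachable)
    return not nx.is_directed_acyclic_graph(sub)


def classify_graph(graph: AssemblyGraph) -> int:
    """Run the full classification: partition, cornerstone, end sets,
    cycle tracing, level assignment.  Assumes a refined component.

    Levels 1 and 2 require a cornerstone and a unique traversal anchor:
    exactly one source node (traced forward) or exactly one sink node
    (traced against edge direction — the component's stored orientation is
    an arbitrary strand choice).  When the anchor differs from the
    periphery-based end sets — compaction can absorb a junction into the
    stem node so that no degree-1 start exists — E1/E2 are re-anchored to
    the traversal start and its reachable end nodes, keeping the level
    semantics (level 1: one path; level 2: one path per end node) exact.
    """
    partition_nodes(graph)
    if len(graph.nodes) == 1:
        # a singleton composite node is a complete unambiguous fragment
        only = next(iter(graph.nodes))
        graph.cornerstone = None
        graph.E1, graph.E2 = {only}, {only}
        graph.has_cycles = False
        graph.level = 1
        return 1
    cornerstone = select_cornerstone(graph)
    if cornerstone is not None:
        e1, e2 = populate_end_sets(graph, cornerstone)

    out = _out_adj(graph)
    inn = _in_adj(graph)
    sources = sorted(i for i in graph.nodes if not inn[i])
    sinks = sorted(i for i in graph.nodes if not out[i])
    if len(sources) == 1:
        start, adj, ends_pool = sources[0], out, sinks
    elif len(sinks) == 1:
        start, adj, ends_pool = sinks[0], inn, sources
    else:
        start, adj, ends_pool = None, None, []

    if start is not None:
        graph.has_cycles = detect_cycles(graph, {start})
    else:
        anchors = graph.E1 or set(sources) or set(sinks)
        graph.has_cycles = detect_cycles(graph, anchors) if anchors else True

    if cornerstone is None or start is None or graph.has_cycles:
        graph.level = 3
        return 3
    reachable: set[int] = set()
    stack = [start]
    while stack:
        node = stack.pop()
        if node not in reachable:
            reachable.add(node)
            stack.extend(adj[node] - reachable)
    if reachable != set(graph.nodes):
        graph.level = 3
        return 3
    ends = set(ends_pool)
    graph.E1, graph.E2 = {start}, ends
    graph.level = 1 if len(ends) == 1 else 2
    return graph.level


def classification_report(graphs: list[AssemblyGraph]) -> str:
    """Per-graph TSV report of classification state."""
    header = (
        "graph_id\tn_nodes\tn_E\tn_J\tn_I\tcornerstone\tn_E1\tn_E2"
        "\thas_cycles\tlevel"
    )
    rows = [header]
    for g in graphs:
        corner = "-" if g.cornerstone is None else str(g.cornerstone)
        rows.append(
            f"{g.graph_id}\t{len(g.nodes)}\t{len(g.set_E)}\t{len(g.set_J)}"
            f"\t{len(g.set_I)}\t{corner}\t{len(g.E1)}\t{len(g.E2)}"
            f"\t{int(g.has_cycles)}\t{g.level}"
        )
    return "\n".join(rows) + "\n"
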