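"""Path enumeration, coverage ranking and contig reconstruction.

Paths start at an E1 node, traverse the cornerstone (when one exists) and
end at an E2 node.  Enumeration is a coverage-greedy depth-first search —
neighbours are visited in descending representative-frequency order — with
each node used at most once per path, so cyclic graphs contribute finitely
many alternatives.  The first ``paths_per_start`` complete paths per start
are pooled and the top ``contigs_per_graph`` by mean per-base coverage
become contigs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .classify import classify_graph, collapse_local_cycles
from .kmer_graph import (
    dedupe_mirror_components,
    extract_components,
    extract_kmers,
    merge_overlapping_nodes,
    place_edges,
)
from .params import AssemblyParams
from .records import (
    AssemblyGraph,
    ContigRecord,
    LEVEL_LABELS,
    SequenceRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class GraphPath:
    """An ordered walk through one graph, from a start node to an end node.

    ``node_sequence`` is in traversal order; when the component's stored
    orientation runs against the traversal (``reversed_traversal``), the
    forward edge order is the reverse of the traversal order.
    """

    node_sequence: list[int]
    sequence: str = ""
    mean_cover: float = 0.0
    partial: bool = False
    reversed_traversal: bool = False

    def forward_order(self) -> list[int]:
        if self.reversed_traversal:
            return list(reversed(self.node_sequence))
        return list(self.node_sequence)


def enumerate_paths(
    graph: AssemblyGraph,
    start: int,
    limit: int | None = None,
    params: AssemblyParams | None = None,
) -> list[GraphPath]:
    """Trace up to ``limit`` complete paths from ``start``.

    A path is complete when it reaches an end node (E2 membership; any
    dead end when E2 is empty) having passed through the cornerstone if
    one exists.  Neighbours are explored in descending frequency order
    (ties: lexicographic sequence), each node at most once per path.  If
    no complete path exists the longest partial path is returned alone,
    flagged partial.
    """
    params = params or AssemblyParams()
    limit = params.paths_per_start if limit is None else limit
    out: dict[int, set[int]] = {i: set() for i in graph.nodes}
    inn: dict[int, set[int]] = {i: set() for i in graph.nodes}
    for e in graph.edges:
        out[e.src].add(e.dst)
        inn[e.dst].add(e.src)
    reversed_traversal = not out[start] and bool(inn[start])
    adj = inn if reversed_traversal else out
    order = {
        n: sorted(
            adj[n],
            key=lambda i: (-graph.nodes[i].frequency, graph.nodes[i].sequence, i),
        )
        for n in graph.nodes
    }
    targets = graph.E2 if graph.E2 and start not in graph.E2 else set()
    need_cornerstone = (
        graph.cornerstone is not None and graph.cornerstone != start
    )

    complete: list[GraphPath] = []
    best_partial: list[int] = [start]
    path: list[int] = [start]
    on_path = {start}

    def is_complete(node: int) -> bool:
        if need_cornerstone and graph.cornerstone not in on_path:
            return False
        if targets:
            return node in targets
        return not any(n not in on_path for n in order[node])

    def dfs(node: int) -> bool:
        nonlocal best_partial
        if is_complete(node) and len(path) > 1:
            complete.append(
                GraphPath(list(path), reversed_traversal=reversed_traversal)
            )
            return len(complete) >= limit
        if len(path) > len(best_partial):
            best_partial = list(path)
        for nxt in order[node]:
            if nxt in on_path:
                continue
            path.append(nxt)
            on_path.add(nxt)
            if dfs(nxt):
                return True
            path.pop()
            on_path.remove(nxt)
        return False

    if len(graph.nodes) == 1:
        complete.append(GraphPath([start]))
    else:
        dfs(start)
    if not complete:
        results = [
            GraphPath(
                best_partial, partial=True, reversed_traversal=reversed_traversal
            )
        ]
    else:
        results = complete
    for p in results:
        p.sequence, cover = reconstruct_with_cover(graph, p, params)
        p.mean_cover = sum(cover) / len(cover)
    return results


def reconstruct_with_cover(
    graph: AssemblyGraph, path: GraphPath, params: AssemblyParams
) -> tuple[str, list[int]]:
    """Reconstruct the nucleotide sequence and per-base coverage along a
    path, appending only the novel bases contributed across each edge."""
    order = path.forward_order()
    overhang = {(e.src, e.dst): e.overhang for e in graph.edges}
    k = params.k
    first = graph.nodes[order[0]]
    seq_parts = [first.sequence]
    cover = list(first.per_base_cover)
    for src, dst in zip(order, order[1:]):
        if (src, dst) not in overhang:
            raise ValueError(f"path nodes {src}->{dst} are not edge-connected")
        d = overhang[(src, dst)]
        src_node, dst_node = graph.nodes[src], graph.nodes[dst]
        if src_node.sequence[-(k - d) :] != dst_node.sequence[: k - d]:
            raise ValueError(
                f"inconsistent overlap on edge {src}->{dst} (overhang {d})"
            )
        seq_parts.append(dst_node.sequence[k - d :])
        cover.extend(dst_node.per_base_cover[k - d :])
    return "".join(seq_parts), cover


def reconstruct_sequence(
    graph: AssemblyGraph, path: GraphPath, params: AssemblyParams | None = None
) -> str:
    return reconstruct_with_cover(graph, path, params or AssemblyParams())[0]


def path_mean_coverage(
    graph: AssemblyGraph, path: GraphPath, params: AssemblyParams | None = None
) -> float:
    """Mean of the per-base coverage of the reconstructed path sequence."""
    _, cover = reconstruct_with_cover(graph, path, params or AssemblyParams())
    return sum(cover) / len(cover)


def select_top_paths(paths: list[GraphPath], n: int) -> list[GraphPath]:
    """Keep the ``n`` paths with highest mean coverage (ties: longer
    sequence first, then lexicographic); deterministic in input order."""
    if not 1 <= n <= 5:
        raise ValueError("n must be in [1, 5]")
    ranked = sorted(
        paths, key=lambda p: (-p.mean_cover, -len(p.sequence), p.sequence)
    )
    return ranked[:n]


def candidate_paths(
    graph: AssemblyGraph, params: AssemblyParams
) -> list[GraphPath]:
    """Pool paths from every start node of a classified graph.

    Starts are the E1 nodes; a graph classified level 3 without end sets
    falls back to its source nodes (or its highest-frequency node when
    every node sits on a cycle).  Partial paths are used only when no
    complete path exists anywhere in the graph.
    """
    starts = sorted(
        graph.E1,
        key=lambda i: (-graph.nodes[i].frequency, graph.nodes[i].sequence, i),
    )
    if not starts:
        indeg = {i: 0 for i in graph.nodes}
        for e in graph.edges:
            indeg[e.dst] += 1
        sources = [i for i, d in indeg.items() if d == 0]
        if not sources:
            sources = [
                min(
                    graph.nodes,
                    key=lambda i: (
                        -graph.nodes[i].frequency,
                        graph.nodes[i].sequence,
                        i,
                    ),
                )
            ]
        starts = sorted(
            sources,
            key=lambda i: (-graph.nodes[i].frequency, graph.nodes[i].sequence, i),
        )
    pooled: list[GraphPath] = []
    for start in starts:
        pooled.extend(
            enumerate_paths(graph, start, params.paths_per_start, params)
        )
    complete = [p for p in pooled if not p.partial]
    return complete if complete else pooled


def assemble(
    reads: list[SequenceRecord], params: AssemblyParams | None = None
) -> list[ContigRecord]:
    """Full pipeline: kmers -> composite nodes -> edges -> components ->
    refinement -> classification -> paths -> coverage-ranked contigs.

    Every graph contributes candidates regardless of expression level;
    contigs shorter than ``min_contig_len`` are dropped and ids are
    assigned sequentially from 0.
    """
    params = params or AssemblyParams()
    if not reads:
        raise ValueError("no reads supplied")
    kmers = extract_kmers(reads, params)
    nodes = merge_overlapping_nodes(kmers)
    edges = place_edges(nodes, params)
    graphs = dedupe_mirror_components(extract_components(nodes, edges))
    contigs: list[ContigRecord] = []
    for graph in graphs:
        collapse_local_cycles(graph, params)
        classify_graph(graph)
        pool = candidate_paths(graph, params)
        n = 1 if graph.level == 1 else params.contigs_per_graph
        for p in select_top_paths(pool, n):
            if len(p.sequence) >= params.min_contig_len:
                contigs.append(
                    ContigRecord(
                        contig_id=len(contigs),
                        level_label=LEVEL_LABELS[graph.level],
                        sequence=p.sequence,
                        mean_cover=p.mean_cover,
                        graph_id=graph.graph_id,
                    )
                )
    if not contigs:
        logger.warning("assembly produced zero contigs above the length cutoff")
    return contigs


def assemble_graphs(
    reads: list[SequenceRecord], params: AssemblyParams | None = None
) -> list[AssemblyGraph]:
    """Run the pipeline up to and including classification, returning the
    refined, classified graphs (for reports and inspection)."""
    params = params or AssemblyParams()
    kmers = extract_kmers(reads, params)
    nodes = merge_overlapping_nodes(kmers)
    edges = place_edges(nodes, params)
    graphs = dedupe_mirror_components(extract_components(nodes, edges))
    for graph in graphs:
        collapse_local_cycles(graph, params)
        classify_graph(graph)
    return graphs


def contig_table(contigs: list[ContigRecord]) -> str:
    """Per-contig TSV (contig_id, level, length, mean_cover, graph_id)."""
    rows = ["contig_id\tlevel\tlength\tmean_cover\tgraph_id"]
    for c in contigs:
        rows.append(
            f"{c.contig_id}\t{c.level_label}\t{len(c.sequence)}"
            f"\t{c.mean_cover:.3f}\t{c.graph_id}"
        )
    return "\n".join(rows) + "\n"
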