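"""De Bruijn-style graph construction from short reads.

The stages mirror the assembly narrative: count kmers from both strands,
drop low-complexity and ambiguous words, collapse unambiguous (k-1)-overlap
chains into composite nodes, place overhang edges between node boundaries,
and extract connected components.  Because both strands are counted, every
component appears twice (once per orientation); `dedupe_mirror_components`
keeps one deterministic orientation of each.
"""
from __future__ import annotations

import logging
from collections import Counter

import networkx as nx

from .params import AssemblyParams
from .records import (
    AssemblyGraph,
    GraphEdge,
    GraphNode,
    KmerRecord,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)


def is_low_complexity(word: str, fraction: float = 0.8) -> bool:
    """True iff a single nucleotide type makes up strictly more than
    ``fraction`` of the word (e.g. >80% of one base by default)."""
    if not word:
        raise ValueError("empty word")
    top = max(Counter(word).values())
    return top / len(word) > fraction


def extract_kmers(
    reads: list[SequenceRecord], params: AssemblyParams
) -> list[KmerRecord]:
    """Count all length-k windows of every read and its reverse complement.

    Kmers containing N and low-complexity kmers are removed after counting.
    The result is sorted by count descending, ties broken lexicographically.
    """
    if not reads:
        raise ValueError("no reads supplied")
    k = params.k
    counts: Counter[str] = Counter()
    for rec in reads:
        for seq in (rec.sequence, reverse_complement(rec.sequence)):
            n = len(seq) - k + 1
            if n > 0:
                counts.update(seq[i : i + k] for i in range(n))
    records = [
        KmerRecord(word, count)
        for word, count in counts.items()
        if "N" not in word
        and not is_low_complexity(word, params.low_complexity_fraction)
    ]
    if not records:
        logger.warning("all %d distinct kmers were filtered out", len(counts))
    records.sort(key=lambda r: (-r.count, r.word))
    return records


def merge_overlapping_nodes(kmers: list[KmerRecord]) -> list[GraphNode]:
    """Collapse maximal unambiguous (k-1)-overlap chains into composite nodes.

    Two kmers u, v are chained when v is u's only successor *and* u is v's
    only predecessor; merging stops at any branching overlap.  A composite
    keeps the maximum constituent count as representative frequency and the
    constituent counts positionally as per-base coverage.
    """
    if not kmers:
        return []
    k = len(kmers[0].word)
    count_of = {rec.word: rec.count for rec in kmers}
    if len(count_of) != len(kmers):
        raise ValueError("kmers must be distinct")

    def successors(w: str) -> list[str]:
        stem = w[1:]
        return [stem + c for c in "ACGT" if stem + c in count_of]

    def predecessors(w: str) -> list[str]:
        stem = w[:-1]
        return [c + stem for c in "ACGT" if c + stem in count_of]

    def out_link(w: str) -> str | None:
        succ = successors(w)
        if len(succ) == 1 and len(predecessors(succ[0])) == 1 and succ[0] != w:
            return succ[0]
        return None

    def in_link(w: str) -> str | None:
        pred = predecessors(w)
        if len(pred) == 1 and len(successors(pred[0])) == 1 and pred[0] != w:
            return pred[0]
        return None

    nodes: list[GraphNode] = []
    visited: set[str] = set()

    def build_chain(start: str) -> None:
        chain = [start]
        visited.add(start)
        nxt = out_link(start)
        while nxt is not None and nxt not in visited:
            chain.append(nxt)
            visited.add(nxt)
            nxt = out_link(nxt)
        seq = chain[0] + "".join(w[-1] for w in chain[1:])
        chain_counts = [count_of[w] for w in chain]
        cover = chain_counts + [chain_counts[-1]] * (k - 1)
        nodes.append(GraphNode(len(nodes), seq, max(chain_counts), cover))

    for word in sorted(count_of):
        if word not in visited and in_link(word) is None:
            build_chain(word)
    # anything left sits on purely cyclic unambiguous chains; break each at
    # its lexicographically smallest member
    for word in sorted(count_of):
        if word not in visited:
            build_chain(word)
    return nodes


def place_edges(nodes: list[GraphNode], params: AssemblyParams) -> list[GraphEdge]:
    """Place a directed edge src->dst whenever the terminal k-window of src
    and the initial k-window of dst are identical except for d overhanging
    nucleotides, d in [1, max_overhang]; the smallest qualifying d is kept.
    """
    k = params.k
    for node in nodes:
        if len(node.sequence) < k:
            raise ValueError(f"node {node.node_id} shorter than k")
    prefix_index: dict[tuple[int, str], list[int]] = {}
    for node in nodes:
        for d in range(1, params.max_overhang + 1):
            key = (d, node.sequence[: k - d])
            prefix_index.setdefault(key, []).append(node.node_id)
    edges: list[GraphEdge] = []
    seen: set[tuple[int, int]] = set()
    for node in nodes:
        for d in range(1, params.max_overhang + 1):
            suffix = node.sequence[-(k - d) :]
            for dst in prefix_index.get((d, suffix), ()):
                if dst != node.node_id and (node.node_id, dst) not in seen:
                    seen.add((node.node_id, dst))
                    edges.append(GraphEdge(node.node_id, dst, d))
    edges.sort(key=lambda e: (e.src, e.dst))
    return edges


def boundary_overhang(
    src: GraphNode, dst: GraphNode, params: AssemblyParams
) -> int | None:
    """Smallest d in [1, max_overhang] for which the src/dst boundary
    windows agree over k-d bases, or None if no d qualifies."""
    k = params.k
    for d in range(1, params.max_overhang + 1):
        if src.sequence[-(k - d) :] == dst.sequence[: k - d]:
            return d
    return None


def extract_components(
    nodes: list[GraphNode], edges: list[GraphEdge]
) -> list[AssemblyGraph]:
    """Partition nodes into connected components (edges treated as
    undirected for connectivity), returned largest-first."""
    by_id = {node.node_id: node for node in nodes}
    for edge in edges:
        if edge.src not in by_id or edge.dst not in by_id:
            raise ValueError("edge references unknown node")
    g = nx.Graph()
    g.add_nodes_from(by_id)
    g.add_edges_from((e.src, e.dst) for e in edges)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    graphs = []
    for gid, members in enumerate(comps):
        member_set = set(members)
        graphs.append(
            AssemblyGraph(
                graph_id=gid,
                nodes={i: by_id[i] for i in members},
                edges=[e for e in edges if e.src in member_set],
            )
        )
    return graphs


def dedupe_mirror_components(graphs: list[AssemblyGraph]) -> list[AssemblyGraph]:
    """Keep one orientation of every mirror pair of components.

    Counting kmers from both strands makes each component appear once per
    orientation.  Components are grouped by a strand-canonical signature of
    their node sequences; within a group the orientation whose
    highest-frequency node sequence is lexicographically <= its reverse
    complement is kept (deterministic).
    """
    groups: dict[tuple[str, ...], list[AssemblyGraph]] = {}
    for graph in graphs:
        fwd = tuple(sorted(n.sequence for n in graph.nodes.values()))
        rev = tuple(sorted(reverse_complement(s) for s in fwd))
        groups.setdefault(min(fwd, rev), []).append(graph)
    kept = []
    for gs in groups.values():
        kept.append(min(gs, key=_orientation_rank))
    kept.sort(key=lambda g: g.graph_id)
    for new_id, graph in enumerate(kept):
        graph.graph_id = new_id
    return kept


def _orientation_rank(graph: AssemblyGraph) -> tuple[int, str]:
    top = min(graph.nodes.values(), key=lambda n: (-n.frequency, n.sequence))
    preferred = top.sequence <= reverse_complement(top.sequence)
    return (0 if preferred else 1, top.sequence)


def to_gfa(graph: AssemblyGraph, params: AssemblyParams) -> str:
    """Render one component as GFA v1 (S lines = node sequences, L lines =
    edges with overlap k-d) for external inspection."""
    lines = ["H\tVN:Z:1.0"]
    for node_id in sorted(graph.nodes):
        node = graph.nodes[node_id]
        lines.append(f"S\t{node_id}\t{node.sequence}\tdp:i:{node.frequency}")
    for edge in sorted(graph.edges, key=lambda e: (e.src, e.dst)):
        lines.append(
            f"L\t{edge.src}\t+\t{edge.dst}\t+\t{params.k - edge.overhang}M"
        )
    return "\n".join(lines) + "\n"
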