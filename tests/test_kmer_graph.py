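from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from levelasm import (
    AssemblyParams,
    GraphEdge,
    GraphNode,
    KmerRecord,
    SequenceRecord,
    dedupe_mirror_components,
    extract_components,
    extract_kmers,
    is_low_complexity,
    merge_overlapping_nodes,
    place_edges,
    reverse_complement,
)
from levelasm.simulate import random_transcript

from conftest import component_count


# ---------------------------------------------------------------- kmers

@pytest.mark.parametrize(
    "word, expected",
    [
        ("A" * 40, True),                      # homopolymer
        ("A" * 33 + "CGT" * 2 + "C", True),    # 33/40 = 0.825 > 0.8
        ("A" * 32 + "CGTCGTCG", False),        # 32/40 = 0.800, strict >
        ("ACGT" * 10, False),                  # uniform composition
    ],
)
def test_low_complexity_boundary_is_strict(word, expected):
    assert len(word) == 40
    assert is_low_complexity(word, 0.8) is expected


@given(st.text(alphabet="ACGT", min_size=1, max_size=60))
def test_low_complexity_matches_counting_oracle(word):
    frac = max(Counter(word).values()) / len(word)
    assert is_low_complexity(word, 0.8) == (frac > 0.8)


def test_extract_kmers_counts_both_strands(rng):
    seq = random_transcript(rng, 200)
    params = AssemblyParams(k=40)
    records = extract_kmers([SequenceRecord("r", seq)], params)
    # 161 windows per strand; a random 200-mer has no repeated kmers
    assert sum(r.count for r in records) == 2 * (200 - 40 + 1)
    words = {r.word for r in records}
    assert all(reverse_complement(w) in words for w in words)


def test_extract_kmers_matches_window_dictionary_oracle(rng):
    reads = [SequenceRecord(f"r{i}", random_transcript(rng, 60)) for i in range(5)]
    params = AssemblyParams(k=15)
    oracle: Counter = Counter()
    for r in reads:
        for s in (r.sequence, reverse_complement(r.sequence)):
            for i in range(len(s) - 14):
                oracle[s[i : i + 15]] += 1
    got = {r.word: r.count for r in extract_kmers(reads, params)}
    expected = {
        w: c
        for w, c in oracle.items()
        if not is_low_complexity(w, 0.8)
    }
    assert got == expected


def test_duplicate_reads_double_every_count(rng):
    read = SequenceRecord("r", random_transcript(rng, 120))
    params = AssemblyParams(k=20)
    single = {r.word: r.count for r in extract_kmers([read], params)}
    double = {
        r.word: r.count for r in extract_kmers([read, read], params)
    }
    assert double == {w: 2 * c for w, c in single.items()}


def test_read_shorter_than_k_contributes_nothing(rng):
    short = SequenceRecord("s", "ACGTACGTACGTAC")
    long = SequenceRecord("l", random_transcript(rng, 50))
    params = AssemblyParams(k=20)
    with_short = extract_kmers([long, short], params)
    without = extract_kmers([long], params)
    assert with_short == without


def test_kmers_sorted_by_count_then_word():
    reads = [SequenceRecord("r", "ACGTACGTACGTACG" + "ACGTACGTACGTACG")]
    records = extract_kmers(reads, AssemblyParams(k=15))
    keys = [(-r.count, r.word) for r in records]
    assert keys == sorted(keys)


def test_n_containing_kmers_are_dropped():
    reads = [SequenceRecord("r", "ACGTACGTACGTANGTACGTACGTACGT")]
    records = extract_kmers(reads, AssemblyParams(k=14))
    assert all("N" not in r.word for r in records)


# ---------------------------------------------------------------- merging

def _kmers_of(seq: str, k: int) -> list[KmerRecord]:
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    return [KmerRecord(w, c) for w, c in sorted(counts.items())]


def test_unique_kmer_transcript_merges_to_single_node(rng):
    tx = random_transcript(rng, 300)
    nodes = merge_overlapping_nodes(_kmers_of(tx, 15))
    assert len(nodes) == 1
    assert nodes[0].sequence == tx
    assert len(nodes[0].per_base_cover) == 300
    assert nodes[0].frequency == 1


def test_non_overlapping_kmers_stay_singletons():
    kmers = [KmerRecord("A" * 7 + "CCGGTTA", 3), KmerRecord("T" * 7 + "GGCCAAT", 5)]
    nodes = merge_overlapping_nodes(kmers)
    assert len(nodes) == 2
    assert sorted(n.frequency for n in nodes) == [3, 5]


def test_branching_overlap_stops_merge(rng):
    # A -> B and A -> C share A's (k-1)-suffix: no merge across the branch
    stem = random_transcript(rng, 15)
    b = stem[1:] + "A"
    c = stem[1:] + "C"
    nodes = merge_overlapping_nodes(
        [KmerRecord(stem, 2), KmerRecord(b, 1), KmerRecord(c, 1)]
    )
    assert len(nodes) == 3


def test_composite_frequency_and_cover_follow_constituents(rng):
    tx = random_transcript(rng, 40)
    k = 15
    kmers = [
        KmerRecord(tx[i : i + k], count)
        for i, count in zip(range(len(tx) - k + 1), range(1, 100))
    ]
    (node,) = merge_overlapping_nodes(kmers)
    m = len(kmers)
    assert node.frequency == m  # max constituent count
    assert node.per_base_cover == list(range(1, m + 1)) + [m] * (k - 1)
    # total coverage mass is preserved positionally
    assert len(node.per_base_cover) == len(tx)


# ---------------------------------------------------------------- edges

def _quadratic_edge_oracle(nodes, params):
    found = set()
    k = params.k
    for a in nodes:
        for b in nodes:
            if a.node_id == b.node_id:
                continue
            for d in range(1, params.max_overhang + 1):
                if a.sequence[-(k - d):] == b.sequence[: k - d]:
                    found.add((a.node_id, b.node_id, d))
                    break
    return found


def test_adjacent_nodes_get_overhang_one_edge(rng):
    params = AssemblyParams(k=15)
    a = random_transcript(rng, 15)
    b = a[1:] + "G"
    nodes = [GraphNode(0, a, 1), GraphNode(1, b, 1)]
    edges = place_edges(nodes, params)
    assert any(e.src == 0 and e.dst == 1 and e.overhang == 1 for e in edges)


def test_overlap_beyond_max_overhang_gives_no_edge(rng):
    params = AssemblyParams(k=15, max_overhang=5)
    a = random_transcript(rng, 15)
    b = a[6:] + random_transcript(rng, 6)  # would need d=6
    edges = place_edges([GraphNode(0, a, 1), GraphNode(1, b, 1)], params)
    assert not any(e.src == 0 and e.dst == 1 for e in edges)


def test_place_edges_matches_quadratic_oracle(rng):
    params = AssemblyParams(k=15, max_overhang=5)
    for _ in range(20):
        nodes = []
        base = random_transcript(rng, 30)
        for i in range(20):
            if i % 3 == 0:
                seq = random_transcript(rng, int(rng.integers(15, 25)))
            else:  # engineered overlaps off a common base
                d = int(rng.integers(1, 7))
                seq = base[d : 15] + random_transcript(rng, d + 3)
            nodes.append(GraphNode(i, seq if len(seq) >= 15 else base[:15], 1))
        got = {(e.src, e.dst, e.overhang) for e in place_edges(nodes, params)}
        assert got == _quadratic_edge_oracle(nodes, params)


# ---------------------------------------------------------------- components

def test_components_partition_nodes_and_sort_largest_first(rng):
    params = AssemblyParams(k=15)
    nodes = [GraphNode(i, random_transcript(rng, 15), 1) for i in range(6)]
    edges = [GraphEdge(0, 1, 2), GraphEdge(1, 2, 2), GraphEdge(3, 4, 2)]
    graphs = extract_components(nodes, edges)
    sizes = [len(g.nodes) for g in graphs]
    assert sizes == sorted(sizes, reverse=True)
    assert sum(sizes) == 6
    assert component_count(set(range(6)), [(0, 1), (1, 2), (3, 4)]) == len(graphs)


def test_isolated_nodes_form_their_own_components(rng):
    nodes = [GraphNode(i, random_transcript(rng, 15), 1) for i in range(3)]
    graphs = extract_components(nodes, [])
    assert len(graphs) == 3
    assert all(len(g.nodes) == 1 for g in graphs)


def test_edge_with_unknown_endpoint_rejected(rng):
    nodes = [GraphNode(0, random_transcript(rng, 15), 1)]
    with pytest.raises(ValueError):
        extract_components(nodes, [GraphEdge(0, 9, 1)])


def test_random_partition_matches_union_find_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(2, 30))
        pair_count = int(rng.integers(0, n * 2))
        raw = [
            tuple(sorted(rng.choice(n, size=2, replace=False).tolist()))
            for _ in range(pair_count)
        ]
        pairs = sorted(set(raw))
        nodes = [GraphNode(i, random_transcript(rng, 15), 1) for i in range(n)]
        edges = [GraphEdge(a, b, 1) for a, b in pairs]
        graphs = extract_components(nodes, edges)
        assert len(graphs) == component_count(set(range(n)), pairs)
        assert sum(len(g.nodes) for g in graphs) == n


# ---------------------------------------------------------------- mirrors

def test_mirror_components_deduplicated(rng):
    tx = random_transcript(rng, 120)
    params = AssemblyParams(k=15)
    reads = [SequenceRecord("f", tx), SequenceRecord("r", reverse_complement(tx))]
    kmers = extract_kmers(reads, params)
    nodes = merge_overlapping_nodes(kmers)
    graphs = extract_components(nodes, place_edges(nodes, params))
    assert len(graphs) == 2  # one per strand before deduplication
    kept = dedupe_mirror_components(graphs)
    assert len(kept) == 1
    (node,) = kept[0].nodes.values()
    assert node.sequence in (tx, reverse_complement(tx))


def test_dedupe_is_deterministic_under_input_order(rng):
    tx1, tx2 = (random_transcript(rng, 90) for _ in range(2))
    params = AssemblyParams(k=15)
    reads = [SequenceRecord("a", tx1), SequenceRecord("b", tx2)]
    kmers = extract_kmers(reads, params)
    nodes = merge_overlapping_nodes(kmers)
    graphs = extract_components(nodes, place_edges(nodes, params))
    kept1 = dedupe_mirror_components(list(graphs))
    kept2 = dedupe_mirror_components(list(reversed(graphs)))
    seqs1 = sorted(n.sequence for g in kept1 for n in g.nodes.values())
    seqs2 = sorted(n.sequence for g in kept2 for n in g.nodes.values())
    assert seqs1 == seqs2


def test_gfa_export_lists_segments_and_links(rng):
    from levelasm import to_gfa

    params = AssemblyParams(k=15)
    a = random_transcript(rng, 15)
    b = a[1:] + "G"
    nodes = [GraphNode(0, a, 3), GraphNode(1, b, 2)]
    (graph,) = extract_components(nodes, place_edges(nodes, params))
    gfa = to_gfa(graph, params)
    lines = gfa.strip().split("\n")
    assert lines[0].startswith("H\t")
    assert sum(1 for l in lines if l.startswith("S\t")) == 2
    assert any(l.startswith("L\t0\t+\t1\t+\t14M") for l in lines)
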