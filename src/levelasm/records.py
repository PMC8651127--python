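"""Core record types shared across the assembler.

The assembler works over plain nucleotide strings ({A,C,G,T,N}); all graph
entities carry integer ids so components can be manipulated as lightweight
id -> record mappings.
"""
from __future__ import annotations

from dataclasses import dataclass, field

VALID_ALPHABET = frozenset("ACGTN")

#: FASTA header suffixes for the three graph-complexity levels.  Level 1
#: graphs hold a single unambiguous path (non-chimeric), level 2 graphs hold
#: one path per end node (each non-chimeric), level 3 graphs admit ambiguous
#: routes and their contigs may be chimeric.
LEVEL_LABELS = {
    1: "LVL_1_NO_CYCLES_ONE_TO_ONE",
    2: "LVL_2_NO_CYCLES_ONE_TO_MANY",
    3: "LVL_3_COMPLEX",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (read, transcript or reference)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """Two mates of one sequenced fragment; mate2 is reverse-complemented."""

    mate1: SequenceRecord
    mate2: SequenceRecord

    def __post_init__(self) -> None:
        if _strip_mate_suffix(self.mate1.id) != _strip_mate_suffix(self.mate2.id):
            raise ValueError(
                f"mate ids disagree: {self.mate1.id!r} vs {self.mate2.id!r}"
            )


def _strip_mate_suffix(read_id: str) -> str:
    for suffix in ("/1", "/2", "_1", "_2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


@dataclass(frozen=True)
class KmerRecord:
    """A fixed-length nucleotide word with its observed frequency."""

    word: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("kmer count must be >= 1")


@dataclass
class GraphNode:
    """A (possibly composite) sequence node.

    ``frequency`` is the representative frequency: the maximum count among
    the constituent kmers.  ``per_base_cover`` holds one coverage value per
    sequence position; position *i* of a composite built from kmers
    ``w_0..w_{m-1}`` carries ``count(w_i)`` for ``i < m`` and the last kmer's
    count for the trailing ``k-1`` positions.
    """

    node_id: int
    sequence: str
    frequency: int
    per_base_cover: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.per_base_cover:
            self.per_base_cover = [self.frequency] * len(self.sequence)
        if len(self.per_base_cover) != len(self.sequence):
            raise ValueError("per_base_cover length must equal sequence length")


@dataclass(frozen=True)
class GraphEdge:
    """Directed overlap edge: the last ``k - overhang`` bases of the source
    node's terminal kmer window equal the first ``k - overhang`` bases of the
    destination node's initial window."""

    src: int
    dst: int
    overhang: int

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise ValueError("self edges are not allowed")
        if self.overhang < 1:
            raise ValueError("overhang must be >= 1")


@dataclass
class AssemblyGraph:
    """One connected component of the assembly graph with its
    classification state."""

    graph_id: int
    nodes: dict[int, GraphNode]
    edges: list[GraphEdge]
    set_E: set[int] = field(default_factory=set)
    set_J: set[int] = field(default_factory=set)
    set_I: set[int] = field(default_factory=set)
    cornerstone: int | None = None
    E1: set[int] = field(default_factory=set)
    E2: set[int] = field(default_factory=set)
    level: int | None = None
    has_cycles: bool = False

    @property
    def level_label(self) -> str:
        if self.level is None:
            raise ValueError("graph not yet classified")
        return LEVEL_LABELS[self.level]


@dataclass(frozen=True)
class ContigRecord:
    """An output contig: unique id, level label, sequence and the mean
    per-base read coverage of the path it was reconstructed from."""

    contig_id: int
    level_label: str
    sequence: str
    mean_cover: float
    graph_id: int

    def __post_init__(self) -> None:
        if self.level_label not in LEVEL_LABELS.values():
            raise ValueError(f"unknown level label {self.level_label!r}")

    def __len__(self) -> int:
        return len(self.sequence)
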