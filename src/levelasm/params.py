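"""Assembly tunables, all in one place."""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AssemblyParams:
    """Tunable parameters of the assembler.

    Parameters
    ----------
    k:
        Kmer length in nucleotides.  The default of 40 keeps chance kmer
        collisions between unrelated gene families negligible while sitting
        between the defaults of comparable de Bruijn assemblers.
    max_overhang:
        Maximum number of overhanging nucleotides allowed when placing an
        edge between two nodes (boundary windows must agree over the
        remaining ``k - overhang`` bases).
    low_complexity_fraction:
        A kmer is discarded when a single nucleotide type makes up strictly
        more than this fraction of it.
    paths_per_start:
        How many complete paths are traced from each start node of a level
        2/3 graph before enumeration stops.
    contigs_per_graph:
        How many coverage-ranked paths per graph become contigs (level 1
        graphs always emit exactly one).  Bounded to [3, 5].
    min_contig_len:
        Contigs shorter than this are dropped from the output.
    """

    k: int = 40
    max_overhang: int = 5
    low_complexity_fraction: float = 0.8
    paths_per_start: int = 10
    contigs_per_graph: int = 3
    min_contig_len: int = 200

    def __post_init__(self) -> None:
        if self.k < 12:
            raise ValueError("k must be >= 12")
        if not (1 <= self.max_overhang < self.k):
            raise ValueError("max_overhang must satisfy 1 <= max_overhang < k")
        if not (0.0 < self.low_complexity_fraction <= 1.0):
            raise ValueError("low_complexity_fraction must be in (0, 1]")
        if not (3 <= self.contigs_per_graph <= 5):
            raise ValueError("contigs_per_graph must be between 3 and 5")
        if self.paths_per_start < 1:
            raise ValueError("paths_per_start must be >= 1")
        if self.min_contig_len < 0:
            raise ValueError("min_contig_len must be >= 0")
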