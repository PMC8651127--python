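"""Paired-end read simulation and toy transcriptome generators.

The simulator emulates an error-free uniform-coverage protocol: 200-nt
mates on 300-nt fragments, fragment starts tiled evenly along each
transcript, pairs allocated across transcripts proportionally to length so
the expected per-site coverage ``2 * n_pairs * read_length / total_length``
is constant over the whole set.  "Insert size" is the outer fragment span,
so 200-nt mates on a 300-nt fragment overlap by 100 nt — the gap-based
reading would need 700-nt fragments and could not fit the shortest (300 nt)
transcripts.

The toy generators build minimal transcript families whose assembly graphs
realise the archetypes of the three classification levels (unique-kmer
chains, shared blocks forcing junctions, SNP bubbles, exact repeats forcing
directed cycles).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ReadPair, SequenceRecord, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationSpec:
    """Simulation settings: read/fragment geometry and target pair count."""

    n_pairs: int
    read_length: int = 200
    insert_size: int = 300
    min_tx_len: int = 300
    max_tx_len: int = 5000
    seed: int = 0
    random_starts: bool = False  # uniform-random fragment starts instead of tiling

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.read_length < 1 or self.insert_size < self.read_length:
            raise ValueError("need insert_size >= read_length >= 1")
        if self.min_tx_len < self.read_length:
            raise ValueError("min_tx_len must be >= read_length")


def random_transcript(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def simulate_read_pairs(
    transcripts: list[SequenceRecord], spec: SimulationSpec
) -> list[ReadPair]:
    """Generate error-free read pairs with uniform expected coverage.

    Pairs are allocated to transcripts proportionally to length (largest
    remainder, so the total equals ``n_pairs`` exactly) and fragment starts
    are tiled evenly over each transcript.  Mate 2 is the reverse
    complement of the fragment's 3' end.  A transcript shorter than the
    fragment span is covered with the span truncated to its length.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    for t in transcripts:
        if not (spec.min_tx_len <= len(t) <= spec.max_tx_len):
            raise ValueError(
                f"transcript {t.id!r} length {len(t)} outside "
                f"[{spec.min_tx_len}, {spec.max_tx_len}]"
            )
    rng = np.random.default_rng(spec.seed)
    lengths = np.array([len(t) for t in transcripts], dtype=float)
    exact = spec.n_pairs * lengths / lengths.sum()
    counts = np.floor(exact).astype(int)
    remainder = spec.n_pairs - counts.sum()
    if remainder > 0:
        order = np.argsort(-(exact - counts))
        counts[order[:remainder]] += 1

    pairs: list[ReadPair] = []
    for t, n_t in zip(transcripts, counts):
        span = min(spec.insert_size, len(t))
        hi = len(t) - span
        if n_t == 0:
            continue
        if spec.random_starts:
            starts = rng.integers(0, hi + 1, size=n_t)
        else:
            starts = np.rint(np.linspace(0, hi, num=n_t)).astype(int)
        for j, s in enumerate(starts):
            frag = t.sequence[s : s + span]
            mate1 = frag[: spec.read_length]
            mate2 = reverse_complement(frag[-spec.read_length :])
            base = f"{t.id}:{j}"
            pairs.append(
                ReadPair(
                    SequenceRecord(f"{base}/1", mate1),
                    SequenceRecord(f"{base}/2", mate2),
                )
            )
    return pairs


def pairs_to_reads(pairs: list[ReadPair]) -> list[SequenceRecord]:
    """Flatten pairs into the read list the assembler consumes."""
    reads: list[SequenceRecord] = []
    for p in pairs:
        reads.append(p.mate1)
        reads.append(p.mate2)
    return reads


def make_toy_transcriptome(
    kind: str,
    seed: int,
    *,
    k: int = 40,
    n: int = 3,
    length: int = 1000,
) -> list[SequenceRecord]:
    """Build a minimal transcript family realising one graph archetype.

    kind='simple'        unrelated random transcripts (unique kmers);
    kind='shared_block'  two transcripts sharing one interior block > k,
                         forcing a junction (level 2/3 graph);
    kind='shared_prefix' two transcripts with a common 5' region then
                         divergent tails (one-to-many archetype);
    kind='bubble_pair'   two haplotypes differing at two well-separated
                         sites, yielding two bubbles in sequence and
                         exactly four end-to-end paths;
    kind='cyclic'        one transcript with an exact internal repeat > k,
                         forcing a directed cycle.
    """
    rng = np.random.default_rng(seed)
    if kind == "simple":
        return [
            SequenceRecord(f"simple_{i}", random_transcript(rng, length))
            for i in range(n)
        ]
    if kind == "shared_block":
        block = random_transcript(rng, k + 20)
        flank = (length - len(block)) // 2
        recs = []
        for i in range(2):
            left = random_transcript(rng, flank)
            right = random_transcript(rng, flank)
            recs.append(SequenceRecord(f"shared_{i}", left + block + right))
        return recs
    if kind == "shared_prefix":
        prefix = random_transcript(rng, length // 2)
        return [
            SequenceRecord(
                f"prefix_{i}", prefix + random_transcript(rng, length // 2)
            )
            for i in range(2)
        ]
    if kind == "bubble_pair":
        base = random_transcript(rng, length)
        p1, p2 = length // 3, 2 * length // 3
        if p2 - p1 <= 2 * k or p1 <= k or length - p2 <= k:
            raise ValueError("length too short for two separated bubbles")
        alt = list(base)
        for p in (p1, p2):
            alt[p] = _BASES[(_BASES.index(base[p]) + 1) % 4]
        return [
            SequenceRecord("hap_0", base),
            SequenceRecord("hap_1", "".join(alt)),
        ]
    if kind == "cyclic":
        repeat = random_transcript(rng, k + 20)
        spacer = random_transcript(rng, 3 * k)
        head = random_transcript(rng, max(k * 2, (length - 2 * len(repeat)) // 2))
        tail = random_transcript(rng, len(head))
        return [SequenceRecord("cyclic_0", head + repeat + spacer + repeat + tail)]
    raise ValueError(f"unknown toy transcriptome kind {kind!r}")


def make_mixture_transcriptome(
    n_total: int,
    family_fraction: float,
    seed: int,
    *,
    k: int = 40,
    min_len: int = 300,
    max_len: int = 800,
) -> list[SequenceRecord]:
    """A transcriptome mixing unrelated transcripts with two-member gene
    families that share sequence (alternating interior-block and common-end
    families), ``family_fraction`` of transcripts belonging to families.

    Unrelated transcripts assemble into simple one-to-one graphs; families
    force junctions, giving a realistic spread over the three levels.
    """
    if not 0.0 <= family_fraction <= 1.0:
        raise ValueError("family_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_family_members = int(round(n_total * family_fraction))
    n_families = n_family_members // 2
    records: list[SequenceRecord] = []
    for fam in range(n_families):
        length = int(rng.integers(min_len, max_len + 1))
        if fam % 2 == 0:
            block = random_transcript(rng, k + 20)
            flank = max((length - len(block)) // 2, k + 10)
            for m in range(2):
                records.append(
                    SequenceRecord(
                        f"famB{fam}_{m}",
                        random_transcript(rng, flank)
                        + block
                        + random_transcript(rng, flank),
                    )
                )
        else:
            shared = random_transcript(rng, max(length // 2, k + 10))
            for m in range(2):
                records.append(
                    SequenceRecord(
                        f"famP{fam}_{m}",
                        shared + random_transcript(rng, max(length // 2, k + 10)),
                    )
                )
    while len(records) < n_total:
        length = int(rng.integers(min_len, max_len + 1))
        records.append(
            SequenceRecord(
                f"solo_{len(records)}", random_transcript(rng, length)
            )
        )
    return records


def make_chimeric_references(
    transcripts: list[SequenceRecord], proportion: float, seed: int
) -> list[SequenceRecord]:
    """Replace a fraction of records with two-parent splices.

    Each chimera joins a random 5' piece of one parent to a random 3' piece
    of another (breakpoints uniform, away from the extreme ends); parents
    are recorded in the record id.  The total record count is preserved.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    if proportion > 0 and len(transcripts) < 2:
        raise ValueError("need >= 2 transcripts to build chimeras")
    n_chim = round(proportion * len(transcripts))
    if n_chim == 0:
        return list(transcripts)
    rng = np.random.default_rng(seed)
    replace = set(rng.choice(len(transcripts), size=n_chim, replace=False).tolist())
    out: list[SequenceRecord] = []
    for i, rec in enumerate(transcripts):
        if i not in replace:
            out.append(rec)
            continue
        j, k_idx = rng.choice(len(transcripts), size=2, replace=False)
        p1, p2 = transcripts[int(j)], transcripts[int(k_idx)]
        bp1 = int(rng.integers(1, len(p1)))
        bp2 = int(rng.integers(1, len(p2)))
        out.append(
            SequenceRecord(
                f"chimera_{i}|{p1.id}|{p2.id}",
                p1.sequence[:bp1] + p2.sequence[bp2:],
            )
        )
    return out
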