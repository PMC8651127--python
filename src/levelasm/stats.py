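"""Assembly summaries: level tallies, contig length statistics and the
expected-coverage arithmetic of uniform error-free simulations."""
from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from itertools import product

from .records import ContigRecord, LEVEL_LABELS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LevelSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


@dataclass(frozen=True)
class LengthSummary:
    n: int
    min: int
    median: float
    mean: float
    max: int
    n_above_5000: int


def expected_per_site_cover(
    n_pairs: int, read_length: int, combined_length: int
) -> float:
    """Expected per-site coverage of an error-free uniform simulation:
    ``2 * n_pairs * read_length / combined_length`` (two mates per pair),
    rounded to 2 decimals for reporting."""
    if n_pairs <= 0 or read_length <= 0:
        raise ValueError("n_pairs and read_length must be positive")
    if combined_length <= 0:
        raise ValueError("combined_length must be positive")
    return round(2 * n_pairs * read_length / combined_length, 2)


def level_summary(contigs: list[ContigRecord]) -> LevelSummary:
    """Tally contigs per classification level with percentages of total."""
    counts = {label: 0 for label in LEVEL_LABELS.values()}
    for c in contigs:
        counts[c.level_label] += 1
    total = len(contigs)
    if total == 0:
        logger.warning("level summary of empty contig list")
        percentages = {label: 0.0 for label in counts}
    else:
        percentages = {
            label: 100.0 * n / total for label, n in counts.items()
        }
    return LevelSummary(counts=counts, percentages=percentages, total=total)


def length_summary(contigs: list[ContigRecord]) -> LengthSummary:
    """Order statistics over contig lengths; the >5000 nt count is strict
    (a 5000-nt contig is in-range, not above it)."""
    lengths = sorted(len(c) for c in contigs)
    if not lengths:
        return LengthSummary(0, 0, 0.0, 0.0, 0, 0)
    return LengthSummary(
        n=len(lengths),
        min=lengths[0],
        median=statistics.median(lengths),
        mean=sum(lengths) / len(lengths),
        max=lengths[-1],
        n_above_5000=sum(1 for x in lengths if x > 5000),
    )


def count_kmer_space(k: int) -> int:
    """Number of distinct DNA words of length k, counted by enumeration
    for small k (else closed form)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k <= 10:
        return len({"".join(w) for w in product("ACGT", repeat=k)})
    return 4**k


def summary_report(
    level: LevelSummary, length: LengthSummary
) -> str:
    """Human-readable combined summary."""
    lines = ["# Assembly summary", f"contigs: {level.total}"]
    for label in LEVEL_LABELS.values():
        lines.append(
            f"  {label}: {level.counts[label]}"
            f" ({level.percentages[label]:.1f}%)"
        )
    lines.append(
        f"lengths: min {length.min}  median {length.median:.0f}"
        f"  mean {length.mean:.1f}  max {length.max}"
        f"  above 5000 nt: {length.n_above_5000}"
    )
    return "\n".join(lines) + "\n"
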