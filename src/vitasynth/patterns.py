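"""Pathway-pattern census, cohort comparison, and inversed-pair detection.

A *pathway pattern* is the ordered 8-bit string of producer calls in
canonical vitamin order (biotin, cobalamin, folate, niacin, pantothenate,
pyridoxine, riboflavin, thiamin), '1' meaning the biosynthesis pathway is
present.  Two observed patterns that are bitwise complements form an
*inversed pair* — candidate metabolic complementarity, where what one
organism cannot synthesise another can.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotations import GenomeRecord, VITAMINS, ValidationError, taxonomy_index
from .predict import PredictionTable, _group_by_rank

N_BITS = len(VITAMINS)
N_PATTERNS = 2**N_BITS

#: All 256 possible patterns, in numeric order.
ALL_PATTERNS = tuple(format(i, f"0{N_BITS}b") for i in range(N_PATTERNS))


def validate_pattern(pattern: str) -> str:
    if len(pattern) != N_BITS or any(c not in "01" for c in pattern):
        raise ValidationError(f"malformed pattern: {pattern!r}")
    return pattern


def complement(pattern: str) -> str:
    """Bitwise complement; an involution over the 256-pattern space."""
    validate_pattern(pattern)
    return "".join("1" if c == "0" else "0" for c in pattern)


@dataclass
class PatternCensus:
    """Counts of observed patterns in one cohort."""

    counts: dict[str, int]
    cohort: str = ""

    def __post_init__(self) -> None:
        for p, n in self.counts.items():
            validate_pattern(p)
            if n < 1:
                raise ValidationError(f"pattern {p!r} stored with count {n}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def patterns(self) -> frozenset[str]:
        return frozenset(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pattern": p, "count": n, "fraction": n / self.total}
            for p, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["pattern", "count", "fraction"])


@dataclass
class CohortComparison:
    """Partition of the 256-pattern space by occurrence in two cohorts."""

    only_a: frozenset[str]
    shared: frozenset[str]
    only_b: frozenset[str]
    absent: frozenset[str]

    def sizes(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "shared": len(self.shared),
            "only_b": len(self.only_b),
            "absent": len(self.absent),
        }


@dataclass(frozen=True)
class InversedPair:
    """One observed complement pair; ``low`` is the lexicographically smaller side."""

    low: str
    high: str
    count_low: int
    count_high: int

    @property
    def n_genomes(self) -> int:
        return self.count_low + self.count_high


@dataclass
class InversedPairSet:
    pairs: tuple[InversedPair, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_genomes(self) -> int:
        """Genomes carrying either side of any pair (the alternative reading
        of a published pair count: genomes rather than patterns)."""
        return sum(p.n_genomes for p in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pattern": p.low,
                "complement": p.high,
                "count": p.count_low,
                "count_complement": p.count_high,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows, columns=["pattern", "complement", "count", "count_complement"]
        )


def pattern_census(
    predictions: PredictionTable,
    cohort: str = "",
    taxonomy: list[GenomeRecord] | None = None,
) -> PatternCensus:
    """Tally pathway patterns over a prediction table.

    When ``cohort`` and ``taxonomy`` are both given, only genomes with that
    cohort label are counted.
    """
    gids = predictions.genome_ids
    if cohort and taxonomy is not None:
        tax = taxonomy_index(taxonomy)
        gids = [g for g in gids if g in tax and tax[g].cohort == cohort]
    counts: dict[str, int] = {}
    for gid in gids:
        p = predictions.pattern(gid)
        counts[p] = counts.get(p, 0) + 1
    return PatternCensus(counts, cohort=cohort)


def compare_cohorts(a: PatternCensus, b: PatternCensus) -> CohortComparison:
    """Split the 256-pattern space into only-A / shared / only-B / absent."""
    pa, pb = a.patterns(), b.patterns()
    universe = frozenset(ALL_PATTERNS)
    comparison = CohortComparison(
        only_a=pa - pb,
        shared=pa & pb,
        only_b=pb - pa,
        absent=universe - pa - pb,
    )
    assert sum(comparison.sizes().values()) == N_PATTERNS
    return comparison


def inversed_pairs(census: PatternCensus) -> InversedPairSet:
    """All unordered pairs {p, complement(p)} with both sides observed.

    Each pair is listed once with the lexicographically smaller pattern
    first.  For even-length binary patterns no pattern can equal its own
    complement, so the two sides are always distinct.
    """
    observed = census.patterns()
    pairs = []
    for p in sorted(observed):
        q = complement(p)
        assert q != p
        if q in observed and p < q:
            pairs.append(InversedPair(p, q, census.counts[p], census.counts[q]))
    return InversedPairSet(tuple(pairs))


def taxon_pattern_summary(
    predictions: PredictionTable,
    taxonomy: list[GenomeRecord],
    rank: str = "phylum",
) -> pd.DataFrame:
    """Per-taxon pattern counts and within-taxon fractions (sum to 1)."""
    known = set(predictions.genome_ids)
    records = [r for r in taxonomy if r.genome_id in known]
    groups = _group_by_rank(records, rank)
    rows = []
    for taxon in sorted(groups):
        gids = groups[taxon]
        counts: dict[str, int] = {}
        for gid in gids:
            p = predictions.pattern(gid)
            counts[p] = counts.get(p, 0) + 1
        for p, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    rank: taxon,
                    "pattern": p,
                    "count": n,
                    "fraction": n / len(gids),
                }
            )
    return pd.DataFrame(rows, columns=[rank, "pattern", "count", "fraction"])


def heatmap_frame(predictions: PredictionTable) -> pd.DataFrame:
    """Genome x vitamin 0/1 frame in canonical column order (heatmap export)."""
    return predictions.calls.astype(int)
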