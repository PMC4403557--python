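"""Scoring of predicted producer calls against experimental evidence.

Evidence semantics follow defined-growth-medium studies: a vitamin required
in the medium is *nonproducer_equivalent*, growth without it (or measured
secretion) is *producer_equivalent*, and ambiguous reports are *unknown*.
A prediction matches when producer status and producer-equivalent evidence
agree (likewise for the negative side); unknown evidence is excluded from
the denominator.  Strain-vs-species comparisons are handled by an explicit
organism-to-genome mapping, never by fuzzy name matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotations import EvidenceTable, ValidationError, _open_text
from .predict import PredictionTable

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """Per-cell verdicts plus summary totals."""

    table: pd.DataFrame  # organism, genome_id, vitamin, predicted, evidence, match
    compared: int
    matched: int
    excluded_unknown: int
    skipped_organisms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.matched > self.compared:
            raise ValidationError("matched cannot exceed compared")

    @property
    def fraction(self) -> float:
        return self.matched / self.compared if self.compared else float("nan")

    def summary(self) -> str:
        return (
            f"{self.matched} of {self.compared} predictions match the experimental "
            f"evidence ({100 * self.fraction:.0f}%); {self.excluded_unknown} "
            f"record(s) with unknown evidence excluded"
        )


def read_organism_map(path) -> dict[str, str]:
    """Read an organism -> genome_id mapping TSV (columns organism, genome_id)."""
    handle, close = _open_text(path)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            handle.close()
    return dict(zip(df["organism"], df["genome_id"]))


def score_concordance(
    predictions: PredictionTable,
    evidence: EvidenceTable,
    mapping: dict[str, str] | None = None,
) -> ConcordanceResult:
    """Score every evidence record against the corresponding prediction.

    ``mapping`` resolves organism names to genome ids; records whose
    genome_id field is set are used directly.  Organisms that resolve to no
    genome in the prediction table are skipped with a logged warning.
    """
    mapping = mapping or {}
    known = set(predictions.genome_ids)
    rows = []
    matched = compared = excluded = 0
    skipped: list[str] = []
    for rec in evidence:
        gid = rec.genome_id or mapping.get(rec.organism, "")
        if gid not in known:
            skipped.append(rec.organism)
            logger.warning(
                "evidence organism %r maps to no genome in predictions; skipped",
                rec.organism,
            )
            continue
        predicted = bool(predictions.calls.at[gid, rec.vitamin])
        if rec.evidence == "unknown":
            excluded += 1
            rows.append(
                {
                    "organism": rec.organism,
                    "genome_id": gid,
                    "vitamin": rec.vitamin,
                    "predicted": predicted,
                    "evidence": rec.evidence,
                    "match": pd.NA,
                }
            )
            continue
        expected = rec.evidence == "producer_equivalent"
        match = predicted == expected
        compared += 1
        matched += int(match)
        rows.append(
            {
                "organism": rec.organism,
                "genome_id": gid,
                "vitamin": rec.vitamin,
                "predicted": predicted,
                "evidence": rec.evidence,
                "match": match,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["organism", "genome_id", "vitamin", "predicted", "evidence", "match"],
    )
    return ConcordanceResult(
        table=table,
        compared=compared,
        matched=matched,
        excluded_unknown=excluded,
        skipped_organisms=tuple(dict.fromkeys(skipped)),
    )


def write_report(result: ConcordanceResult, path) -> None:
    """Write per-cell verdicts plus a trailing summary line."""
    handle, close = _open_text(path, "w")
    try:
        result.table.to_csv(handle, sep="\t", index=False)
        handle.write(f"# {result.summary()}\n")
    finally:
        if close:
            handle.close()
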