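"""Domain types and file I/O for annotation matrices, taxonomy, rules and evidence.

The central container is :class:`RoleMatrix`, a genomes x functional-roles
binary incidence matrix mirroring the spreadsheet view of a curated
metabolic subsystem: rows are genomes, columns are named functional roles
(enzymes or transporters), and a cell is 1 iff the role is annotated in the
genome.  All files are plain TSV so they diff cleanly under version control;
readers accept ``-`` for standard input and writers mirror the format
bit-exactly.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical vitamin order (alphabetical); all 8-bit pathway patterns and
#: every table with one column/row per vitamin use this order.
VITAMINS = (
    "biotin",
    "cobalamin",
    "folate",
    "niacin",
    "pantothenate",
    "pyridoxine",
    "riboflavin",
    "thiamin",
)

EVIDENCE_VALUES = ("producer_equivalent", "nonproducer_equivalent", "unknown")

TAXONOMY_COLUMNS = ("genome_id", "name", "phylum", "class", "order", "family", "cohort")

TAXONOMIC_RANKS = ("phylum", "class", "order", "family")


class ValidationError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


@dataclass(frozen=True)
class FunctionalRole:
    """A named protein function (enzyme or transporter), e.g. ``BioF`` or ``pabAc``.

    Role ids are opaque, case-sensitive tokens; the matrix columns and the
    rule definitions must match exactly.
    """

    id: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("functional role id must be non-empty")


@dataclass
class GenomeRecord:
    """One genome with its taxonomy and cohort label (e.g. HGM / nonHGM)."""

    genome_id: str
    name: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValidationError("genome_id must be non-empty")

    def rank(self, rank: str) -> str:
        """Return the taxon name at ``rank`` ('phylum'/'class'/'order'/'family'/'cohort')."""
        key = "class_" if rank == "class" else rank
        try:
            return getattr(self, key)
        except AttributeError:
            raise ValidationError(f"unknown taxonomic rank: {rank!r}") from None


@dataclass(frozen=True)
class RoleSubset:
    """A compound mnemonic (e.g. ``BioFADB``) naming a conjunction of roles.

    A subset is present in a genome iff every member role is present.
    """

    id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("subset id must be non-empty")
        if not self.members:
            raise ValidationError(f"subset {self.id!r} has no members")


@dataclass(frozen=True)
class EvidenceRecord:
    organism: str
    genome_id: str
    vitamin: str
    evidence: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.vitamin not in VITAMINS:
            raise ValidationError(f"unknown vitamin in evidence record: {self.vitamin!r}")
        if self.evidence not in EVIDENCE_VALUES:
            raise ValidationError(
                f"evidence must be one of {EVIDENCE_VALUES}, got {self.evidence!r}"
            )


@dataclass
class EvidenceTable:
    """Organism x vitamin experimental evidence (growth-requirement style)."""

    records: list[EvidenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.organism, rec.vitamin)
            if key in seen:
                raise ValidationError(
                    f"duplicate evidence record for organism {rec.organism!r}, "
                    f"vitamin {rec.vitamin!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


class RoleMatrix:
    """Binary genome x functional-role incidence matrix.

    Parameters
    ----------
    presence
        DataFrame indexed by genome id with one column per role id; values
        must be exactly 0/1.  Row and column order is preserved.
    genomes, roles
        Optional richer records; when omitted, bare records are derived
        from the presence index/columns.
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        genomes: list[GenomeRecord] | None = None,
        roles: list[FunctionalRole] | None = None,
    ) -> None:
        if presence.index.duplicated().any():
            dup = presence.index[presence.index.duplicated()][0]
            raise ValidationError(f"duplicate genome id: {dup!r}")
        if presence.columns.duplicated().any():
            dup = presence.columns[presence.columns.duplicated()][0]
            raise ValidationError(f"duplicate role id: {dup!r}")
        values = presence.to_numpy()
        bad = (values != 0) & (values != 1)
        if bad.any():
            i, j = [int(x[0]) for x in bad.nonzero()]
            raise ValidationError(
                f"non-binary cell at genome {presence.index[i]!r}, "
                f"role {presence.columns[j]!r}: {presence.iat[i, j]!r}"
            )
        self.presence = presence.astype("int8")
        self.genomes = genomes or [GenomeRecord(g) for g in presence.index]
        self.roles = roles or [FunctionalRole(r) for r in presence.columns]
        if len(self.genomes) != len(presence.index) or len(self.roles) != len(
            presence.columns
        ):
            raise ValidationError("genome/role record lists do not match matrix shape")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def role_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    def roles_of(self, genome_id: str) -> frozenset[str]:
        """Atomic role ids present in one genome."""
        row = self.presence.loc[genome_id]
        return frozenset(row.index[row == 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoleMatrix):
            return NotImplemented
        return self.presence.equals(other.presence)


def _open_text(path, mode: str = "r"):
    if hasattr(path, "read") or hasattr(path, "write"):
        return path, False
    if str(path) == "-":
        return (sys.stdin if "r" in mode else sys.stdout), False
    return open(path, mode), True


def read_role_matrix(
    path,
    truthy: frozenset[str] = frozenset({"1"}),
    falsy: frozenset[str] = frozenset({"0"}),
) -> RoleMatrix:
    """Read a TSV role matrix (first column genome ids, header row role ids).

    ``truthy``/``falsy`` configure the accepted cell tokens; anything else
    raises with the offending row/column coordinates.
    """
    handle, close = _open_text(path)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    lines = [ln for ln in text.splitlines() if ln != ""]
    if not lines:
        raise ValidationError(f"empty role matrix file: {path}")
    header = lines[0].split("\t")[1:]
    seen: set[str] = set()
    for role in header:
        if role in seen:
            raise ValidationError(f"duplicate role id: {role!r}")
        seen.add(role)
    genome_ids: list[str] = []
    rows: list[list[int]] = []
    gseen: set[str] = set()
    for ln in lines[1:]:
        fields = ln.split("\t")
        gid, cells = fields[0], fields[1:]
        if gid in gseen:
            raise ValidationError(f"duplicate genome id: {gid!r}")
        gseen.add(gid)
        if len(cells) != len(header):
            raise ValidationError(
                f"genome {gid!r}: expected {len(header)} cells, got {len(cells)}"
            )
        row = []
        for role, cell in zip(header, cells):
            if cell in truthy:
                row.append(1)
            elif cell in falsy:
                row.append(0)
            else:
                raise ValidationError(
                    f"non-binary cell at genome {gid!r}, role {role!r}: {cell!r}"
                )
        genome_ids.append(gid)
        rows.append(row)
    presence = pd.DataFrame(rows, index=genome_ids, columns=header, dtype="int8")
    return RoleMatrix(presence)


def write_role_matrix(matrix: RoleMatrix, path) -> None:
    """Write a role matrix as TSV, inverse of :func:`read_role_matrix`."""
    handle, close = _open_text(path, "w")
    try:
        buf = io.StringIO()
        matrix.presence.to_csv(buf, sep="\t", index_label="genome_id")
        handle.write(buf.getvalue())
    finally:
        if close:
            handle.close()


def read_taxonomy(path) -> list[GenomeRecord]:
    """Read a taxonomy TSV (genome_id, name, phylum, class, order, family, cohort).

    Missing trailing fields are stored as empty strings; a missing or
    duplicate genome_id is an error.
    """
    handle, close = _open_text(path)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            handle.close()
    missing = [c for c in ("genome_id",) if c not in df.columns]
    if missing:
        raise ValidationError(f"taxonomy file lacks required column(s): {missing}")
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gid = row["genome_id"]
        if not gid:
            raise ValidationError("taxonomy row with empty genome_id")
        if gid in seen:
            raise ValidationError(f"duplicate genome_id in taxonomy: {gid!r}")
        seen.add(gid)
        records.append(
            GenomeRecord(
                genome_id=gid,
                name=row.get("name", ""),
                phylum=row.get("phylum", ""),
                class_=row.get("class", ""),
                order=row.get("order", ""),
                family=row.get("family", ""),
                cohort=row.get("cohort", ""),
            )
        )
    return records


def write_taxonomy(records: list[GenomeRecord], path) -> None:
    handle, close = _open_text(path, "w")
    try:
        df = pd.DataFrame(
            [
                {
                    "genome_id": r.genome_id,
                    "name": r.name,
                    "phylum": r.phylum,
                    "class": r.class_,
                    "order": r.order,
                    "family": r.family,
                    "cohort": r.cohort,
                }
                for r in records
            ],
            columns=list(TAXONOMY_COLUMNS),
        )
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


def taxonomy_index(records: list[GenomeRecord]) -> dict[str, GenomeRecord]:
    return {r.genome_id: r for r in records}


def read_evidence(path) -> EvidenceTable:
    """Read an evidence TSV (organism, genome_id, vitamin, evidence, source)."""
    handle, close = _open_text(path)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            handle.close()
    required = {"organism", "vitamin", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"evidence file lacks required column(s): {sorted(missing)}")
    records = [
        EvidenceRecord(
            organism=row["organism"],
            genome_id=row.get("genome_id", ""),
            vitamin=row["vitamin"],
            evidence=row["evidence"],
            source=row.get("source", ""),
        )
        for _, row in df.iterrows()
    ]
    return EvidenceTable(records)


def write_evidence(table: EvidenceTable, path) -> None:
    handle, close = _open_text(path, "w")
    try:
        df = pd.DataFrame(
            [
                {
                    "organism": r.organism,
                    "genome_id": r.genome_id,
                    "vitamin": r.vitamin,
                    "evidence": r.evidence,
                    "source": r.source,
                }
                for r in table.records
            ],
            columns=["organism", "genome_id", "vitamin", "evidence", "source"],
        )
        df.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


def read_rules(path):
    """Read a rule config (YAML); see :mod:`vitasynth.predict` for the grammar.

    Returns a :class:`vitasynth.predict.RuleSet`.
    """
    from .predict import RuleSet  # local import: predict builds on this module

    return RuleSet.from_yaml(path)


def default_rules():
    """The packaged default producer criteria for all eight vitamins."""
    from .predict import RuleSet

    return RuleSet.default()
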