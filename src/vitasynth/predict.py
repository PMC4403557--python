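"""Boolean producer-rule engine and taxon prevalence summaries.

A vitamin's producer criterion is a disjunction of *lines*; each line is a
conjunction of terms over functional-role ids, where a term is either a
single id or an OR-group.  Compound ids (role subsets) are satisfied only
when every member role is present.  A genome is called a producer when some
line is satisfied outright, or when a line misses at most ``max_missing``
explicitly tolerable roles while every mandatory role is present — the
declarative encoding of "one missing enzyme in a branched pathway is
forgiven, but some steps always veto".

Every producer call carries provenance: which line fired, whether tolerance
rescued it, or whether a manual curation override decided it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .annotations import (
    RoleMatrix,
    RoleSubset,
    GenomeRecord,
    TAXONOMIC_RANKS,
    VITAMINS,
    ValidationError,
    taxonomy_index,
)

logger = logging.getLogger(__name__)

#: A term is a tuple of alternative ids; length 1 means a plain id, length
#: >= 2 an OR-group satisfied by any one member.
Term = tuple[str, ...]


@dataclass(frozen=True)
class RuleLine:
    """One conjunction of terms; satisfied iff every term is satisfied."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("rule line has no terms")

    def ids(self) -> frozenset[str]:
        return frozenset(i for term in self.terms for i in term)

    def satisfied(self, present: frozenset[str] | set[str]) -> bool:
        return all(any(alt in present for alt in term) for term in self.terms)


def parse_rule_line(text: str) -> RuleLine:
    """Parse ``"A + (B or C) + D"`` into a :class:`RuleLine`."""
    if not text or not text.strip():
        raise ValidationError("empty rule line")
    terms: list[Term] = []
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise ValidationError(f"empty term in rule line {text!r}")
        if chunk.startswith("(") and chunk.endswith(")"):
            alts = tuple(a.strip() for a in chunk[1:-1].split(" or "))
            if len(alts) < 2 or any(not a for a in alts):
                raise ValidationError(f"malformed OR-group {chunk!r}")
            terms.append(alts)
        else:
            if " " in chunk:
                raise ValidationError(f"malformed term {chunk!r} in line {text!r}")
            terms.append((chunk,))
    return RuleLine(tuple(terms))


@dataclass(frozen=True)
class VitaminRule:
    """Producer criterion for one vitamin."""

    vitamin: str
    lines: tuple[RuleLine, ...]
    tolerable: frozenset[str] = frozenset()
    max_missing: int = 0
    mandatory: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValidationError(f"rule for {self.vitamin!r} has no lines")
        if self.max_missing < 0:
            raise ValidationError("max_missing must be >= 0")
        overlap = self.tolerable & self.mandatory
        if overlap:
            raise ValidationError(
                f"roles cannot be both tolerable and mandatory: {sorted(overlap)}"
            )

    def ids(self) -> frozenset[str]:
        out = frozenset().union(*(line.ids() for line in self.lines))
        return out | self.tolerable | self.mandatory


@dataclass(frozen=True)
class OverrideRecord:
    """A manual curation verdict that takes precedence over the rule engine.

    The justification is mandatory: overrides are an audit trail, e.g. a
    genome missing one essential role that is called a producer because all
    related genomes carry it.
    """

    genome_id: str
    vitamin: str
    verdict: bool
    justification: str

    def __post_init__(self) -> None:
        if not self.justification:
            raise ValidationError(
                f"override for ({self.genome_id}, {self.vitamin}) lacks a justification"
            )
        if self.vitamin not in VITAMINS:
            raise ValidationError(f"unknown vitamin in override: {self.vitamin!r}")


def evaluate_rule(
    present_ids: frozenset[str] | set[str], rule: VitaminRule
) -> tuple[bool, str]:
    """Evaluate one producer rule against an expanded presence set.

    ``present_ids`` must already contain subset ids for fully-present
    subsets (see :meth:`RuleSet.expand`).  Returns ``(verdict, provenance)``
    where provenance is ``"line:<i>"`` (1-based, config order — the first
    satisfied line wins), ``"tolerance:<i>"``, or ``"none"``.
    """
    for i, line in enumerate(rule.lines, start=1):
        if line.satisfied(present_ids):
            return True, f"line:{i}"
    if rule.max_missing > 0:
        for i, line in enumerate(rule.lines, start=1):
            missing = [t for t in line.terms if not any(a in present_ids for a in t)]
            if not missing:  # pragma: no cover - caught by the loop above
                continue
            if len(missing) > rule.max_missing:
                continue
            if not all(len(t) == 1 and t[0] in rule.tolerable for t in missing):
                continue
            if not rule.mandatory <= set(present_ids):
                continue
            return True, f"tolerance:{i}"
    return False, "none"


class RuleSet:
    """Producer rules for a panel of vitamins plus the shared subset table."""

    def __init__(
        self,
        rules: list[VitaminRule],
        subsets: dict[str, RoleSubset] | None = None,
        declared_roles: frozenset[str] | None = None,
    ) -> None:
        self.subsets = dict(subsets or {})
        self.rules: dict[str, VitaminRule] = {}
        for rule in rules:
            if rule.vitamin in self.rules:
                raise ValidationError(f"duplicate rule for vitamin {rule.vitamin!r}")
            self.rules[rule.vitamin] = rule
        self.declared_roles = declared_roles
        self._validate_references()

    def _validate_references(self) -> None:
        for sub in self.subsets.values():
            if self.declared_roles is not None:
                unknown = set(sub.members) - self.declared_roles
                if unknown:
                    raise ValidationError(
                        f"subset {sub.id!r} references undeclared role(s): {sorted(unknown)}"
                    )
        for rule in self.rules.values():
            for token in rule.ids():
                if token in self.subsets:
                    continue
                if self.declared_roles is not None and token not in self.declared_roles:
                    raise ValidationError(
                        f"rule for {rule.vitamin!r} references undeclared id {token!r}"
                    )

    def __iter__(self):
        return iter(self.rules.values())

    def __getitem__(self, vitamin: str) -> VitaminRule:
        return self.rules[vitamin]

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def vitamins(self) -> list[str]:
        return list(self.rules)

    def expand(self, atomic_present: frozenset[str] | set[str]) -> frozenset[str]:
        """Add every subset id whose members are all present."""
        extra = {
            sid
            for sid, sub in self.subsets.items()
            if all(m in atomic_present for m in sub.members)
        }
        return frozenset(atomic_present) | extra

    def atomic_universe(self, rule: VitaminRule) -> list[str]:
        """Sorted atomic role ids the rule depends on (subsets expanded)."""
        atoms: set[str] = set()
        for token in rule.ids():
            if token in self.subsets:
                atoms.update(self.subsets[token].members)
            else:
                atoms.add(token)
        return sorted(atoms)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RuleSet":
        subsets = {
            sid: RoleSubset(sid, tuple(members))
            for sid, members in (cfg.get("subsets") or {}).items()
        }
        declared = None
        if cfg.get("roles") is not None:
            declared = frozenset(cfg["roles"])
        rules: list[VitaminRule] = []
        for vitamin, spec in (cfg.get("vitamins") or {}).items():
            lines = tuple(parse_rule_line(ln) for ln in spec.get("lines", []))
            tol = spec.get("tolerance") or {}
            rules.append(
                VitaminRule(
                    vitamin=vitamin,
                    lines=lines,
                    tolerable=frozenset(tol.get("tolerable", [])),
                    max_missing=int(tol.get("max_missing", 0)),
                    mandatory=frozenset(spec.get("mandatory", [])),
                )
            )
        return cls(rules, subsets, declared)

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        if str(path) == "-":
            import sys

            cfg = yaml.safe_load(sys.stdin)
        else:
            with open(path) as fh:
                cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg)

    @classmethod
    def default(cls) -> "RuleSet":
        """The packaged default criteria: all eight vitamins."""
        text = resources.files("vitasynth.data").joinpath("rules.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


class PredictionTable:
    """Genome x vitamin producer calls with per-call provenance."""

    def __init__(self, calls: pd.DataFrame, provenance: pd.DataFrame) -> None:
        missing = [v for v in VITAMINS if v not in calls.columns]
        if missing:
            raise ValidationError(f"prediction table lacks vitamin column(s): {missing}")
        self.calls = calls[list(VITAMINS)].astype(bool)
        self.calls.index.name = "genome_id"
        self.provenance = provenance[list(VITAMINS)].astype(str)
        self.provenance.index.name = "genome_id"
        if not self.calls.index.equals(self.provenance.index):
            raise ValidationError("calls and provenance indexed by different genomes")
        if (self.provenance == "").any().any():
            raise ValidationError("provenance must be populated for every call")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.calls.index)

    def __len__(self) -> int:
        return len(self.calls)

    def pattern(self, genome_id: str) -> str:
        """The genome's 8-bit pathway pattern in canonical vitamin order."""
        row = self.calls.loc[genome_id]
        return "".join("1" if row[v] else "0" for v in VITAMINS)

    def write_tsv(self, path) -> None:
        out = self.calls.astype(int).copy()
        for v in VITAMINS:
            out[f"{v}_provenance"] = self.provenance[v]
        from .annotations import _open_text

        handle, close = _open_text(path, "w")
        try:
            out.to_csv(handle, sep="\t", index_label="genome_id")
        finally:
            if close:
                handle.close()

    @classmethod
    def read_tsv(cls, path) -> "PredictionTable":
        from .annotations import _open_text

        handle, close = _open_text(path)
        try:
            df = pd.read_csv(handle, sep="\t", index_col="genome_id", dtype=str)
        finally:
            if close:
                handle.close()
        missing = [v for v in VITAMINS if v not in df.columns]
        if missing:
            raise ValidationError(f"predictions file lacks column(s): {missing}")
        calls = df[list(VITAMINS)].astype(int).astype(bool)
        prov_cols = {v: f"{v}_provenance" for v in VITAMINS}
        if all(c in df.columns for c in prov_cols.values()):
            provenance = df[list(prov_cols.values())].rename(
                columns={c: v for v, c in prov_cols.items()}
            )
        else:
            # external tables (e.g. transcribed published calls) may lack
            # provenance; mark them as imported
            provenance = pd.DataFrame("imported", index=df.index, columns=list(VITAMINS))
        return cls(calls, provenance)


def read_overrides(path) -> list[OverrideRecord]:
    """Read override TSV (genome_id, vitamin, verdict, justification)."""
    from .annotations import _open_text

    handle, close = _open_text(path)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    finally:
        if close:
            handle.close()
    verdict_map = {"producer": True, "non-producer": False, "1": True, "0": False}
    out = []
    for _, row in df.iterrows():
        verdict = verdict_map.get(row["verdict"])
        if verdict is None:
            raise ValidationError(f"unknown override verdict: {row['verdict']!r}")
        out.append(
            OverrideRecord(
                genome_id=row["genome_id"],
                vitamin=row["vitamin"],
                verdict=verdict,
                justification=row.get("justification", ""),
            )
        )
    return out


def predict_cohort(
    matrix: RoleMatrix,
    rules: RuleSet,
    overrides: list[OverrideRecord] = (),
) -> PredictionTable:
    """Call producer/non-producer for every genome and vitamin.

    Overrides take precedence over the rule engine and are provenance-
    flagged ``override``; an override naming a genome absent from the
    matrix is an error.
    """
    missing = [v for v in VITAMINS if v not in rules.vitamins]
    if missing:
        raise ValidationError(f"rule set lacks vitamin(s): {missing}")
    known = set(matrix.genome_ids)
    unknown = sorted({o.genome_id for o in overrides} - known)
    if unknown:
        raise ValidationError(f"override(s) for unknown genome(s): {unknown}")
    override_map = {(o.genome_id, o.vitamin): o for o in overrides}

    calls = pd.DataFrame(False, index=matrix.genome_ids, columns=list(VITAMINS))
    prov = pd.DataFrame("none", index=matrix.genome_ids, columns=list(VITAMINS))
    for gid in matrix.genome_ids:
        present = rules.expand(matrix.roles_of(gid))
        for vitamin in VITAMINS:
            ov = override_map.get((gid, vitamin))
            if ov is not None:
                calls.at[gid, vitamin] = ov.verdict
                prov.at[gid, vitamin] = "override"
                continue
            verdict, tag = evaluate_rule(present, rules[vitamin])
            calls.at[gid, vitamin] = verdict
            prov.at[gid, vitamin] = tag
    return PredictionTable(calls, prov)


MAX_ORACLE_ROLES = 20


def brute_force_oracle(
    rule: VitaminRule,
    rules: RuleSet,
    universe: list[str] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Exhaustive truth table of a rule over all 2^n atomic presence vectors.

    Enumerates every subset of the rule's atomic-role universe, evaluates
    the rule semantics by direct (vectorised) definition, and returns
    ``(universe, verdicts)`` where ``verdicts[k]`` corresponds to the
    presence vector whose bit ``i`` (role ``universe[i]``) is ``(k >> i) & 1``.
    Independent of :func:`evaluate_rule`; used to cross-check it.
    """
    if universe is None:
        universe = rules.atomic_universe(rule)
    n = len(universe)
    if n > MAX_ORACLE_ROLES:
        raise ValidationError(
            f"oracle universe too large: {n} roles (max {MAX_ORACLE_ROLES})"
        )
    idx = np.arange(2**n, dtype=np.uint32)
    atom_present = {
        role: ((idx >> i) & 1).astype(bool) for i, role in enumerate(universe)
    }
    zeros = np.zeros(2**n, dtype=bool)

    def token_present(token: str) -> np.ndarray:
        if token in rules.subsets:
            cols = [atom_present.get(m, zeros) for m in rules.subsets[token].members]
            return np.logical_and.reduce(cols)
        return atom_present.get(token, zeros)

    def term_satisfied(term: Term) -> np.ndarray:
        return np.logical_or.reduce([token_present(a) for a in term])

    verdicts = zeros.copy()
    for line in rule.lines:
        verdicts |= np.logical_and.reduce([term_satisfied(t) for t in line.terms])
    if rule.max_missing > 0:
        mandatory_ok = (
            np.logical_and.reduce([token_present(m) for m in rule.mandatory])
            if rule.mandatory
            else ~zeros
        )
        for line in rule.lines:
            hard_ok = ~zeros
            n_missing_tolerable = np.zeros(2**n, dtype=np.int16)
            for term in line.terms:
                sat = term_satisfied(term)
                if len(term) == 1 and term[0] in rule.tolerable:
                    n_missing_tolerable += (~sat).astype(np.int16)
                else:
                    hard_ok &= sat
            verdicts |= (
                hard_ok
                & (n_missing_tolerable > 0)
                & (n_missing_tolerable <= rule.max_missing)
                & mandatory_ok
            )
    return universe, verdicts


def _group_by_rank(records: list[GenomeRecord], rank: str) -> dict[str, list[str]]:
    valid = TAXONOMIC_RANKS + ("cohort",)
    if rank not in valid:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {valid}")
    groups: dict[str, list[str]] = {}
    for rec in records:
        taxon = rec.rank(rank)
        if not taxon:
            continue
        groups.setdefault(taxon, []).append(rec.genome_id)
    return groups


def role_prevalence(
    matrix: RoleMatrix,
    taxonomy: list[GenomeRecord],
    ids: list[str],
    rank: str = "phylum",
    subsets: dict[str, RoleSubset] | None = None,
) -> pd.DataFrame:
    """Fraction of genomes per taxon carrying each role (or full subset).

    Genomes present in the matrix but absent from the taxonomy are excluded
    from the summary with a logged warning; taxa with zero genomes never
    appear.
    """
    tax = taxonomy_index(taxonomy)
    known = set(matrix.genome_ids)
    records = [r for r in taxonomy if r.genome_id in known]
    dropped = known - set(tax)
    if dropped:
        logger.warning(
            "%d genome(s) in matrix lack taxonomy and are excluded from summaries",
            len(dropped),
        )
    groups = _group_by_rank(records, rank)
    subsets = subsets or {}
    rows = []
    for taxon in sorted(groups):
        gids = groups[taxon]
        sub = matrix.presence.loc[gids]
        for rid in ids:
            if rid in subsets:
                members = list(subsets[rid].members)
                missing = [m for m in members if m not in sub.columns]
                if missing:
                    raise ValidationError(
                        f"subset {rid!r} member(s) absent from matrix: {missing}"
                    )
                present = (sub[members] == 1).all(axis=1)
            else:
                if rid not in sub.columns:
                    raise ValidationError(f"role {rid!r} absent from matrix")
                present = sub[rid] == 1
            n_present = int(present.sum())
            rows.append(
                {
                    rank: taxon,
                    "id": rid,
                    "n_present": n_present,
                    "n_taxon": len(gids),
                    "fraction": n_present / len(gids),
                }
            )
    return pd.DataFrame(rows, columns=[rank, "id", "n_present", "n_taxon", "fraction"])


def producer_prevalence(
    predictions: PredictionTable,
    taxonomy: list[GenomeRecord],
    rank: str = "phylum",
) -> pd.DataFrame:
    """Fraction of predicted producers per taxon and vitamin.

    ``rank="cohort"`` groups by the cohort label, giving whole-cohort
    producer ratios (the HGM ratios of the supply model).
    """
    known = set(predictions.genome_ids)
    records = [r for r in taxonomy if r.genome_id in known]
    if len(records) < len(known):
        logger.warning(
            "%d genome(s) in predictions lack taxonomy and are excluded",
            len(known) - len(records),
        )
    groups = _group_by_rank(records, rank)
    rows = []
    for taxon in sorted(groups):
        gids = groups[taxon]
        sub = predictions.calls.loc[gids]
        for vitamin in VITAMINS:
            n_prod = int(sub[vitamin].sum())
            rows.append(
                {
                    rank: taxon,
                    "vitamin": vitamin,
                    "n_producers": n_prod,
                    "n_taxon": len(gids),
                    "fraction": n_prod / len(gids),
                }
            )
    return pd.DataFrame(
        rows, columns=[rank, "vitamin", "n_producers", "n_taxon", "fraction"]
    )
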