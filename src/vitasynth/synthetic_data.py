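"""Synthetic cohorts with planted ground truth.

Generates role matrices, taxonomies and evidence tables whose true
producer status is known by construction, so every pipeline stage can be
tested end-to-end without external downloads.  The generator emulates the
statistical structure of curated gut-microbiome annotation data: taxonomic
block structure over five phyla, per-(phylum, vitamin) producer
probabilities, complete essential-role sets for producers, rule-breaking
deletions for non-producers, and optional vitamin-transporter roles in
non-producers (a need-for-the-vitamin signal).

Generation is rejection-verified: every genome is re-evaluated through the
rule engine and corrected until its calls equal the planted truth, rather
than trusting the construction — tolerances make naive deletion unsafe.
All randomness flows from one integer seed through a single generator
stream; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    EvidenceRecord,
    EvidenceTable,
    GenomeRecord,
    RoleMatrix,
    VITAMINS,
    ValidationError,
)
from .predict import PredictionTable, RuleSet, VitaminRule, evaluate_rule

#: Transporter/salvage role emitted (with probability ``transporter_prob``)
#: in non-producers of the corresponding vitamin.
TRANSPORTERS = {
    "biotin": "BioY",
    "pantothenate": "PANF",
    "riboflavin": "RibU",
    "niacin": "PnuC",
    "pyridoxine": "PdxK",
}

#: Default human-gut-like cohort: five phyla at realistic cohort sizes.
HGM_PHYLA = (
    ("Actinobacteria", 23),
    ("Bacteroidetes", 51),
    ("Firmicutes", 130),
    ("Fusobacteria", 14),
    ("Proteobacteria", 38),
)

#: Per-(phylum, vitamin) producer probabilities for the default gut-like
#: cohort, set to the per-phylum producer fractions characteristic of gut
#: genomes (cohort-level fractions land in the 40-65% band).
HGM_PRODUCER_PROB = {
    "Actinobacteria": {
        "biotin": 0.0,
        "cobalamin": 0.09,
        "folate": 0.26,
        "niacin": 0.87,
        "pantothenate": 0.13,
        "pyridoxine": 0.87,
        "riboflavin": 0.09,
        "thiamin": 0.65,
    },
    "Bacteroidetes": {
        "biotin": 0.96,
        "cobalamin": 0.51,
        "folate": 0.92,
        "niacin": 1.0,
        "pantothenate": 1.0,
        "pyridoxine": 0.94,
        "riboflavin": 1.0,
        "thiamin": 0.98,
    },
    "Firmicutes": {
        "biotin": 0.05,
        "cobalamin": 0.43,
        "folate": 0.14,
        "niacin": 0.38,
        "pantothenate": 0.32,
        "pyridoxine": 0.25,
        "riboflavin": 0.50,
        "thiamin": 0.33,
    },
    "Fusobacteria": {
        "biotin": 1.0,
        "cobalamin": 1.0,
        "folate": 0.79,
        "niacin": 0.86,
        "pantothenate": 0.0,
        "pyridoxine": 0.21,
        "riboflavin": 1.0,
        "thiamin": 1.0,
    },
    "Proteobacteria": {
        "biotin": 0.84,
        "cobalamin": 0.26,
        "folate": 0.71,
        "niacin": 0.76,
        "pantothenate": 0.95,
        "pyridoxine": 0.63,
        "riboflavin": 0.95,
        "thiamin": 0.79,
    },
}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``producer_prob`` may be a scalar (every phylum and vitamin), a
    per-vitamin mapping, or a per-phylum mapping of per-vitamin mappings.
    ``noise`` is the dropout probability for *tolerated* roles in producer
    genomes (bounded by each rule's ``max_missing``, so planted truth is
    preserved).  ``planted_pairs`` is an optional list of
    ``(pattern, count, count_complement)`` triples consumed by
    :func:`plant_pattern_pairs`.
    """

    seed: int
    phyla: tuple[tuple[str, int], ...] = (("SynthPhylum", 50),)
    producer_prob: float | dict = 0.5
    noise: float = 0.0
    transporter_prob: float = 0.0
    cohort: str = "HGM"
    planted_pairs: tuple[tuple[str, int, int], ...] = ()
    n_filler: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for _, n in self.phyla:
            if n < 0:
                raise ValidationError("phylum genome counts must be >= 0")
        for p in (self.noise, self.transporter_prob):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0, 1]")

    def prob(self, phylum: str, vitamin: str) -> float:
        if isinstance(self.producer_prob, (int, float)):
            p = float(self.producer_prob)
        elif phylum in self.producer_prob:
            p = float(self.producer_prob[phylum][vitamin])
        else:
            p = float(self.producer_prob[vitamin])
        if not (0 <= p <= 1):
            raise ValidationError(f"producer probability {p} out of [0, 1]")
        return p

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "phyla" in cfg:
            cfg["phyla"] = tuple((p["name"], int(p["n"])) for p in cfg["phyla"])
        if "planted_pairs" in cfg:
            cfg["planted_pairs"] = tuple(tuple(t) for t in cfg["planted_pairs"])
        return cls(**cfg)


def hgm_like_spec(seed: int, noise: float = 0.0, transporter_prob: float = 0.8) -> CohortSpec:
    """The default gut-like study conditions (256 genomes over five phyla)."""
    return CohortSpec(
        seed=seed,
        phyla=HGM_PHYLA,
        producer_prob=HGM_PRODUCER_PROB,
        noise=noise,
        transporter_prob=transporter_prob,
        cohort="HGM",
    )


def nonhgm_like_spec(seed: int, noise: float = 0.0, transporter_prob: float = 0.5) -> CohortSpec:
    """A contrast cohort (257 genomes) with shifted phylum mix and producer rates."""
    phyla = (
        ("Actinobacteria", 60),
        ("Bacteroidetes", 20),
        ("Firmicutes", 110),
        ("Fusobacteria", 12),
        ("Proteobacteria", 55),
    )
    probs = {
        ph: {v: min(1.0, max(0.0, 0.15 + 0.7 * p)) for v, p in vm.items()}
        for ph, vm in HGM_PRODUCER_PROB.items()
    }
    return CohortSpec(
        seed=seed,
        phyla=phyla,
        producer_prob=probs,
        noise=noise,
        transporter_prob=transporter_prob,
        cohort="nonHGM",
    )


@dataclass
class TruthTable:
    """Planted producer booleans per genome and vitamin."""

    calls: pd.DataFrame  # bool, genomes x 8 vitamins

    def __post_init__(self) -> None:
        self.calls = self.calls[list(VITAMINS)].astype(bool)
        self.calls.index.name = "genome_id"

    def pattern(self, genome_id: str) -> str:
        row = self.calls.loc[genome_id]
        return "".join("1" if row[v] else "0" for v in VITAMINS)

    def as_predictions(self) -> PredictionTable:
        prov = pd.DataFrame("planted", index=self.calls.index, columns=list(VITAMINS))
        return PredictionTable(self.calls.copy(), prov)

    def write_tsv(self, path) -> None:
        self.calls.astype(int).to_csv(path, sep="\t", index_label="genome_id")


def _breakable_atoms(rule: VitaminRule, rules: RuleSet) -> set[str]:
    """Atoms whose deletion the tolerance cannot rescue."""
    atoms = set(rules.atomic_universe(rule))
    if rule.max_missing > 0:
        if rule.mandatory:
            hard = set()
            for m in rule.mandatory:
                if m in rules.subsets:
                    hard.update(rules.subsets[m].members)
                else:
                    hard.add(m)
            return hard
        breakable = atoms - rule.tolerable
        if not breakable:
            raise ValidationError(
                f"rule for {rule.vitamin!r}: tolerance rescues every deletion; "
                "cannot guarantee a non-producer"
            )
        return breakable
    return atoms


def _line_atoms(rng: np.random.Generator, rule: VitaminRule, rules: RuleSet) -> set[str]:
    """Atoms satisfying one randomly chosen line (one alternative per OR-group)."""
    line = rule.lines[rng.integers(len(rule.lines))]
    atoms: set[str] = set()
    for term in line.terms:
        token = term[rng.integers(len(term))] if len(term) > 1 else term[0]
        if token in rules.subsets:
            atoms.update(rules.subsets[token].members)
        else:
            atoms.add(token)
    return atoms


def _emit_vitamin_roles(
    rng: np.random.Generator,
    rule: VitaminRule,
    rules: RuleSet,
    producer: bool,
    noise: float,
    transporter_prob: float,
) -> set[str]:
    atoms = _line_atoms(rng, rule, rules)
    if producer:
        if noise > 0 and rule.max_missing > 0:
            droppable = sorted(atoms & rule.tolerable)
            drop = [a for a in droppable if rng.random() < noise][: rule.max_missing]
            atoms -= set(drop)
        assert evaluate_rule(rules.expand(frozenset(atoms)), rule)[0]
        return atoms
    # non-producer: delete rule-breaking atoms until the call flips
    breakable = _breakable_atoms(rule, rules)
    while evaluate_rule(rules.expand(frozenset(atoms)), rule)[0]:
        candidates = sorted(atoms & breakable)
        if not candidates:
            raise ValidationError(
                f"cannot break producer status for {rule.vitamin!r}"
            )
        atoms.discard(candidates[rng.integers(len(candidates))])
    transporter = TRANSPORTERS.get(rule.vitamin)
    if transporter and rng.random() < transporter_prob:
        atoms.add(transporter)
    return atoms


def _role_universe(rules: RuleSet) -> list[str]:
    if rules.declared_roles is not None:
        return sorted(rules.declared_roles)
    atoms: set[str] = set()
    for rule in rules:
        atoms.update(rules.atomic_universe(rule))
    atoms.update(TRANSPORTERS.values())
    return sorted(atoms)


def _assemble(
    spec: CohortSpec,
    rules: RuleSet,
    genome_plan: list[tuple[str, str, dict[str, bool]]],
    rng: np.random.Generator,
) -> tuple[RoleMatrix, list[GenomeRecord], TruthTable]:
    """Emit roles for planned (genome_id, phylum, truth) rows and verify."""
    universe = _role_universe(rules)
    col_index = {r: i for i, r in enumerate(universe)}
    presence = np.zeros((len(genome_plan), len(universe)), dtype="int8")
    taxonomy: list[GenomeRecord] = []
    truth_rows = []
    for i, (gid, phylum, truth) in enumerate(genome_plan):
        roles: set[str] = set()
        for vitamin in VITAMINS:
            roles |= _emit_vitamin_roles(
                rng,
                rules[vitamin],
                rules,
                truth[vitamin],
                spec.noise,
                spec.transporter_prob,
            )
        # rejection verification: the combined role set must reproduce the
        # planted truth for every vitamin (role sharing between rules could
        # otherwise upgrade a planted non-producer)
        for _ in range(100):
            expanded = rules.expand(frozenset(roles))
            wrong = [
                v
                for v in VITAMINS
                if evaluate_rule(expanded, rules[v])[0] != truth[v]
            ]
            if not wrong:
                break
            for v in wrong:
                if truth[v]:
                    roles |= _line_atoms(rng, rules[v], rules)
                else:
                    breakable = _breakable_atoms(rules[v], rules)
                    candidates = sorted(roles & breakable)
                    if not candidates:
                        raise ValidationError(
                            f"cannot break {v!r} for genome {gid!r}"
                        )
                    roles.discard(candidates[rng.integers(len(candidates))])
        else:
            raise ValidationError(f"verification failed for genome {gid!r}")
        for r in roles:
            if r in col_index:
                presence[i, col_index[r]] = 1
        taxonomy.append(GenomeRecord(gid, name=gid, phylum=phylum, cohort=spec.cohort))
        truth_rows.append({"genome_id": gid, **truth})
    gids = [g for g, _, _ in genome_plan]
    matrix = RoleMatrix(pd.DataFrame(presence, index=gids, columns=universe))
    truth_df = pd.DataFrame(truth_rows).set_index("genome_id")
    return matrix, taxonomy, TruthTable(truth_df)


def generate_cohort(
    spec: CohortSpec, rules: RuleSet | None = None
) -> tuple[RoleMatrix, list[GenomeRecord], TruthTable]:
    """Generate a cohort with Bernoulli-planted producer status.

    Producers receive a complete essential-role set for one randomly chosen
    rule line (minus tolerated dropouts when ``noise`` > 0); non-producers
    receive the set minus rule-breaking deletions, verified through the
    rule engine.  Deterministic under a fixed seed.
    """
    rules = rules or RuleSet.default()
    rng = np.random.default_rng(spec.seed)
    genome_plan: list[tuple[str, str, dict[str, bool]]] = []
    idx = 0
    for phylum, n in spec.phyla:
        for _ in range(n):
            gid = f"{spec.cohort}-{idx:04d}"
            truth = {
                v: bool(rng.random() < spec.prob(phylum, v)) for v in VITAMINS
            }
            genome_plan.append((gid, phylum, truth))
            idx += 1
    return _assemble(spec, rules, genome_plan, rng)


def plant_pattern_pairs(
    spec: CohortSpec, rules: RuleSet | None = None
) -> tuple[RoleMatrix, list[GenomeRecord], TruthTable]:
    """Generate a cohort containing exactly the requested complement pairs.

    Each ``(pattern, count, count_complement)`` triple in
    ``spec.planted_pairs`` contributes that many genomes on each side.
    ``spec.n_filler`` extra genomes receive rejection-sampled patterns that
    are mutually distinct, distinct from the planted ones, and whose
    complements are absent — so the inversed-pair count of the cohort is
    exactly ``len(spec.planted_pairs)``.
    """
    from .patterns import complement, validate_pattern

    rules = rules or RuleSet.default()
    rng = np.random.default_rng(spec.seed)
    patterns = [validate_pattern(p) for p, _, _ in spec.planted_pairs]
    if len(set(patterns)) != len(patterns):
        raise ValidationError("planted pair patterns must be distinct")
    used: set[str] = set()
    plan: list[tuple[str, str, dict[str, bool]]] = []
    phylum = spec.phyla[0][0]
    idx = 0

    def add(pattern: str, n: int) -> None:
        nonlocal idx
        truth = {v: pattern[k] == "1" for k, v in enumerate(VITAMINS)}
        for _ in range(n):
            plan.append((f"{spec.cohort}-{idx:04d}", phylum, dict(truth)))
            idx += 1

    for pattern, n_a, n_b in spec.planted_pairs:
        comp = complement(pattern)
        if comp in patterns and pattern > comp:
            raise ValidationError(
                f"pair ({pattern}, {comp}) listed twice; list each pair once"
            )
        used.update({pattern, comp})
        add(pattern, n_a)
        add(comp, n_b)
    for _ in range(spec.n_filler):
        for _ in range(10_000):
            candidate = "".join(rng.choice(["0", "1"], size=len(VITAMINS)))
            if candidate not in used and complement(candidate) not in used:
                used.add(candidate)
                add(candidate, 1)
                break
        else:
            raise ValidationError("could not sample a complement-free filler pattern")
    return _assemble(spec, rules, plan, rng)


def generate_evidence(
    truth: TruthTable, n_strains: int, error_rate: float, seed: int
) -> tuple[EvidenceTable, dict[str, str]]:
    """Evidence that flips planted truth with probability ``error_rate``.

    Expected concordance against perfect predictions is ``1 - error_rate``.
    Returns the table and the organism-to-genome mapping.
    """
    if n_strains > len(truth.calls):
        raise ValidationError(
            f"n_strains={n_strains} exceeds cohort size {len(truth.calls)}"
        )
    if not (0 <= error_rate <= 1):
        raise ValidationError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gids = list(truth.calls.index[:n_strains])
    records = []
    mapping = {}
    for gid in gids:
        organism = f"Strain {gid}"
        mapping[organism] = gid
        for vitamin in VITAMINS:
            produces = bool(truth.calls.at[gid, vitamin])
            if rng.random() < error_rate:
                produces = not produces
            records.append(
                EvidenceRecord(
                    organism=organism,
                    genome_id=gid,
                    vitamin=vitamin,
                    evidence="producer_equivalent" if produces else "nonproducer_equivalent",
                    source="synthetic",
                )
            )
    return EvidenceTable(records), mapping


def predictions_with_pattern_profile(
    n_genomes: int,
    n_distinct: int,
    n_pairs: int,
    seed: int,
    prefix: str = "G",
) -> PredictionTable:
    """Synthetic prediction table with an exact pattern-census profile.

    Plants exactly ``n_distinct`` distinct pathway patterns over
    ``n_genomes`` genomes, of which exactly ``n_pairs`` complement pairs
    are present (all other patterns have absent complements).  A synthetic
    stand-in for supplement-scale per-genome call tables, used to exercise
    the census and inversed-pair machinery at realistic profile sizes.
    """
    from .patterns import complement

    if n_distinct > n_genomes:
        raise ValidationError("cannot have more distinct patterns than genomes")
    if 2 * n_pairs > n_distinct:
        raise ValidationError("n_distinct too small for the requested pair count")
    if n_distinct > 2 ** len(VITAMINS):
        raise ValidationError("n_distinct exceeds the pattern space")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    used: set[str] = set()
    while len(chosen) < 2 * n_pairs:
        p = format(int(rng.integers(2 ** len(VITAMINS))), f"0{len(VITAMINS)}b")
        q = complement(p)
        if p in used or q in used:
            continue
        chosen.extend([p, q])
        used.update({p, q})
    while len(chosen) < n_distinct:
        p = format(int(rng.integers(2 ** len(VITAMINS))), f"0{len(VITAMINS)}b")
        if p in used or complement(p) in used:
            continue
        chosen.append(p)
        used.add(p)
    # every pattern appears at least once; spread the remainder randomly
    counts = np.ones(n_distinct, dtype=int)
    extra = rng.multinomial(n_genomes - n_distinct, np.full(n_distinct, 1 / n_distinct))
    counts += extra
    rows = []
    gids = []
    idx = 0
    for pattern, count in zip(chosen, counts):
        bits = {v: pattern[k] == "1" for k, v in enumerate(VITAMINS)}
        for _ in range(int(count)):
            gids.append(f"{prefix}{idx:04d}")
            rows.append(bits)
            idx += 1
    calls = pd.DataFrame(rows, index=gids)
    prov = pd.DataFrame("planted", index=gids, columns=list(VITAMINS))
    return PredictionTable(calls, prov)


#: Number of strains and planted disagreements of the published-scale
#: concordance comparison (16 strains x 8 vitamins, 15 mismatches).
EVIDENCE_PANEL_N_STRAINS = 16
EVIDENCE_PANEL_N_MISMATCHES = 15


def evidence_panel_stand_in() -> tuple[PredictionTable, EvidenceTable, dict[str, str]]:
    """Synthetic stand-in for the published prediction-vs-evidence table.

    The published cell-level comparison (16 strains x 8 vitamins with 113
    agreements out of 128) is only available as a figure; this fixture
    reproduces its *structure* — the same dimensions and the same number of
    planted disagreements — with synthetic strains, so the scoring path can
    be exercised at the published scale.  The contents are synthetic, not a
    transcription.
    """
    rng = np.random.default_rng(1280113)
    gids = [f"EV-{i:02d}" for i in range(EVIDENCE_PANEL_N_STRAINS)]
    calls = pd.DataFrame(
        rng.random((EVIDENCE_PANEL_N_STRAINS, len(VITAMINS))) < 0.55,
        index=gids,
        columns=list(VITAMINS),
    )
    prov = pd.DataFrame("planted", index=gids, columns=list(VITAMINS))
    predictions = PredictionTable(calls, prov)
    n_cells = EVIDENCE_PANEL_N_STRAINS * len(VITAMINS)
    flip_flat = rng.choice(n_cells, size=EVIDENCE_PANEL_N_MISMATCHES, replace=False)
    flips = {(int(k) // len(VITAMINS), int(k) % len(VITAMINS)) for k in flip_flat}
    records = []
    mapping = {}
    for i, gid in enumerate(gids):
        organism = f"Synthetic strain {i + 1:02d}"
        mapping[organism] = gid
        for j, vitamin in enumerate(VITAMINS):
            produces = bool(calls.at[gid, vitamin])
            if (i, j) in flips:
                produces = not produces
            records.append(
                EvidenceRecord(
                    organism=organism,
                    genome_id=gid,
                    vitamin=vitamin,
                    evidence="producer_equivalent" if produces else "nonproducer_equivalent",
                    source="synthetic",
                )
            )
    return predictions, EvidenceTable(records), mapping
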