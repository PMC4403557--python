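# Methods

## Producer prediction

A genome is called a producer of a vitamin when its annotated functional
roles satisfy the vitamin's rule — a disjunction of conjunctive lines over
role ids, with OR-groups for alternative enzymes. The packaged default
rules cover the eight B-vitamins with the line counts biotin 2, cobalamin 2
(aerobic route listed before anaerobic; provenance records the first
satisfied line in config order), folate 1, niacin 1, pantothenate 1,
pyridoxine 2, riboflavin 1, thiamin 2.

Biological sufficiency conventions are encoded purely by which roles appear
in the lines, with no special-case logic:

- thiamin-monophosphate production suffices for thiamin producer status
  (no thiamin-diphosphate kinase requirement);
- dihydrofolate or tetrahydrofolate production suffices for folate, and of
  the PABA branch only pabAc vetoes (pabAa/pabAb are too unreliably
  annotated to be essential);
- FolQ and PyrP are absent from the essential lists because they are
  commonly missing from genome annotations despite the pathways being
  functional.

The single engine-level special case is the declarative *tolerance*: the
pantothenate/CoA rule forgives one missing enzyme among the early branched
steps (KPHMT, KPRED, ASPDC) while PBAL and the four CoA steps (PANK, PPCS,
PPCDC, DPCK) are mandatory and always veto. Tolerances are configured per
vitamin, not hard-coded, so user rule sets can declare their own.

Manual curation verdicts are supplied as override records with a mandatory
free-text justification and take precedence over the engine; every call's
provenance is exactly one of `line:<i>`, `tolerance:<i>`, `override`, or
`none`.

**Compound role tokens.** Compound mnemonics are declared as subsets of
atomic roles in the default config, expanded letter-wise (e.g. BioFADB =
{BioF, BioA, BioD, BioB}, PdxBFAJH = {PdxB, PdxF, PdxA, PdxJ, PdxH}).
Two nomenclature collisions in the cobalamin pathway are resolved with
qualified tokens: the aerobic cobaltochelatase subunits are CobN/CobSch/
CobTch and the cobalamin synthase is CobV, keeping them distinct from the
nucleotide-loop roles CobU/CobS/CobT that every route requires. CbiKX is
kept as a single atomic role naming the CbiK/CbiX chelatase family. All of
this lives in the editable YAML config, not in code.

**Verification oracle.** `brute_force_oracle` enumerates all 2^n presence
vectors of a rule's atomic universe (n ≤ 20; the largest default rule,
cobalamin, has exactly 20 atoms) and evaluates the rule semantics by a
direct vectorised definition, independent of the scalar engine. The test
suite checks scalar/oracle agreement exhaustively for every default rule.
Producer calls are monotone: adding roles to a genome can never flip a
producer to a non-producer (tolerances and overrides preserve this), and
this is property-tested.

## Pattern analysis

Patterns are the ordered 8-bit strings of producer calls in alphabetical
vitamin order (biotin, cobalamin, folate, niacin, pantothenate, pyridoxine,
riboflavin, thiamin); the same order fixes heatmap-export columns, so
outputs are deterministic. Pattern strings, not integers, are the
interchange form in all files. Complementation is an involution, and at
even pattern length no pattern equals its own complement, so inversed pairs
always have two distinct sides; the code asserts rather than handles the
self-complement case. Because the published pair counts can be read as
patterns or as genomes, `InversedPairSet` reports both (`n_pairs` and
`n_genomes`).

## Concordance

Evidence semantics: "vitamin required in a defined growth medium" maps to
`nonproducer_equivalent`, "grows without it / secretes it" to
`producer_equivalent`, ambiguous reports to `unknown` (excluded from the
denominator). Strain-vs-species comparisons go through an explicit
organism→genome mapping file. The published cell-level comparison table is
available only as a figure in the source we work from, so the
published-scale check uses a synthetic stand-in
(`synthetic_data.evidence_panel_stand_in`) with the same structure — 16 strains ×
8 vitamins and 15 planted disagreements — exercised through the real
scoring path.

## Supply model

Assumptions, with defaults (all editable in `data/supply.yaml`):

| parameter | default | meaning |
|---|---|---|
| n_cells | 1·10¹⁴ | bacterial cells in the colonic space |
| cell_dry_mass | 4.89·10⁻¹³ gDW | E. coli reference dry mass per cell |
| cell_volume | 1.1·10⁻¹⁵ L | E. coli reference cell volume (1.1 µm³) |
| dead_fraction | 0.317 | fraction of cells dead in fecal matter; lysis releases intracellular vitamins |
| growth_rate | 0.26 h⁻¹ | anaerobic E. coli growth rate, converts production rates to content |
| avogadro | 6.02214·10²³ | fixed in config |

The dead fraction multiplies available biomass: only lysed cells release
their vitamin pool to the host. Molar masses are packaged ChEBI values for
the measured chemical form — biotin 244.31, cobalamin 1329.35,
dihydrofolic acid 443.41, nicotinic acid 123.11, pantothenic acid 219.23,
pyridoxine 5′-phosphate 249.16, riboflavin 376.36, thiamine monophosphate
345.3 g/mol. The cobalamin form is not pinned down by the source
measurements; cobalamin (1329.35) and cyanocobalamin (1355.37) differ by
2 % in the final percentage and both round to the same printed value.

Unit conversions to mmol/gDW: molar and mass-per-volume measurements scale
by cell_volume/cell_dry_mass; molecules-per-cell divides by Avogadro ×
cell_dry_mass; mass-per-gDW divides by molar mass; production rates divide
by the growth rate (steady-state content of an exponentially growing
culture) and rescale mgDW → gDW. The conversion chain is dimensionally
consistent (round-trip property-tested) and %DRI is linear in every factor
and inverse in DRI.

Two literature rows do not convert consistently and are *flagged, not
forced* (`audit_conversions` logs them; the canonical concentration column
is used for %DRI): the biotin measurement (40 µM) converts 100-fold above
the canonical 9.0·10⁻⁷ mmol/gDW, and the niacin measurement (1.12·10⁶
molecules/cell) converts to 3.8·10⁻³ rather than the canonical 3.3·10⁻³.
Correspondingly the niacin percentage recomputes to ≈26 rather than the
commonly quoted 27, and pantothenate to 0.080 rather than 0.078 —
path-dependent rounding upstream of this package. The folate measurement
(22 µM) converts to 4.95·10⁻⁵, within one unit of the last digit of the
canonical 5.0·10⁻⁵; the pantothenate measurement is a < 1 µM upper bound
and is used at its bound, consistent with the model being a maximal
estimate. Display rounding is two significant figures for concentrations;
all internal computation is full precision.

## Synthetic data

The generator emulates curated annotation data for cohort-level analyses:

- taxonomic block structure — genomes are drawn from named phyla with
  per-(phylum, vitamin) producer probabilities; the default gut-like
  conditions use five phyla at cohort sizes 23/51/130/14/38 (= 256
  genomes) with per-phylum producer rates characteristic of gut genomes,
  so cohort-level fractions land in the 40–65 % band. Rates not directly
  constrained by published per-phylum figures (niacin in Actinobacteria,
  thiamin in Firmicutes/Proteobacteria) were fixed once to match the known
  cohort totals.
- producers receive a complete essential-role set for one randomly chosen
  rule line (one alternative per OR-group); optional `noise` drops
  tolerated roles within `max_missing`, which by construction never flips
  the planted call;
- non-producers receive the set minus rule-breaking deletions. The
  breakable set is the declared mandatory ids when a tolerance exists,
  otherwise every non-tolerable essential id; if a tolerance could rescue
  every deletion the generator refuses (it cannot guarantee breakage).
  With probability `transporter_prob` a non-producer carries the vitamin's
  transporter/salvage role (BioY, PANF, RibU, PnuC, PdxK) — the
  "needs-the-vitamin" signal seen in real genomes;
- every genome is rejection-verified through the rule engine against the
  planted truth rather than trusting construction;
- all randomness flows from one integer seed through a single numpy
  generator; identical spec + seed gives byte-identical files.

What the generator does **not** emulate: annotation error structure beyond
role dropout, horizontal transfer, genome incompleteness gradients,
correlated pathway loss, or within-phylum taxonomic substructure. Passing
tests therefore demonstrate that the pipeline machinery is correct on data
with known truth, not that the default rules are biologically correct for
any particular real genome.

`plant_pattern_pairs` builds cohorts containing exactly a requested set of
complement pattern pairs plus filler genomes whose patterns are rejection-
sampled to be mutually distinct and complement-free, so the inversed-pair
count is exact by construction. `predictions_with_pattern_profile` builds
prediction tables with an exact (n genomes, n distinct patterns, n pairs)
census profile — used to exercise the census machinery at the scale of
published per-genome call supplements (256 genomes / 68 patterns / 10
pairs), which are not redistributable as desk-scale fixtures.

## Numerical and design choices

- Role ids are opaque and case-sensitive; matrices are TSV with genomes as
  rows (the spreadsheet orientation), cells strictly 0/1.
- Genomes present in a matrix but missing from the taxonomy are allowed:
  they are predicted normally and excluded from taxon summaries with a
  logged warning.
- Vitamin order is fixed alphabetically everywhere; the order defines
  pattern bit positions, so changing it would silently change every
  pattern string — it is deliberately not configurable.
- The rule config may declare the atomic-role universe (`roles:`); when it
  does, rule lines referencing undeclared ids fail at load time, catching
  typos that would otherwise read as permanently-absent roles.
- Degenerate inputs: empty matrices (header only) are valid; empty
  presence sets are non-producers of everything; an empty pattern census
  has no pairs and contributes nothing to comparisons.
- Exit codes of the CLI: 0 ok, 2 validation error, 3 stage failure.

## Problem sizes

The test suite and the analysis scripts run on cohorts of 250–513 genomes
(the scale of the real curated collections), exhaustive rule verification
up to 2²⁰ presence vectors, and 30-replicate evidence simulations; the
whole suite completes in well under a minute on one CPU.

## Known limitations

- Producer calls are binary; there is no fractional pathway-completeness
  score, by design.
- The supply estimate is an upper bound with strong assumptions (complete
  lysis release, colonic dead fraction equated to the fecal measurement,
  E. coli cell geometry for all taxa); it is a capacity estimate, not a
  flux prediction.
- No statistical enrichment test for pattern pairs is provided — observed
  counts only.
- The default compound-role expansions are a documented editorial choice;
  users with access to the underlying subsystem definitions should verify
  them against their curation before applying the rules to real matrices.
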