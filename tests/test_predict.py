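"""Rule-engine semantics, oracle agreement, predictions and prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vitasynth.annotations import GenomeRecord, RoleMatrix, VITAMINS, ValidationError
from vitasynth.predict import (
    OverrideRecord,
    RuleSet,
    brute_force_oracle,
    evaluate_rule,
    parse_rule_line,
    predict_cohort,
    producer_prevalence,
    role_prevalence,
)
from vitasynth.synthetic_data import CohortSpec, generate_cohort


def presence_from_index(universe, k):
    return frozenset(universe[i] for i in range(len(universe)) if (k >> i) & 1)


class TestEvaluateRule:
    def test_biotin_malonyl_route_satisfies(self, rules):
        verdict, tag = evaluate_rule({"BioC", "BioFADB"}, rules["biotin"])
        assert verdict and tag == "line:2"

    def test_biotin_pimelate_route_satisfies(self, rules):
        verdict, tag = evaluate_rule({"BioW", "BioFADB"}, rules["biotin"])
        assert verdict and tag == "line:1"

    def test_empty_presence_never_produces(self, rules):
        for vitamin in VITAMINS:
            verdict, tag = evaluate_rule(frozenset(), rules[vitamin])
            assert not verdict and tag == "none"

    def test_pantothenate_single_branch_enzyme_tolerated(self, rules):
        rule = rules["pantothenate"]
        full = {"KPHMT", "KPRED", "ASPDC", "PBAL", "PANK", "PPCS", "PPCDC", "DPCK"}
        verdict, tag = evaluate_rule(full - {"ASPDC"}, rule)
        assert verdict and tag == "tolerance:1"
        # two missing branch enzymes exceed the tolerance
        verdict, _ = evaluate_rule(full - {"ASPDC", "KPHMT"}, rule)
        assert not verdict

    def test_pantothenate_missing_pbal_always_nonproducer(self, rules):
        rule = rules["pantothenate"]
        full = {"KPHMT", "KPRED", "ASPDC", "PBAL", "PANK", "PPCS", "PPCDC", "DPCK"}
        verdict, tag = evaluate_rule(full - {"PBAL"}, rule)
        assert not verdict and tag == "none"

    def test_mandatory_and_tolerable_must_not_overlap(self):
        from vitasynth.predict import VitaminRule

        with pytest.raises(ValidationError, match="tolerable and mandatory"):
            VitaminRule(
                vitamin="biotin",
                lines=(parse_rule_line("A + B"),),
                tolerable=frozenset({"A"}),
                max_missing=1,
                mandatory=frozenset({"A"}),
            )


class TestBruteForceOracle:
    def test_plain_conjunction_truth_table(self):
        rs = RuleSet.from_dict({"vitamins": {"biotin": {"lines": ["A + B"]}}})
        universe, verdicts = brute_force_oracle(rs["biotin"], rs)
        assert len(verdicts) == 4
        assert int(verdicts.sum()) == 1  # only {A, B}

    def test_or_group_truth_table(self):
        rs = RuleSet.from_dict({"vitamins": {"biotin": {"lines": ["(A or B) + C"]}}})
        universe, verdicts = brute_force_oracle(rs["biotin"], rs)
        assert len(verdicts) == 8
        assert int(verdicts.sum()) == 3  # {A,C}, {B,C}, {A,B,C}

    def test_biotin_universe_has_six_roles(self, rules):
        universe, verdicts = brute_force_oracle(rules["biotin"], rules)
        assert len(universe) == 6
        assert len(verdicts) == 64

    def test_oversized_universe_refused(self, rules):
        with pytest.raises(ValidationError, match="too large"):
            brute_force_oracle(
                rules["biotin"], rules, universe=[f"r{i}" for i in range(21)]
            )

    @pytest.mark.parametrize(
        "vitamin",
        ["biotin", "folate", "niacin", "pantothenate", "pyridoxine", "riboflavin", "thiamin"],
    )
    def test_engine_matches_oracle_exhaustively_small_rules(self, rules, vitamin):
        """Scalar evaluation agrees with the enumerated truth table on every
        presence vector (rules with <= 9 atomic roles; the 20-role cobalamin
        rule is covered by the acceptance suite)."""
        rule = rules[vitamin]
        universe, verdicts = brute_force_oracle(rule, rules)
        for k in range(2 ** len(universe)):
            present = rules.expand(presence_from_index(universe, k))
            assert evaluate_rule(present, rule)[0] == bool(verdicts[k])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(k=st.integers(0, 2**20 - 1), extra=st.integers(0, 19))
    def test_monotonicity_adding_roles_never_flips_to_nonproducer(self, rules, k, extra):
        rule = rules["cobalamin"]
        universe = rules.atomic_universe(rule)
        present = presence_from_index(universe, k)
        before = evaluate_rule(rules.expand(present), rule)[0]
        after = evaluate_rule(rules.expand(present | {universe[extra]}), rule)[0]
        assert after or not before


class TestPredictCohort:
    def test_planted_truth_recovered_exactly_with_noise_off(self, rules):
        spec = CohortSpec(
            seed=11,
            phyla=(("Firmicutes", 30), ("Bacteroidetes", 30)),
            producer_prob=0.5,
        )
        matrix, _, truth = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        pd.testing.assert_frame_equal(predictions.calls, truth.calls)

    def test_genome_with_every_role_produces_all_eight(self, rules):
        universe = sorted(rules.declared_roles)
        presence = pd.DataFrame([[1] * len(universe)], index=["g1"], columns=universe)
        predictions = predict_cohort(RoleMatrix(presence), rules)
        assert predictions.calls.loc["g1"].all()

    def test_override_wins_and_is_provenance_flagged(self, rules):
        # genome missing BioC (biotin route incomplete) but curated a producer
        universe = sorted(rules.declared_roles)
        row = {r: 0 for r in universe}
        for r in ("BioF", "BioA", "BioD", "BioB"):
            row[r] = 1
        presence = pd.DataFrame([row], index=["fuso_d11"])
        override = OverrideRecord(
            "fuso_d11", "biotin", True, "all related genomes contain BioC"
        )
        predictions = predict_cohort(RoleMatrix(presence), rules, [override])
        assert predictions.calls.at["fuso_d11", "biotin"]
        assert predictions.provenance.at["fuso_d11", "biotin"] == "override"

    def test_override_for_unknown_genome_rejected(self, rules):
        presence = pd.DataFrame([[1]], index=["g1"], columns=["BioW"])
        override = OverrideRecord("ghost", "biotin", True, "justified")
        with pytest.raises(ValidationError, match="ghost"):
            predict_cohort(RoleMatrix(presence), rules, [override])

    def test_every_positive_call_is_justified(self, rules):
        spec = CohortSpec(seed=3, phyla=(("P", 40),), producer_prob=0.5)
        matrix, _, _ = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        for gid in predictions.genome_ids:
            for v in VITAMINS:
                tag = predictions.provenance.at[gid, v]
                if predictions.calls.at[gid, v]:
                    assert tag.startswith(("line:", "tolerance:")) or tag == "override"
                else:
                    assert tag in ("none", "override")


class TestPrevalence:
    @staticmethod
    def matrix_and_taxonomy():
        presence = pd.DataFrame(
            {"BioG": [1, 1, 1, 0], "BioH": [0, 0, 0, 0]},
            index=["g1", "g2", "g3", "g4"],
        )
        taxonomy = [
            GenomeRecord(g, phylum="Bacteroidetes", cohort="HGM")
            for g in ["g1", "g2", "g3", "g4"]
        ]
        return RoleMatrix(presence), taxonomy

    def test_counted_fraction(self):
        matrix, taxonomy = self.matrix_and_taxonomy()
        table = role_prevalence(matrix, taxonomy, ["BioG"], rank="phylum")
        row = table.iloc[0]
        assert (row["phylum"], row["id"], row["fraction"]) == (
            "Bacteroidetes",
            "BioG",
            0.75,
        )

    def test_absent_role_fraction_zero_and_universal_role_one(self):
        matrix, taxonomy = self.matrix_and_taxonomy()
        table = role_prevalence(matrix, taxonomy, ["BioH"], rank="phylum")
        assert table.iloc[0]["fraction"] == 0.0
        matrix.presence["BioH"] = 1
        table = role_prevalence(matrix, taxonomy, ["BioH"], rank="phylum")
        assert table.iloc[0]["fraction"] == 1.0

    def test_unknown_rank_rejected(self):
        matrix, taxonomy = self.matrix_and_taxonomy()
        with pytest.raises(ValidationError, match="rank"):
            role_prevalence(matrix, taxonomy, ["BioG"], rank="genus")

    def test_cohort_producer_fraction(self, rules):
        spec = CohortSpec(
            seed=5,
            phyla=(("P", 10),),
            producer_prob={v: 0.0 for v in VITAMINS} | {"biotin": 1.0},
        )
        matrix, taxonomy, truth = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        table = producer_prevalence(predictions, taxonomy, rank="cohort")
        biotin = table[table["vitamin"] == "biotin"].iloc[0]
        assert biotin["fraction"] == 1.0
        folate = table[table["vitamin"] == "folate"].iloc[0]
        assert folate["fraction"] == 0.0

    def test_planted_probability_recovered_within_three_binomial_se(self, rules):
        p, n_per_phylum = 0.5, 200
        spec = CohortSpec(
            seed=7, phyla=(("A", n_per_phylum), ("B", n_per_phylum)), producer_prob=p
        )
        matrix, taxonomy, _ = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        table = producer_prevalence(predictions, taxonomy, rank="cohort")
        n = 2 * n_per_phylum
        se = np.sqrt(p * (1 - p) / n)
        for _, row in table.iterrows():
            assert abs(row["fraction"] - p) <= 3 * se
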