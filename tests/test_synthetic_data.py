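"""Planted-truth cohort generation, pattern planting and evidence simulation."""

import io

import numpy as np
import pandas as pd
import pytest

from vitasynth.annotations import VITAMINS, ValidationError, write_role_matrix
from vitasynth.concordance import score_concordance
from vitasynth.patterns import inversed_pairs, pattern_census
from vitasynth.predict import predict_cohort
from vitasynth.synthetic_data import (
    CohortSpec,
    generate_cohort,
    generate_evidence,
    hgm_like_spec,
    plant_pattern_pairs,
    predictions_with_pattern_profile,
    evidence_panel_stand_in,
)


def matrix_bytes(matrix):
    buf = io.StringIO()
    write_role_matrix(matrix, buf)
    return buf.getvalue()


class TestGenerateCohort:
    def test_identical_seed_gives_byte_identical_output(self, rules):
        spec = hgm_like_spec(seed=42, noise=0.3)
        a = generate_cohort(spec, rules)
        b = generate_cohort(spec, rules)
        assert matrix_bytes(a[0]) == matrix_bytes(b[0])
        pd.testing.assert_frame_equal(a[2].calls, b[2].calls)

    def test_forced_producers_yield_all_true(self, rules):
        spec = CohortSpec(seed=1, phyla=(("P", 12),), producer_prob=1.0)
        matrix, _, truth = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        assert predictions.calls.all().all()
        assert truth.calls.all().all()

    def test_forced_nonproducers_yield_all_false(self, rules):
        spec = CohortSpec(seed=1, phyla=(("P", 12),), producer_prob=0.0)
        matrix, _, truth = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        assert not predictions.calls.any().any()
        assert not truth.calls.any().any()

    def test_noise_on_tolerated_roles_preserves_planted_truth(self, rules):
        """Dropout restricted to tolerable roles (within max_missing) must
        never flip a planted producer call."""
        spec = CohortSpec(seed=9, phyla=(("P", 60),), producer_prob=0.6, noise=0.9)
        matrix, _, truth = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        pd.testing.assert_frame_equal(predictions.calls, truth.calls)
        # noise actually removed tolerated pantothenate roles somewhere
        tagged = (predictions.provenance == "tolerance:1").any().any()
        assert tagged

    def test_binomial_prevalence_bound(self, rules):
        p = 0.4
        spec = CohortSpec(
            seed=7,
            phyla=(("A", 100), ("B", 100)),
            producer_prob={v: 0.5 for v in VITAMINS} | {"biotin": p},
        )
        _, _, truth = generate_cohort(spec, rules)
        observed = truth.calls["biotin"].mean()
        assert abs(observed - p) <= 3 * np.sqrt(p * (1 - p) / 200)

    def test_transporters_only_in_nonproducers(self, rules):
        spec = CohortSpec(
            seed=13, phyla=(("P", 40),), producer_prob=0.5, transporter_prob=1.0
        )
        matrix, _, truth = generate_cohort(spec, rules)
        biotin_nonproducers = truth.calls.index[~truth.calls["biotin"]]
        biotin_producers = truth.calls.index[truth.calls["biotin"]]
        assert (matrix.presence.loc[biotin_nonproducers, "BioY"] == 1).all()
        assert (matrix.presence.loc[biotin_producers, "BioY"] == 0).all()


class TestPlantPatternPairs:
    def test_three_planted_pairs_detected(self, rules):
        spec = CohortSpec(
            seed=2,
            planted_pairs=(
                ("11111111", 3, 2),
                ("10101010", 1, 1),
                ("11110000", 4, 1),
            ),
            n_filler=6,
        )
        matrix, _, truth = plant_pattern_pairs(spec, rules)
        predictions = predict_cohort(matrix, rules)
        census = pattern_census(predictions)
        assert inversed_pairs(census).n_pairs == 3

    def test_zero_pairs_with_complement_free_filler(self, rules):
        spec = CohortSpec(seed=3, planted_pairs=(), n_filler=12)
        matrix, _, _ = plant_pattern_pairs(spec, rules)
        census = pattern_census(predict_cohort(matrix, rules))
        assert inversed_pairs(census).n_pairs == 0

    def test_pair_counts_reported_per_side(self, rules):
        spec = CohortSpec(seed=4, planted_pairs=(("11111110", 5, 2),))
        matrix, _, _ = plant_pattern_pairs(spec, rules)
        census = pattern_census(predict_cohort(matrix, rules))
        (pair,) = inversed_pairs(census).pairs
        counts = {pair.low: pair.count_low, pair.high: pair.count_high}
        assert counts == {"11111110": 5, "00000001": 2}


class TestGenerateEvidence:
    def test_error_rate_zero_gives_full_concordance(self, rules):
        spec = CohortSpec(seed=5, phyla=(("P", 20),), producer_prob=0.5)
        matrix, _, truth = generate_cohort(spec, rules)
        evidence, mapping = generate_evidence(truth, 16, error_rate=0.0, seed=5)
        result = score_concordance(predict_cohort(matrix, rules), evidence, mapping)
        assert result.fraction == 1.0
        assert result.compared == 16 * 8

    def test_error_rate_one_gives_zero_concordance(self, rules):
        spec = CohortSpec(seed=5, phyla=(("P", 20),), producer_prob=0.5)
        matrix, _, truth = generate_cohort(spec, rules)
        evidence, mapping = generate_evidence(truth, 16, error_rate=1.0, seed=5)
        result = score_concordance(predict_cohort(matrix, rules), evidence, mapping)
        assert result.fraction == 0.0

    def test_mean_concordance_tracks_error_rate(self, rules):
        """With a 12% flip rate, mean concordance over many replicates sits
        at 88% within binomial error of the mean."""
        error_rate, n_seeds = 0.12, 30
        spec = CohortSpec(seed=6, phyla=(("P", 16),), producer_prob=0.5)
        matrix, _, truth = generate_cohort(spec, rules)
        predictions = predict_cohort(matrix, rules)
        fractions = []
        for s in range(n_seeds):
            evidence, mapping = generate_evidence(truth, 16, error_rate, seed=s)
            fractions.append(score_concordance(predictions, evidence, mapping).fraction)
        se_mean = np.sqrt(error_rate * (1 - error_rate) / (128 * n_seeds))
        assert abs(np.mean(fractions) - (1 - error_rate)) <= 3 * se_mean

    def test_too_many_strains_rejected(self, rules):
        spec = CohortSpec(seed=5, phyla=(("P", 4),), producer_prob=0.5)
        _, _, truth = generate_cohort(spec, rules)
        with pytest.raises(ValidationError, match="n_strains"):
            generate_evidence(truth, 10, 0.0, seed=1)


class TestStandIns:
    def test_pattern_profile_is_exact(self):
        preds = predictions_with_pattern_profile(120, 30, 4, seed=8)
        census = pattern_census(preds)
        assert census.total == 120
        assert census.n_distinct == 30
        assert inversed_pairs(census).n_pairs == 4

    def test_evidence_panel_stand_in_dimensions(self):
        predictions, evidence, mapping = evidence_panel_stand_in()
        assert len(predictions) == 16
        assert len(evidence) == 128
        assert len(mapping) == 16
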