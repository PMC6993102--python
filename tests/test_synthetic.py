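"""Cohort generator: BMI labeling, determinism, planted structure."""

import dataclasses

import numpy as np
import pytest

from mzmarker.exceptions import ConfigError
from mzmarker.io import normalize_rows
from mzmarker.markers import marker_delta
from mzmarker.synthetic import (
    SyntheticSpec,
    WhoCategory,
    class_label,
    compute_bmi,
    generate_cohort,
    who_category,
)


class TestBmi:
    @pytest.mark.parametrize(
        "weight, height, expected",
        [(80, 2.0, 20.0), (90, 1.5, 40.0), (72.25, 1.7, 25.0)],
    )
    def test_weight_over_height_squared(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected)

    @pytest.mark.parametrize("weight, height", [(0, 1.7), (70, 0), (-1, 1.7)])
    def test_non_positive_inputs_rejected(self, weight, height):
        with pytest.raises(ConfigError):
            compute_bmi(weight, height)


class TestWhoCategory:
    @pytest.mark.parametrize(
        "bmi, expected",
        [
            (20.0, WhoCategory.EUTROPHIC),
            (25.0, WhoCategory.OVERWEIGHT),  # >=25 boundary is inclusive
            (32.0, WhoCategory.OBESE_I),
            (36.0, WhoCategory.OBESE_II),
            (41.0, WhoCategory.OBESE_III),
        ],
    )
    def test_cut_points(self, bmi, expected):
        assert who_category(bmi) == expected

    def test_below_floor_is_explicit_sentinel_not_eutrophic(self):
        assert who_category(17.0) == WhoCategory.UNDERWEIGHT
        with pytest.raises(ConfigError):
            class_label(17.0)

    def test_case_control_boundary(self):
        assert class_label(24.9) == "control"  # eutrophic band is [18, 25)
        assert class_label(25.0) == "case"
        assert class_label(22.0) == "control"


class TestGenerateCohort:
    def test_deterministic_given_seed(self, small_spec):
        m1, _ = generate_cohort(small_spec)
        m2, _ = generate_cohort(small_spec)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert list(m1.patient_id) == list(m2.patient_id)

    def test_different_seed_changes_values(self, small_spec):
        m1, _ = generate_cohort(small_spec)
        m2, _ = generate_cohort(dataclasses.replace(small_spec, seed=8))
        assert not np.array_equal(m1.values, m2.values)

    def test_shape_and_class_balance(self, small_cohort, small_spec):
        matrix, truth = small_cohort
        n = small_spec.n_per_class
        assert matrix.values.shape == (
            2 * n * small_spec.replicates_per_patient, small_spec.n_channels
        )
        labels = list(matrix.patient_class.values())
        assert labels.count("case") == n and labels.count("control") == n
        assert all(s.bmi == pytest.approx(s.weight / s.height**2) for s in truth.subjects)

    def test_default_spec_matches_study_scale(self):
        spec = SyntheticSpec()
        assert spec.n_per_class == 90
        assert spec.replicates_per_patient == 5
        assert spec.n_channels == 1752
        # 2 * 90 * 5 rows x 1752 channels once generated

    def test_all_intensities_positive(self, small_cohort):
        matrix, _ = small_cohort
        assert (matrix.values >= 0).all()

    def test_dependent_members_are_exact_multiples(self, small_cohort):
        matrix, truth = small_cohort
        for gen_mz, members in truth.group_mz.items():
            gen = matrix.channel_values(gen_mz)
            for member_mz in members:
                member = matrix.channel_values(member_mz)
                ratio = member / gen
                assert np.allclose(ratio, ratio[0])

    def test_zero_shift_gives_equal_class_distributions(self, small_spec):
        matrix, truth = generate_cohort(small_spec.null())
        positive = matrix.row_class == "case"
        for mz in truth.marker_mz:
            col = matrix.channel_values(mz)
            pos_med, neg_med = np.median(col[positive]), np.median(col[~positive])
            assert abs(pos_med - neg_med) / neg_med < 0.25  # same law, noise only

    def test_positive_shift_raises_positive_class(self, small_cohort):
        matrix, truth = small_cohort
        positive = matrix.row_class == "case"
        for mz in truth.marker_mz:
            col = matrix.channel_values(mz)
            assert np.median(col[positive]) > np.median(col[~positive])

    def test_overlapping_groups_rejected(self, small_spec):
        from mzmarker.synthetic import DependentGroupSpec

        bad = dataclasses.replace(
            small_spec,
            dependent_groups=(
                DependentGroupSpec(22, (25,), (0.5,)),
                DependentGroupSpec(25, (28,), (0.5,)),
            ),
        )
        with pytest.raises(ConfigError, match="overlap"):
            generate_cohort(bad)

    def test_marker_on_group_member_rejected(self, small_spec):
        bad = dataclasses.replace(small_spec, marker_channels=((25, 3.0),))
        with pytest.raises(ConfigError, match="disjoint"):
            generate_cohort(bad)

    def test_ground_truth_json_round_trips(self, small_cohort):
        import json

        _, truth = small_cohort
        payload = json.loads(truth.to_json())
        assert payload["seed"] == truth.seed
        assert set(map(int, payload["marker_mz"])) == set(truth.marker_mz)


class TestPlantedSeparability:
    def test_planted_markers_exceed_beta_across_seeds(self):
        """A 3-sigma planted shift keeps the CDF gap above beta = 0.4.

        Checked at reduced cohort size (50+50 patients, the invariant's
        stated lower bound) over 12 seeds on normalized data.
        """
        failures = 0
        total = 0
        for seed in range(12):
            spec = dataclasses.replace(SyntheticSpec(seed=seed), n_per_class=50)
            matrix, truth = generate_cohort(spec)
            norm = normalize_rows(matrix)
            positive = norm.row_class == "case"
            for mz in truth.marker_mz:
                col = norm.channel_values(mz)
                decision = marker_delta(col[positive], col[~positive], beta=0.4)
                total += 1
                failures += not decision.delta > 0.4
        assert failures / total <= 0.05
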