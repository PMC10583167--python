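"""Derived variables: adversity score, weighted deciles, composite
classifications, covariate constructions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acehealth.config import SUPPORT_COLUMNS, TRACT_COLUMNS
from acehealth.derive import (
    DecileCutoffs,
    classify_hypertension,
    classify_mets,
    compute_ace,
    decile_cutoffs,
    derive_covariates,
    weighted_quantile,
)


class TestComputeAce:
    @pytest.mark.parametrize(
        "components, score, elevated",
        [
            ([1] * 10, 10, 1),
            ([0] * 10, 0, 0),
            ([1, 1, 1, 1] + [0] * 6, 4, 1),
            ([1, 1, 1] + [0] * 7, 3, 0),
        ],
    )
    def test_threshold_examples(self, components, score, elevated):
        s, e = compute_ace(np.array(components, dtype=float))
        assert (s[0], e[0]) == (score, elevated)

    def test_missing_component_signals_skipped_imputation(self):
        row = np.array([1, 0, np.nan] + [0] * 7)
        with pytest.raises(ValueError, match="imputed"):
            compute_ace(row)

    def test_nonbinary_component_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            compute_ace(np.array([2.0] + [0] * 9))

    @given(st.lists(st.integers(0, 1), min_size=10, max_size=10), st.randoms())
    def test_permutation_invariance(self, components, rnd):
        shuffled = components.copy()
        rnd.shuffle(shuffled)
        s1, e1 = compute_ace(np.array(components, dtype=float))
        s2, e2 = compute_ace(np.array(shuffled, dtype=float))
        assert s1[0] == s2[0] and e1[0] == e2[0]


class TestWeightedQuantile:
    def test_seventh_decile_of_1_to_100_is_70(self):
        values = np.arange(1.0, 101.0)
        assert weighted_quantile(values, np.ones(100), 0.7) == 70.0

    def test_degenerate_distribution(self):
        values = np.full(25, 3.5)
        for q in (0.1, 0.5, 0.9):
            assert weighted_quantile(values, np.ones(25), q) == 3.5

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=200)
        weights = rng.uniform(0.5, 2.0, size=200)
        qs = np.arange(1, 10) / 10
        a = weighted_quantile(values, weights, qs)
        b = weighted_quantile(values, 2.0 * weights, qs)
        np.testing.assert_array_equal(a, b)

    def test_unit_weights_match_inverted_cdf_quantiles(self):
        """Left-continuous inverse CDF equals numpy's inverted_cdf method
        on 1,000 random draws."""
        rng = np.random.default_rng(42)
        values = rng.normal(size=1000)
        qs = np.linspace(0.05, 0.95, 19)
        ours = weighted_quantile(values, np.ones(1000), qs)
        ref = np.quantile(values, qs, method="inverted_cdf")
        np.testing.assert_allclose(ours, ref)


def make_cutoffs(trig_cut_male=150.0, trig_cut_female=140.0, hdl_cut_male=40.0,
                 hdl_cut_female=45.0) -> DecileCutoffs:
    """Cutoff object with controlled MetS-relevant boundaries."""

    def grid(cut, pos):
        return cut + (np.arange(9) - pos) * 5.0

    return DecileCutoffs(
        trig_deciles={"male": grid(trig_cut_male, 6), "female": grid(trig_cut_female, 7)},
        hdl_deciles={"male": grid(hdl_cut_male, 1), "female": grid(hdl_cut_female, 2)},
    )


def biomarker_row(**overrides) -> pd.DataFrame:
    base = {
        "sex": "male", "systolic": 110.0, "diastolic": 70.0, "waist": 90.0,
        "triglycerides": 100.0, "hdl": 60.0, "hba1c": 5.0,
        "dx_hypertension": 0, "med_hypertension": 0, "dx_diabetes": 0, "med_diabetes": 0,
    }
    base.update(overrides)
    return pd.DataFrame([base])


class TestClassifyMets:
    def test_three_positive_categories_is_mets(self):
        row = biomarker_row(systolic=135.0, waist=110.0, triglycerides=200.0, hdl=70.0)
        assert classify_mets(row, make_cutoffs())[0] == 1

    def test_all_negative_is_not_mets(self):
        assert classify_mets(biomarker_row(), make_cutoffs())[0] == 0

    def test_boundary_systolic_counts_but_one_category_is_not_mets(self):
        row = biomarker_row(sex="female", systolic=130.0, diastolic=70.0)
        assert classify_hypertension(row)[0] == 1  # boundary inclusive
        assert classify_mets(row, make_cutoffs())[0] == 0

    def test_unknown_sex_code_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            classify_mets(biomarker_row(sex="unknown"), make_cutoffs())

    @given(
        st.floats(100, 180), st.floats(60, 110), st.floats(60, 130),
        st.floats(30, 400), st.floats(20, 90), st.floats(4.0, 9.0),
        st.sampled_from(["male", "female"]),
    )
    def test_monotone_in_biomarker_severity(self, sys_, dia, waist, trig, hdl, a1c, sex):
        """Worsening any biomarker never flips the classification 1 -> 0."""
        cuts = make_cutoffs()
        row = biomarker_row(sex=sex, systolic=sys_, diastolic=dia, waist=waist,
                            triglycerides=trig, hdl=hdl, hba1c=a1c)
        before = classify_mets(row, cuts)[0]
        worse = biomarker_row(sex=sex, systolic=sys_ + 20, diastolic=dia + 10,
                              waist=waist + 15, triglycerides=trig + 100,
                              hdl=hdl - 10, hba1c=a1c + 1)
        assert classify_mets(worse, cuts)[0] >= before


class TestClassifyHypertension:
    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({"diastolic": 80.0}, 1),
            ({"systolic": 129.0, "diastolic": 79.0}, 0),
            ({"med_hypertension": 1}, 1),
        ],
    )
    def test_rule(self, overrides, expected):
        assert classify_hypertension(biomarker_row(**overrides))[0] == expected


class TestDecileCutoffs:
    def test_computed_from_cohort_and_invariant_to_weight_scale(self, default_cohort):
        a = decile_cutoffs(default_cohort)
        b = decile_cutoffs(default_cohort, weights=2.0 * default_cohort["weight"].to_numpy())
        for s in ("male", "female"):
            np.testing.assert_array_equal(a.trig_deciles[s], b.trig_deciles[s])
            assert np.all(np.diff(a.trig_deciles[s]) >= 0)
            assert np.all(np.diff(a.hdl_deciles[s]) >= 0)

    def test_insufficient_data_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="insufficient"):
            decile_cutoffs(default_cohort.head(8))


def covariate_row(**overrides) -> pd.DataFrame:
    base = {
        "sex": "female", "household_income": 100.0, "household_size": 4,
        "parent1_education": 4, "parent2_education": 3,
        **{c: 3 for c in SUPPORT_COLUMNS},
        **{c: 0.2 for c in TRACT_COLUMNS},
    }
    base.update(overrides)
    return pd.DataFrame([base])


class TestDeriveCovariates:
    def test_equivalized_income_sqrt_rule(self):
        out = derive_covariates(covariate_row())
        assert out["equivalized_income"].iloc[0] == pytest.approx(50.0)

    def test_parental_education_takes_max(self):
        out = derive_covariates(covariate_row(parent1_education=3, parent2_education=2))
        assert out["parental_education_max"].iloc[0] == 3  # some college beats HS diploma

    def test_constant_tract_proportions_mean(self):
        out = derive_covariates(covariate_row())
        assert out["neighborhood_disadvantage"].iloc[0] == pytest.approx(0.2)

    def test_support_index_is_item_mean(self):
        row = covariate_row(support_1=1, support_2=2, support_3=3, support_4=4, support_5=5)
        out = derive_covariates(row)
        assert out["parental_support_index"].iloc[0] == pytest.approx(3.0)

    def test_household_size_below_one_rejected(self):
        with pytest.raises(ValueError, match="household size"):
            derive_covariates(covariate_row(household_size=0))

    def test_tract_proportion_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="tract"):
            derive_covariates(covariate_row(tract_1=1.2))
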