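"""BMI classification and survey-weighted prevalence."""

import numpy as np
import pandas as pd
import pytest

from ssbtax import (
    DataError,
    DomainError,
    apply_weight_change,
    bmi,
    classify,
    mean_bmi_reduction,
    prevalence_table,
    weighted_prevalence,
)


def toy_cohort(weights=None, bmis=(20, 22, 24, 27, 31), height=1.60):
    n = len(bmis)
    return pd.DataFrame({
        "id": range(n), "age": [30] * n,
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "weight_kg": [b * height**2 for b in bmis],
        "height_m": [height] * n,
        "survey_weight": weights if weights is not None else [1.0] * n,
    })


class TestBmiAndClassify:
    def test_bmi_arithmetic(self):
        assert bmi(57.5, 1.60) == pytest.approx(22.46, abs=0.005)
        assert bmi(1.7**2, 1.7) == pytest.approx(1.0)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(DomainError):
            bmi(60.0, 0.0)

    @pytest.mark.parametrize("x, label", [
        (23.0, "overweight"), (25.0, "obesity1"), (30.0, "obesity2"),
        (22.99, "below"), (24.999, "overweight"), (29.999, "obesity1"),
    ])
    def test_half_open_boundaries(self, x, label):
        assert classify(x) == label


class TestApplyWeightChange:
    def test_sex_specific_reduction(self):
        c = toy_cohort()
        out = apply_weight_change(c, {"male": 0.59, "female": 0.76})
        male = c["sex"] == "male"
        np.testing.assert_allclose(out.loc[male, "weight_kg"],
                                   c.loc[male, "weight_kg"] - 0.59)
        np.testing.assert_allclose(out.loc[~male, "weight_kg"],
                                   c.loc[~male, "weight_kg"] - 0.76)
        assert (out["height_m"] == c["height_m"]).all()

    def test_input_not_mutated_and_zero_is_identity(self):
        c = toy_cohort()
        before = c.copy()
        out = apply_weight_change(c, {"male": 0.0, "female": 0.0})
        assert c.equals(before) and out["weight_kg"].equals(c["weight_kg"])

    def test_inverse_restores_weights(self):
        c = toy_cohort()
        fwd = apply_weight_change(c, {"male": 0.15, "female": 0.19})
        back = apply_weight_change(fwd, {"male": -0.15, "female": -0.19})
        np.testing.assert_allclose(back["weight_kg"], c["weight_kg"], rtol=1e-12)

    def test_negative_resulting_weight_rejected(self):
        with pytest.raises(DataError):
            apply_weight_change(toy_cohort(), {"male": 100.0, "female": 100.0})


class TestWeightedPrevalence:
    def test_degenerate_all_in_class(self):
        c = toy_cohort(bmis=(23.5, 24.0, 24.5, 23.2, 24.9))
        est = weighted_prevalence(c, "overweight")
        assert est.estimate == 1.0 and est.se == 0.0

    def test_equal_weights_reduce_to_share(self):
        c = toy_cohort()  # one of five in [23, 25)
        assert weighted_prevalence(c, "overweight").estimate == pytest.approx(0.2)

    def test_weights_shift_estimate(self):
        c = toy_cohort(weights=[1, 1, 8, 1, 1])
        assert weighted_prevalence(c, "overweight").estimate == pytest.approx(8 / 12)

    def test_class_shares_sum_to_one(self, small_cohort):
        t = prevalence_table(small_cohort)
        for stratum in ("both", "male", "female"):
            total = t[t.stratum == stratum]["estimate"].sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_top_class_never_grows_after_weight_loss(self, small_cohort):
        base = weighted_prevalence(small_cohort, "obesity2").estimate
        shifted = apply_weight_change(small_cohort, {"male": 0.59, "female": 0.76})
        assert weighted_prevalence(shifted, "obesity2").estimate <= base

    def test_monotone_policy_response(self, small_cohort):
        # larger price rises (larger weight reductions) never raise the
        # combined overweight+obesity prevalence
        deltas = [(0.15, 0.19), (0.28, 0.36), (0.57, 0.73), (0.58, 0.75), (0.59, 0.76)]
        prev = []
        for dm, df_ in deltas:
            c = apply_weight_change(small_cohort, {"male": dm, "female": df_})
            prev.append(sum(weighted_prevalence(c, cls).estimate
                            for cls in ("overweight", "obesity1", "obesity2")))
        assert all(b <= a + 1e-12 for a, b in zip(prev, prev[1:]))


class TestMeanBmiReduction:
    def test_zero_delta(self):
        assert mean_bmi_reduction(toy_cohort(), {"male": 0.0, "female": 0.0}) == 0.0

    def test_uniform_height_closed_form(self):
        c = toy_cohort(height=1.60)
        got = mean_bmi_reduction(c, {"male": 0.59, "female": 0.59})
        assert got == pytest.approx(0.59 / 2.56)

    def test_exactly_linear_in_delta(self, small_cohort):
        one = mean_bmi_reduction(small_cohort, {"male": 0.1, "female": 0.2})
        three = mean_bmi_reduction(small_cohort, {"male": 0.3, "female": 0.6})
        assert three == pytest.approx(3 * one, rel=1e-12)
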