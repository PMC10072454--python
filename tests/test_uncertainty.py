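"""Monte Carlo propagation and one-way elasticity sensitivity analysis."""

import numpy as np
import pytest
from scipy import stats

from ssbtax import (
    DomainError,
    Elasticity,
    MCConfig,
    PAPER_SCENARIOS,
    deterministic_outputs,
    fit_beta_from_ci,
    one_way_sa,
    run_mc,
)

S5 = PAPER_SCENARIOS[4]


class TestBetaFit:
    def test_mean_enforced_exactly(self):
        a, b = fit_beta_from_ci(0.27, 0.23, 0.30)
        assert a / (a + b) == pytest.approx(0.27, abs=1e-6)

    def test_quantiles_near_target_interval(self):
        a, b = fit_beta_from_ci(0.27, 0.23, 0.30)
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        assert lo == pytest.approx(0.23, abs=0.01)
        assert hi == pytest.approx(0.30, abs=0.01)

    def test_tiny_interval_gives_vanishing_variance(self):
        a, b = fit_beta_from_ci(0.27, 0.2699, 0.2701)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var < 1e-7

    def test_degenerate_ordering_rejected(self):
        with pytest.raises(DomainError):
            fit_beta_from_ci(0.27, 0.28, 0.30)


class TestRunMC:
    def test_degenerate_distributions_equal_deterministic(self, small_cohort, calibration):
        cfg = MCConfig(iterations=1, seed=3, model="model1", conversion_cv=0.0)
        res = run_mc(S5, small_cohort, cfg, calibration)
        det = deterministic_outputs(S5, small_cohort, calibration)
        for k, v in det.items():
            assert res.means[k] == v, k  # bit-for-bit
            assert res.sds[k] == 0.0

    def test_mc_mean_converges_to_deterministic(self, small_cohort, calibration):
        cfg = MCConfig(iterations=2000, seed=3, model="model2")
        res = run_mc(S5, small_cohort, cfg, calibration)
        det = deterministic_outputs(S5, small_cohort, calibration)
        for k, v in det.items():
            assert abs(res.means[k] - v) < 4 * res.sds[k] / np.sqrt(2000), k

    def test_seed_determinism(self, small_cohort, calibration):
        cfg = MCConfig(iterations=500, seed=9, model="model2")
        a = run_mc(S5, small_cohort, cfg, calibration)
        b = run_mc(S5, small_cohort, cfg, calibration)
        assert a == b

    def test_model2_widens_diabetes_outputs_only(self, small_cohort, calibration):
        c1 = MCConfig(iterations=2000, seed=3, model="model1")
        c2 = MCConfig(iterations=2000, seed=3, model="model2")
        r1 = run_mc(S5, small_cohort, c1, calibration)
        r2 = run_mc(S5, small_cohort, c2, calibration)
        assert r1.means["weight_change_male"] == r2.means["weight_change_male"]
        assert r1.sds["weight_change_male"] == r2.sds["weight_change_male"]
        for k in ("avoided_cases", "prevalence_reduction_pp", "cost_saving_bn_vnd"):
            assert r2.sds[k] >= r1.sds[k], k

    def test_scenario5_weight_change_near_published(self, small_cohort, calibration):
        cfg = MCConfig(iterations=10_000, seed=1, model="model1")
        res = run_mc(S5, small_cohort, cfg, calibration)
        assert res.means["weight_change_male"] == pytest.approx(0.59, abs=0.01)
        assert res.means["weight_change_female"] == pytest.approx(0.76, abs=0.01)


class TestOneWaySA:
    def test_base_elasticity_row_is_identity(self, small_cohort, calibration):
        sa = one_way_sa([-1.14], list(PAPER_SCENARIOS), small_cohort,
                        calibration=calibration)
        det = deterministic_outputs(S5, small_cohort, calibration)
        row = sa[(sa.scenario_id == "scenario5")].iloc[0]
        assert row["weight_change_male"] == det["weight_change_male"]

    def test_weaker_elasticity_scales_everything_exactly(self, small_cohort, calibration):
        sa = one_way_sa([-1.14, -1.0, -0.8], list(PAPER_SCENARIOS), small_cohort,
                        calibration=calibration)
        base = sa[sa.elasticity == -1.14].set_index("scenario_id")
        for e in (-1.0, -0.8):
            sub = sa[sa.elasticity == e].set_index("scenario_id")
            ratio = abs(e) / 1.14
            np.testing.assert_allclose(sub["dvolume_total"],
                                       base["dvolume_total"] * ratio, rtol=1e-12)
            np.testing.assert_allclose(sub["avoided_cases"],
                                       base["avoided_cases"] * ratio, rtol=1e-12)

    def test_unit_elasticity_scenario1_decrease(self, small_cohort, calibration):
        sa = one_way_sa([-1.0], [PAPER_SCENARIOS[0]], small_cohort,
                        calibration=calibration)
        assert -sa["dvolume_total"].iloc[0] == pytest.approx(150.3, abs=0.05)

    def test_positive_elasticity_rejected(self, small_cohort):
        with pytest.raises(DomainError):
            one_way_sa([0.5], [S5], small_cohort)
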