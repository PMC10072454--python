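"""Probabilistic and deterministic sensitivity analysis.

Two Monte Carlo models propagate parameter uncertainty through the full
deterministic chain (energy decrease → weight change → BMI reduction →
diabetes burden), resampling at parameter level per iteration:

* model 1 resamples only the per-sex energy-to-weight conversion factors
  (normal, means 93.0/72.3 kJ·day⁻¹ per kg);
* model 2 additionally resamples the diabetes relative risk reduction per
  2 BMI units (beta, matched to mean 0.27 and 95% CI 0.23–0.30).

Conversion-factor standard deviations are not published; the default is a
5% coefficient of variation, calibrated so simulated weight-change SDs
approximate the published ones (e.g. 0.58 (0.03) kg), and overridable.
Normal draws have unbounded support, so non-positive conversion-factor
draws are rejected and redrawn (count logged on the result).

A one-way deterministic sensitivity analysis reruns the pipeline at
alternative own-price elasticities (−1.0 and −0.8 beside the base −1.14);
with the market calibrated once at the base elasticity, every consumption
decrease scales exactly by ε/ε_base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .anthropometry import DEFAULT_ENERGY_WEIGHT, EnergyWeightParams
from .diabetes import DEFAULT_DIABETES, DiabetesParams
from .errors import ConfigurationError, DomainError
from .tax_market import (
    DEFAULT_ELASTICITY,
    Elasticity,
    MarketCalibration,
    TaxScenario,
    calibrate_market,
    market_impact,
)

logger = logging.getLogger(__name__)

OUTPUT_KEYS = (
    "weight_change_male", "weight_change_female",
    "bmi_reduction_male", "bmi_reduction_female", "bmi_reduction_both",
    "prevalence_reduction_pp", "avoided_cases",
    "cost_saving_bn_vnd", "cost_saving_m_usd",
)


@dataclass
class MCConfig:
    """Monte Carlo configuration (defaults: 10,000 iterations, model 1)."""

    iterations: int = 10_000
    seed: int = 0
    model: str = "model1"
    conversion_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 93.0, "female": 72.3})
    conversion_sd: Mapping[str, float] | None = None  # default: cv × mean
    conversion_cv: float = 0.05
    rrr_mean: float = 0.27
    rrr_ci: tuple[float, float] = (0.23, 0.30)
    rrr_fit: str = "ci"  # "ci" (quantile least squares) or "moments"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.model not in ("model1", "model2"):
            raise ConfigurationError(f"unknown MC model {self.model!r}")
        if self.conversion_cv < 0:
            raise ConfigurationError("conversion_cv must be >= 0")
        if self.conversion_sd is not None and any(v < 0 for v in self.conversion_sd.values()):
            raise ConfigurationError("conversion SDs must be >= 0")

    def sd(self, sex: str) -> float:
        if self.conversion_sd is not None:
            return float(self.conversion_sd[sex])
        return self.conversion_cv * float(self.conversion_mean[sex])


@dataclass(frozen=True)
class MCResult:
    model: str
    iterations: int
    means: dict[str, float]
    sds: dict[str, float]
    n_redraws: int


def fit_beta_from_ci(mean: float = 0.27, lo: float = 0.23, hi: float = 0.30
                     ) -> tuple[float, float]:
    """Beta shape parameters with the given mean and ≈95% central interval.

    The mean is enforced exactly by parametrizing ``a = mean·s``,
    ``b = (1−mean)·s``; the concentration ``s`` is found by least squares
    on the 2.5% and 97.5% quantiles.  If the optimum leaves a residual
    larger than the interval width itself, the fit falls back to moment
    matching with ``sd = (hi − lo)/3.92`` and logs a warning.
    """
    if not (0.0 < lo < mean < hi < 1.0):
        raise DomainError(f"need 0 < lo < mean < hi < 1, got {lo}, {mean}, {hi}")

    def resid(log_s: float) -> float:
        s = np.exp(log_s)
        q = stats.beta.ppf([0.025, 0.975], mean * s, (1.0 - mean) * s)
        return float((q[0] - lo) ** 2 + (q[1] - hi) ** 2)

    res = optimize.minimize_scalar(resid, bounds=(np.log(2.0), np.log(1e8)),
                                   method="bounded")
    if np.sqrt(res.fun) > (hi - lo):
        logger.warning("beta CI fit residual %.3g too large; moment matching", res.fun)
        sd = (hi - lo) / 3.92
        s = mean * (1.0 - mean) / sd**2 - 1.0
        if s <= 0:
            raise DomainError("moment-matched beta concentration non-positive")
        return mean * s, (1.0 - mean) * s
    s = float(np.exp(res.x))
    return mean * s, (1.0 - mean) * s


@dataclass(frozen=True)
class _CohortPrecomp:
    """Weighted sums fixing the cohort side of the weight→BMI mapping."""

    s_invh2_male: float  # Σ w/h² over males
    s_invh2_female: float
    w_male: float  # Σ w over males
    w_female: float

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "_CohortPrecomp":
        w = cohort["survey_weight"].to_numpy(dtype=float)
        invh2 = 1.0 / cohort["height_m"].to_numpy(dtype=float) ** 2
        male = (cohort["sex"] == "male").to_numpy()
        return cls(
            s_invh2_male=float(np.sum(w[male] * invh2[male])),
            s_invh2_female=float(np.sum(w[~male] * invh2[~male])),
            w_male=float(np.sum(w[male])),
            w_female=float(np.sum(w[~male])),
        )


def _chain(denergy, conv_male, conv_female, rrr_per_2, pre: _CohortPrecomp,
           dparams: DiabetesParams, maturity: float):
    """Deterministic downstream chain; broadcasts over iteration vectors.

    ``denergy`` is the per-capita decrease in daily energy intake (kJ/day,
    positive); outputs are positive reductions.
    """
    dw_m = denergy / conv_male * maturity
    dw_f = denergy / conv_female * maturity
    dbmi_m = dw_m * (pre.s_invh2_male / pre.w_male)
    dbmi_f = dw_f * (pre.s_invh2_female / pre.w_female)
    w_tot = pre.w_male + pre.w_female
    dbmi_both = (dw_m * pre.s_invh2_male + dw_f * pre.s_invh2_female) / w_tot
    rrr = rrr_per_2 * dbmi_both / 2.0 if dparams.dose_response == "linear" \
        else 1.0 - (1.0 - rrr_per_2) ** (dbmi_both / 2.0)
    pp = dparams.baseline_prevalence * rrr * 100.0
    avoided = pp / 100.0 * dparams.adult_population
    vnd = avoided * dparams.blended_cost_vnd
    return {
        "weight_change_male": dw_m,
        "weight_change_female": dw_f,
        "bmi_reduction_male": dbmi_m,
        "bmi_reduction_female": dbmi_f,
        "bmi_reduction_both": dbmi_both,
        "prevalence_reduction_pp": pp,
        "avoided_cases": avoided,
        "cost_saving_bn_vnd": vnd / 1e9,
        "cost_saving_m_usd": vnd / dparams.vnd_per_usd / 1e6,
    }


def deterministic_outputs(
    scenario: TaxScenario,
    cohort: pd.DataFrame,
    calibration: MarketCalibration | None = None,
    elasticity: Elasticity | float = DEFAULT_ELASTICITY,
    diabetes_params: DiabetesParams = DEFAULT_DIABETES,
    energy_params: EnergyWeightParams = DEFAULT_ENERGY_WEIGHT,
) -> dict[str, float]:
    """Point-estimate chain for one scenario (no sampling)."""
    calibration = calibration or calibrate_market()
    impact = market_impact(scenario, calibration, elasticity)
    denergy = -impact.denergy_per_capita
    pre = _CohortPrecomp.from_cohort(cohort)
    out = _chain(denergy, energy_params.adult_kj_per_kg["male"],
                 energy_params.adult_kj_per_kg["female"],
                 diabetes_params.rrr_per_2_bmi, pre, diabetes_params,
                 energy_params.maturity_fraction)
    return {k: float(v) for k, v in out.items()}


def run_mc(
    scenario: TaxScenario,
    cohort: pd.DataFrame,
    config: MCConfig,
    calibration: MarketCalibration | None = None,
    elasticity: Elasticity | float = DEFAULT_ELASTICITY,
    diabetes_params: DiabetesParams = DEFAULT_DIABETES,
    energy_params: EnergyWeightParams = DEFAULT_ENERGY_WEIGHT,
) -> MCResult:
    """Monte Carlo propagation for one scenario.

    The conversion factors are drawn first from the seeded generator, so
    model 1 and model 2 with the same seed share identical weight-change
    draws; model 2's extra RRR draws only widen the diabetes outputs.
    Bit-reproducible for a fixed seed; with zero-SD distributions under
    model 1 the result equals :func:`deterministic_outputs` exactly.
    """
    calibration = calibration or calibrate_market()
    impact = market_impact(scenario, calibration, elasticity)
    denergy = -impact.denergy_per_capita
    pre = _CohortPrecomp.from_cohort(cohort)

    rng = np.random.default_rng(config.seed)
    n = config.iterations
    n_redraws = 0
    draws = {}
    for sex in ("male", "female"):
        x = rng.normal(config.conversion_mean[sex], config.sd(sex), size=n)
        bad = x <= 0
        while bad.any():
            n_redraws += int(bad.sum())
            x[bad] = rng.normal(config.conversion_mean[sex], config.sd(sex),
                                size=int(bad.sum()))
            bad = x <= 0
        draws[sex] = x
    if config.model == "model2":
        a, b = (fit_beta_from_ci(config.rrr_mean, *config.rrr_ci)
                if config.rrr_fit == "ci"
                else _beta_moments(config.rrr_mean, config.rrr_ci))
        rrr = rng.beta(a, b, size=n)
    else:
        rrr = config.rrr_mean

    out = _chain(denergy, draws["male"], draws["female"], rrr, pre,
                 diabetes_params, energy_params.maturity_fraction)
    if n_redraws:
        logger.info("rejected and redrew %d non-positive conversion draws", n_redraws)
    ddof = 1 if n > 1 else 0
    means = {k: float(np.mean(np.broadcast_to(v, (n,)))) for k, v in out.items()}
    sds = {k: float(np.std(np.broadcast_to(v, (n,)), ddof=ddof)) for k, v in out.items()}
    return MCResult(config.model, n, means, sds, n_redraws)


def _beta_moments(mean: float, ci: tuple[float, float]) -> tuple[float, float]:
    sd = (ci[1] - ci[0]) / 3.92
    s = mean * (1.0 - mean) / sd**2 - 1.0
    if s <= 0:
        raise DomainError("moment-matched beta concentration non-positive")
    return mean * s, (1.0 - mean) * s


def one_way_sa(
    elasticities: list[float],
    scenarios: list[TaxScenario],
    cohort: pd.DataFrame,
    base_elasticity: Elasticity | float = DEFAULT_ELASTICITY,
    diabetes_params: DiabetesParams = DEFAULT_DIABETES,
    energy_params: EnergyWeightParams = DEFAULT_ENERGY_WEIGHT,
    calibration: MarketCalibration | None = None,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis on the price elasticity.

    The market is calibrated once at ``base_elasticity``; the demand
    response is then re-evaluated at each alternative elasticity, so every
    consumption decrease (and the whole downstream chain) scales by
    ``ε/ε_base``.
    """
    for e in elasticities:
        if (e.value if isinstance(e, Elasticity) else e) >= 0:
            raise DomainError("elasticities must be negative")
    calibration = calibration or calibrate_market(elasticity=base_elasticity)
    rows = []
    for e in elasticities:
        for sc in scenarios:
            impact = market_impact(sc, calibration, e)
            det = deterministic_outputs(sc, cohort, calibration, e,
                                        diabetes_params, energy_params)
            rows.append({"elasticity": (e.value if isinstance(e, Elasticity) else e),
                         "scenario_id": sc.id,
                         "price_increase": impact.price_increase,
                         "dvolume_total": impact.dvolume_total,
                         "dsugar_per_capita": impact.dsugar_per_capita,
                         "denergy_per_capita": impact.denergy_per_capita,
                         **det})
    return pd.DataFrame(rows)
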