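"""Synthetic adult cohort and child age structure.

The weight-change and obesity stages of the model run on survey microdata
(one row per adult: age, sex, weight, height, survey weight) from a
national risk-factor survey that is not publicly redistributable.  This
module generates a synthetic stand-in cohort whose survey-weighted BMI
class structure matches the published baseline: overweight 17.9%
(WPRO 23 ≤ BMI < 25), obesity class I 13.6% (25 ≤ BMI < 30) and obesity
class II 3.4% (BMI ≥ 30), split by sex (male 19.2/13.1/1.7, female
16.5/14.2/5.1), with a weighted mean BMI of ≈21.96 kg/m².

Calibration strategy
--------------------
Per sex, a base log-normal BMI distribution is fitted by least squares to
the three class cut-off exceedance probabilities.  A two-parameter
log-normal cannot hit all three class shares simultaneously (the observed
distribution has a narrower overweight band relative to its obesity tail
than any log-normal), so sampling draws each person's BMI *class* exactly
at the target probabilities and then draws BMI from the base log-normal
truncated to that class interval.  Class shares are therefore exact in
expectation while the within-class shape stays smooth and realistic.  A
final one-dimensional root-find shifts the common log-location so the
expected weighted mean BMI equals the target.

Heights are auxiliary (BMI is the calibrated quantity): normal per sex
with synthetic means 1.62 m (men) / 1.53 m (women), SD 0.06 m.  Weight is
reconstructed as BMI × height².  Survey weights are i.i.d. gamma with
mean 1 (shape 10), exercising weighted estimators without reproducing the
survey's unpublished design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CalibrationError, DataError, DomainError, SchemaError

COHORT_COLUMNS = ["id", "age", "sex", "weight_kg", "height_m", "survey_weight"]

#: Baseline BMI-class prevalence targets by sex (survey-weighted shares).
DEFAULT_SEX_CLASS_TARGETS: dict[str, dict[str, float]] = {
    "male": {"overweight": 0.192, "obesity1": 0.131, "obesity2": 0.017},
    "female": {"overweight": 0.165, "obesity1": 0.142, "obesity2": 0.051},
}

_BMI_CUTS = (23.0, 25.0, 30.0)
_BMI_LO, _BMI_HI = 13.0, 58.0  # clip guards; keep weight inside plausible bounds


@dataclass
class CohortSpec:
    """Specification for the synthetic adult cohort.

    Defaults mirror the source survey: n = 3,856 adults aged 18–69.  The
    mean-BMI target of 21.96 kg/m² is a soft target reconstructed from the
    published post-tax mean (21.89) plus the smallest scenario's reduction
    (0.07).
    """

    n: int = 3856
    seed: int = 0
    sex_split: float = 0.5  # fraction male
    sex_targets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(t) for s, t in DEFAULT_SEX_CLASS_TARGETS.items()})
    target_mean_bmi: float = 21.96
    height_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.62, "female": 1.53})
    height_sd: float = 0.06
    survey_weight_gamma_shape: float = 10.0
    age_range: tuple[int, int] = (18, 69)

    def __post_init__(self) -> None:
        if self.n < 100:
            raise DomainError("cohort size n must be >= 100")
        if not 0.0 <= self.sex_split <= 1.0:
            raise DomainError("sex_split must be in [0, 1]")
        for sex, t in self.sex_targets.items():
            vals = [t["overweight"], t["obesity1"], t["obesity2"]]
            if any(not 0.0 <= v <= 1.0 for v in vals) or sum(vals) >= 1.0:
                raise CalibrationError(
                    f"{sex}: class prevalence targets must lie in [0,1] and sum < 1: {t}")

    def class_probs(self, sex: str) -> np.ndarray:
        t = self.sex_targets[sex]
        below = 1.0 - t["overweight"] - t["obesity1"] - t["obesity2"]
        return np.array([below, t["overweight"], t["obesity1"], t["obesity2"]])


def _fit_base_lognormal(class_probs: np.ndarray) -> tuple[float, float]:
    """Least-squares log-normal fit to the class cut-off quantiles."""
    cum = np.cumsum(class_probs[:-1])  # P(BMI < 23), < 25, < 30
    if np.any(cum <= 0) or np.any(cum >= 1) or np.any(np.diff(cum) <= 0):
        raise CalibrationError(f"class cut-off probabilities infeasible: {cum}")
    z = stats.norm.ppf(cum)
    lncuts = np.log(_BMI_CUTS)
    sigma, mu = np.polyfit(z, lncuts, 1)
    if sigma <= 0:
        raise CalibrationError("fitted log-normal scale is non-positive")
    return float(mu), float(sigma)


def _trunc_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Mean of a log-normal truncated to (lo, hi)."""
    a = -np.inf if lo <= 0 else (np.log(lo) - mu) / sigma
    b = np.inf if np.isinf(hi) else (np.log(hi) - mu) / sigma
    denom = stats.norm.cdf(b) - stats.norm.cdf(a)
    if denom <= 0:
        raise CalibrationError(f"empty truncation interval ({lo}, {hi})")
    num = stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
    return float(np.exp(mu + 0.5 * sigma**2) * num / denom)


_CLASS_BOUNDS = ((0.0, 23.0), (23.0, 25.0), (25.0, 30.0), (30.0, np.inf))


def _expected_mean_bmi(spec: CohortSpec, fits: dict[str, tuple[float, float]],
                       shift: float) -> float:
    total = 0.0
    for sex, share in (("male", spec.sex_split), ("female", 1.0 - spec.sex_split)):
        mu, sigma = fits[sex]
        probs = spec.class_probs(sex)
        m = sum(p * _trunc_lognormal_mean(mu + shift, sigma, lo, hi)
                for p, (lo, hi) in zip(probs, _CLASS_BOUNDS))
        total += share * m
    return total


def _calibrate(spec: CohortSpec) -> dict[str, tuple[float, float]]:
    """Fit per-sex (mu, sigma) and shift the location to hit the mean-BMI target."""
    fits = {sex: _fit_base_lognormal(spec.class_probs(sex)) for sex in ("male", "female")}

    def gap(d: float) -> float:
        return _expected_mean_bmi(spec, fits, d) - spec.target_mean_bmi

    lo, hi = -0.5, 0.5
    glo, ghi = gap(lo), gap(hi)
    if glo * ghi > 0:
        raise CalibrationError(
            "mean-BMI target infeasible for the fitted class structure: "
            f"attainable mean range [{glo + spec.target_mean_bmi:.2f}, "
            f"{ghi + spec.target_mean_bmi:.2f}], target {spec.target_mean_bmi}")
    shift = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return {sex: (mu + shift, sigma) for sex, (mu, sigma) in fits.items()}


def generate_adult_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate a synthetic adult cohort as a DataFrame.

    Columns: ``id, age, sex, weight_kg, height_m, survey_weight``.
    Reproducible for a fixed ``spec.seed``.
    """
    spec = spec or CohortSpec()
    fits = _calibrate(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    male = rng.random(n) < spec.sex_split
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)

    # draw BMI class exactly at the per-sex target probabilities
    cum_by_sex = {s: np.cumsum(spec.class_probs(s)) for s in ("male", "female")}
    cums = np.where(male[:, None], cum_by_sex["male"], cum_by_sex["female"])
    u_class = rng.random(n)
    cls = (u_class[:, None] > cums).sum(axis=1)  # 0=below 1=ow 2=ob1 3=ob2

    # per-person truncated log-normal BMI via inverse CDF
    mu = np.where(male, fits["male"][0], fits["female"][0])
    sigma = np.where(male, fits["male"][1], fits["female"][1])
    bounds = np.array([[0.0, 23.0], [23.0, 25.0], [25.0, 30.0], [30.0, np.inf]])
    lo_b, hi_b = bounds[cls, 0], bounds[cls, 1]
    with np.errstate(divide="ignore"):
        F_lo = np.where(lo_b <= 0, 0.0, stats.norm.cdf((np.log(np.maximum(lo_b, 1e-12)) - mu) / sigma))
        F_hi = np.where(np.isinf(hi_b), 1.0, stats.norm.cdf((np.log(np.where(np.isinf(hi_b), 1.0, hi_b)) - mu) / sigma))
    v = rng.random(n)
    uu = np.clip(F_lo + v * (F_hi - F_lo), 1e-12, 1.0 - 1e-12)
    bmi = np.exp(mu + sigma * stats.norm.ppf(uu))
    bmi = np.clip(bmi, _BMI_LO, _BMI_HI)

    hmean = np.where(male, spec.height_mean["male"], spec.height_mean["female"])
    height = np.clip(rng.normal(hmean, spec.height_sd), 1.30, 2.05)
    weight = bmi * height**2

    shape = spec.survey_weight_gamma_shape
    survey_weight = rng.gamma(shape, 1.0 / shape, size=n)

    df = pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "age": age.astype(np.int64),
        "sex": np.where(male, "male", "female"),
        "weight_kg": weight,
        "height_m": height,
        "survey_weight": survey_weight,
    })
    _validate_cohort(df)
    return df


def child_age_weights(mode: str = "uniform",
                      table: Mapping[int, float] | None = None) -> dict[int, float]:
    """Age shares for children aged 2–17.

    ``uniform`` gives each of the 16 single years of age weight 1/16; a
    custom table must cover ages 2–17 with non-negative weights and is
    normalized.
    """
    ages = range(2, 18)
    if mode == "uniform":
        return {a: 1.0 / 16.0 for a in ages}
    if mode != "custom":
        raise DomainError(f"unknown age-weight mode {mode!r}")
    if table is None:
        raise DomainError("custom mode requires a table")
    w = {int(a): float(table.get(a, 0.0)) for a in ages}
    if any(v < 0 for v in w.values()):
        raise DomainError("age weights must be non-negative")
    total = sum(w.values())
    if total <= 0:
        raise DomainError("age weights must have positive total")
    return {a: v / total for a, v in w.items()}


def _validate_cohort(df: pd.DataFrame, adults_only: bool = True) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort missing columns: {missing}")
    if len(df) == 0:
        raise DataError("cohort is empty")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise SchemaError(f"invalid sex at rows {df.index[bad_sex][:5].tolist()}")
    for col, lo, hi in (("weight_kg", 10.0, 250.0), ("height_m", 1.2, 2.1)):
        bad = ~df[col].between(lo, hi, inclusive="neither")
        if bad.any():
            raise DataError(
                f"{col} outside ({lo}, {hi}) at rows {df.index[bad][:5].tolist()}")
    if (df["survey_weight"] <= 0).any():
        raise DataError("survey weights must be positive")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (lossless round-trip with :func:`read_cohort`)."""
    _validate_cohort(cohort)
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-validate a cohort CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty cohort file") from None
    try:
        _validate_cohort(df)
    except (SchemaError, DataError) as e:
        raise type(e)(f"{path}: {e}") from None
    return df
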