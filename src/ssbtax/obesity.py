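"""BMI classification and survey-weighted prevalence estimation.

Applies sex-specific weight reductions to the cohort (heights held fixed),
recomputes BMI, classifies by the WHO Western Pacific (WPRO) cut-offs for
Asian populations — overweight 23 ≤ BMI < 25, obesity class I 25 ≤ BMI
< 30, obesity class II BMI ≥ 30 — and produces survey-weighted prevalence
and mean-BMI estimates with linearized standard errors.

Standard errors use the weighted-ratio linearization without cluster or
stratum terms (the source survey's design variables are unpublished), so
they approximate rather than reproduce design-based errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, EstimationError

CLASS_LABELS = ("below", "overweight", "obesity1", "obesity2")
BMI_CUTS = (23.0, 25.0, 30.0)
STRATA = ("both", "male", "female")


@dataclass(frozen=True)
class PrevalenceEstimate:
    class_label: str
    stratum: str
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.estimate <= 1.0 or self.se < 0:
            raise DomainError("estimate must be in [0,1] and se >= 0")


def bmi(weight, height):
    """Body-mass index, kg/m²; vectorized."""
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise DomainError("height must be positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def classify(bmi_value):
    """WPRO BMI class; intervals are half-open on the right (23.0 → overweight)."""
    x = np.asarray(bmi_value, dtype=float)
    idx = np.searchsorted(BMI_CUTS, x, side="right")
    labels = np.asarray(CLASS_LABELS, dtype=object)[idx]
    return str(labels) if x.ndim == 0 else labels


def apply_weight_change(cohort: pd.DataFrame,
                        dweight_by_sex: Mapping[str, float]) -> pd.DataFrame:
    """Return a copy of the cohort with sex-specific weight reductions applied.

    ``dweight_by_sex`` gives the weight *reduction* in kg per sex; positive
    values lower body weight.  Heights are unchanged; the input cohort is
    not mutated.
    """
    if len(cohort) == 0:
        raise DataError("cohort is empty")
    out = cohort.copy()
    dw = out["sex"].map(dict(dweight_by_sex)).astype(float)
    if dw.isna().any():
        raise DomainError("dweight_by_sex must cover every sex present in the cohort")
    out["weight_kg"] = out["weight_kg"] - dw
    if (out["weight_kg"] <= 0).any():
        raise DataError("weight change drives body weight to zero or below")
    return out


def _stratum_mask(cohort: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "both":
        return pd.Series(True, index=cohort.index)
    if stratum not in ("male", "female"):
        raise DomainError(f"unknown stratum {stratum!r}")
    return cohort["sex"] == stratum


def weighted_prevalence(cohort: pd.DataFrame, class_label: str,
                        stratum: str = "both") -> PrevalenceEstimate:
    """Survey-weighted prevalence of one BMI class within a stratum.

    Point estimate is the weighted share Σw·1[class]/Σw; the standard
    error comes from the linearized variance of the weighted ratio,
    ``se² = Σ w²(x − p̂)² / (Σw)²``.
    """
    if class_label not in CLASS_LABELS:
        raise DomainError(f"unknown class {class_label!r}")
    sub = cohort[_stratum_mask(cohort, stratum)]
    if len(sub) == 0:
        raise EstimationError(f"stratum {stratum!r} is empty")
    w = sub["survey_weight"].to_numpy(dtype=float)
    x = (classify(bmi(sub["weight_kg"], sub["height_m"])) == class_label).astype(float)
    W = w.sum()
    p = float((w * x).sum() / W)
    se = float(np.sqrt(np.sum(w**2 * (x - p) ** 2)) / W)
    return PrevalenceEstimate(class_label, stratum, p, se)


def weighted_mean_bmi(cohort: pd.DataFrame, stratum: str = "both") -> tuple[float, float]:
    """Survey-weighted mean BMI and its linearized standard error."""
    sub = cohort[_stratum_mask(cohort, stratum)]
    if len(sub) == 0:
        raise EstimationError(f"stratum {stratum!r} is empty")
    w = sub["survey_weight"].to_numpy(dtype=float)
    x = np.asarray(bmi(sub["weight_kg"], sub["height_m"]), dtype=float)
    W = w.sum()
    m = float((w * x).sum() / W)
    se = float(np.sqrt(np.sum(w**2 * (x - m) ** 2)) / W)
    return m, se


def prevalence_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """All class × stratum weighted prevalence estimates as a tidy table."""
    rows = []
    for stratum in STRATA:
        for cls in CLASS_LABELS:
            est = weighted_prevalence(cohort, cls, stratum)
            rows.append({"stratum": stratum, "class": cls,
                         "estimate": est.estimate, "se": est.se})
    return pd.DataFrame(rows)


def mean_bmi_reduction(cohort: pd.DataFrame, dweight_by_sex: Mapping[str, float],
                       stratum: str = "both") -> float:
    """Survey-weighted mean BMI reduction Δw/height² for a stratum (kg/m²).

    Exactly linear in the weight reductions because heights are fixed.
    """
    sub = cohort[_stratum_mask(cohort, stratum)]
    if len(sub) == 0:
        raise EstimationError(f"stratum {stratum!r} is empty")
    dw = sub["sex"].map(dict(dweight_by_sex)).astype(float).to_numpy()
    w = sub["survey_weight"].to_numpy(dtype=float)
    h = sub["height_m"].to_numpy(dtype=float)
    return float(np.sum(w * dw / h**2) / np.sum(w))
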