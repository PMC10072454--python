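"""Sustained energy-intake change → equilibrium body-weight change.

Age-band-specific equilibrium coefficients translate a sustained change in
daily energy intake into a steady-state body-weight change:

* adults (18+): 93.0 kJ/day per kg for men, 72.3 kJ/day per kg for women;
* young children (2–5): 216 kJ/day per kg for boys, 204 for girls;
* children and adolescents (6–17): sex-specific linear equations
  ``kcal/day/kg = 68 − 2.5·age`` (males) and ``62 − 2.2·age`` (females).

About 50% of the equilibrium change is attained after one year and 95%
after three; the model reports the full equilibrium change at the 3-year
horizon by default (``maturity_fraction = 1.0``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .errors import DomainError

logger = logging.getLogger(__name__)

_SEX_ALIASES = {
    "male": "male", "m": "male", "boy": "male", "boys": "male", "men": "male",
    "female": "female", "f": "female", "girl": "female", "girls": "female",
    "women": "female",
}


def _norm_sex(sex: str) -> str:
    try:
        return _SEX_ALIASES[str(sex).strip().lower()]
    except KeyError:
        raise DomainError(f"unknown sex {sex!r}; expected male/female") from None


@dataclass(frozen=True)
class EnergyWeightParams:
    """Equilibrium energy-to-weight coefficients by age band and sex."""

    adult_kj_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 93.0, "female": 72.3})
    child25_kj_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 216.0, "female": 204.0})
    hall_intercept: Mapping[str, float] = field(
        default_factory=lambda: {"male": 68.0, "female": 62.0})
    hall_slope: Mapping[str, float] = field(
        default_factory=lambda: {"male": 2.5, "female": 2.2})
    kcal_to_kj: float = 4.184
    #: Fraction of the equilibrium change attained at the reporting horizon.
    maturity_fraction: float = 1.0

    def __post_init__(self) -> None:
        for m in (self.adult_kj_per_kg, self.child25_kj_per_kg,
                  self.hall_intercept, self.hall_slope):
            if any(v <= 0 for v in m.values()):
                raise DomainError("all energy-weight coefficients must be > 0")
        for sex in ("male", "female"):
            if self.hall_intercept[sex] - self.hall_slope[sex] * 17 <= 0:
                raise DomainError("Hall denominator must stay positive up to age 17")
        if not 0.0 < self.maturity_fraction <= 1.0:
            raise DomainError("maturity_fraction must be in (0, 1]")


DEFAULT_ENERGY_WEIGHT = EnergyWeightParams()


def adult_weight_change(
    denergy: float, sex: str, params: EnergyWeightParams = DEFAULT_ENERGY_WEIGHT
) -> float:
    """Equilibrium weight change (kg) for an adult, sign-preserving.

    ``denergy`` is the sustained change in daily energy intake (kJ/day);
    a positive decrease in intake gives a positive weight reduction.
    """
    return denergy / params.adult_kj_per_kg[_norm_sex(sex)] * params.maturity_fraction


def child_weight_change(
    denergy: float, age: float, sex: str,
    params: EnergyWeightParams = DEFAULT_ENERGY_WEIGHT,
) -> float:
    """Equilibrium weight change (kg) for a child aged 2–17."""
    sex = _norm_sex(sex)
    if not 2 <= age <= 17:
        raise DomainError(f"child age {age} outside [2, 17]; adults use adult_weight_change")
    if age <= 5:
        return denergy / params.child25_kj_per_kg[sex] * params.maturity_fraction
    kcal_per_kg = params.hall_intercept[sex] - params.hall_slope[sex] * age
    return (denergy / params.kcal_to_kj) / kcal_per_kg * params.maturity_fraction


def population_average_child_change(
    denergy: float, age_weights: Mapping[int, float], sex: str,
    params: EnergyWeightParams = DEFAULT_ENERGY_WEIGHT,
) -> float:
    """Age-structure-weighted mean child weight change (kg).

    ``age_weights`` maps single years of age (2–17) to population shares;
    weights that do not sum to one are normalized with a logged warning.
    """
    total = float(sum(age_weights.values()))
    if total <= 0:
        raise DomainError("age weights must have positive total mass")
    if abs(total - 1.0) > 1e-9:
        logger.warning("age weights sum to %.6f; normalizing", total)
    return sum(
        w / total * child_weight_change(denergy, age, sex, params)
        for age, w in age_weights.items()
    )
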