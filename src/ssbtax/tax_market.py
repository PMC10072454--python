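"""Tax design → retail price → SSB consumption, sugar and energy intake.

This module implements the demand side of the model.  An excise tax on
sugar-sweetened beverages (SSBs) — ad valorem on the ex-factory price, a
specific amount per litre, or a specific amount per gram of sugar — raises
the retail price.  A constant own-price elasticity of demand converts the
relative price rise into a change in the volume consumed; the sugar density
of the beverage mix converts volume into grams of sugar, and a fixed energy
density of sugar converts grams into kilojoules.

Price transmission follows a pass-through assumption: the tax is passed
100% into the factory price, which corresponds to roughly 50% of the tax
amount appearing in the retail price (excise applies to the pre-tax factory
price, which is about half the shelf price).

Because the proprietary market-volume and price data behind the published
scenario tables are not public, :func:`calibrate_market` inverts the
published scenario-1 outcome (a 5% price rise cutting consumption by
171.3 million litres/year, 2.6 L/person/year and 0.8 g sugar/person/day)
to recover an internally consistent aggregate baseline volume, market
population and mean sugar density.  Every published scenario then follows
from the linear elasticity response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigurationError, DomainError

#: kJ provided by one gram of sugar (4 kcal).
KJ_PER_GRAM_SUGAR = 16.7

DAYS_PER_YEAR = 365.0

AD_VALOREM = "ad_valorem"
SPECIFIC_VOLUME = "specific_volume"
SPECIFIC_SUGAR = "specific_sugar"
TAX_TYPES = frozenset({AD_VALOREM, SPECIFIC_VOLUME, SPECIFIC_SUGAR})

#: Average sugar content of the four market segments, g per 100 ml.
DEFAULT_SUGAR_DENSITY = {
    "carbonates": 11.0,
    "juices": 7.0,
    "rtd_tea_coffee": 9.0,
    "energy_sport": 16.0,
}


@dataclass(frozen=True)
class BeverageCategory:
    """One SSB market segment.

    Parameters
    ----------
    name
        Segment label, conventionally one of ``carbonates``, ``juices``,
        ``rtd_tea_coffee``, ``energy_sport``.
    baseline_volume
        Annual consumption, million litres/year.
    baseline_retail_price
        Shelf price, VND per litre.
    sugar_density
        Average sugar content, g per 100 ml.
    """

    name: str
    baseline_volume: float
    baseline_retail_price: float
    sugar_density: float

    def __post_init__(self) -> None:
        if self.baseline_volume < 0:
            raise DomainError(f"{self.name}: baseline_volume must be >= 0")
        if self.baseline_retail_price <= 0:
            raise DomainError(f"{self.name}: baseline_retail_price must be > 0")
        if not 0.0 <= self.sugar_density <= 30.0:
            raise DomainError(
                f"{self.name}: sugar_density {self.sugar_density} outside [0, 30] g/100ml"
            )


@dataclass(frozen=True)
class TaxScenario:
    """A tax design and rate, optionally with a known average price rise.

    ``rate`` is a fraction of the factory price for ``ad_valorem``, VND per
    litre for ``specific_volume`` and VND per gram of sugar contained per
    litre for ``specific_sugar``.  ``avg_price_increase_override`` carries an
    externally estimated average retail price increase (the published
    scenarios ship 5%/11%/19%/20%/20% from an external price model); when
    set it takes precedence over the in-package price computation.
    """

    id: str
    tax_type: str
    rate: float
    avg_price_increase_override: float | None = None

    def __post_init__(self) -> None:
        if self.tax_type not in TAX_TYPES:
            raise ConfigurationError(
                f"scenario {self.id}: unknown tax_type {self.tax_type!r}; "
                f"expected one of {sorted(TAX_TYPES)}"
            )
        if self.rate < 0:
            raise ConfigurationError(f"scenario {self.id}: rate must be >= 0")
        if self.avg_price_increase_override is not None and not (
            0.0 <= self.avg_price_increase_override <= 1.0
        ):
            raise ConfigurationError(
                f"scenario {self.id}: avg_price_increase_override must be in [0, 1]"
            )


@dataclass(frozen=True)
class PassThrough:
    """Tax-to-price transmission rates.

    ``factory_rate`` is the share of the tax passed into the factory price
    (default 1.0, i.e. full pass-through); ``retail_rate`` is the share of
    the tax amount that reaches the retail price (default 0.5, since excise
    applies to the factory price, roughly half the shelf price).
    """

    factory_rate: float = 1.0
    retail_rate: float = 0.5

    def __post_init__(self) -> None:
        for name, v in (("factory_rate", self.factory_rate), ("retail_rate", self.retail_rate)):
            if not 0.0 <= v <= 1.5:
                raise ConfigurationError(f"{name} {v} outside [0, 1.5]")


@dataclass(frozen=True)
class Elasticity:
    """Own-price elasticity of SSB demand (default −1.14)."""

    value: float = -1.14

    def __post_init__(self) -> None:
        if self.value >= 0:
            raise ConfigurationError("own-price elasticity must be negative")


DEFAULT_ELASTICITY = Elasticity()


@dataclass(frozen=True)
class MarketImpact:
    """Per-scenario consumption, sugar and energy deltas (negative = decrease)."""

    scenario_id: str
    price_increase: float
    dvolume_total: float  # million litres/year
    dvolume_per_capita: float  # litres/person/year
    dsugar_per_capita: float  # g/person/day
    denergy_per_capita: float  # kJ/person/day

    def __post_init__(self) -> None:
        deltas = (self.dvolume_total, self.dvolume_per_capita,
                  self.dsugar_per_capita, self.denergy_per_capita)
        signs = {np.sign(d) for d in deltas if d != 0}
        if len(signs) > 1:
            raise DomainError(f"{self.scenario_id}: delta signs disagree: {deltas}")
        if not np.isclose(self.denergy_per_capita,
                          KJ_PER_GRAM_SUGAR * self.dsugar_per_capita, rtol=1e-6, atol=1e-9):
            raise DomainError(
                f"{self.scenario_id}: energy delta inconsistent with sugar delta"
            )


@dataclass(frozen=True)
class MarketCalibration:
    """Aggregate market recovered from the published scenario-1 outcome."""

    baseline_volume_total: float  # million litres/year
    population: float  # persons
    mean_sugar_density: float  # g/100ml


def _elasticity_value(elasticity: Elasticity | float) -> float:
    return elasticity.value if isinstance(elasticity, Elasticity) else float(elasticity)


def retail_price_increase(
    scenario: TaxScenario,
    category: BeverageCategory | None = None,
    pass_through: PassThrough = PassThrough(),
) -> float:
    """Fractional retail price increase a tax scenario produces.

    An explicit ``avg_price_increase_override`` on the scenario always wins
    (that is how externally estimated average price rises enter the model).
    Otherwise, ad valorem taxes raise the retail price by ``rate ×
    retail_rate`` (the factory price is about half the shelf price), and
    specific taxes by the per-litre tax amount times ``retail_rate`` divided
    by the category's retail price — which requires a ``category``.
    """
    if scenario.avg_price_increase_override is not None:
        return scenario.avg_price_increase_override
    if scenario.rate == 0:
        return 0.0
    if scenario.tax_type == AD_VALOREM:
        return scenario.rate * pass_through.retail_rate
    if category is None:
        raise ConfigurationError(
            f"scenario {scenario.id}: a specific tax needs a beverage category "
            "with a retail price, or an avg_price_increase_override"
        )
    if category.baseline_retail_price <= 0:
        raise DomainError("retail price must be positive")
    if scenario.tax_type == SPECIFIC_VOLUME:
        tax_per_litre = scenario.rate
    else:  # SPECIFIC_SUGAR: rate is VND per gram of sugar; density g/100ml → g/L
        tax_per_litre = scenario.rate * (category.sugar_density * 10.0)
    return tax_per_litre * pass_through.retail_rate / category.baseline_retail_price


def consumption_change(
    price_increase: float,
    elasticity: Elasticity | float,
    baseline_volume: float,
) -> float:
    """Change in annual volume (million litres/year, negative for a decrease).

    Linear point-elasticity response: ``ΔV = ε · Δp · V``.  The linear form
    (rather than a constant-elasticity power curve) is what makes scenario
    outcomes scale proportionally with the price rise, e.g. a 20% rise
    produces exactly four times the decrease of a 5% rise.
    """
    if baseline_volume < 0:
        raise DomainError("baseline_volume must be >= 0")
    return _elasticity_value(elasticity) * price_increase * baseline_volume


def calibrate_market(
    printed_decrease_s1: float = 171.3,
    price_increase_s1: float = 0.05,
    elasticity: Elasticity | float = DEFAULT_ELASTICITY,
    per_capita_decrease_s1: float = 2.6,
    sugar_decrease_s1: float = 0.8,
    energy_decrease_s1: float | None = None,
) -> MarketCalibration:
    """Invert the published scenario-1 outcome into an aggregate market.

    From a 5% price rise reducing consumption by ``printed_decrease_s1``
    million litres/year, ``per_capita_decrease_s1`` litres/person/year and
    ``sugar_decrease_s1`` g sugar/person/day, recover:

    * total baseline volume ``V = ΔV / (Δp · |ε|)`` (million litres/year),
    * the consuming population ``ΔV / Δv_pc`` (persons),
    * the volume-weighted mean sugar density (g/100 ml).

    The published sugar decrease is rounded to one decimal; if the energy
    decrease (kJ/person/day) is supplied via ``energy_decrease_s1`` the
    sugar decrease is taken as ``energy / 16.7`` instead, which keeps the
    calibrated chain consistent with the published energy row.
    """
    if energy_decrease_s1 is not None:
        sugar_decrease_s1 = energy_decrease_s1 / KJ_PER_GRAM_SUGAR
    eps = _elasticity_value(elasticity)
    if price_increase_s1 <= 0 or eps == 0:
        raise CalibrationError("price increase and elasticity must be non-zero")
    for name, v in (("printed_decrease_s1", printed_decrease_s1),
                    ("per_capita_decrease_s1", per_capita_decrease_s1),
                    ("sugar_decrease_s1", sugar_decrease_s1)):
        if v <= 0:
            raise CalibrationError(f"{name} must be > 0 in magnitude")
    volume = printed_decrease_s1 / (price_increase_s1 * abs(eps))
    population = printed_decrease_s1 * 1e6 / per_capita_decrease_s1
    ml_per_day = per_capita_decrease_s1 * 1000.0 / DAYS_PER_YEAR
    density = sugar_decrease_s1 / ml_per_day * 100.0
    return MarketCalibration(volume, population, density)


def sugar_change(dvolume_ml_per_day, sugar_density) -> float:
    """Sugar change (g/person/day) from a volume change (ml/person/day).

    Accepts scalars or aligned per-category vectors; vectors are summed.
    """
    dv = np.asarray(dvolume_ml_per_day, dtype=float)
    dens = np.asarray(sugar_density, dtype=float)
    if np.any(dens < 0):
        raise DomainError("sugar density must be >= 0")
    return float(np.sum(dv * dens / 100.0))


def energy_change(dsugar: float) -> float:
    """Energy change (kJ/person/day) from a sugar change (g/person/day)."""
    return KJ_PER_GRAM_SUGAR * dsugar


def market_impact(
    scenario: TaxScenario,
    calibration: MarketCalibration,
    elasticity: Elasticity | float = DEFAULT_ELASTICITY,
    pass_through: PassThrough = PassThrough(),
) -> MarketImpact:
    """Run one scenario against the calibrated aggregate market."""
    dp = retail_price_increase(scenario, None, pass_through)
    dtotal = consumption_change(dp, elasticity, calibration.baseline_volume_total)
    dpc = dtotal * 1e6 / calibration.population
    dml_day = dpc * 1000.0 / DAYS_PER_YEAR
    dsugar = sugar_change(dml_day, calibration.mean_sugar_density)
    return MarketImpact(
        scenario_id=scenario.id,
        price_increase=dp,
        dvolume_total=dtotal,
        dvolume_per_capita=dpc,
        dsugar_per_capita=dsugar,
        denergy_per_capita=energy_change(dsugar),
    )


def market_impact_by_category(
    scenario: TaxScenario,
    categories: list[BeverageCategory],
    population: float,
    elasticity: Elasticity | float = DEFAULT_ELASTICITY,
    pass_through: PassThrough = PassThrough(),
) -> MarketImpact:
    """Run one scenario against a user-supplied category table.

    Price increases are computed per category from the tax design (the
    scenario's override, an aggregate shortcut, is ignored here), so this
    path needs real category retail prices.
    """
    if not categories:
        raise ConfigurationError("category list is empty")
    if population <= 0:
        raise DomainError("population must be > 0")
    base = TaxScenario(scenario.id, scenario.tax_type, scenario.rate, None)
    dps = np.array([retail_price_increase(base, c, pass_through) for c in categories])
    vols = np.array([c.baseline_volume for c in categories])
    dens = np.array([c.sugar_density for c in categories])
    eps = _elasticity_value(elasticity)
    dvols = eps * dps * vols  # million litres/year per category
    dtotal = float(dvols.sum())
    dml_day = dvols * 1e6 / population * 1000.0 / DAYS_PER_YEAR
    dsugar = sugar_change(dml_day, dens)
    avg_dp = float(np.average(dps, weights=vols)) if vols.sum() > 0 else 0.0
    return MarketImpact(
        scenario_id=scenario.id,
        price_increase=avg_dp,
        dvolume_total=dtotal,
        dvolume_per_capita=dtotal * 1e6 / population,
        dsugar_per_capita=dsugar,
        denergy_per_capita=energy_change(dsugar),
    )


#: The five published tax scenarios with their externally estimated average
#: retail price increases (5%, 11%, 19%, 20%, 20%).
PAPER_SCENARIOS: tuple[TaxScenario, ...] = (
    TaxScenario("scenario1", AD_VALOREM, 0.10, 0.05),
    TaxScenario("scenario2", SPECIFIC_VOLUME, 3500.0, 0.11),
    TaxScenario("scenario3", SPECIFIC_SUGAR, 60.0, 0.19),
    TaxScenario("scenario4", SPECIFIC_VOLUME, 7000.0, 0.20),
    TaxScenario("scenario5", AD_VALOREM, 0.40, 0.20),
)
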