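"""Run configuration, orchestration and table emission.

``run_pipeline`` executes the full causal chain for every configured tax
scenario — price rise → consumption, sugar and energy decrease → adult and
child weight change → cohort BMI/obesity prevalence → diabetes burden —
plus the probabilistic and one-way sensitivity analyses, and writes one
tidy CSV per published results table together with a reproducibility
manifest (config hash, seed, package versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometry import (
    DEFAULT_ENERGY_WEIGHT,
    EnergyWeightParams,
    adult_weight_change,
    population_average_child_change,
)
from .cohort import CohortSpec, child_age_weights, generate_adult_cohort, read_cohort
from .diabetes import DEFAULT_DIABETES, DiabetesParams, burden
from .errors import ConfigurationError, PipelineError
from .obesity import (
    apply_weight_change,
    mean_bmi_reduction,
    prevalence_table,
    weighted_mean_bmi,
)
from .tax_market import (
    PAPER_SCENARIOS,
    Elasticity,
    TaxScenario,
    calibrate_market,
    market_impact,
)
from .uncertainty import MCConfig, one_way_sa, run_mc

logger = logging.getLogger(__name__)

TABLE_FILES = ("market_impact.csv", "weight_change.csv", "prevalence.csv",
               "burden.csv", "mc_summary.csv", "sa_elasticity.csv")


@dataclass
class RunConfig:
    """Validated run configuration; every default is echoed to the log."""

    scenarios: list[TaxScenario] = field(default_factory=lambda: list(PAPER_SCENARIOS))
    elasticity: float = -1.14
    calibration_inputs: dict = field(default_factory=lambda: {
        "printed_decrease_s1": 171.3, "price_increase_s1": 0.05,
        "per_capita_decrease_s1": 2.6, "energy_decrease_s1": 13.7})
    cohort_path: str | None = None
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    energy_weight: EnergyWeightParams = field(default_factory=EnergyWeightParams)
    diabetes: DiabetesParams = field(default_factory=DiabetesParams)
    mc: MCConfig | None = field(default_factory=MCConfig)
    sa_elasticities: list[float] = field(default_factory=lambda: [-1.14, -1.0, -0.8])
    outputs: str = "outputs"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigurationError("scenario list is empty")
        if self.elasticity >= 0:
            raise ConfigurationError("elasticity must be negative")

    def to_dict(self) -> dict:
        d = {
            "scenarios": [asdict(s) for s in self.scenarios],
            "elasticity": self.elasticity,
            "calibration_inputs": dict(self.calibration_inputs),
            "cohort_path": self.cohort_path,
            "cohort_spec": _plain(asdict(self.cohort_spec)),
            "energy_weight": _plain(asdict(self.energy_weight)),
            "diabetes": _plain(asdict(self.diabetes)),
            "mc": _plain(asdict(self.mc)) if self.mc is not None else None,
            "sa_elasticities": list(self.sa_elasticities),
            "outputs": self.outputs,
            "seed": self.seed,
        }
        return d


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    kwargs: dict = {}
    if "scenarios" in raw:
        kwargs["scenarios"] = [
            TaxScenario(s["id"], s["tax_type"], float(s["rate"]),
                        s.get("avg_price_increase"))
            for s in raw["scenarios"]]
    for key in ("elasticity", "calibration_inputs", "cohort_path",
                "sa_elasticities", "outputs", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "cohort_spec" in raw:
        kwargs["cohort_spec"] = CohortSpec(**raw["cohort_spec"])
    if "energy_weight" in raw:
        kwargs["energy_weight"] = EnergyWeightParams(**raw["energy_weight"])
    if "diabetes" in raw:
        d = dict(raw["diabetes"])
        if "rrr_ci" in d:
            d["rrr_ci"] = tuple(d["rrr_ci"])
        kwargs["diabetes"] = DiabetesParams(**d)
    if "mc" in raw:
        if raw["mc"] is None:
            kwargs["mc"] = None
        else:
            m = dict(raw["mc"])
            if "rrr_ci" in m:
                m["rrr_ci"] = tuple(m["rrr_ci"])
            kwargs["mc"] = MCConfig(**m)
    return RunConfig(**kwargs)


def _stage(name: str, scenario_id: str | None = None):
    where = f"stage {name!r}" + (f", scenario {scenario_id!r}" if scenario_id else "")
    class _Ctx:
        def __enter__(self):
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"{where}: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute all stages for every scenario and write the output tables."""
    logger.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True))
    outdir = Path(config.outputs)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    with _stage("calibrate_market"):
        cal = calibrate_market(elasticity=config.elasticity,
                               **config.calibration_inputs)

    with _stage("cohort"):
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            spec = config.cohort_spec
            if spec.seed != config.seed:
                spec = CohortSpec(**{**asdict(spec), "seed": config.seed})
            cohort = generate_adult_cohort(spec)

    elasticity = Elasticity(config.elasticity)
    impacts = {}
    rows = []
    for sc in config.scenarios:
        with _stage("market_impact", sc.id):
            imp = market_impact(sc, cal, elasticity)
        impacts[sc.id] = imp
        rows.append({
            "scenario_id": sc.id, "price_increase": imp.price_increase,
            "decrease_total_ml_per_year": -imp.dvolume_total,
            "decrease_l_per_person_year": -imp.dvolume_per_capita,
            "decrease_sugar_g_per_day": -imp.dsugar_per_capita,
            "decrease_energy_kj_per_day": -imp.denergy_per_capita,
        })
    tables["market_impact"] = pd.DataFrame(rows)

    ages = child_age_weights("uniform")
    rows = []
    dw_by_scenario = {}
    for sc in config.scenarios:
        with _stage("weight_change", sc.id):
            de = -impacts[sc.id].denergy_per_capita
            dw = {"male": adult_weight_change(de, "male", config.energy_weight),
                  "female": adult_weight_change(de, "female", config.energy_weight)}
            dw_by_scenario[sc.id] = dw
            rows.append({
                "scenario_id": sc.id, "denergy_kj_per_day": de,
                "adult_male_kg": dw["male"], "adult_female_kg": dw["female"],
                "child_boys_kg": population_average_child_change(
                    de, ages, "male", config.energy_weight),
                "child_girls_kg": population_average_child_change(
                    de, ages, "female", config.energy_weight),
            })
    tables["weight_change"] = pd.DataFrame(rows)

    prev_frames = []
    base = prevalence_table(cohort).assign(scenario_id="baseline")
    for stratum in ("both", "male", "female"):
        m, se = weighted_mean_bmi(cohort, stratum)
        base.loc[len(base)] = {"stratum": stratum, "class": "mean_bmi",
                               "estimate": m, "se": se, "scenario_id": "baseline"}
    prev_frames.append(base)
    for sc in config.scenarios:
        with _stage("prevalence", sc.id):
            shifted = apply_weight_change(cohort, dw_by_scenario[sc.id])
            t = prevalence_table(shifted).assign(scenario_id=sc.id)
            for stratum in ("both", "male", "female"):
                m, se = weighted_mean_bmi(shifted, stratum)
                t.loc[len(t)] = {"stratum": stratum, "class": "mean_bmi",
                                 "estimate": m, "se": se, "scenario_id": sc.id}
            prev_frames.append(t)
    tables["prevalence"] = pd.concat(prev_frames, ignore_index=True)[
        ["scenario_id", "stratum", "class", "estimate", "se"]]

    rows = []
    for sc in config.scenarios:
        with _stage("burden", sc.id):
            for stratum in ("both", "male", "female"):
                dbmi = mean_bmi_reduction(cohort, dw_by_scenario[sc.id], stratum)
                b = burden(sc.id, dbmi, config.diabetes, stratum)
                rows.append({
                    "scenario_id": sc.id, "stratum": stratum, "dbmi": b.dbmi,
                    "prevalence_reduction_pp": b.prevalence_reduction_pp,
                    "avoided_cases": b.avoided_cases,
                    "cost_saving_bn_vnd": b.cost_saving_bn_vnd,
                    "cost_saving_m_usd": b.cost_saving_m_usd,
                })
    tables["burden"] = pd.DataFrame(rows)

    if config.mc is not None:
        rows = []
        for sc in config.scenarios:
            for model in ("model1", "model2"):
                with _stage("monte_carlo", sc.id):
                    mc_cfg = MCConfig(**{**asdict(config.mc), "model": model,
                                         "seed": config.mc.seed})
                    res = run_mc(sc, cohort, mc_cfg, cal, elasticity,
                                 config.diabetes, config.energy_weight)
                for key in res.means:
                    rows.append({"scenario_id": sc.id, "model": model,
                                 "output": key, "mean": res.means[key],
                                 "sd": res.sds[key]})
        tables["mc_summary"] = pd.DataFrame(rows)

    if config.sa_elasticities:
        with _stage("one_way_sa"):
            tables["sa_elasticity"] = one_way_sa(
                config.sa_elasticities, config.scenarios, cohort,
                Elasticity(config.elasticity), config.diabetes,
                config.energy_weight, cal)

    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    _write_manifest(config, outdir)
    return tables


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "ssbtax": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _fmt(df: pd.DataFrame, ndigits: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in ndigits.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    return out


def render_report(outdir) -> str:
    """Assemble a plain-markdown summary of the pipeline outputs.

    Litres and kJ print with 1 decimal, kg and BMI with 2; missing tables
    are listed as absent rather than failing.
    """
    outdir = Path(outdir)
    parts = ["# SSB tax health-impact model — run report", ""]
    specs = {
        "market_impact.csv": ("Consumption, sugar and energy decreases", {
            "price_increase": 3, "decrease_total_ml_per_year": 1,
            "decrease_l_per_person_year": 1, "decrease_sugar_g_per_day": 1,
            "decrease_energy_kj_per_day": 1}),
        "weight_change.csv": ("Equilibrium weight change (kg, 3-year horizon)", {
            "denergy_kj_per_day": 1, "adult_male_kg": 2, "adult_female_kg": 2,
            "child_boys_kg": 2, "child_girls_kg": 2}),
        "prevalence.csv": ("BMI class prevalence (survey-weighted)", {
            "estimate": 4, "se": 4}),
        "burden.csv": ("Diabetes burden and cost savings", {
            "dbmi": 2, "prevalence_reduction_pp": 3,
            "cost_saving_bn_vnd": 2, "cost_saving_m_usd": 2}),
        "mc_summary.csv": ("Monte Carlo summary (means and SDs)", {
            "mean": 4, "sd": 5}),
        "sa_elasticity.csv": ("One-way sensitivity analysis on elasticity", {
            "dvolume_total": 1, "dsugar_per_capita": 2, "denergy_per_capita": 1,
            "weight_change_male": 2, "weight_change_female": 2,
            "bmi_reduction_both": 3, "prevalence_reduction_pp": 3}),
    }
    for fname, (title, digits) in specs.items():
        path = outdir / fname
        parts.append(f"## {title}")
        if not path.exists():
            note = ("(table absent — deterministic-only run)"
                    if fname == "mc_summary.csv" else "(table absent)")
            parts.extend([note, ""])
            continue
        try:
            df = pd.read_csv(path)
        except Exception as e:  # noqa: BLE001 - report what is unreadable
            from .errors import SchemaError
            raise SchemaError(f"{path}: unreadable table: {e}") from e
        parts.extend(["```", _fmt(df, digits).to_string(index=False), "```", ""])
    report = "\n".join(parts)
    (outdir / "report.md").write_text(report)
    return report
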