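"""End-to-end orchestration: one config in, every analysis artefact out.

A scenario is a named combination of savings model, volume mode and per-drug
reference years (given literally or as a selection rule), so every published
variant - basic estimated, fixed-volume estimated, real-life, and the
alternative real-life anchoring infliximab at its pre-biosimilar year - is
reachable through configuration alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import yaml

from . import access as access_mod
from . import costs as costs_mod
from . import savings as savings_mod
from .errors import BIAError, SchemaError
from .records import (RecordSet, Sector, load_poland, load_poland_reported_costs,
                      patients_by_year, read_recordset, subset)

__all__ = [
    "ScenarioSpec",
    "AnalysisConfig",
    "ScenarioResult",
    "AnalysisBundle",
    "run_pipeline",
    "study_config",
]

log = logging.getLogger("tnfi_bia")


@dataclass(frozen=True)
class ScenarioSpec:
    """One savings scenario: model + volume mode + per-drug reference anchors.

    ``refs`` values are calendar years or rule names
    (``PRE_BIOSIMILAR`` / ``PEAK_EXPENDITURE``).
    """

    name: str
    model: str                     # "estimated" | "real_life"
    refs: Mapping[str, int | str]
    mode: str = "ACTUAL_VOLUME"    # estimated model only

    def __post_init__(self) -> None:
        if self.model not in ("estimated", "real_life"):
            raise SchemaError(f"scenario {self.name}: unknown model {self.model!r}")
        savings_mod.VolumeMode(self.mode)


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs, scenario matrix and display options for one full analysis."""

    records_csv: str | None = None        # None -> packaged Poland fixture
    meta_yaml: str | None = None
    sectors: tuple[str, ...] = ("ALL", "RMD")
    scenarios: tuple[ScenarioSpec, ...] = ()
    cost_ref_years: Mapping[str, int | str] = field(default_factory=dict)
    sensitivity_tolerance: float = 5.0
    use_reported_costs: bool = True       # reinvestment cost basis, when available
    population: float | None = None       # override fixture population
    output_dir: str = "bia_output"

    @staticmethod
    def from_yaml(path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        scenarios = tuple(
            ScenarioSpec(name=s["name"], model=s["model"], refs=s.get("refs", {}),
                         mode=s.get("mode", "ACTUAL_VOLUME"))
            for s in doc.get("scenarios", []))
        cfg = AnalysisConfig(
            records_csv=doc.get("records_csv"),
            meta_yaml=doc.get("meta_yaml"),
            sectors=tuple(doc.get("sectors", ("ALL", "RMD"))),
            scenarios=scenarios,
            cost_ref_years=doc.get("cost_ref_years", {}),
            sensitivity_tolerance=float(doc.get("sensitivity_tolerance", 5.0)),
            use_reported_costs=bool(doc.get("use_reported_costs", True)),
            population=doc.get("population"),
            output_dir=doc.get("output_dir", "bia_output"),
        )
        return cfg if cfg.scenarios else replace(cfg, scenarios=_default_scenarios())


def _default_scenarios() -> tuple[ScenarioSpec, ...]:
    pre = "PRE_BIOSIMILAR"
    return (
        ScenarioSpec("estimated", "estimated",
                     MappingProxyType({"*": pre})),
        ScenarioSpec("estimated_fixed", "estimated",
                     MappingProxyType({"*": pre}), mode="FIXED_VOLUME"),
        ScenarioSpec("real_life", "real_life",
                     MappingProxyType({"INF": "PEAK_EXPENDITURE", "*": pre})),
        ScenarioSpec("real_life_alt", "real_life",
                     MappingProxyType({"*": pre})),
    )


def study_config(output_dir: str = "bia_output") -> AnalysisConfig:
    """The study configuration: packaged Poland fixture, both sectors, all four
    published scenarios, cost references at each drug's pre-biosimilar year."""
    return AnalysisConfig(scenarios=_default_scenarios(),
                          cost_ref_years={"*": "PRE_BIOSIMILAR"},
                          output_dir=output_dir)


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    sector: Sector
    series: Mapping[str, savings_mod.SavingsSeries]
    aggregate: savings_mod.AggregateSavings


@dataclass(frozen=True)
class AnalysisBundle:
    """Everything one pipeline run produces, keyed for rendering."""

    recordset: RecordSet
    scenarios: Mapping[str, Mapping[str, ScenarioResult]]  # name -> sector -> result
    costs: Mapping[str, Mapping[str, object]]              # drug -> component map
    ddd: Mapping[str, access_mod.DDDSeries]
    access: Mapping[str, Mapping[str, access_mod.AccessReport]]  # sector -> drug
    provenance: Mapping[str, object]

    def scenario(self, name: str, sector: str | Sector) -> ScenarioResult:
        return self.scenarios[name][Sector(sector).value]


def _resolve_ref(refs: Mapping[str, int | str], drug: str, series, meta) -> int:
    ref = refs.get(drug, refs.get("*"))
    if ref is None:
        raise SchemaError(f"no reference year or rule configured for drug {drug}")
    if isinstance(ref, int):
        return ref
    return savings_mod.select_reference_year(series, ref, meta)


def _run_scenario(rs: RecordSet, spec: ScenarioSpec, sector: Sector) -> ScenarioResult:
    series_by_drug: dict[str, savings_mod.SavingsSeries] = {}
    for drug in rs.drugs:
        series = subset(rs, drug, sector)
        ref_year = _resolve_ref(spec.refs, drug, series, rs.meta[drug])
        if spec.model == "estimated":
            ref_price = savings_mod.reference_unit_price(series, ref_year)
            result = savings_mod.estimated_savings(series, ref_price, spec.mode)
        else:
            result = savings_mod.real_life_savings(series, ref_year)
        series_by_drug[drug] = result
    agg = savings_mod.aggregate(series_by_drug.values())
    return ScenarioResult(spec=spec, sector=sector,
                          series=MappingProxyType(series_by_drug), aggregate=agg)


def run_pipeline(config: AnalysisConfig) -> AnalysisBundle:
    """Run every configured scenario, cost metric, exposure and access report.

    Errors from any stage propagate annotated with the stage and drug.
    """
    t0 = time.perf_counter()
    if config.records_csv is None:
        rs = load_poland()
        reported = load_poland_reported_costs() if config.use_reported_costs else {}
    else:
        if config.meta_yaml is None:
            raise SchemaError("records_csv given without meta_yaml")
        rs = read_recordset(config.records_csv, config.meta_yaml)
        reported = {}
    if config.population is not None:
        rs = RecordSet(records=rs.records, meta=rs.meta, population=config.population,
                       currency=rs.currency, flags=rs.flags, version=rs.version)
    scenarios = config.scenarios or _default_scenarios()

    scen_out: dict[str, dict[str, ScenarioResult]] = {}
    for spec in scenarios:
        scen_out[spec.name] = {}
        for sector_name in config.sectors:
            sector = Sector(sector_name)
            try:
                scen_out[spec.name][sector.value] = _run_scenario(rs, spec, sector)
            except BIAError as exc:
                raise type(exc)(f"scenario {spec.name} [{sector.value}]: {exc}") from exc
        log.info("scenario %s done (%.3fs)", spec.name, time.perf_counter() - t0)

    # treatment costs: computed on the combined sector, both methods
    cost_out: dict[str, dict[str, object]] = {}
    for drug in rs.drugs:
        series = subset(rs, drug, Sector.ALL)
        ref_year = _resolve_ref(config.cost_ref_years or {"*": "PRE_BIOSIMILAR"},
                                drug, series, rs.meta[drug])
        try:
            per_mg = costs_mod.unit_cost_series(series, ref_year)
            per_pt = costs_mod.per_patient_cost_series(series, ref_year)
        except BIAError as exc:
            raise type(exc)(f"costs [{drug}]: {exc}") from exc
        entry: dict[str, object] = {
            "per_mg": per_mg,
            "per_patient": per_pt,
            "sensitivity": costs_mod.sensitivity_compare(
                per_mg, per_pt, config.sensitivity_tolerance),
        }
        if drug in reported:
            entry["reported_per_patient"] = costs_mod.cost_series_from_values(
                drug, Sector.ALL, costs_mod.CostMethod.PER_PATIENT, ref_year,
                reported[drug]["per_patient"])
            entry["reported_per_mg"] = costs_mod.cost_series_from_values(
                drug, Sector.ALL, costs_mod.CostMethod.PER_MG, ref_year,
                reported[drug]["per_mg"])
        cost_out[drug] = entry
    log.info("costs done (%.3fs)", time.perf_counter() - t0)

    # exposure: DDD on the combined sector only (rates are population-wide)
    ddd_out: dict[str, access_mod.DDDSeries] = {}
    for drug in rs.drugs:
        series = subset(rs, drug, Sector.ALL)
        ref_year = _resolve_ref(config.cost_ref_years or {"*": "PRE_BIOSIMILAR"},
                                drug, series, rs.meta[drug])
        ddd_out[drug] = access_mod.ddd_series(series, rs.meta[drug].ddd_mg,
                                              rs.population, ref_year)

    # access: reinvestment counterfactual from the primary real-life scenario,
    # costed at the payer's reported per-patient cost when available
    access_out: dict[str, dict[str, access_mod.AccessReport]] = {}
    rl_name = next((s.name for s in scenarios if s.model == "real_life"), None)
    if rl_name is not None:
        for sector_name in config.sectors:
            sector = Sector(sector_name)
            access_out[sector.value] = {}
            for drug in rs.drugs:
                sav = scen_out[rl_name][sector.value].series[drug]
                cost_basis = cost_out[drug].get("reported_per_patient",
                                                cost_out[drug]["per_patient"])
                series = subset(rs, drug, sector)
                report = access_mod.potential_additional_patients(
                    sav, cost_basis, series)
                patients = patients_by_year(series)
                era = (max(min(patients), rs.meta[drug].first_biosimilar_year - 1),
                       max(patients))
                try:
                    growth = access_mod.era_growth(patients, era)
                except BIAError:
                    growth = None
                access_out[sector.value][drug] = access_mod.AccessReport(
                    drug=drug, sector=sector, per_year=report.per_year,
                    era_growth=growth)
    log.info("access done (%.3fs)", time.perf_counter() - t0)

    provenance = {
        "fixture_version": rs.version,
        "sectors": list(config.sectors),
        "scenarios": {s.name: {"model": s.model, "mode": s.mode,
                               "refs": dict(s.refs)} for s in scenarios},
        "population": rs.population,
        "pln_per_eur": rs.currency.pln_per_eur,
    }
    return AnalysisBundle(recordset=rs,
                          scenarios=MappingProxyType(scen_out),
                          costs=MappingProxyType(cost_out),
                          ddd=MappingProxyType(ddd_out),
                          access=MappingProxyType(access_out),
                          provenance=MappingProxyType(provenance))
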