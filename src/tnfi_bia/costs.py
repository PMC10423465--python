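"""Annual treatment-cost metrics and the two-method sensitivity check.

Costs are computed by two independent routes: spend per milligram
(``PER_MG``) and spend per patient treated (``PER_PATIENT``).  Because the
payer publishes spend, volumes and patient counts in different data sets,
agreement between the two percent-of-reference trajectories is the study's
sensitivity check on data consistency.

Display rounding follows the published convention (per-mg to 2 decimals,
per-patient to whole EUR, percentages to whole points, half away from zero);
all computation is full precision.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

from .errors import MissingYearError
from .records import AnnualDrugRecord, Sector

__all__ = [
    "CostMethod",
    "YearCost",
    "CostSeries",
    "SensitivityReport",
    "unit_cost_series",
    "per_patient_cost_series",
    "cost_series_from_values",
    "sensitivity_compare",
    "round_half_away",
]


class CostMethod(str, enum.Enum):
    PER_MG = "PER_MG"
    PER_PATIENT = "PER_PATIENT"


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the published tables' convention)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class YearCost:
    cost: float                      # EUR per mg, or EUR per patient-year
    pct_of_reference: float | None   # None before the reference year


@dataclass(frozen=True)
class CostSeries:
    """Per-year unit cost with percent-of-reference index for one drug/sector."""

    drug: str
    sector: Sector
    method: CostMethod
    ref_year: int
    per_year: Mapping[int, YearCost]
    overall_reduction: float  # 100 * (1 - cost(last year) / cost(ref year)), percent

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.per_year))

    def cost(self, year: int) -> float:
        if year not in self.per_year:
            raise MissingYearError(f"{self.drug}: no cost for year {year}")
        return self.per_year[year].cost


def _build(drug: str, sector: Sector, method: CostMethod, ref_year: int,
           costs: dict[int, float]) -> CostSeries:
    if ref_year not in costs:
        raise MissingYearError(f"{drug}: reference year {ref_year} has no cost")
    ref_cost = costs[ref_year]
    per_year = {
        y: YearCost(cost=c,
                    pct_of_reference=(100.0 * c / ref_cost if y >= ref_year else None))
        for y, c in sorted(costs.items())
    }
    last = max(costs)
    overall = 100.0 * (1.0 - costs[last] / ref_cost)
    return CostSeries(drug=drug, sector=sector, method=method, ref_year=ref_year,
                      per_year=MappingProxyType(per_year), overall_reduction=overall)


def unit_cost_series(series: Sequence[AnnualDrugRecord], ref_year: int) -> CostSeries:
    """Average annual cost of one milligram: E_t / V_t for each year with volume."""
    costs: dict[int, float] = {}
    drug = sector = None
    for rec in series:
        drug, sector = rec.drug, rec.sector
        if rec.reimbursement_value is None or rec.mg_volume is None:
            continue
        if rec.mg_volume == 0:
            raise MissingYearError(f"{rec.drug} {rec.year}: zero mg_volume, "
                                   "unit cost undefined")
        costs[rec.year] = rec.reimbursement_value / rec.mg_volume
    if not costs:
        raise MissingYearError("series has no year with both spend and volume")
    return _build(drug, sector, CostMethod.PER_MG, ref_year, costs)


def per_patient_cost_series(series: Sequence[AnnualDrugRecord],
                            ref_year: int) -> CostSeries:
    """Average annual cost of treating one patient: E_t / patients_t."""
    costs: dict[int, float] = {}
    drug = sector = None
    for rec in series:
        drug, sector = rec.drug, rec.sector
        if rec.reimbursement_value is None or rec.patients is None:
            continue
        if rec.patients == 0:
            raise MissingYearError(f"{rec.drug} {rec.year}: zero patients, "
                                   "per-patient cost undefined")
        costs[rec.year] = rec.reimbursement_value / rec.patients
    if not costs:
        raise MissingYearError("series has no year with both spend and patients")
    return _build(drug, sector, CostMethod.PER_PATIENT, ref_year, costs)


def cost_series_from_values(drug: str, sector: Sector | str, method: CostMethod | str,
                            ref_year: int, values: Mapping[int, float]) -> CostSeries:
    """Build a CostSeries from externally published cost values.

    Used for the payer's independently sourced annual per-patient costs, which
    are not exactly spend/patients for every year.
    """
    return _build(drug, Sector(sector), CostMethod(method), ref_year, dict(values))


@dataclass(frozen=True)
class SensitivityReport:
    """Agreement between two costing methods for the same drug/sector/reference."""

    drug: str
    per_year_diff: Mapping[int, float]  # pct-of-reference difference (a - b), points
    overall_diff: float                 # overall_reduction difference, points
    max_abs_diff: float
    tolerance: float
    passed: bool


def sensitivity_compare(a: CostSeries, b: CostSeries,
                        tolerance: float = 5.0) -> SensitivityReport:
    """Compare two costing methods.

    PASS when the overall-reduction difference is within ``tolerance``
    percentage points - the study-level consistency claim.  Per-year
    percent-of-reference differences are reported as diagnostics (single
    years can diverge more when patient mix shifts faster than volume, as
    the published infliximab 2016 cells do)."""
    if (a.drug, a.sector, a.ref_year) != (b.drug, b.sector, b.ref_year):
        raise ValueError(
            f"cannot compare cost series with mismatched keys: "
            f"{(a.drug, a.sector.value, a.ref_year)} vs "
            f"{(b.drug, b.sector.value, b.ref_year)}")
    diffs: dict[int, float] = {}
    for y in sorted(set(a.per_year) & set(b.per_year)):
        pa, pb = a.per_year[y].pct_of_reference, b.per_year[y].pct_of_reference
        if pa is None or pb is None:
            continue
        diffs[y] = pa - pb
    overall = a.overall_reduction - b.overall_reduction
    max_abs = max([abs(overall)] + [abs(d) for d in diffs.values()])
    return SensitivityReport(drug=a.drug, per_year_diff=MappingProxyType(diffs),
                             overall_diff=overall, max_abs_diff=max_abs,
                             tolerance=tolerance, passed=abs(overall) <= tolerance)
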