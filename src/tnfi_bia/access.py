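"""Drug exposure, treatment access and the savings-reinvestment counterfactual.

Exposure is expressed as WHO defined daily doses (DDD) per 1000 inhabitants
per year (a year, not a day, keeps the numbers on a readable scale for these
drugs).  Access is measured directly as patients treated, and
counterfactually as the additional patients the payer could have funded had
every euro of real-life savings been reinvested at that year's per-patient
treatment cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

from .costs import CostSeries
from .errors import MissingYearError, RecordValidationError
from .records import AnnualDrugRecord, DrugMeta, Sector, patients_by_year
from .savings import SavingsSeries

__all__ = [
    "DDDYear",
    "DDDSeries",
    "AccessYear",
    "AccessReport",
    "EraGrowth",
    "ddd_series",
    "potential_additional_patients",
    "era_growth",
    "market_share",
    "eligible_coverage",
]


@dataclass(frozen=True)
class DDDYear:
    n_ddd: float                    # defined daily doses dispensed (fractional)
    ddd_per_1000_per_year: float
    pct_of_reference: float | None


@dataclass(frozen=True)
class DDDSeries:
    """Population exposure to one drug in defined daily doses."""

    drug: str
    ddd_mg: float
    population: float
    ref_year: int
    per_year: Mapping[int, DDDYear]

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.per_year))


def ddd_series(series: Sequence[AnnualDrugRecord], ddd_mg: float,
               population: float, ref_year: int) -> DDDSeries:
    """DDD counts and per-1000-inhabitant rates with a percent-of-reference index.

    ``n_ddd = mg_volume / ddd_mg``; the rate divides by population in
    thousands.  Counts stay fractional here; rendering rounds them to whole
    doses (nearest, matching the published counts).
    """
    if not ddd_mg > 0:
        raise RecordValidationError(f"ddd_mg must be > 0, got {ddd_mg}")
    if not population > 0:
        raise RecordValidationError(f"population must be > 0, got {population}")
    per_year: dict[int, DDDYear] = {}
    raw: dict[int, float] = {}
    drug = None
    for rec in series:
        drug = rec.drug
        if rec.mg_volume is None:
            continue
        raw[rec.year] = rec.mg_volume / ddd_mg
    if ref_year not in raw:
        raise MissingYearError(f"reference year {ref_year} has no volume")
    ref_ddd = raw[ref_year]
    for y, n in sorted(raw.items()):
        pct = 100.0 * n / ref_ddd if (y >= ref_year and ref_ddd > 0) else None
        per_year[y] = DDDYear(n_ddd=n, ddd_per_1000_per_year=n / (population / 1000.0),
                              pct_of_reference=pct)
    return DDDSeries(drug=drug, ddd_mg=ddd_mg, population=population,
                     ref_year=ref_year, per_year=MappingProxyType(per_year))


@dataclass(frozen=True)
class AccessYear:
    real_patients: int
    potential_additional: int | None   # None before savings exist for the year
    total_potential: int


@dataclass(frozen=True)
class EraGrowth:
    absolute: int
    relative: float  # percent of the era-start count


@dataclass(frozen=True)
class AccessReport:
    """Real and reinvestment-counterfactual patient counts for one drug/sector."""

    drug: str
    sector: Sector
    per_year: Mapping[int, AccessYear]
    era_growth: EraGrowth | None = None

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.per_year))


def potential_additional_patients(savings: SavingsSeries,
                                  per_patient_cost: CostSeries,
                                  real_patients: Mapping[int, int] |
                                  Sequence[AnnualDrugRecord],
                                  ) -> AccessReport:
    """Additional patients fundable by reinvesting each year's savings.

    ``additional_t = floor(savings_t / cost_t)`` - a partial patient-year
    cannot be funded - with negative savings clamped to zero (reduced access
    is never reported as a negative patient count).  Real counts pass through;
    totals add the two.
    """
    if isinstance(real_patients, Mapping):
        patients = dict(real_patients)
    else:
        patients = patients_by_year(real_patients)
    per_year: dict[int, AccessYear] = {}
    for y, n_real in sorted(patients.items()):
        if y in savings.per_year:
            if y not in per_patient_cost.per_year:
                raise MissingYearError(
                    f"{savings.drug} {y}: savings present but no per-patient cost")
            cost = per_patient_cost.per_year[y].cost
            if not cost > 0:
                raise MissingYearError(f"{savings.drug} {y}: nonpositive cost")
            additional = max(0, math.floor(savings.per_year[y].savings / cost))
        else:
            additional = None
        per_year[y] = AccessYear(real_patients=n_real,
                                 potential_additional=additional,
                                 total_potential=n_real + (additional or 0))
    return AccessReport(drug=savings.drug, sector=savings.sector,
                        per_year=MappingProxyType(per_year))


def era_growth(series: Mapping[int, int] | Sequence[AnnualDrugRecord],
               era: tuple[int, int]) -> EraGrowth:
    """Patient growth over an era: absolute end-start difference and percent
    change relative to the start year."""
    patients = (dict(series) if isinstance(series, Mapping)
                else patients_by_year(series))
    start, end = era
    for y in era:
        if y not in patients:
            raise MissingYearError(f"era endpoint {y} has no patient count")
    absolute = patients[end] - patients[start]
    if patients[start] == 0:
        raise MissingYearError(f"era start {start} has zero patients; relative "
                               "growth undefined")
    return EraGrowth(absolute=absolute,
                     relative=100.0 * absolute / patients[start])


def market_share(product_level_spend: Mapping[tuple[str, int], float],
                 meta: DrugMeta) -> dict[int, tuple[float, float]]:
    """Reference vs biosimilar market share by reimbursement value.

    Returns ``{year: (reference_pct, biosimilar_pct)}``; shares sum to 100 for
    every year with any spend.
    """
    flags = {p.name: p.is_biosimilar for p in meta.products}
    by_year: dict[int, list[float]] = {}
    for (product, year), spend in product_level_spend.items():
        if product not in flags:
            raise RecordValidationError(
                f"product {product!r} has no biosimilar flag in {meta.drug} metadata")
        ref_bio = by_year.setdefault(year, [0.0, 0.0])
        ref_bio[1 if flags[product] else 0] += spend
    shares: dict[int, tuple[float, float]] = {}
    for year, (ref, bio) in sorted(by_year.items()):
        total = ref + bio
        if total <= 0:
            raise RecordValidationError(f"year {year}: nonpositive total spend")
        shares[year] = (100.0 * ref / total, 100.0 * bio / total)
    return shares


def eligible_coverage(total_potential: float, ia_population: float,
                      eligibility_rate: float) -> float:
    """Share of the biologic-eligible population coverable by the
    reinvestment counterfactual, in percent.

    ``ia_population`` is the national inflammatory-arthritis population and
    ``eligibility_rate`` the assumed fraction of it eligible for biologics.
    """
    if not 0 < eligibility_rate <= 1:
        raise RecordValidationError(
            f"eligibility_rate must be in (0, 1], got {eligibility_rate}")
    if not ia_population > 0 or not total_potential > 0:
        raise RecordValidationError("populations must be positive")
    return 100.0 * total_potential / (ia_population * eligibility_rate)
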