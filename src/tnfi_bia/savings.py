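"""Counterfactual savings models for biosimilar market entry.

Two models are implemented, both anchored to a reference year whose price or
expenditure defines the counterfactual:

* **Estimated savings** - what the payer *would* have spent had the unit price
  stayed at the reference-year level, minus actual spend.  With
  ``ACTUAL_VOLUME`` the counterfactual uses the observed yearly volume
  (potential_t = p_ref * V_t); with ``FIXED_VOLUME`` utilisation is frozen at
  the reference-year level (potential_t = p_ref * V_ref = E_ref).
* **Real-life savings** - the plain expenditure difference E_ref - E_t: what
  the payer actually stopped spending, regardless of how volume moved.

Savings can be negative (an expenditure increase); they are reported
algebraically and only rendered as "increase in expenses" at report time.
Years at or before the reference year never contribute.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

from .errors import AggregationError, MissingYearError
from .records import AnnualDrugRecord, DrugMeta, Sector

__all__ = [
    "SavingsModel",
    "VolumeMode",
    "ReferenceRule",
    "ReferencePrice",
    "YearSavings",
    "SavingsSeries",
    "AggregateSavings",
    "reference_unit_price",
    "select_reference_year",
    "estimated_savings",
    "real_life_savings",
    "aggregate",
]


class SavingsModel(str, enum.Enum):
    ESTIMATED = "ESTIMATED"
    ESTIMATED_FIXED_VOLUME = "ESTIMATED_FIXED_VOLUME"
    REAL_LIFE = "REAL_LIFE"


class VolumeMode(str, enum.Enum):
    ACTUAL_VOLUME = "ACTUAL_VOLUME"
    FIXED_VOLUME = "FIXED_VOLUME"


class ReferenceRule(str, enum.Enum):
    PRE_BIOSIMILAR = "PRE_BIOSIMILAR"      # year before first biosimilar coverage
    PEAK_EXPENDITURE = "PEAK_EXPENDITURE"  # year of maximum reimbursement value


@dataclass(frozen=True)
class ReferencePrice:
    """Reference-year unit price, EUR per mg, at full precision."""

    drug: str
    ref_year: int
    unit_price: float
    sector: Sector


@dataclass(frozen=True)
class YearSavings:
    potential: float
    actual: float
    savings: float


@dataclass(frozen=True)
class SavingsSeries:
    """Per-year counterfactual-minus-actual amounts for one drug and sector."""

    drug: str
    sector: Sector
    model: SavingsModel
    ref_year: int
    per_year: Mapping[int, YearSavings]
    total: float

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.per_year))


def _series_index(series: Sequence[AnnualDrugRecord]) -> dict[int, AnnualDrugRecord]:
    return {r.year: r for r in series}


def reference_unit_price(series: Sequence[AnnualDrugRecord],
                         ref_year: int) -> ReferencePrice:
    """Unit price (EUR/mg) of the reference year: spend / volume at full precision."""
    idx = _series_index(series)
    if ref_year not in idx:
        raise MissingYearError(f"reference year {ref_year} absent from series")
    rec = idx[ref_year]
    if not rec.mg_volume or rec.reimbursement_value is None:
        raise MissingYearError(
            f"{rec.drug} {ref_year}: reference year needs positive mg_volume and a "
            "reimbursement value")
    return ReferencePrice(drug=rec.drug, ref_year=ref_year,
                          unit_price=rec.reimbursement_value / rec.mg_volume,
                          sector=rec.sector)


def select_reference_year(series: Sequence[AnnualDrugRecord],
                          rule: ReferenceRule | str,
                          meta: DrugMeta | None = None) -> int:
    """Pick the counterfactual anchor year.

    ``PRE_BIOSIMILAR`` is the year preceding first biosimilar coverage (needs
    ``meta``); ``PEAK_EXPENDITURE`` is the year of maximum reimbursement value,
    earliest year winning ties.
    """
    if not series:
        raise MissingYearError("cannot select a reference year from an empty series")
    rule = ReferenceRule(rule)
    if rule is ReferenceRule.PRE_BIOSIMILAR:
        if meta is None:
            raise ValueError("PRE_BIOSIMILAR rule requires drug metadata")
        year = meta.first_biosimilar_year - 1
        if year not in {r.year for r in series}:
            raise MissingYearError(
                f"{meta.drug}: pre-biosimilar year {year} absent from series")
        return year
    candidates = [r for r in series if r.reimbursement_value is not None]
    if not candidates:
        raise MissingYearError("no reimbursement values present in series")
    best = max(candidates, key=lambda r: (r.reimbursement_value, -r.year))
    return best.year


def estimated_savings(series: Sequence[AnnualDrugRecord],
                      ref_price: ReferencePrice,
                      mode: VolumeMode | str = VolumeMode.ACTUAL_VOLUME,
                      ) -> SavingsSeries:
    """Estimated (price-counterfactual) savings for every year after the reference.

    ``ACTUAL_VOLUME``: potential_t = p_ref * V_t.
    ``FIXED_VOLUME``:  potential_t = p_ref * V_ref, i.e. the reference-year
    expenditure held constant.
    """
    mode = VolumeMode(mode)
    idx = _series_index(series)
    years = sorted(y for y in idx if y > ref_price.ref_year)
    if mode is VolumeMode.FIXED_VOLUME:
        ref_rec = idx.get(ref_price.ref_year)
        if ref_rec is None or ref_rec.mg_volume is None:
            raise MissingYearError(
                f"FIXED_VOLUME needs the reference year {ref_price.ref_year} volume")
        fixed_potential = ref_price.unit_price * ref_rec.mg_volume
    per_year: dict[int, YearSavings] = {}
    for y in years:
        rec = idx[y]
        if rec.reimbursement_value is None:
            raise MissingYearError(f"{rec.drug} {y}: reimbursement value missing")
        if mode is VolumeMode.ACTUAL_VOLUME:
            if rec.mg_volume is None:
                raise MissingYearError(f"{rec.drug} {y}: mg_volume missing")
            potential = ref_price.unit_price * rec.mg_volume
        else:
            potential = fixed_potential
        per_year[y] = YearSavings(potential=potential,
                                  actual=rec.reimbursement_value,
                                  savings=potential - rec.reimbursement_value)
    model = (SavingsModel.ESTIMATED if mode is VolumeMode.ACTUAL_VOLUME
             else SavingsModel.ESTIMATED_FIXED_VOLUME)
    return SavingsSeries(drug=ref_price.drug, sector=ref_price.sector, model=model,
                         ref_year=ref_price.ref_year,
                         per_year=MappingProxyType(per_year),
                         total=sum(v.savings for v in per_year.values()))


def real_life_savings(series: Sequence[AnnualDrugRecord],
                      ref_year: int) -> SavingsSeries:
    """Expenditure-difference savings E_ref - E_t for every year after ref_year."""
    idx = _series_index(series)
    if ref_year not in idx or idx[ref_year].reimbursement_value is None:
        raise MissingYearError(f"reference year {ref_year} absent from series")
    ref_rec = idx[ref_year]
    e_ref = ref_rec.reimbursement_value
    per_year: dict[int, YearSavings] = {}
    for y in sorted(y for y in idx if y > ref_year):
        rec = idx[y]
        if rec.reimbursement_value is None:
            raise MissingYearError(f"{rec.drug} {y}: reimbursement value missing")
        per_year[y] = YearSavings(potential=e_ref, actual=rec.reimbursement_value,
                                  savings=e_ref - rec.reimbursement_value)
    return SavingsSeries(drug=ref_rec.drug, sector=ref_rec.sector,
                         model=SavingsModel.REAL_LIFE, ref_year=ref_year,
                         per_year=MappingProxyType(per_year),
                         total=sum(v.savings for v in per_year.values()))


@dataclass(frozen=True)
class AggregateSavings:
    sector: Sector
    per_year: Mapping[int, float]
    grand_total: float
    per_drug: Mapping[str, float]


def aggregate(serieses: Iterable[SavingsSeries]) -> AggregateSavings:
    """Sum savings series across drugs within one sector.

    Absent years contribute zero; negative components enter algebraically.
    Mixing sectors is an error because ALL already contains RMD.
    """
    serieses = list(serieses)
    if not serieses:
        raise AggregationError("cannot aggregate an empty collection of savings series")
    sectors = {s.sector for s in serieses}
    if len(sectors) > 1:
        raise AggregationError(
            f"cannot aggregate across sectors {sorted(s.value for s in sectors)}; "
            "aggregate within one sector")
    per_year: dict[int, float] = {}
    per_drug: dict[str, float] = {}
    for s in serieses:
        for y, v in s.per_year.items():
            per_year[y] = per_year.get(y, 0.0) + v.savings
        per_drug[s.drug] = per_drug.get(s.drug, 0.0) + s.total
    per_year = dict(sorted(per_year.items()))
    return AggregateSavings(sector=sectors.pop(),
                            per_year=MappingProxyType(per_year),
                            grand_total=sum(per_year.values()),
                            per_drug=MappingProxyType(per_drug))
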