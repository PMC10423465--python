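"""Domain model and I/O for annual payer reimbursement records.

The unit of observation is one drug x calendar year x indication sector:
milligrams reimbursed, payer expenditure (EUR, full precision) and the number
of patients treated.  Sectors are ``ALL`` (rheumatology + gastroenterology +
dermatology combined) and ``RMD`` (rheumatic musculoskeletal diseases only).

The package ships a fixture with the complete Polish National Health Fund
series for infliximab (INF), etanercept (ETN) and adalimumab (ADA) over
2013-2021, loadable with :func:`load_poland`.  A handful of cells in the
published source tables are internally inconsistent; the fixture stores the
corrected value used for computation and keeps the published value in
:attr:`RecordSet.flags` (see ``data/poland_meta.yaml``).

Missing years (e.g. etanercept volumes before 2015) are *absent*, never
zero-filled; downstream operations raise :class:`~tnfi_bia.errors.MissingYearError`
when they genuinely need an absent value.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .errors import DrugLookupError, RecordValidationError, SchemaError

__all__ = [
    "Sector",
    "AnnualDrugRecord",
    "Product",
    "DrugMeta",
    "CurrencyRate",
    "FlaggedCell",
    "RecordSet",
    "convert_currency",
    "read_recordset",
    "write_recordset",
    "read_meta",
    "subset",
    "patients_by_year",
    "load_poland",
    "load_poland_reported_costs",
]

CSV_COLUMNS = ("drug", "year", "sector", "mg_volume", "reimbursement_value",
               "patients", "currency")


class Sector(str, enum.Enum):
    """Indication sector of an annual record."""

    ALL = "ALL"   # rheumatology + gastroenterology + dermatology combined
    RMD = "RMD"   # rheumatic musculoskeletal diseases only


class CurrencyMode(str, enum.Enum):
    EUR = "EUR"
    PLN = "PLN"


@dataclass(frozen=True)
class AnnualDrugRecord:
    """One drug x year x sector payer observation.

    ``mg_volume`` and ``patients`` may be ``None`` when the payer source does
    not report them for that year; ``reimbursement_value`` is EUR at full
    precision (reports render it in millions).
    """

    drug: str
    year: int
    sector: Sector
    mg_volume: float | None = None
    reimbursement_value: float | None = None
    patients: int | None = None

    def __post_init__(self) -> None:
        if self.mg_volume is not None and self.mg_volume < 0:
            raise RecordValidationError(
                f"{self.drug} {self.year} {self.sector.value}: mg_volume must be >= 0, "
                f"got {self.mg_volume}")
        if self.reimbursement_value is not None and self.reimbursement_value < 0:
            raise RecordValidationError(
                f"{self.drug} {self.year} {self.sector.value}: reimbursement_value must "
                f"be >= 0, got {self.reimbursement_value}")
        if self.patients is not None and self.patients < 0:
            raise RecordValidationError(
                f"{self.drug} {self.year} {self.sector.value}: patients must be >= 0, "
                f"got {self.patients}")


@dataclass(frozen=True)
class Product:
    """A medicinal product containing the active substance."""

    name: str
    is_biosimilar: bool
    first_year: int
    last_year: int


@dataclass(frozen=True)
class DrugMeta:
    """Per-drug constants: biosimilar entry year, WHO DDD, product grid."""

    drug: str
    first_biosimilar_year: int
    ddd_mg: float
    products: tuple[Product, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.ddd_mg <= 0:
            raise RecordValidationError(f"{self.drug}: ddd_mg must be > 0, got {self.ddd_mg}")
        if self.products and not any(not p.is_biosimilar for p in self.products):
            raise RecordValidationError(
                f"{self.drug}: product list must contain at least one reference "
                "(non-biosimilar) product")


@dataclass(frozen=True)
class CurrencyRate:
    """PLN per one EUR."""

    pln_per_eur: float

    def __post_init__(self) -> None:
        if not self.pln_per_eur > 0:
            raise RecordValidationError(
                f"pln_per_eur must be positive, got {self.pln_per_eur}")


@dataclass(frozen=True)
class FlaggedCell:
    """A fixture cell whose published value is inconsistent; the record set
    stores the corrected value, this object keeps the published one."""

    drug: str
    year: int
    sector: Sector
    field: str
    printed: float
    note: str = ""


def convert_currency(amount_pln: float, rate: CurrencyRate) -> float:
    """Convert a PLN amount to EUR by dividing by the PLN-per-EUR rate."""
    if not isinstance(rate, CurrencyRate):
        rate = CurrencyRate(float(rate))
    return amount_pln / rate.pln_per_eur


@dataclass
class RecordSet:
    """A validated collection of annual records plus study-level constants."""

    records: list[AnnualDrugRecord]
    meta: dict[str, DrugMeta]
    population: float
    currency: CurrencyRate = field(default_factory=lambda: CurrencyRate(1.0))
    flags: tuple[FlaggedCell, ...] = ()
    version: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -------------------------------------------------------------

    @property
    def drugs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.drug)
        return tuple(seen)

    def is_flagged(self, drug: str, year: int, sector: Sector, field_name: str) -> bool:
        return any(f.drug == drug and f.year == year and f.sector == sector
                   and f.field == field_name for f in self.flags)

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        if not self.population > 0:
            raise RecordValidationError(f"population must be > 0, got {self.population}")
        seen: set[tuple[str, int, Sector]] = set()
        for r in self.records:
            key = (r.drug, r.year, r.sector)
            if key in seen:
                raise RecordValidationError(
                    f"duplicate record for {r.drug} {r.year} {r.sector.value}")
            seen.add(key)
            if r.drug not in self.meta:
                raise RecordValidationError(f"record drug {r.drug!r} has no metadata")
        # year span contiguous per drug-sector
        by_ds: dict[tuple[str, Sector], list[int]] = {}
        for r in self.records:
            by_ds.setdefault((r.drug, r.sector), []).append(r.year)
        for (drug, sector), yrs in by_ds.items():
            yrs = sorted(yrs)
            if yrs != list(range(yrs[0], yrs[-1] + 1)):
                raise RecordValidationError(
                    f"{drug} {sector.value}: year span {yrs} is not contiguous")
        # sector consistency: RMD never exceeds ALL unless the cell is flagged
        index = {(r.drug, r.year, r.sector): r for r in self.records}
        for r in self.records:
            if r.sector is not Sector.RMD:
                continue
            allr = index.get((r.drug, r.year, Sector.ALL))
            if allr is None:
                continue
            for field_name in ("mg_volume", "reimbursement_value", "patients"):
                rmd_v = getattr(r, field_name)
                all_v = getattr(allr, field_name)
                if rmd_v is None or all_v is None:
                    continue
                if rmd_v > all_v and not self.is_flagged(r.drug, r.year, Sector.RMD,
                                                         field_name):
                    raise RecordValidationError(
                        f"{r.drug} {r.year}: RMD {field_name} {rmd_v} exceeds "
                        f"ALL value {all_v}")
        # meta sanity against the data span
        for drug, m in self.meta.items():
            yrs = [r.year for r in self.records if r.drug == drug]
            if yrs and not (min(yrs) <= m.first_biosimilar_year <= max(yrs) + 1):
                raise RecordValidationError(
                    f"{drug}: first_biosimilar_year {m.first_biosimilar_year} outside "
                    f"data span {min(yrs)}-{max(yrs)}")


def subset(recordset: RecordSet, drug: str, sector: Sector | str) -> list[AnnualDrugRecord]:
    """Year-ordered series of records for one drug and sector.

    Missing years are simply absent from the returned list.
    """
    if drug not in recordset.meta:
        raise DrugLookupError(f"unknown drug {drug!r}; known: {sorted(recordset.meta)}")
    sector = Sector(sector)
    return sorted((r for r in recordset.records
                   if r.drug == drug and r.sector is sector),
                  key=lambda r: r.year)


def patients_by_year(series: Sequence[AnnualDrugRecord]) -> dict[int, int]:
    """Map year -> patient count, skipping years without a count."""
    return {r.year: r.patients for r in series if r.patients is not None}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_float(raw: str, row_idx: int, col: str) -> float | None:
    raw = raw.strip()
    if raw in ("", "NA", "N/A"):
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise SchemaError(f"row {row_idx}: cannot parse {col}={raw!r}") from exc


def read_meta(path: str | Path) -> tuple[dict[str, DrugMeta], float, CurrencyRate,
                                         tuple[FlaggedCell, ...], str]:
    """Read drug metadata, population, currency and flagged cells from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("drugs", "population", "currency"):
        if key not in doc:
            raise SchemaError(f"metadata file is missing the {key!r} section")
    meta = {}
    for drug, d in doc["drugs"].items():
        products = tuple(Product(p["name"], bool(p["biosimilar"]),
                                 int(p["first_year"]), int(p["last_year"]))
                         for p in d.get("products", []))
        meta[drug] = DrugMeta(drug=drug,
                              first_biosimilar_year=int(d["first_biosimilar_year"]),
                              ddd_mg=float(d["ddd_mg"]),
                              products=products,
                              name=str(d.get("name", "")))
    flags = tuple(FlaggedCell(f["drug"], int(f["year"]), Sector(f["sector"]),
                              f["field"], float(f["printed"]), f.get("note", ""))
                  for f in doc.get("flagged_cells", []))
    currency = CurrencyRate(float(doc["currency"]["pln_per_eur"]))
    return meta, float(doc["population"]), currency, flags, str(doc.get("fixture_version", ""))


def read_recordset(path: str | Path, meta_path: str | Path,
                   currency_mode: CurrencyMode | str = CurrencyMode.EUR) -> RecordSet:
    """Read a long-format record CSV plus its metadata YAML.

    With ``currency_mode="PLN"`` monetary inputs are divided by the
    PLN-per-EUR rate from the metadata; with ``"EUR"`` they are taken as is.
    """
    currency_mode = CurrencyMode(currency_mode)
    meta, population, currency, flags, version = read_meta(meta_path)
    records: list[AnnualDrugRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s) {missing} in {path}")
        for i, row in enumerate(reader, start=2):
            value = _parse_float(row["reimbursement_value"], i, "reimbursement_value")
            row_currency = (row.get("currency") or "EUR").strip() or "EUR"
            if value is not None and (currency_mode is CurrencyMode.PLN
                                      or row_currency == "PLN"):
                value = convert_currency(value, currency)
            patients_f = _parse_float(row["patients"], i, "patients")
            try:
                rec = AnnualDrugRecord(
                    drug=row["drug"].strip(),
                    year=int(row["year"]),
                    sector=Sector(row["sector"].strip()),
                    mg_volume=_parse_float(row["mg_volume"], i, "mg_volume"),
                    reimbursement_value=value,
                    patients=None if patients_f is None else int(patients_f),
                )
            except RecordValidationError as exc:
                raise RecordValidationError(f"row {i}: {exc}") from exc
            except ValueError as exc:
                raise SchemaError(f"row {i}: {exc}") from exc
            records.append(rec)
    return RecordSet(records=records, meta=meta, population=population,
                     currency=currency, flags=flags, version=version)


def _fmt_money(v: float | None) -> str:
    if v is None:
        return ""
    # cent precision, no trailing zeros for integral amounts
    return f"{v:.2f}".rstrip("0").rstrip(".") if not float(v).is_integer() else str(int(v))


def write_recordset(recordset: RecordSet, path: str | Path) -> None:
    """Write records as the same long-format CSV dialect read_recordset accepts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in recordset.records:
            w.writerow([
                r.drug, r.year, r.sector.value,
                "" if r.mg_volume is None else (
                    int(r.mg_volume) if float(r.mg_volume).is_integer() else r.mg_volume),
                _fmt_money(r.reimbursement_value),
                "" if r.patients is None else r.patients,
                "EUR",
            ])


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("tnfi_bia").joinpath("data", name)


def load_poland() -> RecordSet:
    """The packaged Polish NHF 2013-2021 TNF-inhibitor record set."""
    with resources.as_file(_data_path("poland_tnfi_2013_2021.csv")) as csv_path, \
            resources.as_file(_data_path("poland_meta.yaml")) as meta_path:
        return read_recordset(csv_path, meta_path, CurrencyMode.EUR)


def load_poland_reported_costs() -> dict[str, dict[str, dict[int, float]]]:
    """Published annual treatment costs per drug, from the payer's independent
    cost source: ``{drug: {"per_mg": {year: EUR/mg}, "per_patient": {year: EUR}}}``.

    These are *not* recomputable as spend/patients for every cell (the payer
    published them from a different data set); they are the second arm of the
    two-method sensitivity check and the cost basis of the published
    reinvestment counterfactual.
    """
    out: dict[str, dict[str, dict[int, float]]] = {}
    with resources.as_file(_data_path("poland_reported_costs.csv")) as p:
        with open(p, newline="") as fh:
            for row in csv.DictReader(fh):
                d = out.setdefault(row["drug"], {"per_mg": {}, "per_patient": {}})
                d["per_mg"][int(row["year"])] = float(row["cost_per_mg"])
                d["per_patient"][int(row["year"])] = float(row["cost_per_patient"])
    return out
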