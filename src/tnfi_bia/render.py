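"""Rendering of the analysis bundle into publication-style tables and tidy files.

Display tables follow the published layout: one column per year, drug blocks
as rows, "Reference" marking the anchor year and "N/A" marking years outside
a drug's series.  Large counts use a thin-space thousands separator
("255 657" style); monetary values are millions of EUR to 3 decimals.
Machine-readable CSV/JSON outputs are unformatted.  Nothing written contains
timestamps, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
import pandas as pd

from .access import AccessReport
from .costs import CostSeries, round_half_away
from .errors import BIAError
from .pipeline import AnalysisBundle
from .records import Sector

__all__ = ["render_tables", "write_outputs", "fmt_thin", "fmt_millions"]

THIN = " "
NA = "N/A"


def fmt_thin(n: float | int) -> str:
    """Integer with thin-space thousands separator: 255657 -> '255 657'."""
    return f"{int(n):,}".replace(",", THIN)


def fmt_millions(eur: float) -> str:
    """EUR amount rendered in millions to 3 decimals (published precision)."""
    return f"{round_half_away(eur / 1e6, 3):.3f}"


def _year_columns(bundle: AnalysisBundle) -> list[int]:
    return sorted({r.year for r in bundle.recordset.records})


def _fmt_mg(v: float | None) -> str:
    return NA if v is None else fmt_thin(round(v))


def _savings_table(bundle: AnalysisBundle, scenario: str, sector: str,
                   with_volume: bool) -> pd.DataFrame:
    """Estimated-savings layout (volume/actual/potential/savings rows) or
    real-life layout (reimbursement/savings rows), plus the totals row."""
    result = bundle.scenario(scenario, sector)
    years = _year_columns(bundle)
    records = {(r.drug, r.year): r
               for r in bundle.recordset.records if r.sector is Sector(sector)}
    rows: list[list[str]] = []
    index: list[str] = []
    for drug, s in result.series.items():
        index.append(f"[{drug}]")
        rows.append([""] * (len(years) + 1))
        e_ref = records[(drug, s.ref_year)].reimbursement_value
        if with_volume:
            index.append("Milligrams of the drug")
            rows.append([_fmt_mg(records[(drug, y)].mg_volume
                                 if (drug, y) in records else None)
                         for y in years] + [""])
        index.append("Reimbursement value" if not with_volume else "Actual refund value")
        rows.append([fmt_millions(records[(drug, y)].reimbursement_value)
                     if (drug, y) in records
                     and records[(drug, y)].reimbursement_value is not None else NA
                     for y in years] + [""])
        if with_volume:
            index.append("Potential refund value")
            pot_row = []
            for y in years:
                if y == s.ref_year:
                    pot_row.append(fmt_millions(e_ref))
                elif y in s.per_year:
                    pot_row.append(fmt_millions(s.per_year[y].potential))
                else:
                    pot_row.append(NA)
            rows.append(pot_row + [""])
        index.append("Savings versus reference value" if not with_volume
                     else "Estimated savings value")
        sav_row = []
        for y in years:
            if y == s.ref_year:
                sav_row.append("Reference")
            elif y in s.per_year:
                sav_row.append(fmt_millions(s.per_year[y].savings))
            else:
                sav_row.append(NA)
        rows.append(sav_row + [fmt_millions(s.total)])
    index.append("Total savings")
    agg = result.aggregate
    rows.append([fmt_millions(agg.per_year[y]) if y in agg.per_year else NA
                 for y in years] + [fmt_millions(agg.grand_total)])
    return pd.DataFrame(rows, index=index,
                        columns=[str(y) for y in years] + ["Total savings"])


def _costs_table(bundle: AnalysisBundle) -> pd.DataFrame:
    years = _year_columns(bundle)
    rows, index = [], []
    for drug, entry in bundle.costs.items():
        index.append(f"[{drug}]")
        rows.append([""] * len(years))
        for p in bundle.recordset.meta[drug].products:
            index.append(p.name)
            rows.append(["Yes" if p.first_year <= y <= p.last_year else "No"
                         for y in years])
        for key, label, ndig in (("per_mg", "Cost for 1 mg (EUR)", 2),
                                 ("per_patient", "Annual cost per pt (EUR)", 0)):
            cs: CostSeries = entry[key]
            index.append(label)
            cost_row = []
            for y in years:
                if y not in cs.per_year:
                    cost_row.append(NA)
                elif ndig:
                    cost_row.append(f"{round_half_away(cs.per_year[y].cost, ndig):.{ndig}f}")
                else:
                    cost_row.append(fmt_thin(round_half_away(cs.per_year[y].cost)))
            rows.append(cost_row)
            index.append("% of the reference cost")
            pct_row = []
            for y in years:
                pct = cs.per_year[y].pct_of_reference if y in cs.per_year else None
                if y == cs.ref_year:
                    pct_row.append("Reference")
                elif pct is None:
                    pct_row.append(NA)
                else:
                    pct_row.append(f"{round_half_away(pct):.0f}%")
            rows.append(pct_row)
    return pd.DataFrame(rows, index=index, columns=[str(y) for y in years])


def _ddd_table(bundle: AnalysisBundle) -> pd.DataFrame:
    years = _year_columns(bundle)
    rows, index = [], []
    records = {(r.drug, r.year): r
               for r in bundle.recordset.records if r.sector is Sector.ALL}
    for drug, ds in bundle.ddd.items():
        index.append(f"[{drug}]")
        rows.append([""] * len(years))
        index.append("Milligrams of the drug")
        rows.append([_fmt_mg(records[(drug, y)].mg_volume
                             if (drug, y) in records else None) for y in years])
        index.append("Number of DDD")
        rows.append([fmt_thin(round_half_away(ds.per_year[y].n_ddd))
                     if y in ds.per_year else NA for y in years])
        index.append("DDD per 1000 inhabitants per year")
        rows.append([f"{ds.per_year[y].ddd_per_1000_per_year:.2f}"
                     if y in ds.per_year else NA for y in years])
        index.append("% of the reference prescription")
        pct_row = []
        for y in years:
            if y == ds.ref_year:
                pct_row.append("Reference")
            elif y in ds.per_year and ds.per_year[y].pct_of_reference is not None:
                pct_row.append(f"{round_half_away(ds.per_year[y].pct_of_reference):.0f}%")
            else:
                pct_row.append(NA)
        rows.append(pct_row)
    return pd.DataFrame(rows, index=index, columns=[str(y) for y in years])


def _access_table(bundle: AnalysisBundle) -> pd.DataFrame:
    years = _year_columns(bundle)
    rows, index = [], []
    sector_label = {"ALL": "all", "RMD": "REUMA"}
    drugs = bundle.recordset.drugs
    for drug in drugs:
        index.append(f"[{drug}]")
        rows.append([""] * len(years))
        for sector in bundle.access:
            rep: AccessReport = bundle.access[sector][drug]
            lab = sector_label.get(sector, sector)
            index.append(f"Real number of pts ({lab})")
            rows.append([fmt_thin(rep.per_year[y].real_patients)
                         if y in rep.per_year else NA for y in years])
            index.append(f"Potential additional number of pts ({lab})")
            rows.append([fmt_thin(rep.per_year[y].potential_additional)
                         if y in rep.per_year
                         and rep.per_year[y].potential_additional is not None
                         else NA for y in years])
            index.append(f"Total potential number of pts ({lab})")
            rows.append([fmt_thin(rep.per_year[y].total_potential)
                         if y in rep.per_year else NA for y in years])
    return pd.DataFrame(rows, index=index, columns=[str(y) for y in years])


_TABLE_BUILDERS = {
    "table1_estimated_all": ("estimated", "ALL", True),
    "table2_estimated_rmd": ("estimated", "RMD", True),
    "table3_real_life_all": ("real_life", "ALL", False),
    "table4_real_life_rmd": ("real_life", "RMD", False),
}


def render_tables(bundle: AnalysisBundle) -> dict[str, pd.DataFrame]:
    """The seven publication-layout tables as DataFrames of display strings."""
    missing = [c for c in ("scenarios", "costs", "ddd", "access")
               if not getattr(bundle, c)]
    if missing:
        raise BIAError(f"bundle incomplete, missing components: {missing}")
    tables: dict[str, pd.DataFrame] = {}
    for name, (scenario, sector, with_volume) in _TABLE_BUILDERS.items():
        if scenario in bundle.scenarios and sector in bundle.scenarios[scenario]:
            tables[name] = _savings_table(bundle, scenario, sector, with_volume)
    tables["table5_costs"] = _costs_table(bundle)
    tables["table6_ddd"] = _ddd_table(bundle)
    tables["table7_access"] = _access_table(bundle)
    return tables


def _to_markdown(df: pd.DataFrame, title: str) -> str:
    # hand-rolled pipe table; avoids an extra dependency for trivial output
    header = "| | " + " | ".join(df.columns) + " |"
    sep = "|" + "---|" * (len(df.columns) + 1)
    lines = [f"### {title}", "", header, sep]
    for idx, row in df.iterrows():
        lines.append("| " + str(idx) + " | " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _tidy_savings(bundle: AnalysisBundle) -> pd.DataFrame:
    rows = []
    for name, by_sector in bundle.scenarios.items():
        for sector, result in by_sector.items():
            for drug, s in result.series.items():
                for y, v in s.per_year.items():
                    rows.append(dict(scenario=name, model=s.model.value,
                                     sector=sector, drug=drug, ref_year=s.ref_year,
                                     year=y, potential_eur=v.potential,
                                     actual_eur=v.actual, savings_eur=v.savings))
    return pd.DataFrame(rows)


def _summary(bundle: AnalysisBundle) -> dict:
    out: dict = {"provenance": dict(bundle.provenance), "scenarios": {}}
    for name, by_sector in bundle.scenarios.items():
        out["scenarios"][name] = {
            sector: {
                "grand_total_eur_millions": round(res.aggregate.grand_total / 1e6, 3),
                "per_drug_eur_millions": {d: round(t / 1e6, 3)
                                          for d, t in res.aggregate.per_drug.items()},
            } for sector, res in by_sector.items()}
    out["overall_cost_reduction_pct"] = {
        drug: {"per_mg": round(entry["per_mg"].overall_reduction, 1),
               "per_patient": round(entry["per_patient"].overall_reduction, 1),
               "sensitivity_pass": entry["sensitivity"].passed}
        for drug, entry in bundle.costs.items()}
    return out


def write_outputs(bundle: AnalysisBundle, output_dir: str | Path) -> list[Path]:
    """Write display tables (Markdown + CSV), the tidy savings CSV and the JSON
    summary.  Returns the list of files written."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in render_tables(bundle).items():
        md = outdir / f"{name}.md"
        md.write_text(_to_markdown(df, name.replace("_", " ")))
        csv = outdir / f"{name}.csv"
        df.to_csv(csv, index_label="row")
        written += [md, csv]
    tidy = outdir / "savings_tidy.csv"
    _tidy_savings(bundle).to_csv(tidy, index=False)
    written.append(tidy)
    summary = outdir / "summary.json"
    summary.write_text(json.dumps(_summary(bundle), indent=2, sort_keys=True) + "\n")
    written.append(summary)
    return written
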