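# tnfi-bia

Budget-impact analysis of biosimilar TNF-inhibitor market entry, built as a
reusable, tested Python pipeline around the complete Polish National Health
Fund (NHF) reimbursement series for infliximab (INF), etanercept (ETN) and
adalimumab (ADA) over 2013–2021, which ships with the package.

## The problem

When biosimilars of a biologic enter a tender-based market, unit prices
collapse — but that does not say what the payer *gained*, nor whether patients
gained anything. This package separates the question into two counterfactuals
plus access metrics, for health-economics and pharmacoepidemiology analysts:

- **Estimated savings** — spend avoided relative to frozen pre-biosimilar
  prices: for each year *t* after a reference year *r*,

  `S_t = p_r · V_t − E_t`,  with `p_r = E_r / V_r`

  where `E_t` is reimbursement and `V_t` milligrams dispensed. An alternative
  scenario freezes utilisation too (`S_t = E_r − E_t` with `V_t ≡ V_r`).
- **Real-life savings** — what the payer actually stopped spending:
  `S_t = E_r − E_t`, with the reference year either the pre-biosimilar year or
  the expenditure peak. Negative values are expenditure growth and are kept
  algebraically.
- **Treatment cost** — `E_t / V_t` (per mg) and `E_t / N_t` (per patient),
  computed from independently published payer sources and cross-checked
  against each other (the two-method sensitivity analysis).
- **Exposure and access** — WHO defined daily doses (DDD) per 1000
  inhabitants per year, patient-count growth by market era, biosimilar market
  share, and the reinvestment counterfactual: `floor(S_t / cost_per_patient_t)`
  additional patients fundable if every euro of savings bought more therapy.

A synthetic-market generator with a closed-form savings oracle makes every
stage testable without any external data.

## Worked example

```python
from tnfi_bia import (load_poland, subset, reference_unit_price,
                      estimated_savings, real_life_savings, aggregate)

rs = load_poland()                       # packaged Polish NHF 2013-2021 data
series = subset(rs, "ADA", "ALL")        # adalimumab, all indications
rp = reference_unit_price(series, 2018)  # 9.4044 EUR/mg pre-biosimilar price
est = estimated_savings(series, rp)
for y, v in est.per_year.items():
    print(f"{y}: potential {v.potential/1e6:7.3f}M  actual {v.actual/1e6:7.3f}M"
          f"  saved {v.savings/1e6:7.3f}M")
print(f"total: {est.total/1e6:.3f}M EUR")
```

prints

```
2019: potential  37.647M  actual  11.457M  saved  26.190M
2020: potential  37.618M  actual   5.951M  saved  31.667M
2021: potential  45.317M  actual   4.953M  saved  40.364M
total: 98.222M EUR
```

i.e. had adalimumab stayed at its 2018 tender price, the observed volumes
would have cost €37.6–45.3M a year; biosimilar competition cut the actual
bills to €5–11.5M, avoiding €98.2M over three years. Aggregating the
*real-life* model over all three drugs (INF anchored at its 2018 expenditure
peak) gives the payer's realised saving:

```python
agg = aggregate([real_life_savings(subset(rs, d, "ALL"), r)
                 for d, r in {"INF": 2018, "ETN": 2015, "ADA": 2018}.items()])
print(f"{agg.grand_total/1e6:.3f}M EUR")   # -> 133.447M EUR
```

The `bia` command exposes the same operations from a shell
(`bia run`, `bia savings`, `bia costs`, `bia access`, `bia synth`); `bia run`
writes the seven report tables (Markdown + CSV), a tidy savings CSV and a
JSON summary.

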