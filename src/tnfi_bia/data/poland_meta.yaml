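# Metadata for the packaged Poland 2013-2021 TNF-inhibitor payer fixture.
# Monetary values in the companion CSV are EUR at full precision (tables print
# millions to 3 decimals, i.e. thousand-EUR precision).
population: 37990000          # average inhabitants over the analysed period
currency:
  pln_per_eur: 4.4124         # average EUR exchange rate, last 5 years of the period
drugs:
  INF:
    name: infliximab
    first_biosimilar_year: 2014
    ddd_mg: 3.75              # WHO defined daily dose
    products:
      - {name: Remicade, biosimilar: false, first_year: 2013, last_year: 2021}
      - {name: Remsima, biosimilar: true, first_year: 2014, last_year: 2021}
      - {name: Inflectra, biosimilar: true, first_year: 2014, last_year: 2021}
      - {name: Flixabi, biosimilar: true, first_year: 2018, last_year: 2021}
      - {name: Zessly, biosimilar: true, first_year: 2019, last_year: 2021}
  ETN:
    name: etanercept
    first_biosimilar_year: 2016
    ddd_mg: 7.0
    products:
      - {name: Enbrel, biosimilar: false, first_year: 2013, last_year: 2021}
      - {name: Benepali, biosimilar: true, first_year: 2016, last_year: 2021}
      - {name: Erelzi, biosimilar: true, first_year: 2017, last_year: 2021}
  ADA:
    name: adalimumab
    first_biosimilar_year: 2019
    ddd_mg: 2.9
    products:
      - {name: Humira, biosimilar: false, first_year: 2013, last_year: 2021}
      - {name: Imraldi, biosimilar: true, first_year: 2019, last_year: 2021}
      - {name: Amgevita, biosimilar: true, first_year: 2019, last_year: 2021}
      - {name: Hyrimoz, biosimilar: true, first_year: 2019, last_year: 2021}
      - {name: Idacio, biosimilar: true, first_year: 2020, last_year: 2021}

# Cells where the published tables are internally inconsistent. The CSV stores
# the corrected value used for computation; the published value is kept here.
# The ETN RMD milligram column disagrees with the same table's monetary columns
# (the implied unit price would drift from 4.29 to 5.57 EUR/mg instead of being
# the constant 2015 reference price); the potential/actual/savings columns are
# mutually consistent, so mg is corrected: 2015 from the all-indications value,
# 2016-2021 back-derived as potential / (spend_2015 / mg_2015).
flagged_cells:
  - {drug: INF, year: 2013, sector: RMD, field: reimbursement_value,
     printed: 789000,
     note: "real-life table prints 0.789; estimated-savings table prints 0.790 (used, as the reference price quoted downstream originates there)"}
  - {drug: ETN, year: 2015, sector: RMD, field: mg_volume, printed: 4481792,
     note: "published value exceeds the all-indications volume 4 296 845; corrected to the all-indications value, which reproduces the published potential column"}
  - {drug: ETN, year: 2016, sector: RMD, field: mg_volume, printed: 4377043,
     note: "back-derived from published potential 18.760M at the 2015 reference price"}
  - {drug: ETN, year: 2017, sector: RMD, field: mg_volume, printed: 4286443,
     note: "back-derived from published potential 18.800M"}
  - {drug: ETN, year: 2018, sector: RMD, field: mg_volume, printed: 4367818,
     note: "back-derived from published potential 20.649M; corrected value marginally exceeds the all-indications volume (rounding of the published potential)"}
  - {drug: ETN, year: 2019, sector: RMD, field: mg_volume, printed: 4377019,
     note: "back-derived from published potential 24.400M; marginally exceeds the all-indications volume (rounding)"}
  - {drug: ETN, year: 2020, sector: RMD, field: mg_volume, printed: 4807625,
     note: "back-derived from published potential 24.298M"}
  - {drug: ETN, year: 2021, sector: RMD, field: mg_volume, printed: 6535877,
     note: "back-derived from published potential 28.072M"}

notes:
  - "INF all-indications 2014 estimated savings are published as '2189', a display typo for 2.189 million EUR; savings are computed, never stored, so no cell correction is needed."
  - "Published per-patient annual treatment costs (reported_costs CSV) come from a different payer source than spend/patients and are NOT exactly spend/patients for ETN 2017-2021; both series are kept so the two-method sensitivity check is meaningful."
fixture_version: "poland-tnfi-2013-2021 v1"
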