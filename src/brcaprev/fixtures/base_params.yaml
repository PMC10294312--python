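# Base-case model inputs: natural-history transitions, surgery effect
# measures, health-state utilities and aggregated 2022-EUR costs for the
# BRCA-1/2 breast/ovarian prevention model. Schema documented in
# docs/methods.md.

onset:
  # decade bands: [age_start, age_end, annual p in first band year, in last]
  breast:
    - [20, 29, 0.0002, 0.0020]
    - [30, 39, 0.0106, 0.0185]
    - [40, 49, 0.0326, 0.0688]
    - [50, 59, 0.0705, 0.0723]
    - [60, 69, 0.0740, 0.0757]
    - [70, 79, 0.0666, 0.0638]
    - [80, 89, 0.0609, 0.0583]
    - [90, 99, 0.0557, 0.0531]
  ovarian:
    - [20, 29, 0.000015, 0.00002]
    - [30, 39, 0.0019, 0.0025]
    - [40, 49, 0.0119, 0.0178]
    - [50, 59, 0.0242, 0.0242]
    - [60, 69, 0.0348, 0.0433]
    - [70, 79, 0.0465, 0.0553]
    - [80, 89, 0.0497, 0.0441]
    - [90, 99, 0.0385, 0.0328]

progression:
  # annual probability stage k -> k+1 for undetected cancer (3 entries)
  breast: [0.205, 0.25, 0.60]     # pT1->pT2, pT2->pT3, pT3->pT4
  ovarian: [0.70, 0.93, 0.99]     # FIGO I->II, II->III, III->IV

detection:
  # annual probability of symptomatic detection per undetected stage
  breast: [0.23, 0.55, 0.60, 1.00]   # pT1..pT4
  ovarian: [0.15, 0.15, 0.72, 0.95]  # FIGO I..IV

five_year_survival:
  # disease-specific 5-year survival per diagnosed stage
  breast: [0.993, 0.876, 0.595, 0.262]
  ovarian: [0.871, 0.704, 0.350, 0.155]

# annual_survival:               # optional 4 x 10 per-year override, e.g.
#   breast: [[...10 values...], ...]

effects:
  rr_breast_pbm: 0.070
  rr_breast_pbso: 0.500
  rr_breast_both: 0.039
  rr_ovarian_pbso: 0.038

utilities:
  well: 0.92
  detected:
    breast: [0.68, 0.61, 0.56, 0.42]    # pT1..pT4/metastatic
    ovarian: [0.81, 0.72, 0.63, 0.55]   # FIGO I..IV/metastatic
  remission: 0.83
  surgery:
    pbm: 0.88
    pbso: 0.95
    both: 0.84
  # undetected:                  # optional per cancer x stage override;
  #   defaults to the detected-stage values

costs:
  surveillance: 608.0
  surveillance_after_pbm_fraction: 0.5
  surgery:
    pbm: 9032.0
    pbso: 3099.0
    both: 12131.0
  initial:
    breast:            # early = pT1-pT3, late = metastatic pT4
      early: {none: 20092.0, pbm: 14333.0, pbso: 20092.0, both: 14333.0}
      late: {none: 30623.0, pbm: 24865.0, pbso: 30623.0, both: 24865.0}
    ovarian:           # early = FIGO I-II, late = advanced FIGO III-IV
      early: {none: 13666.0, pbm: 13666.0, pbso: 11280.0, both: 11280.0}
      late: {none: 35052.0, pbm: 35052.0, pbso: 32666.0, both: 32666.0}
  palliative:
    breast: 12103.0
    ovarian: 12103.0
  followup:
    breast:            # annual, per stage pT1..pT4, 10 years of follow-up
      none: [595.0, 652.0, 589.0, 686.0]
      pbm: [443.0, 500.0, 437.0, 534.0]
      pbso: [595.0, 652.0, 589.0, 686.0]
      both: [443.0, 500.0, 437.0, 534.0]
    ovarian:           # annual, [non-advanced, advanced], 5 years
      none: [1356.0, 2389.0]
      pbm: [1052.0, 2085.0]
      pbso: [1214.0, 2246.0]
      both: [910.0, 1942.0]
  followup_years:
    breast: 10
    ovarian: 5

analysis:
  discount_rate: 0.03
  wtp: 90000.0
  start_age: 30
  end_age: 100
  discount_origin_age: 0
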