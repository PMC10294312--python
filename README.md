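# brcaprev

Decision-analytic evaluation of breast and ovarian cancer prevention
strategies for women with *BRCA1/2* mutations, for health-economics and
medical-decision-making researchers.

Carriers face lifetime breast-cancer risks of 70–90% and substantially
elevated ovarian-cancer risk, starting around age 30. `brcaprev`
implements a deterministic annual-cycle Markov cohort model of the
two-cancer natural history (undetected stage-specific disease →
symptomatic detection → stage/year-specific survival in 10-year tunnel
states → survivor or cancer death, with competing background mortality)
and evaluates 16 prevention strategies built from intensified
surveillance (IS), prophylactic bilateral mastectomy (PBM) and
prophylactic bilateral salpingo-oophorectomy (PBSO) at ages 30–45.

For each strategy the package computes lifetime cancer incidence and
mortality, life-years (LY), quality-adjusted life-years (QALY) and
direct medical costs (2022 €, German health-care perspective, 3%
discounting), classifies strategies by strong and extended dominance,
and builds the efficiency frontier with stepwise incremental
cost-effectiveness ratios

    ICER = (C_j - C_i) / (E_j - E_i)

between adjacent non-dominated strategies, on both the LY and the QALY
scale. It also provides hierarchical calibration of the natural-history
parameters to incidence and stage-distribution targets, one-way
deterministic sensitivity analysis (utilities, effect measures, costs,
discount rate), and synthetic generators for every external input so
the full pipeline runs offline.

## Worked example

```bash
brcaprev run --strategies 1,8,11,12 --out results/demo
```

writes per-strategy outcomes, the incremental table versus standard
care, and both frontiers. `results/demo/outcomes.csv` (abridged):

```
 strategy_id                  label    ly  qaly  cost_disc
           1     Standard care (IS) 48.37 41.30   11859.26
           8       PBM + PBSO at 30 54.24 49.44    8905.23
          11 PBM at 30 + PBSO at 35 53.93 49.19    8843.51
          12 PBM at 30 + PBSO at 40 53.61 48.87    8804.58
```

Standard care is the most expensive and least effective of the four:
every surgical strategy prevents enough cancer treatment to more than
repay its surgery and halved surveillance costs. `frontier_ly.csv`
shows the discounted efficiency frontier:

```
 strategy_id     classification    effect        cost  stepwise_ratio
           1 strongly-dominated       NaN         NaN            NaN
          12        on-frontier 11.000389 8804.579280            NaN
          11        on-frontier 11.049812 8843.507758     787.649315
           8        on-frontier 11.103112 8905.229209    1158.008427
```

PBM at 30 + PBSO at 40 is the least costly non-dominated (reference)
strategy; moving to PBSO at 35 costs 788 €/LY gained, and on to the
combined surgery at 30 another 1,158 €/LY — far below a 90,000 €/LY
willingness-to-pay threshold. The same library calls are available in
Python (`load_parameters`, `run_cohort`, `lifetime_outcomes`,
`efficiency_frontier`, `calibrate`, `run_dsa`).

The packaged mortality fixtures
(`fixtures/*_german_female_synthetic.csv`) are synthetic
reconstructions of a German female life table and breast+ovarian cancer
mortality curve; substitute your own two-column (age, probability) CSVs
via the config file for other settings.

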