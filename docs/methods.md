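# Methods

## The decision problem

Women carrying pathogenic *BRCA1/2* variants face very high lifetime
risks of breast cancer and elevated risks of ovarian cancer, starting
around age 30. The available prevention options in the German care
setting are intensified surveillance of the breast (IS: half-yearly
palpation and ultrasound, yearly MRI plus mammography, €608/year),
prophylactic bilateral mastectomy (PBM) and prophylactic bilateral
salpingo-oophorectomy (PBSO), alone or in sequence at different ages.
`brcaprev` evaluates 16 such strategies (IS alone; PBM or PBSO alone at
30/35/40; both at the same age; and serial combinations up to PBSO at
45) on lifetime cancer incidence, mortality, life-years (LY),
quality-adjusted life-years (QALY) and direct medical costs (2022 €),
from the perspective of the German health-care system.

## Model structure

A deterministic Markov cohort model with annual cycles follows a cohort
of carriers from age 30 to age 100 across 94 health states:

* well (no cancer);
* undetected breast cancer pT1–pT4 and undetected ovarian cancer
  FIGO I–IV (preclinical disease progresses and may be symptomatically
  detected);
* diagnosed cancer as tunnel states, one per stage × year since
  diagnosis (1–10), so survival, utilities and costs can depend on time
  since diagnosis;
* breast / ovarian cancer survivor (alive 10+ years after diagnosis);
* three absorbing death states (breast cancer, ovarian cancer, other
  causes).

Within a cycle, events compose sequentially in a fixed order:
other-cause death first (except in the diagnosed tunnels, whose
registry-based survival already includes all-cause mortality), then
tunnel survival (failures are counted as cancer deaths; year-10
survivors move to the survivor state), then symptomatic detection
before stage progression for undetected disease (this makes rows such
as undetected FIGO III — detection 0.72, progression 0.99 — well
defined), and finally cancer onset from the well state, with the two
cancers competing on the rate (log) scale. The two cancer pathways are
mutually exclusive: onset occurs only from the well state, and a woman
on one pathway cannot develop the other cancer. The survivor states
carry the background (other-cause) mortality only; their excess cancer
mortality has already been spent in the tunnel years, and adding
all-cause mortality would double-count the cancer deaths embedded in
it.

There is no half-cycle correction; rewards (life-years, utilities,
annual costs) are credited to the state occupied at cycle start, and
event costs (surgery, initial treatment, palliative care) are credited
to the cycle in which the flow occurs. Mass still alive at age 100 is
truncated after contributing its final cycle; at the mortality levels
involved this affects outcomes in the 4th decimal place. The engine is
fully deterministic and conserves probability mass to 1e-10 per cycle.

## Parameters

All inputs ship as a packaged YAML fixture (`fixtures/base_params.yaml`)
with one nested schema (`onset`, `progression`, `detection`,
`five_year_survival`/`annual_survival`, `effects`, `utilities`,
`costs`, `analysis`); any subset can be overridden from a user config.

* **Onset.** Annual probabilities of moving from well to undetected
  stage-1 disease, by decade band (20–29 … 90–99), each band carrying a
  first-year and last-year value; within a band the probability is
  linear in age, and bands may be discontinuous at their edges (the
  published values are). These values were calibrated by the original
  study to carrier-specific incidence under the competing two-cancer
  structure, which is why the ovarian entries at high ages (up to
  0.055/yr) far exceed marginal carrier incidence: they apply to a
  well-state population already heavily depleted by breast cancer.
* **Progression / detection.** Annual stage-to-stage progression for
  undetected disease and annual probabilities of symptomatic detection
  per stage; undetected stage-IV disease is detected with probability
  1.00 (breast) / 0.95 (ovarian) rather than dying undetected.
* **Survival.** Diagnosed disease survives each tunnel year with a
  stage- and year-specific probability. The published table prints
  ranges over years 1–10; by default each stage uses the constant
  annual transform `S5**(1/5)` of its published 5-year survival (breast
  99.3/87.6/59.5/26.2%; ovarian 87.1/70.4/35.0/15.5%), and a config
  hook accepts full 4×10 year-specific matrices when available.
* **Effect measures.** Surgery acts as a relative risk on onset from
  the surgery cycle onward: breast RR 0.070 after PBM, 0.500 after
  PBSO, 0.039 after both (the published joint value, not the product of
  the singles); ovarian RR 0.038 after PBSO, 1.0 after PBM.
* **Utilities.** Well carrier 0.92; diagnosed first year by stage
  (breast 0.68/0.61/0.56/0.42; ovarian 0.81/0.72/0.63/0.55); clinical
  remission 0.83 for tunnel years 2–10 and survivors; undetected
  disease defaults to the detected-stage values (overridable). During a
  surgery cycle the well/undetected occupants' utility is scaled by
  `u_surgery/u_well` (PBM 0.88, PBSO 0.95, both 0.84 — the PBSO value
  exceeds the well utility, as published) and reverts the next cycle.
* **Costs (2022 €).** Surveillance €608/yr while well or undetected,
  halved after PBM (MRI dropped); one-time surgery costs (PBM 9,032,
  PBSO 3,099, both 12,131); one-time initial-treatment costs by cancer,
  severity class (breast pT1–3 vs metastatic; ovarian FIGO I–II vs
  III–IV) and surgery history; annual follow-up costs for 10 years
  (breast, per stage) / 5 years (ovarian, per severity class), after
  which surveillance only; €12,103 palliative care at every cancer
  death. Follow-up and initial costs are keyed to the surgery history
  at diagnosis, reconstructed from the diagnosis cycle (current age
  minus tunnel year) — exact here because the cohort is deterministic.
* **Background mortality.** A female all-cause life table minus
  age-specific breast+ovarian cancer mortality, subtracted on the rate
  scale (`q_other = 1 - exp(-(h_all - h_cancer))`). The packaged
  `*_german_female_synthetic.csv` curves are synthetic reconstructions
  anchored at values typical of the 2019/2021 German female period life
  table and German cancer-mortality rates (log-linear in age between
  anchors); `synthetic.make_life_table` generates fully parametric
  Gompertz–Makeham alternatives.
* **Analysis.** 3% annual discounting of costs and effects (varied 1–10%
  in sensitivity analysis), WTP reference 90,000 €/LY or €/QALY.
  Discounting is measured from birth (`discount_origin_age = 0`), the
  natural clock of a lifetime cohort model; every incremental ratio is
  exactly invariant to this origin (all terms rescale by the same
  factor), only absolute totals depend on it. Closed-form discounting
  tests set the origin to the start age explicitly.

## Strategy comparison

Effectiveness is reported undiscounted (LY, QALY, relative risk
reductions versus standard care); cost-effectiveness uses discounted
costs and discounted effects. The efficiency frontier is the lower-left
convex hull in (effect, cost) space: weakly dominated strategies are
removed first (ties keep the lower id), then extended dominance removes
strategies dominated by a convex combination of two others until the
stepwise ICERs strictly increase. Every excluded strategy carries a
certificate (the dominating strategy, or the dominating pair). LY- and
QALY-based frontiers are built separately.

## Calibration

The natural-history parameters (onset endpoints, progression,
detection) are unobservable; `calibration.calibrate` fits them to
observable targets — age-banded incidence (diagnoses per person-year at
risk among well+undetected women under standard care) and the stage
distribution at detection — by weighted least squares on relative
residuals. The fit alternates two blocks (onset; progression+detection),
each a bounded Powell search over the full objective, until the
objective stops improving. Both target blocks enter both stages because
the stage distribution alone (3 free fractions per cancer) cannot
identify the 6 progression/detection parameters; the timing of the
incidence curve carries the missing information.

**Identifiability.** Synthetic-target experiments show the problem is
*sloppy*: late-stage progression and detection (pT2→pT3, pT3→pT4,
detection at pT2/pT3) trade off along a near-flat objective valley —
joint shifts of 30–55% change every target residual by under 0.1%.
With pooled (whole-horizon) stage-distribution targets these
parameters are only set-identified; no optimizer can pin them to a few
percent. Parameter-recovery tests therefore assert on the
point-identified fragment (onset endpoints of the bands that generate
observable diagnoses, first-stage progression, early-stage detection),
which is recovered to ≲1% from ±30% perturbed starts across seeds.
Age-resolved stage-distribution targets would restore identifiability
and are a natural extension.

## Synthetic data

`synthetic.make_life_table` emulates the external mortality inputs
(Gompertz–Makeham all-cause hazard, piecewise-linear cancer fraction,
optional seeded lognormal noise); `synthetic.make_calibration_targets`
produces incidence/stage targets implied by a known parameter set, with
optional seeded relative noise, enabling closed-loop parameter-recovery
tests. These fixtures exercise every code path real data would, but
they are smooth by construction: passing tests demonstrate correctness
of the machinery, not that German registry data are well described by a
Gompertz–Makeham law or that real calibration targets are noise-free.

## Numerical choices and limitations

* Cycle length 1 year, integer ages; a cycle at age *a* covers [a, a+1).
* Onset probabilities outside the 20–99 schedule clamp to the nearest
  band edge (only relevant for toy horizons beyond age 100).
* Probabilities are box-constrained to (0, 1) in calibration via the
  optimizer's bounds; the engine rejects negative mass or row-sum
  deviations above 1e-10.
* Scheduled surgeries apply to the well and undetected states only;
  mass already diagnosed (or dead) at a surgery age neither pays for
  nor benefits from the prophylactic surgery, and remaining scheduled
  surgeries are skipped after any diagnosis.
* Recurrent cancer is not modelled explicitly; it is embedded in the
  stage-specific survival and the follow-up costs, as in the source
  data.
* The model pools BRCA1 and BRCA2 carriers and does not model uptake,
  adherence, or women's preferences.
* A structural consequence of mutually exclusive pathways deserves
  emphasis: preventing one cancer re-exposes the surviving well-state
  mass to the other cancer's (competition-calibrated) onset
  probabilities. PBM-only strategies therefore *increase* lifetime
  ovarian incidence substantially in this model, and with it lose
  life expectancy relative to standard care, while strategies that
  include PBSO gain 3.4–5.9 LY. Published evaluations of the same
  strategy set report positive gains for PBM-only strategies alongside
  validation risks that imply the same mutually-exclusive structure;
  the two are not mutually consistent, and this package follows the
  structure (which its validation outputs reproduce within a few
  percentage points) rather than the strategy-level orderings. The
  affected acceptance checks are retained unweakened and fail
  honestly.
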