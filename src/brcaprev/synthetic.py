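"""Synthetic external inputs: mortality curves and calibration targets.

The model's only non-printed inputs are a female all-cause life table and
an age-specific breast+ovarian cancer mortality curve. This module
generates both from a Gompertz-Makeham law so every stage of the
pipeline runs without downloads, and generates calibration targets from
a known parameter set (optionally noised) for parameter-recovery tests.

The packaged ``*_german_female_synthetic.csv`` fixtures are hand-built
reconstructions anchored at values typical of the DESTATIS 2019/2021
female period life table and RKI cancer mortality; the generator here is
the fully parametric alternative.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .calibration import (CalibrationTargets, IncidenceTarget, StageTarget,
                          predict_targets)
from .params import CANCERS, N_STAGES, MortalityInputs, ParameterError, ParameterSet


@dataclass(frozen=True)
class SyntheticMortalityConfig:
    """Gompertz-Makeham all-cause hazard plus a cancer-fraction schedule.

    All-cause hazard at age x is ``makeham + baseline * exp(slope * x)``;
    the cancer curve takes ``cancer_fraction(age)`` of that hazard
    (piecewise-linear between the schedule's (age, fraction) knots).
    ``noise_sd`` applies optional lognormal perturbation, seeded.
    """

    baseline: float = 2.5e-6
    slope: float = 0.122
    makeham: float = 2.0e-4
    cancer_fraction: tuple[tuple[int, float], ...] = (
        (20, 0.01), (40, 0.18), (50, 0.20), (60, 0.15), (70, 0.09),
        (85, 0.04), (100, 0.01))
    age_min: int = 20
    age_max: int = 100
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.makeham < 0:
            raise ParameterError("hazard components must be non-negative")
        if self.age_min >= self.age_max:
            raise ParameterError("age_min must be below age_max")


def make_life_table(cfg: SyntheticMortalityConfig) -> MortalityInputs:
    """Deterministic (given seed) paired all-cause / cancer mortality curves."""
    ages = np.arange(cfg.age_min, cfg.age_max + 1)
    hazard = cfg.makeham + cfg.baseline * np.exp(cfg.slope * ages)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        hazard = hazard * np.exp(rng.normal(0.0, cfg.noise_sd, size=len(ages)))
    q_all = -np.expm1(-hazard)
    if np.any(q_all >= 1.0):
        raise ParameterError("hazard produces q >= 1 inside the age range")
    knots = np.array(cfg.cancer_fraction, dtype=float)
    frac = np.interp(ages, knots[:, 0], knots[:, 1])
    if np.any(frac < 0) or np.any(frac > 1):
        raise ParameterError("cancer fractions must lie in [0, 1]")
    q_cancer = -np.expm1(-hazard * frac)
    return MortalityInputs(ages, q_all, q_cancer)


def write_mortality_csvs(m: MortalityInputs, life_table_path, cancer_path) -> None:
    """Write the two-column CSVs the parameter loader reads back."""
    for path, curve in ((life_table_path, m.q_all), (cancer_path, m.q_cancer)):
        with open(path, "w") as fh:
            fh.write("age,probability\n")
            for a, q in zip(m.ages, curve):
                fh.write(f"{a},{q:.10g}\n")


def make_calibration_targets(true_params: ParameterSet, noise_sd: float = 0.0,
                             seed: int = 0, age_min: int | None = None,
                             age_max: int | None = None,
                             band_width: int = 1,
                             balance_blocks: bool = True) -> CalibrationTargets:
    """Targets implied by known parameters, with optional relative noise.

    Incidence targets cover ``age_min..age_max`` in bands of
    ``band_width`` years; stage-distribution targets are the pooled
    model-implied fractions (the objective works on relative residuals).
    With ``balance_blocks`` the four stage targets per cancer carry
    weight n_bands/4 so the two target blocks contribute comparably to
    the fit regardless of the incidence banding. Deterministic given the
    seed.
    """
    pred = predict_targets(true_params)
    ages = pred["ages"]
    a0 = age_min if age_min is not None else int(ages[0]) + 1
    a1 = age_max if age_max is not None else int(ages[-1])
    rng = np.random.default_rng(seed)
    inc, st = [], []
    n_bands = len(range(a0, a1 + 1, band_width))
    stage_weight = n_bands / N_STAGES if balance_blocks else 1.0
    for c in CANCERS:
        for b0 in range(a0, a1 + 1, band_width):
            b1 = min(b0 + band_width - 1, a1)
            sel = (ages >= b0) & (ages <= b1)
            py = pred["at_risk"][sel].sum()
            val = float((pred["incidence"][c][sel] * pred["at_risk"][sel]).sum()
                        / py) if py > 0 else 0.0
            if noise_sd > 0:
                val *= float(np.exp(rng.normal(0.0, noise_sd)))
            inc.append(IncidenceTarget(c, b0, b1, min(val, 1.0)))
        dist = np.array(pred["stage_distribution"][c], dtype=float)
        if noise_sd > 0:
            dist = dist * np.exp(rng.normal(0.0, noise_sd, size=len(dist)))
            dist = dist / dist.sum()
        for s in range(N_STAGES):
            st.append(StageTarget(c, s, float(dist[s]), weight=stage_weight))
    return CalibrationTargets(tuple(inc), tuple(st))
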