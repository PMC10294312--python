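"""Hierarchical calibration of the natural-history parameters.

The unobservable natural-history inputs (age-specific onset, stage
progression, symptomatic detection) are fitted to observable targets:
age-specific cancer incidence (diagnoses per person-year at risk) and
the stage distribution at detection. Fitting alternates between two
stages of a block-coordinate descent:

* stage A moves the onset band endpoints,
* stage B moves progression and detection probabilities,

each stage minimizing the full weighted sum of squared relative errors
with a deterministic derivative-free local search (bounded Powell).
Stage distribution alone cannot identify progression and detection (six
parameters against three free fractions); the timing information in the
age-resolved incidence curve completes the identification, so both
target blocks enter every stage's objective.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .engine import run_cohort
from .params import (CANCERS, N_STAGES, AgeIncidenceSchedule, ParameterSet,
                     StageTransitionTable, with_updates)
from .strategies import get_strategy


@dataclass(frozen=True)
class IncidenceTarget:
    cancer: str
    age_start: int
    age_end: int
    value: float
    weight: float = 1.0


@dataclass(frozen=True)
class StageTarget:
    cancer: str
    stage: int  # 0-based
    value: float
    weight: float = 1.0


@dataclass(frozen=True)
class CalibrationTargets:
    """Incidence-by-age-band and stage-distribution targets."""

    incidence: tuple[IncidenceTarget, ...]
    stage_distribution: tuple[StageTarget, ...]

    def __post_init__(self) -> None:
        for t in self.incidence:
            if not 0.0 <= t.value <= 1.0:
                raise ValueError(f"incidence target {t} outside [0, 1]")
        for c in CANCERS:
            vals = [t.value for t in self.stage_distribution if t.cancer == c]
            if vals and abs(sum(vals) - 1.0) > 1e-6:
                raise ValueError(f"{c} stage fractions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cancer": t.cancer, "kind": "incidence", "key": f"{t.age_start}-{t.age_end}",
                 "value": t.value, "weight": t.weight} for t in self.incidence]
        rows += [{"cancer": t.cancer, "kind": "stage", "key": str(t.stage + 1),
                  "value": t.value, "weight": t.weight} for t in self.stage_distribution]
        return pd.DataFrame(rows)


def targets_from_frame(df: pd.DataFrame) -> CalibrationTargets:
    """Read targets from the CSV schema written by :meth:`to_frame`."""
    inc, st = [], []
    for _, r in df.iterrows():
        w = float(r.get("weight", 1.0))
        if r["kind"] == "incidence":
            a0, a1 = (int(x) for x in str(r["key"]).split("-"))
            inc.append(IncidenceTarget(r["cancer"], a0, a1, float(r["value"]), w))
        elif r["kind"] == "stage":
            st.append(StageTarget(r["cancer"], int(r["key"]) - 1, float(r["value"]), w))
        else:
            raise ValueError(f"unknown target kind {r['kind']!r}")
    return CalibrationTargets(tuple(inc), tuple(st))


# ---------------------------------------------------------------------------
# model-implied targets


def predict_targets(params: ParameterSet, config=None) -> dict:
    """Model-implied incidence by age and stage distribution at detection.

    The cohort engine runs under standard care; annual incidence at age a
    is new diagnoses during cycle a divided by the well+undetected mass at
    the cycle start; the stage distribution pools diagnoses over the
    whole horizon.
    """
    from .engine import WELL, und_index

    trace = run_cohort(get_strategy(1), params, config)
    cfg = config or params.analysis
    ages = np.arange(cfg.start_age, cfg.end_age)
    out: dict = {"ages": ages, "incidence": {}, "stage_distribution": {},
                 "at_risk": None}
    idx = [WELL] + [und_index(c, s) for c in CANCERS for s in range(N_STAGES)]
    at_risk = trace.occupancy[:len(ages), idx].sum(axis=1)
    out["at_risk"] = at_risk
    for c in CANCERS:
        diags = np.array([fl.diagnoses[c].sum() for fl in trace.flows])
        with np.errstate(invalid="ignore", divide="ignore"):
            out["incidence"][c] = np.where(at_risk > 0, diags / at_risk, 0.0)
        total_by_stage = np.sum([fl.diagnoses[c] for fl in trace.flows], axis=0)
        tot = total_by_stage.sum()
        out["stage_distribution"][c] = (
            total_by_stage / tot if tot > 0 else np.zeros(N_STAGES))
    return out


def _band_incidence(pred: dict, cancer: str, a0: int, a1: int) -> float:
    """Person-year-weighted incidence over an age band."""
    ages, at_risk = pred["ages"], pred["at_risk"]
    sel = (ages >= a0) & (ages <= a1)
    py = at_risk[sel].sum()
    if py <= 0:
        return 0.0
    return float((pred["incidence"][cancer][sel] * at_risk[sel]).sum() / py)


def objective_value(params: ParameterSet, targets: CalibrationTargets,
                    config=None) -> float:
    """Weighted SSE of relative residuals (fast path for the optimizer)."""
    pred = predict_targets(params, config)
    total = 0.0
    for t in targets.incidence:
        model = _band_incidence(pred, t.cancer, t.age_start, t.age_end)
        resid = (model - t.value) / t.value if t.value > 0 else model
        total += t.weight * resid ** 2
    for t in targets.stage_distribution:
        model = float(pred["stage_distribution"][t.cancer][t.stage])
        resid = (model - t.value) / t.value if t.value > 0 else model
        total += t.weight * resid ** 2
    return total


def objective(params: ParameterSet, targets: CalibrationTargets,
              config=None) -> tuple[float, pd.DataFrame]:
    """Weighted SSE of relative residuals, plus the per-target table."""
    pred = predict_targets(params, config)
    rows = []
    total = 0.0
    for t in targets.incidence:
        model = _band_incidence(pred, t.cancer, t.age_start, t.age_end)
        resid = (model - t.value) / t.value if t.value > 0 else model
        total += t.weight * resid ** 2
        rows.append({"cancer": t.cancer, "kind": "incidence",
                     "key": f"{t.age_start}-{t.age_end}", "target": t.value,
                     "model": model, "residual": resid})
    for t in targets.stage_distribution:
        model = float(pred["stage_distribution"][t.cancer][t.stage])
        resid = (model - t.value) / t.value if t.value > 0 else model
        total += t.weight * resid ** 2
        rows.append({"cancer": t.cancer, "kind": "stage", "key": str(t.stage + 1),
                     "target": t.value, "model": model, "residual": resid})
    return total, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# free-parameter bookkeeping


@dataclass(frozen=True)
class FreeParameters:
    """Which natural-history entries the optimizer may move.

    ``onset_bands`` maps cancer -> band start-ages whose two endpoints are
    free; ``progression``/``detection`` map cancer -> 0-based stage
    indices. The default frees everything except stage-IV detection
    (pinned near 1 so late disease cannot linger undetected).
    """

    onset_bands: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {c: () for c in CANCERS})
    progression: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {c: () for c in CANCERS})
    detection: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {c: () for c in CANCERS})

    def stage_a_size(self) -> int:
        return 2 * sum(len(v) for v in self.onset_bands.values())

    def stage_b_size(self) -> int:
        return (sum(len(v) for v in self.progression.values())
                + sum(len(v) for v in self.detection.values()))


def default_free_parameters() -> FreeParameters:
    return FreeParameters(
        onset_bands={c: tuple(range(20, 100, 10)) for c in CANCERS},
        progression={c: (0, 1, 2) for c in CANCERS},
        detection={c: (0, 1, 2) for c in CANCERS},
    )


def _get_vector(params: ParameterSet, free: FreeParameters, block: str) -> np.ndarray:
    vals: list[float] = []
    if block == "onset":
        for c in CANCERS:
            bands = {b[0]: b for b in params.onset[c].decade_bands}
            for a0 in free.onset_bands[c]:
                vals.extend(bands[a0][2:4])
    else:
        for c in CANCERS:
            vals.extend(params.stages[c].progression[i] for i in free.progression[c])
            vals.extend(params.stages[c].detection[i] for i in free.detection[c])
    return np.array(vals)


def _set_vector(params: ParameterSet, free: FreeParameters, block: str,
                vec: np.ndarray) -> ParameterSet:
    vec = iter(vec.tolist())
    if block == "onset":
        onset = {}
        for c in CANCERS:
            bands = []
            for b in params.onset[c].decade_bands:
                if b[0] in free.onset_bands[c]:
                    bands.append((b[0], b[1], next(vec), next(vec)))
                else:
                    bands.append(b)
            onset[c] = AgeIncidenceSchedule(c, tuple(bands))
        return with_updates(params, onset=onset)
    stages = {}
    for c in CANCERS:
        prog = list(params.stages[c].progression)
        det = list(params.stages[c].detection)
        for i in free.progression[c]:
            prog[i] = next(vec)
        for i in free.detection[c]:
            det[i] = next(vec)
        stages[c] = StageTransitionTable(c, tuple(prog), tuple(det))
    return with_updates(params, stages=stages)


# ---------------------------------------------------------------------------
# the fit


@dataclass
class CalibrationResult:
    params: ParameterSet
    objective: float
    residuals: pd.DataFrame
    iterations: int
    n_evaluations: int
    converged: bool
    terminated_by: str
    history: list[float]


def calibrate(targets: CalibrationTargets, init: ParameterSet,
              free: FreeParameters | None = None, config=None,
              max_rounds: int = 10, tol: float = 1e-10,
              stage_maxfev: int = 4000) -> CalibrationResult:
    """Alternate onset (stage A) and progression/detection (stage B) fits.

    Deterministic given the initial parameters; each stage is a bounded
    Powell search on the full weighted-SSE objective, and rounds stop
    once the objective improves by less than ``tol`` (absolute) or
    ``max_rounds`` is hit.
    """
    free = free or default_free_parameters()
    params = copy.deepcopy(init)
    n_eval = 0
    bounds_hi = 1.0 - 1e-9

    def run_stage(block: str, p: ParameterSet) -> tuple[ParameterSet, float]:
        nonlocal n_eval
        x0 = _get_vector(p, free, block)
        if x0.size == 0:
            n_eval += 1
            return p, objective_value(p, targets, config)

        def fun(x):
            nonlocal n_eval
            n_eval += 1
            return objective_value(_set_vector(p, free, block, np.asarray(x)),
                                   targets, config)

        res = optimize.minimize(
            fun, x0, method="Powell",
            bounds=[(1e-9, bounds_hi)] * x0.size,
            options={"maxfev": stage_maxfev, "xtol": 1e-7, "ftol": 1e-12})
        return _set_vector(p, free, block, np.asarray(res.x)), float(res.fun)

    best = objective_value(params, targets, config)
    history = [best]
    terminated_by = "max_rounds"
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        params, _ = run_stage("onset", params)
        params, val = run_stage("stages", params)
        val = min(val, best)  # accept-only-improving bookkeeping
        history.append(val)
        if best - val < tol:
            best = val
            terminated_by = "objective_tolerance"
            break
        best = val
    final_obj, residuals = objective(params, targets, config)
    return CalibrationResult(params, final_obj, residuals, rounds, n_eval,
                             terminated_by == "objective_tolerance",
                             terminated_by, history)
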