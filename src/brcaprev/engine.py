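"""Deterministic annual-cycle Markov cohort engine.

State space (94 states): well; undetected breast pT1-pT4 and ovarian
FIGO I-IV; diagnosed-cancer tunnel states (4 stages x 10 years since
diagnosis per cancer); two survivor states (alive 10+ years after
diagnosis); three absorbing death states (breast cancer, ovarian cancer,
other causes).

Within a cycle events compose sequentially in a fixed order:

1. other-cause death (rate-adjusted background mortality) hits every
   living state except the diagnosed tunnels, whose stage/year survival
   already embeds all-cause mortality (registry data);
2. diagnosed tunnels: survive the year or die of cancer; year-10
   survivors move to the survivor state;
3. undetected states: symptomatic detection first, then stage
   progression of the still-undetected remainder (so rows like FIGO III,
   where detection 0.72 and progression 0.99 would otherwise exceed 1,
   are well-defined);
4. well: onset of breast or ovarian cancer competes on the rate scale;
   once on one cancer pathway the other cancer cannot occur.

The engine is purely deterministic; reruns are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (CANCERS, N_STAGES, TUNNEL_YEARS, AnalysisConfig,
                     ParameterSet, severity_class)
from .strategies import AgeModifiers, StrategySpec, modifiers_at

# --- state indexing --------------------------------------------------------

WELL = 0
UND_BASE = {"breast": 1, "ovarian": 5}
DET_BASE = {"breast": 9, "ovarian": 49}
SURVIVOR = {"breast": 89, "ovarian": 90}
DEATH = {"breast": 91, "ovarian": 92, "other": 93}
N_STATES = 94
LIVING = np.array([i for i in range(N_STATES) if i not in DEATH.values()])

_MASS_TOL = 1e-10


def und_index(cancer: str, stage: int) -> int:
    """Index of an undetected-cancer state (stage 0-based)."""
    return UND_BASE[cancer] + stage


def det_index(cancer: str, stage: int, year: int) -> int:
    """Index of a diagnosed tunnel state (stage 0-based, year 1..10)."""
    return DET_BASE[cancer] + stage * TUNNEL_YEARS + (year - 1)


def state_labels() -> list[str]:
    labels = [""] * N_STATES
    labels[WELL] = "well"
    from .params import STAGES
    for c in CANCERS:
        for s in range(N_STAGES):
            labels[und_index(c, s)] = f"undetected {c} {STAGES[c][s]}"
            for y in range(1, TUNNEL_YEARS + 1):
                labels[det_index(c, s, y)] = f"detected {c} {STAGES[c][s]} year {y}"
        labels[SURVIVOR[c]] = f"{c} survivor"
        labels[DEATH[c]] = f"{c} cancer death"
    labels[DEATH["other"]] = "death other causes"
    return labels


class EngineError(RuntimeError):
    """Internal consistency failure (negative mass or mass leak)."""


@dataclass
class CycleFlows:
    """Inter-state flows recorded during one annual cycle."""

    onset: dict[str, float]
    diagnoses: dict[str, np.ndarray]  # per stage
    cancer_deaths: dict[str, float]
    other_deaths: float
    surgery_mass: float  # well + undetected mass receiving a surgery event


@dataclass
class CohortTrace:
    """State occupancy by age plus per-cycle flow counters for one strategy."""

    strategy: StrategySpec
    ages: np.ndarray          # start_age .. end_age inclusive
    occupancy: np.ndarray     # (len(ages), N_STATES)
    flows: list[CycleFlows]   # one per cycle (len(ages) - 1)

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    def row(self, age: int) -> np.ndarray:
        return self.occupancy[int(age) - self.start_age]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (age, state, occupancy) export."""
        labels = state_labels()
        recs = [(int(a), labels[s], self.occupancy[i, s])
                for i, a in enumerate(self.ages) for s in range(N_STATES)]
        return pd.DataFrame(recs, columns=["age", "state", "occupancy"])


def step(row: np.ndarray, age: int, mod: AgeModifiers, params: ParameterSet,
         _pre: tuple[float, float, float] | None = None) -> tuple[np.ndarray, CycleFlows]:
    """Advance one annual cycle; returns the next row and its flows.

    ``_pre`` optionally carries precomputed (q_other, raw breast onset,
    raw ovarian onset) for this age; ``run_cohort`` uses it to avoid
    re-deriving per-age hazards every cycle.
    """
    new = np.zeros(N_STATES)
    if _pre is None:
        q_other = params.q_other(age)
        p_onset = {c: params.onset_at(c, age) for c in CANCERS}
    else:
        q_other, pb, po = _pre
        p_onset = {"breast": pb, "ovarian": po}
    onset_flow = {c: 0.0 for c in CANCERS}
    diag = {c: np.zeros(N_STAGES) for c in CANCERS}
    cdeath = {c: 0.0 for c in CANCERS}
    odeath = 0.0

    # (1)+(4) well: other-cause death, then onset competing on the rate scale
    w = row[WELL]
    if w > 0:
        odeath += w * q_other
        alive = w * (1.0 - q_other)
        rr = {"breast": mod.rr_breast, "ovarian": mod.rr_ovarian}
        h = {c: -math.log1p(-min(p_onset[c] * rr[c], 1.0 - 1e-15))
             for c in CANCERS}
        h_tot = h["breast"] + h["ovarian"]
        if h_tot > 0:
            p_any = -math.expm1(-h_tot)
            for c in CANCERS:
                onset_flow[c] = alive * p_any * h[c] / h_tot
                new[und_index(c, 0)] += onset_flow[c]
            alive -= alive * p_any
        new[WELL] += alive

    # (1)+(3) undetected: other-cause death, detection first, then progression
    for c in CANCERS:
        det = params.stages[c].detection
        prog = params.stages[c].progression
        for s in range(N_STAGES):
            m = row[und_index(c, s)]
            if m <= 0:
                continue
            odeath += m * q_other
            alive = m * (1.0 - q_other)
            detected = alive * det[s]
            diag[c][s] += detected
            new[det_index(c, s, 1)] += detected
            rest = alive - detected
            if s < N_STAGES - 1:
                progressed = rest * prog[s]
                new[und_index(c, s + 1)] += progressed
                rest -= progressed
            new[und_index(c, s)] += rest

    # (2) diagnosed tunnels: stage/year survival (all-cause inclusive)
    for c in CANCERS:
        base = DET_BASE[c]
        tun = row[base:base + N_STAGES * TUNNEL_YEARS].reshape(N_STAGES, TUNNEL_YEARS)
        if tun.any():
            surv = params.survival[c].annual_survival
            alive = tun * surv
            cdeath[c] += float((tun - alive).sum())
            nxt = new[base:base + N_STAGES * TUNNEL_YEARS].reshape(N_STAGES, TUNNEL_YEARS)
            nxt[:, 1:] += alive[:, :-1]
            new[SURVIVOR[c]] += float(alive[:, -1].sum())

        m = row[SURVIVOR[c]]
        if m > 0:
            odeath += m * q_other
            new[SURVIVOR[c]] += m * (1.0 - q_other)

    new[DEATH["breast"]] = row[DEATH["breast"]] + cdeath["breast"]
    new[DEATH["ovarian"]] = row[DEATH["ovarian"]] + cdeath["ovarian"]
    new[DEATH["other"]] = row[DEATH["other"]] + odeath

    if new.min() < -_MASS_TOL:
        raise EngineError(f"negative occupancy at age {age}")
    if abs(new.sum() - row.sum()) > _MASS_TOL:
        raise EngineError(f"mass leak at age {age}: {new.sum() - row.sum():.3e}")

    surgery_mass = 0.0
    if mod.surgery_event is not None:
        surgery_mass = float(row[WELL]
                             + sum(row[und_index(c, s)]
                                   for c in CANCERS for s in range(N_STAGES)))
    return new, CycleFlows(onset_flow, diag, cdeath, odeath, surgery_mass)


def run_cohort(strategy: StrategySpec, params: ParameterSet,
               config: AnalysisConfig | None = None) -> CohortTrace:
    """Run the cohort (mass 1 in well at ``start_age``) to ``end_age``."""
    cfg = config or params.analysis
    ages = np.arange(cfg.start_age, cfg.end_age + 1)
    occ = np.zeros((len(ages), N_STATES))
    occ[0, WELL] = 1.0
    flows: list[CycleFlows] = []
    pre = [(params.q_other(int(a)), params.onset_at("breast", int(a)),
            params.onset_at("ovarian", int(a))) for a in ages[:-1]]
    for i, age in enumerate(ages[:-1]):
        mod = modifiers_at(strategy, int(age), params.effects, params.costs)
        occ[i + 1], fl = step(occ[i], int(age), mod, params, _pre=pre[i])
        flows.append(fl)
    return CohortTrace(strategy, ages, occ, flows)


@dataclass(frozen=True)
class OutcomeSummary:
    """Lifetime outcomes of one strategy run."""

    strategy_id: int
    label: str
    ly: float
    qaly: float
    ly_disc: float
    qaly_disc: float
    cost_undisc: float
    cost_disc: float
    cum_incidence: Mapping[str, float]      # lifetime diagnosed cases
    cum_onset: Mapping[str, float]          # lifetime developed (incl. undetected)
    cancer_mortality: Mapping[str, float]   # lifetime cancer deaths
    diagnoses_by_stage: Mapping[str, np.ndarray] = field(default=None, repr=False)  # type: ignore

    def as_dict(self) -> dict:
        d = {"strategy_id": self.strategy_id, "label": self.label,
             "ly": self.ly, "qaly": self.qaly, "ly_disc": self.ly_disc,
             "qaly_disc": self.qaly_disc, "cost_undisc": self.cost_undisc,
             "cost_disc": self.cost_disc}
        for c in CANCERS:
            d[f"incidence_{c}"] = self.cum_incidence[c]
            d[f"onset_{c}"] = self.cum_onset[c]
            d[f"mortality_{c}"] = self.cancer_mortality[c]
        return d


def _utility_vector(params: ParameterSet, mod: AgeModifiers) -> np.ndarray:
    """State utilities for one cycle (surgery cycles scale well/undetected)."""
    u = params.utilities
    vec = np.zeros(N_STATES)
    vec[WELL] = u.u_well
    for c in CANCERS:
        for s in range(N_STAGES):
            vec[und_index(c, s)] = u.u_undetected[c][s]
            vec[det_index(c, s, 1)] = u.u_detected[c][s]
            for y in range(2, TUNNEL_YEARS + 1):
                vec[det_index(c, s, y)] = u.u_remission
        vec[SURVIVOR[c]] = u.u_remission
    if mod.surgery_event is not None:
        scale = u.u_surgery[mod.surgery_event] / u.u_well
        vec[WELL] *= scale
        for c in CANCERS:
            for s in range(N_STAGES):
                vec[und_index(c, s)] *= scale
    return vec


def _cycle_cost(trace: CohortTrace, i: int, age: int, mod: AgeModifiers,
                params: ParameterSet) -> float:
    """Costs accrued during cycle ``age`` (state costs + event costs)."""
    row = trace.occupancy[i]
    fl = trace.flows[i]
    strat = trace.strategy
    costs = params.costs
    total = 0.0

    # surveillance while well or undetected (halved after PBM)
    at_risk = row[WELL] + sum(row[und_index(c, s)]
                              for c in CANCERS for s in range(N_STAGES))
    total += at_risk * mod.surveillance_cost

    # annual follow-up in the diagnosed tunnels, keyed by the surgery
    # history at diagnosis (diagnosis cycle = age - tunnel year)
    for c in CANCERS:
        fu_years = costs.followup_years[c]
        for s in range(N_STAGES):
            for y in range(1, TUNNEL_YEARS + 1):
                m = row[det_index(c, s, y)]
                if m <= 0:
                    continue
                hist = strat.history_at(age - y)
                if y <= fu_years:
                    total += m * costs.followup_cost(c, s, hist)
                else:
                    total += m * costs.surveillance(had_pbm=hist in ("pbm", "both"))
        # survivors pay surveillance only (diagnosed >= 11 cycles ago)
        m = row[SURVIVOR[c]]
        if m > 0:
            hist = strat.history_at(age - TUNNEL_YEARS - 1)
            total += m * costs.surveillance(had_pbm=hist in ("pbm", "both"))

    # event costs fired this cycle
    if mod.surgery_event is not None:
        total += fl.surgery_mass * costs.c_surgery[mod.surgery_event]
    for c in CANCERS:
        hist = strat.history_at(age)
        for s in range(N_STAGES):
            d = fl.diagnoses[c][s]
            if d > 0:
                total += d * costs.c_initial[c][severity_class(c, s)][hist]
        total += fl.cancer_deaths[c] * costs.c_palliative[c]
    return total


def lifetime_outcomes(trace: CohortTrace, params: ParameterSet,
                      config: AnalysisConfig | None = None) -> OutcomeSummary:
    """Aggregate a trace into LY, QALY and cost totals.

    Rewards are credited to the state occupied at cycle start; the cycle
    at age ``a`` is discounted by ``(1+r)^-(a - discount_origin_age)``.
    """
    cfg = config or params.analysis
    ly = qaly = ly_d = qaly_d = cost = cost_d = 0.0
    for i, age in enumerate(trace.ages[:-1]):
        age = int(age)
        mod = modifiers_at(trace.strategy, age, params.effects, params.costs)
        row = trace.occupancy[i]
        living = row.sum() - sum(row[DEATH[k]] for k in DEATH)
        u = _utility_vector(params, mod)
        q = float(row @ u)
        c = _cycle_cost(trace, i, age, mod, params)
        df = cfg.discount_factor(age)
        ly += living
        qaly += q
        cost += c
        ly_d += living * df
        qaly_d += q * df
        cost_d += c * df

    cum_inc = {c: float(sum(fl.diagnoses[c].sum() for fl in trace.flows))
               for c in CANCERS}
    cum_onset = {c: float(sum(fl.onset[c] for fl in trace.flows)) for c in CANCERS}
    mort = {c: float(sum(fl.cancer_deaths[c] for fl in trace.flows)) for c in CANCERS}
    stages = {c: np.sum([fl.diagnoses[c] for fl in trace.flows], axis=0)
              for c in CANCERS}
    return OutcomeSummary(trace.strategy.id, trace.strategy.label,
                          ly, qaly, ly_d, qaly_d, cost, cost_d,
                          cum_inc, cum_onset, mort, stages)


def cumulative_risk_by_age(trace: CohortTrace, cancer: str, age: int) -> float:
    """Cumulative probability of having developed the cancer before ``age``.

    Counts onset flows (well -> undetected stage 1), i.e. developing the
    cancer whether or not it has been detected yet.
    """
    if not trace.start_age <= age <= int(trace.ages[-1]):
        raise ValueError(f"age {age} outside the trace horizon")
    n = age - trace.start_age
    return float(sum(fl.onset[cancer] for fl in trace.flows[:n]))


def run_all(strategies, params: ParameterSet,
            config: AnalysisConfig | None = None) -> dict[int, OutcomeSummary]:
    """Run and summarize a list of strategies; keyed by strategy id."""
    out = {}
    for s in strategies:
        trace = run_cohort(s, params, config)
        out[s.id] = lifetime_outcomes(trace, params, config)
    return out
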