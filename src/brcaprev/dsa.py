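"""One-way deterministic sensitivity analysis.

Four parameter groups are varied one at a time, jointly within the
group: all utilities x0.8..x1.2 (clipped at 1), all surgery relative
risks x0.8..x1.2 (clipped at 1), all costs x0.5..x2.0, and the annual
discount rate 1%..10%. Every scenario re-runs all strategies, rebuilds
both frontiers and records rank orders and frontier-membership changes
against the base case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import OutcomeSummary, run_all
from .frontier import FrontierResult, efficiency_frontier, points_from_outcomes
from .params import (CANCERS, SURGERY_HISTORIES, AnalysisConfig, CostTable,
                     EffectMeasures, ParameterSet, UtilityTable, with_updates)
from .strategies import strategy_catalog

GROUPS = ("utilities", "effect_measures", "costs", "discount_rate")

_DEFAULT_GRID = {
    "utilities": (0.8, 1.0, 1.2),
    "effect_measures": (0.8, 1.0, 1.2),
    "costs": (0.5, 1.0, 2.0),
    "discount_rate": (0.01, 0.03, 0.05, 0.10),
}


@dataclass(frozen=True)
class DsaSpec:
    """Which group to vary and over which multipliers/values."""

    group: str
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown DSA group {self.group!r}")
        vals = self.values or _DEFAULT_GRID[self.group]
        object.__setattr__(self, "values", tuple(float(v) for v in vals))


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def scale_utilities(params: ParameterSet, k: float) -> ParameterSet:
    u = params.utilities
    new = UtilityTable(
        u_well=_clip01(u.u_well * k),
        u_detected={c: tuple(_clip01(v * k) for v in u.u_detected[c]) for c in CANCERS},
        u_remission=_clip01(u.u_remission * k),
        u_surgery={h: _clip01(v * k) for h, v in u.u_surgery.items()},
        u_undetected={c: tuple(_clip01(v * k) for v in u.u_undetected[c])
                      for c in CANCERS},
    )
    return with_updates(params, utilities=new)


def scale_effects(params: ParameterSet, k: float) -> ParameterSet:
    e = params.effects
    new = EffectMeasures(
        rr_breast_pbm=_clip01(e.rr_breast_pbm * k) or 1e-12,
        rr_breast_pbso=_clip01(e.rr_breast_pbso * k) or 1e-12,
        rr_breast_both=_clip01(e.rr_breast_both * k) or 1e-12,
        rr_ovarian_pbso=_clip01(e.rr_ovarian_pbso * k) or 1e-12,
    )
    return with_updates(params, effects=new)


def scale_costs(params: ParameterSet, k: float) -> ParameterSet:
    c = params.costs
    new = CostTable(
        c_surveillance=c.c_surveillance * k,
        surveillance_after_pbm_fraction=c.surveillance_after_pbm_fraction,
        c_surgery={h: v * k for h, v in c.c_surgery.items()},
        c_initial={cn: {sev: {h: c.c_initial[cn][sev][h] * k
                              for h in SURGERY_HISTORIES}
                        for sev in ("early", "late")} for cn in CANCERS},
        c_followup={cn: {h: tuple(v * k for v in c.c_followup[cn][h])
                         for h in SURGERY_HISTORIES} for cn in CANCERS},
        c_palliative={cn: c.c_palliative[cn] * k for cn in CANCERS},
        followup_years=c.followup_years,
    )
    return with_updates(params, costs=new)


def apply_scenario(params: ParameterSet, group: str, value: float) -> ParameterSet:
    if group == "utilities":
        return scale_utilities(params, value)
    if group == "effect_measures":
        return scale_effects(params, value)
    if group == "costs":
        return scale_costs(params, value)
    analysis = AnalysisConfig(
        discount_rate=value, wtp=params.analysis.wtp,
        start_age=params.analysis.start_age, end_age=params.analysis.end_age,
        discount_origin_age=params.analysis.discount_origin_age)
    return with_updates(params, analysis=analysis)


@dataclass
class DsaScenario:
    group: str
    value: float
    outcomes: Mapping[int, OutcomeSummary]
    frontier_ly: FrontierResult
    frontier_qaly: FrontierResult
    rank_by_ly: tuple[int, ...]
    rank_by_qaly: tuple[int, ...]
    rank_by_cost: tuple[int, ...]


@dataclass
class DsaResult:
    """All scenarios of one group plus base-case comparison flags."""

    spec: DsaSpec
    base: DsaScenario
    scenarios: list[DsaScenario]
    membership_changes: dict[float, dict[str, list[int]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sc in self.scenarios:
            for sid, o in sorted(sc.outcomes.items()):
                d = o.as_dict()
                d.update(scenario_group=sc.group, scenario_value=sc.value,
                         frontier_ly=sc.frontier_ly.classification[sid],
                         frontier_qaly=sc.frontier_qaly.classification[sid])
                rows.append(d)
        return pd.DataFrame(rows)


def _scenario(params: ParameterSet, group: str, value: float,
              strategies) -> DsaScenario:
    outcomes = run_all(strategies, params)
    f_ly = efficiency_frontier(points_from_outcomes(outcomes, "ly"), "ly")
    f_q = efficiency_frontier(points_from_outcomes(outcomes, "qaly"), "qaly")
    by_ly = tuple(sid for sid, _ in sorted(outcomes.items(),
                                           key=lambda kv: -kv[1].ly))
    by_q = tuple(sid for sid, _ in sorted(outcomes.items(),
                                          key=lambda kv: -kv[1].qaly))
    by_c = tuple(sid for sid, _ in sorted(outcomes.items(),
                                          key=lambda kv: kv[1].cost_disc))
    return DsaScenario(group, value, outcomes, f_ly, f_q, by_ly, by_q, by_c)


def run_dsa(spec: DsaSpec, base_params: ParameterSet,
            strategies: Sequence | None = None) -> DsaResult:
    """Run every scenario of one group and flag frontier changes."""
    strategies = list(strategies) if strategies else strategy_catalog()
    base_value = (base_params.analysis.discount_rate
                  if spec.group == "discount_rate" else 1.0)
    base = _scenario(base_params, spec.group, base_value, strategies)
    result = DsaResult(spec, base, [])
    for v in spec.values:
        sc = (base if np.isclose(v, base_value)
              else _scenario(apply_scenario(base_params, spec.group, v),
                             spec.group, v, strategies))
        result.scenarios.append(sc)
        changes = {}
        for scale, f_base, f_sc in (("ly", base.frontier_ly, sc.frontier_ly),
                                    ("qaly", base.frontier_qaly, sc.frontier_qaly)):
            moved = [sid for sid in f_base.classification
                     if (f_base.classification[sid] == "on-frontier")
                     != (f_sc.classification[sid] == "on-frontier")]
            changes[scale] = sorted(moved)
        result.membership_changes[v] = changes
    return result
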