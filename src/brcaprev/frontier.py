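"""Strategy comparison: dominance, efficiency frontier, stepwise ICER/ICUR.

The efficiency frontier is the lower-left convex hull of the
(effectiveness, cost) cloud: strategies that are strongly dominated
(another strategy costs no more and delivers at least as much, one
strictly) are removed first, then extended dominance removes strategies
dominated by a convex combination of two others, iteratively, until the
stepwise incremental ratios are strictly increasing along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .engine import OutcomeSummary
from .params import CANCERS


@dataclass(frozen=True)
class StrategyPoint:
    """One strategy as a point in (effect, cost) space."""

    strategy_id: int
    effect: float
    cost: float
    label: str = ""


@dataclass(frozen=True)
class FrontierStep:
    strategy_id: int
    effect: float
    cost: float
    icer: float | None  # None for the reference (first) strategy


@dataclass
class FrontierResult:
    """Frontier chain plus a certificate for every excluded strategy."""

    chain: list[FrontierStep]
    classification: dict[int, str]   # on-frontier | strongly-dominated | extended-dominated
    certificates: dict[int, tuple]   # dominating id, or dominating pair
    effect_scale: str = "effect"

    @property
    def reference_id(self) -> int:
        """Least costly non-dominated strategy."""
        return self.chain[0].strategy_id

    def to_frame(self) -> pd.DataFrame:
        rows = []
        by_id = {s.strategy_id: s for s in self.chain}
        for sid, cls in sorted(self.classification.items()):
            step = by_id.get(sid)
            rows.append({
                "strategy_id": sid,
                "classification": cls,
                "effect": step.effect if step else None,
                "cost": step.cost if step else None,
                "stepwise_ratio": step.icer if step else None,
                "certificate": "" if cls == "on-frontier" else str(self.certificates[sid]),
            })
        return pd.DataFrame(rows)


class UndefinedRatioError(ZeroDivisionError):
    """ICER between two points with equal effects is undefined."""


def icer(point_low: StrategyPoint, point_high: StrategyPoint) -> float:
    """Incremental cost per unit of effect between two strategies."""
    d_eff = point_high.effect - point_low.effect
    if d_eff <= 0:
        raise UndefinedRatioError(
            f"effect of {point_high.strategy_id} does not exceed "
            f"{point_low.strategy_id}")
    return (point_high.cost - point_low.cost) / d_eff


def efficiency_frontier(points: Sequence[StrategyPoint],
                        effect_scale: str = "effect") -> FrontierResult:
    """Classify strategies and build the stepwise frontier chain."""
    if not points:
        raise ValueError("need at least one strategy point")
    classification: dict[int, str] = {}
    certificates: dict[int, tuple] = {}

    # strong (weak-inequality) dominance; equal points keep the lowest id
    alive: list[StrategyPoint] = []
    for p in points:
        dominated_by = None
        for q in points:
            if q.strategy_id == p.strategy_id:
                continue
            if q.cost <= p.cost and q.effect >= p.effect:
                if q.cost < p.cost or q.effect > p.effect:
                    dominated_by = q
                    break
                if q.strategy_id < p.strategy_id:  # exact tie
                    dominated_by = q
                    break
        if dominated_by is None:
            alive.append(p)
        else:
            classification[p.strategy_id] = "strongly-dominated"
            certificates[p.strategy_id] = (dominated_by.strategy_id,)

    # extended dominance: drop interior points until slopes strictly increase
    chain = sorted(alive, key=lambda p: (p.effect, p.cost))
    while True:
        removed = False
        for k in range(1, len(chain) - 1):
            lo, mid, hi = chain[k - 1], chain[k], chain[k + 1]
            if icer(lo, mid) >= icer(lo, hi):
                classification[mid.strategy_id] = "extended-dominated"
                certificates[mid.strategy_id] = (lo.strategy_id, hi.strategy_id)
                del chain[k]
                removed = True
                break
        if not removed:
            break

    steps = []
    for k, p in enumerate(chain):
        classification[p.strategy_id] = "on-frontier"
        ratio = icer(chain[k - 1], p) if k else None
        steps.append(FrontierStep(p.strategy_id, p.effect, p.cost, ratio))
    return FrontierResult(steps, classification, certificates, effect_scale)


def points_from_outcomes(outcomes: Mapping[int, OutcomeSummary],
                         effect_scale: str = "ly") -> list[StrategyPoint]:
    """Discounted (effect, cost) points; ``effect_scale`` is 'ly' or 'qaly'."""
    attr = {"ly": "ly_disc", "qaly": "qaly_disc"}[effect_scale]
    return [StrategyPoint(o.strategy_id, getattr(o, attr), o.cost_disc, o.label)
            for o in outcomes.values()]


def compare_to_reference(outcomes: Mapping[int, OutcomeSummary],
                         reference_id: int = 1) -> pd.DataFrame:
    """Incremental effectiveness versus a reference strategy.

    Reports undiscounted LY/QALY gains and the relative risk reduction
    (RRR) of lifetime incidence and cancer-specific mortality per cancer.
    """
    if reference_id not in outcomes:
        raise KeyError(f"reference strategy {reference_id} not among outcomes")
    ref = outcomes[reference_id]
    rows = []
    for sid, o in sorted(outcomes.items()):
        row = {"strategy_id": sid, "label": o.label,
               "delta_ly": o.ly - ref.ly, "delta_qaly": o.qaly - ref.qaly}
        for c in CANCERS:
            inc_ref = ref.cum_incidence[c]
            mort_ref = ref.cancer_mortality[c]
            row[f"rrr_incidence_{c}"] = (
                1.0 - o.cum_incidence[c] / inc_ref if inc_ref > 0 else 0.0)
            row[f"rrr_mortality_{c}"] = (
                1.0 - o.cancer_mortality[c] / mort_ref if mort_ref > 0 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
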