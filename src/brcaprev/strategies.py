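"""The 16 compared prevention strategies and their age-dependent modifiers.

A strategy is a schedule of prophylactic surgeries (PBM and/or PBSO at
ages 30/35/40/45, or none). At a given age it induces: relative risks on
breast/ovarian onset, the surveillance cost level (MRI is dropped after
PBM, halving the surveillance bundle), and a surgery event in the cycle
of each surgery age.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CostTable, EffectMeasures, ParameterError

ALLOWED_SURGERY_AGES = (30, 35, 40, 45)


@dataclass(frozen=True)
class StrategySpec:
    """One prevention strategy: which surgeries happen at which ages."""

    id: int
    label: str
    pbm_age: int | None = None
    pbso_age: int | None = None
    custom: bool = False  # user-defined strategies outside the compared set

    def __post_init__(self) -> None:
        if not self.custom:
            for age in (self.pbm_age, self.pbso_age):
                if age is not None and age not in ALLOWED_SURGERY_AGES:
                    raise ParameterError(
                        f"surgery age {age} not in {ALLOWED_SURGERY_AGES}")

    def history_at(self, age: int) -> str:
        """Surgery history ('none'/'pbm'/'pbso'/'both') once age is reached."""
        pbm = self.pbm_age is not None and age >= self.pbm_age
        pbso = self.pbso_age is not None and age >= self.pbso_age
        if pbm and pbso:
            return "both"
        if pbm:
            return "pbm"
        if pbso:
            return "pbso"
        return "none"

    def event_at(self, age: int) -> str | None:
        """Surgery event firing in this cycle, if any."""
        pbm = self.pbm_age == age
        pbso = self.pbso_age == age
        if pbm and pbso:
            return "both"
        if pbm:
            return "pbm"
        if pbso:
            return "pbso"
        return None


@dataclass(frozen=True)
class AgeModifiers:
    """Engine-facing view of a strategy at one age."""

    rr_breast: float
    rr_ovarian: float
    surveillance_cost: float
    surgery_event: str | None  # None | 'pbm' | 'pbso' | 'both'
    history: str


def strategy_catalog() -> list[StrategySpec]:
    """The 16 compared strategies, in their published order."""
    return [
        StrategySpec(1, "Standard care (IS)"),
        StrategySpec(2, "PBM at 30", pbm_age=30),
        StrategySpec(3, "PBM at 35", pbm_age=35),
        StrategySpec(4, "PBM at 40", pbm_age=40),
        StrategySpec(5, "PBSO at 30", pbso_age=30),
        StrategySpec(6, "PBSO at 35", pbso_age=35),
        StrategySpec(7, "PBSO at 40", pbso_age=40),
        StrategySpec(8, "PBM + PBSO at 30", pbm_age=30, pbso_age=30),
        StrategySpec(9, "PBM + PBSO at 35", pbm_age=35, pbso_age=35),
        StrategySpec(10, "PBM + PBSO at 40", pbm_age=40, pbso_age=40),
        StrategySpec(11, "PBM at 30 + PBSO at 35", pbm_age=30, pbso_age=35),
        StrategySpec(12, "PBM at 30 + PBSO at 40", pbm_age=30, pbso_age=40),
        StrategySpec(13, "PBM at 35 + PBSO at 40", pbm_age=35, pbso_age=40),
        StrategySpec(14, "PBM at 35 + PBSO at 45", pbm_age=35, pbso_age=45),
        StrategySpec(15, "PBM at 40 + PBSO at 45", pbm_age=40, pbso_age=45),
        StrategySpec(16, "PBSO at 35 + PBM at 40", pbm_age=40, pbso_age=35),
    ]


def get_strategy(key: int | str) -> StrategySpec:
    """Look a compared strategy up by id or label."""
    for s in strategy_catalog():
        if s.id == key or s.label == key:
            return s
    raise KeyError(f"no strategy {key!r}")


def modifiers_at(strategy: StrategySpec, age: int,
                 effects: EffectMeasures, costs: CostTable) -> AgeModifiers:
    """Modifiers the engine needs for one strategy at one age.

    A surgery's relative risk and the post-PBM surveillance price apply
    from the surgery cycle onward; the event itself (one-time cost,
    one-cycle disutility) fires only in the cycle equal to the surgery age.
    """
    hist = strategy.history_at(age)
    rr_breast = effects.rr("breast", hist)
    rr_ovarian = effects.rr("ovarian", hist)
    surv_cost = costs.surveillance(had_pbm=hist in ("pbm", "both"))
    return AgeModifiers(rr_breast, rr_ovarian, surv_cost,
                        strategy.event_at(age), hist)
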