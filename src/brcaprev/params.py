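"""Model parameters for the BRCA-1/2 breast/ovarian prevention model.

Everything the cohort engine consumes lives in a :class:`ParameterSet`:
age-specific onset schedules, stage progression and symptomatic-detection
probabilities, stage/year survival after diagnosis, surgery effect
measures (relative risks), health-state utilities, aggregated 2022-EUR
costs, background-mortality inputs and the analysis configuration
(discounting, horizon, willingness-to-pay).

Parameters are loaded from a nested-YAML fixture (the packaged base case)
plus optional user overrides; mortality curves come from two-column CSV
files (age, annual probability). All quantities are validated on
construction.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

CANCERS = ("breast", "ovarian")
STAGES = {"breast": ("pT1", "pT2", "pT3", "pT4"),
          "ovarian": ("FIGO I", "FIGO II", "FIGO III", "FIGO IV")}
SURGERY_HISTORIES = ("none", "pbm", "pbso", "both")
N_STAGES = 4
TUNNEL_YEARS = 10


class ParameterError(ValueError):
    """Raised when a parameter violates its domain or an invariant."""


class ConfigError(ValueError):
    """Raised for unknown or malformed configuration keys."""


def _check_prob(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> float:
    value = float(value)
    if not (lo <= value <= hi) or not math.isfinite(value):
        raise ParameterError(f"{name} = {value!r} outside [{lo}, {hi}]")
    return value


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AgeIncidenceSchedule:
    """Decade-banded annual onset probabilities (well -> undetected stage 1).

    Each band is ``(age_start, age_end, p_first_year, p_last_year)``; the
    onset probability is linear in age between the two endpoints within a
    band, and bands may be discontinuous at their boundaries.
    """

    cancer: str
    decade_bands: tuple[tuple[int, int, float, float], ...]

    def __post_init__(self) -> None:
        if self.cancer not in CANCERS:
            raise ParameterError(f"unknown cancer {self.cancer!r}")
        bands = sorted(self.decade_bands)
        if not bands:
            raise ParameterError("onset schedule has no bands")
        prev_end = bands[0][0] - 1
        for a0, a1, p0, p1 in bands:
            if int(a0) != a0 or int(a1) != a1 or a1 < a0:
                raise ParameterError(f"bad band ({a0}, {a1})")
            if a0 != prev_end + 1:
                raise ParameterError("onset bands must be contiguous")
            prev_end = a1
            _check_prob(f"{self.cancer} onset[{a0}-{a1}] start", p0)
            _check_prob(f"{self.cancer} onset[{a0}-{a1}] end", p1)
        object.__setattr__(self, "decade_bands", tuple(map(tuple, bands)))

    @property
    def age_min(self) -> int:
        return self.decade_bands[0][0]

    @property
    def age_max(self) -> int:
        return self.decade_bands[-1][1]


def interpolate_onset(schedule: AgeIncidenceSchedule, age: int) -> float:
    """Annual onset probability at an integer age.

    Linear within the band: the first printed value belongs to the band's
    first integer age, the second to its last.
    """
    if not (schedule.age_min <= age <= schedule.age_max):
        raise ParameterError(
            f"age {age} outside the onset schedule "
            f"[{schedule.age_min}, {schedule.age_max}]")
    for a0, a1, p0, p1 in schedule.decade_bands:
        if a0 <= age <= a1:
            if a1 == a0:
                return p0
            return p0 + (age - a0) / (a1 - a0) * (p1 - p0)
    raise AssertionError("contiguous bands must cover the age")  # pragma: no cover


@dataclass(frozen=True)
class StageTransitionTable:
    """Annual progression (stage k -> k+1) and detection probabilities."""

    cancer: str
    progression: tuple[float, float, float]
    detection: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.progression) != N_STAGES - 1:
            raise ParameterError("progression needs 3 entries (terminal stage has none)")
        if len(self.detection) != N_STAGES:
            raise ParameterError("detection needs one entry per stage")
        for i, p in enumerate(self.progression):
            _check_prob(f"{self.cancer} progression[{i}]", p)
        for i, p in enumerate(self.detection):
            _check_prob(f"{self.cancer} detection[{i}]", p)
        object.__setattr__(self, "progression", tuple(float(p) for p in self.progression))
        object.__setattr__(self, "detection", tuple(float(p) for p in self.detection))


def annual_survival_from_5yr(s5: float) -> float:
    """Constant annual survival implied by a 5-year survival fraction."""
    if not 0.0 < s5 <= 1.0:
        raise ParameterError(f"five-year survival {s5!r} outside (0, 1]")
    return float(s5) ** 0.2


@dataclass(frozen=True)
class SurvivalTable:
    """Stage- and year-specific annual survival for diagnosed cancer.

    ``annual_survival[stage, year-1]`` is the probability of surviving
    tunnel year 1..10 after diagnosis in that stage. When only 5-year
    survival fractions are configured, each stage gets the constant-rate
    annual value ``S5**(1/5)`` for all ten years.
    """

    cancer: str
    five_year_survival: tuple[float, float, float, float]
    annual_survival: np.ndarray  # (4, 10)

    def __post_init__(self) -> None:
        arr = np.asarray(self.annual_survival, dtype=float)
        if arr.shape != (N_STAGES, TUNNEL_YEARS):
            raise ParameterError("annual_survival must be 4 stages x 10 years")
        if np.any(arr <= 0) or np.any(arr > 1):
            raise ParameterError(f"{self.cancer} annual survival outside (0, 1]")
        for i, s in enumerate(self.five_year_survival):
            if not 0 < s <= 1:
                raise ParameterError(f"{self.cancer} 5y survival[{i}] outside (0, 1]")
        arr.flags.writeable = False
        object.__setattr__(self, "annual_survival", arr)

    @classmethod
    def from_five_year(cls, cancer: str, s5: Sequence[float]) -> "SurvivalTable":
        ann = np.array([[annual_survival_from_5yr(s)] * TUNNEL_YEARS for s in s5])
        return cls(cancer, tuple(float(s) for s in s5), ann)


@dataclass(frozen=True)
class EffectMeasures:
    """Relative risks of cancer onset after prophylactic surgery."""

    rr_breast_pbm: float
    rr_breast_pbso: float
    rr_breast_both: float
    rr_ovarian_pbso: float
    rr_ovarian_pbm: float = 1.0
    rr_ovarian_both: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rr_ovarian_both is None:
            object.__setattr__(self, "rr_ovarian_both", self.rr_ovarian_pbso)
        for name in ("rr_breast_pbm", "rr_breast_pbso", "rr_breast_both",
                     "rr_ovarian_pbso", "rr_ovarian_pbm", "rr_ovarian_both"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} = {v!r} outside (0, 1]")
        if self.rr_ovarian_pbm != 1.0:
            raise ParameterError("PBM does not modify ovarian onset (rr must be 1)")

    def rr(self, cancer: str, history: str) -> float:
        if history == "none":
            return 1.0
        return getattr(self, f"rr_{cancer}_{history}")


@dataclass(frozen=True)
class UtilityTable:
    """Quality-of-life weights per health state.

    ``u_surgery`` is the utility experienced during the surgery cycle by a
    woman whose base state is "well"; occupants of other states scale it
    relatively (``u_state * u_surgery / u_well``).
    """

    u_well: float
    u_detected: Mapping[str, tuple[float, float, float, float]]
    u_remission: float
    u_surgery: Mapping[str, float]  # keys pbm, pbso, both
    u_undetected: Mapping[str, tuple[float, float, float, float]] = None  # type: ignore

    def __post_init__(self) -> None:
        _check_prob("u_well", self.u_well)
        _check_prob("u_remission", self.u_remission)
        det = {c: tuple(float(u) for u in self.u_detected[c]) for c in CANCERS}
        for c in CANCERS:
            for i, u in enumerate(det[c]):
                _check_prob(f"u_detected[{c}][{i}]", u)
            if any(b > a + 1e-12 for a, b in zip(det[c], det[c][1:])):
                raise ParameterError(f"{c} detected utilities must be non-increasing in stage")
        object.__setattr__(self, "u_detected", det)
        surg = {k: _check_prob(f"u_surgery[{k}]", v) for k, v in self.u_surgery.items()}
        if set(surg) != {"pbm", "pbso", "both"}:
            raise ParameterError("u_surgery needs keys pbm, pbso, both")
        object.__setattr__(self, "u_surgery", surg)
        und = self.u_undetected
        if und is None:
            und = det
        else:
            und = {c: tuple(float(u) for u in und[c]) for c in CANCERS}
            for c in CANCERS:
                for i, u in enumerate(und[c]):
                    _check_prob(f"u_undetected[{c}][{i}]", u)
        object.__setattr__(self, "u_undetected", und)


@dataclass(frozen=True)
class CostTable:
    """Aggregated direct medical costs (2022 EUR).

    Initial-treatment and follow-up costs are stratified by surgery
    history because prophylactic surgery changes the subsequent treatment
    mix (e.g. no MRI surveillance and no breast surgery after PBM).
    Severity classes: breast "early" = pT1-pT3, "late" = metastatic pT4;
    ovarian "early" = FIGO I-II, "late" = advanced FIGO III-IV.
    """

    c_surveillance: float
    surveillance_after_pbm_fraction: float
    c_surgery: Mapping[str, float]
    c_initial: Mapping[str, Mapping[str, Mapping[str, float]]]
    c_followup: Mapping[str, Mapping[str, tuple]]
    c_palliative: Mapping[str, float]
    followup_years: Mapping[str, int]

    def __post_init__(self) -> None:
        def nonneg(name, v):
            if float(v) < 0:
                raise ParameterError(f"{name} negative")
            return float(v)

        nonneg("surveillance", self.c_surveillance)
        _check_prob("surveillance_after_pbm_fraction", self.surveillance_after_pbm_fraction)
        surg = {k: nonneg(f"surgery[{k}]", v) for k, v in self.c_surgery.items()}
        if set(surg) != {"pbm", "pbso", "both"}:
            raise ParameterError("surgery costs need keys pbm, pbso, both")
        if abs(surg["both"] - surg["pbm"] - surg["pbso"]) > 0.5:
            raise ParameterError("combined surgery cost must equal PBM + PBSO")
        for c in CANCERS:
            for sev in ("early", "late"):
                for h in SURGERY_HISTORIES:
                    nonneg(f"initial[{c}][{sev}][{h}]", self.c_initial[c][sev][h])
            for h in SURGERY_HISTORIES:
                for v in self.c_followup[c][h]:
                    nonneg(f"followup[{c}][{h}]", v)
            nonneg(f"palliative[{c}]", self.c_palliative[c])
            if not 0 < int(self.followup_years[c]) <= TUNNEL_YEARS:
                raise ParameterError("follow-up duration must be in 1..10 years")

    def initial_cost(self, cancer: str, stage: int, history: str) -> float:
        sev = severity_class(cancer, stage)
        return self.c_initial[cancer][sev][history]

    def followup_cost(self, cancer: str, stage: int, history: str) -> float:
        if cancer == "breast":
            return self.c_followup[cancer][history][stage]
        return self.c_followup[cancer][history][0 if stage < 2 else 1]

    def surveillance(self, had_pbm: bool) -> float:
        f = self.surveillance_after_pbm_fraction if had_pbm else 1.0
        return self.c_surveillance * f


def severity_class(cancer: str, stage: int) -> str:
    """Map a 0-based stage index to the cost severity class."""
    if cancer == "breast":
        return "late" if stage == 3 else "early"
    return "late" if stage >= 2 else "early"


@dataclass(frozen=True)
class MortalityInputs:
    """All-cause and breast+ovarian cancer mortality curves (annual q_x)."""

    ages: np.ndarray
    q_all: np.ndarray
    q_cancer: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qa = np.asarray(self.q_all, dtype=float)
        qc = np.asarray(self.q_cancer, dtype=float)
        if not (ages.shape == qa.shape == qc.shape) or ages.ndim != 1:
            raise ParameterError("mortality curves must share one age grid")
        if np.any(np.diff(ages) != 1):
            raise ParameterError("mortality ages must be consecutive integers")
        if np.any(qa < 0) or np.any(qa > 1) or np.any(qc < 0) or np.any(qc > 1):
            raise ParameterError("mortality probabilities outside [0, 1]")
        if np.any(qc > qa + 1e-12):
            raise ParameterError("cancer mortality exceeds all-cause mortality")
        for a in (ages, qa, qc):
            a.flags.writeable = False
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_all", qa)
        object.__setattr__(self, "q_cancer", qc)

    def _at(self, curve: np.ndarray, age: int) -> float:
        # ages beyond the table reuse its last (first) entry
        i = min(max(int(age) - int(self.ages[0]), 0), len(self.ages) - 1)
        return float(curve[i])

    def all_cause(self, age: int) -> float:
        return self._at(self.q_all, age)

    def cancer(self, age: int) -> float:
        return self._at(self.q_cancer, age)


def background_mortality(m: MortalityInputs, age: int) -> float:
    """Annual probability of death from causes other than breast/ovarian cancer.

    The subtraction is done on the rate scale so competing risks compose
    correctly: ``q_other = 1 - exp(-(h_all - h_cancer))`` with
    ``h = -ln(1 - q)``.
    """
    q_all = m.all_cause(age)
    q_cancer = m.cancer(age)
    if q_cancer > q_all:
        raise ParameterError(f"cancer mortality > all-cause at age {age}")
    if q_all >= 1.0:
        return 1.0
    h = -math.log1p(-q_all) + math.log1p(-q_cancer)
    return -math.expm1(-h)


@dataclass(frozen=True)
class AnalysisConfig:
    """Horizon, discounting and willingness-to-pay settings.

    ``discount_origin_age`` sets the age at which the discount factor is 1;
    the base case discounts from birth (the model clock of a lifetime
    cohort), which leaves every incremental ratio unchanged relative to
    discounting from ``start_age`` but matches lifetime totals.
    """

    discount_rate: float = 0.03
    wtp: float = 90_000.0
    start_age: int = 30
    end_age: int = 100
    discount_origin_age: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.discount_rate < 1:
            raise ParameterError("discount rate must be in [0, 1)")
        if self.start_age >= self.end_age:
            raise ParameterError("start_age must be below end_age")

    def discount_factor(self, age: int) -> float:
        return (1.0 + self.discount_rate) ** (-(age - self.discount_origin_age))


@dataclass(frozen=True)
class ParameterSet:
    """Single source of model inputs for the cohort engine."""

    onset: Mapping[str, AgeIncidenceSchedule]
    stages: Mapping[str, StageTransitionTable]
    survival: Mapping[str, SurvivalTable]
    effects: EffectMeasures
    utilities: UtilityTable
    costs: CostTable
    mortality: MortalityInputs
    analysis: AnalysisConfig

    def onset_at(self, cancer: str, age: int) -> float:
        sched = self.onset[cancer]
        age = min(max(int(age), sched.age_min), sched.age_max)
        return interpolate_onset(sched, age)

    def q_other(self, age: int) -> float:
        return background_mortality(self.mortality, age)

    def content_hash(self) -> str:
        """Stable digest of every numeric input (for run manifests)."""
        payload = {
            "onset": {c: self.onset[c].decade_bands for c in CANCERS},
            "progression": {c: self.stages[c].progression for c in CANCERS},
            "detection": {c: self.stages[c].detection for c in CANCERS},
            "survival": {c: self.survival[c].annual_survival.tolist() for c in CANCERS},
            "effects": [self.effects.rr_breast_pbm, self.effects.rr_breast_pbso,
                        self.effects.rr_breast_both, self.effects.rr_ovarian_pbso],
            "utilities": [self.utilities.u_well, self.utilities.u_remission,
                          self.utilities.u_detected, self.utilities.u_undetected,
                          self.utilities.u_surgery],
            "costs": [self.costs.c_surveillance, self.costs.surveillance_after_pbm_fraction,
                      self.costs.c_surgery, self.costs.c_initial,
                      {c: {h: list(v) for h, v in self.costs.c_followup[c].items()}
                       for c in CANCERS},
                      self.costs.c_palliative, dict(self.costs.followup_years)],
            "mortality": [self.mortality.ages.tolist(), self.mortality.q_all.tolist(),
                          self.mortality.q_cancer.tolist()],
            "analysis": [self.analysis.discount_rate, self.analysis.wtp,
                         self.analysis.start_age, self.analysis.end_age,
                         self.analysis.discount_origin_age],
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# loading


_FIXTURE_PKG = "brcaprev.fixtures"
BASE_PARAMS_FIXTURE = "base_params.yaml"
LIFE_TABLE_FIXTURE = "life_table_german_female_synthetic.csv"
CANCER_MORTALITY_FIXTURE = "cancer_mortality_german_female_synthetic.csv"

_SCHEMA = {
    "onset": {"breast", "ovarian"},
    "progression": {"breast", "ovarian"},
    "detection": {"breast", "ovarian"},
    "five_year_survival": {"breast", "ovarian"},
    "annual_survival": {"breast", "ovarian"},
    "effects": {"rr_breast_pbm", "rr_breast_pbso", "rr_breast_both", "rr_ovarian_pbso"},
    "utilities": {"well", "detected", "remission", "surgery", "undetected"},
    "costs": {"surveillance", "surveillance_after_pbm_fraction", "surgery",
              "initial", "palliative", "followup", "followup_years"},
    "analysis": {"discount_rate", "wtp", "start_age", "end_age", "discount_origin_age"},
}


def _validate_keys(doc: Mapping) -> None:
    for key, sub in doc.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(sub, Mapping):
            for k2 in sub:
                if k2 not in _SCHEMA[key]:
                    raise ConfigError(f"unknown configuration key {key!r}.{k2!r}")


def _deep_update(base: dict, overrides: Mapping) -> dict:
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = copy.deepcopy(v)
    return base


def read_mortality_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (age, probability) CSV."""
    rows = np.genfromtxt(path, delimiter=",", names=True)
    if rows.dtype.names is None or len(rows.dtype.names) != 2:
        raise ConfigError(f"{path}: expected a two-column CSV with a header")
    ages = rows[rows.dtype.names[0]].astype(int)
    probs = rows[rows.dtype.names[1]].astype(float)
    order = np.argsort(ages)
    return ages[order], probs[order]


def load_mortality(life_table_path=None, cancer_mortality_path=None) -> MortalityInputs:
    """Load the mortality inputs, defaulting to the packaged synthetic curves."""
    if life_table_path is None:
        life_table_path = resources.files(_FIXTURE_PKG) / LIFE_TABLE_FIXTURE
    if cancer_mortality_path is None:
        cancer_mortality_path = resources.files(_FIXTURE_PKG) / CANCER_MORTALITY_FIXTURE
    ages_a, q_all = read_mortality_csv(life_table_path)
    ages_c, q_cancer = read_mortality_csv(cancer_mortality_path)
    lo, hi = max(ages_a[0], ages_c[0]), min(ages_a[-1], ages_c[-1])
    sel_a = (ages_a >= lo) & (ages_a <= hi)
    sel_c = (ages_c >= lo) & (ages_c <= hi)
    return MortalityInputs(ages_a[sel_a], q_all[sel_a], q_cancer[sel_c])


def parameter_set_from_dict(doc: Mapping, mortality: MortalityInputs) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a configuration mapping."""
    _validate_keys(doc)
    onset = {c: AgeIncidenceSchedule(c, tuple(map(tuple, doc["onset"][c])))
             for c in CANCERS}
    stages = {c: StageTransitionTable(c, tuple(doc["progression"][c]),
                                      tuple(doc["detection"][c]))
              for c in CANCERS}
    survival = {}
    for c in CANCERS:
        s5 = tuple(float(v) for v in doc["five_year_survival"][c])
        if "annual_survival" in doc and c in doc.get("annual_survival", {}):
            survival[c] = SurvivalTable(c, s5, np.asarray(doc["annual_survival"][c], float))
        else:
            survival[c] = SurvivalTable.from_five_year(c, s5)
    eff = EffectMeasures(**{k: float(v) for k, v in doc["effects"].items()})
    u = doc["utilities"]
    utilities = UtilityTable(
        u_well=float(u["well"]),
        u_detected={c: tuple(u["detected"][c]) for c in CANCERS},
        u_remission=float(u["remission"]),
        u_surgery={k: float(v) for k, v in u["surgery"].items()},
        u_undetected=({c: tuple(u["undetected"][c]) for c in CANCERS}
                      if "undetected" in u else None),
    )
    cc = doc["costs"]
    costs = CostTable(
        c_surveillance=float(cc["surveillance"]),
        surveillance_after_pbm_fraction=float(cc["surveillance_after_pbm_fraction"]),
        c_surgery={k: float(v) for k, v in cc["surgery"].items()},
        c_initial=cc["initial"],
        c_followup={c: {h: tuple(v) for h, v in cc["followup"][c].items()}
                    for c in CANCERS},
        c_palliative={c: float(cc["palliative"][c]) for c in CANCERS},
        followup_years={c: int(cc["followup_years"][c]) for c in CANCERS},
    )
    analysis = AnalysisConfig(**doc["analysis"])
    return ParameterSet(onset, stages, survival, eff, utilities, costs,
                        mortality, analysis)


def base_params_dict() -> dict:
    """The packaged base-case fixture as a plain dict."""
    text = (resources.files(_FIXTURE_PKG) / BASE_PARAMS_FIXTURE).read_text()
    return yaml.safe_load(text)


def load_parameters(overrides: Mapping | None = None,
                    mortality: MortalityInputs | None = None,
                    config_path: str | Path | None = None) -> ParameterSet:
    """Base-case parameters, optionally overridden from a YAML file or dict."""
    doc = base_params_dict()
    if config_path is not None:
        user = yaml.safe_load(Path(config_path).read_text()) or {}
        _validate_keys(user)
        _deep_update(doc, user)
    if overrides:
        _validate_keys(overrides)
        _deep_update(doc, overrides)
    if mortality is None:
        mortality = load_mortality()
    return parameter_set_from_dict(doc, mortality)


# ---------------------------------------------------------------------------
# derived parameter sets


def with_updates(params: ParameterSet, **replacements) -> ParameterSet:
    """Return a copy of ``params`` with the named top-level fields replaced."""
    fields = dict(onset=params.onset, stages=params.stages, survival=params.survival,
                  effects=params.effects, utilities=params.utilities, costs=params.costs,
                  mortality=params.mortality, analysis=params.analysis)
    unknown = set(replacements) - set(fields)
    if unknown:
        raise ConfigError(f"unknown ParameterSet fields {sorted(unknown)}")
    fields.update(replacements)
    return ParameterSet(**fields)


def neutralize_surgery_effects(params: ParameterSet) -> ParameterSet:
    """Remove every channel through which surgery affects outcomes.

    Sets all relative risks to 1, surgery costs to 0, surgery-cycle
    utilities to the well utility, keeps full-price surveillance after PBM
    and collapses history-stratified treatment costs onto the no-surgery
    column. Under the result, every strategy is outcome-identical to
    standard care.
    """
    eff = EffectMeasures(1.0, 1.0, 1.0, 1.0)
    u = params.utilities
    utilities = UtilityTable(u.u_well, u.u_detected, u.u_remission,
                             {k: u.u_well for k in ("pbm", "pbso", "both")},
                             u.u_undetected)
    c = params.costs
    costs = CostTable(
        c_surveillance=c.c_surveillance,
        surveillance_after_pbm_fraction=1.0,
        c_surgery={"pbm": 0.0, "pbso": 0.0, "both": 0.0},
        c_initial={cn: {sev: {h: c.c_initial[cn][sev]["none"]
                              for h in SURGERY_HISTORIES}
                        for sev in ("early", "late")} for cn in CANCERS},
        c_followup={cn: {h: c.c_followup[cn]["none"] for h in SURGERY_HISTORIES}
                    for cn in CANCERS},
        c_palliative=c.c_palliative,
        followup_years=c.followup_years,
    )
    return with_updates(params, effects=eff, utilities=utilities, costs=costs)
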