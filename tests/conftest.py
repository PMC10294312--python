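import numpy as np
import pytest
from hypothesis import settings

import brcaprev as b
from brcaprev.params import MortalityInputs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def base_params():
    """Base-case parameters with the packaged synthetic mortality curves."""
    return b.load_parameters()


@pytest.fixture(scope="session")
def base_outcomes(base_params):
    """Outcomes of all 16 strategies under the base case (computed once)."""
    return b.run_all(b.strategy_catalog(), base_params)


def constant_mortality(q_all: float, q_cancer: float = 0.0,
                       age_min: int = 20, age_max: int = 100) -> MortalityInputs:
    ages = np.arange(age_min, age_max + 1)
    return MortalityInputs(ages, np.full(len(ages), q_all),
                           np.full(len(ages), q_cancer))


def toy_params(onset_breast=0.0, onset_ovarian=0.0, q_all=0.0,
               detection_breast=None, survival_breast=None,
               progression_breast=None, **overrides):
    """Simplified parameterization for closed-form checks.

    Constant onset over ages 20-99, optional constant mortality,
    optional detection/survival overrides for the breast pathway.
    """
    doc = {
        "onset": {"breast": [[20, 99, onset_breast, onset_breast]],
                  "ovarian": [[20, 99, onset_ovarian, onset_ovarian]]},
    }
    if detection_breast is not None:
        doc["detection"] = {"breast": list(detection_breast),
                            "ovarian": [0.15, 0.15, 0.72, 0.95]}
    if progression_breast is not None:
        doc["progression"] = {"breast": list(progression_breast),
                              "ovarian": [0.70, 0.93, 0.99]}
    if survival_breast is not None:
        doc["annual_survival"] = {"breast": [[survival_breast] * 10] * 4}
    doc.update(overrides)
    return b.load_parameters(overrides=doc,
                             mortality=constant_mortality(q_all))


def zero_costs_overrides():
    """Cost table with everything zeroed except what a test re-enables."""
    zero4 = {"none": 0.0, "pbm": 0.0, "pbso": 0.0, "both": 0.0}
    return {"costs": {
        "surveillance": 0.0,
        "surveillance_after_pbm_fraction": 0.5,
        "surgery": {"pbm": 0.0, "pbso": 0.0, "both": 0.0},
        "initial": {c: {"early": dict(zero4), "late": dict(zero4)}
                    for c in ("breast", "ovarian")},
        "palliative": {"breast": 0.0, "ovarian": 0.0},
        "followup": {"breast": {h: [0.0] * 4 for h in zero4},
                     "ovarian": {h: [0.0] * 2 for h in zero4}},
        "followup_years": {"breast": 10, "ovarian": 5},
    }}
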