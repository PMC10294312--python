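"""Parameter fixtures, transforms and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brcaprev as b
from brcaprev.params import (ConfigError, ParameterError, annual_survival_from_5yr,
                             background_mortality,
                             interpolate_onset, severity_class)
from tests.conftest import constant_mortality


class TestFixtureRoundTrip:
    """The packaged fixture must reproduce the published inputs exactly."""

    def test_onset_band_endpoints(self, base_params):
        breast = dict((b0, (p0, p1)) for b0, _, p0, p1
                      in base_params.onset["breast"].decade_bands)
        assert breast[30] == (0.0106, 0.0185)
        assert breast[70] == (0.0666, 0.0638)
        ovarian = dict((b0, (p0, p1)) for b0, _, p0, p1
                       in base_params.onset["ovarian"].decade_bands)
        assert ovarian[20] == (0.000015, 0.00002)
        assert ovarian[60] == (0.0348, 0.0433)

    def test_progression_and_detection(self, base_params):
        assert base_params.stages["breast"].progression == (0.205, 0.25, 0.60)
        assert base_params.stages["ovarian"].progression == (0.70, 0.93, 0.99)
        assert base_params.stages["breast"].detection == (0.23, 0.55, 0.60, 1.00)
        assert base_params.stages["ovarian"].detection == (0.15, 0.15, 0.72, 0.95)

    def test_survival_effects_utilities_costs(self, base_params):
        assert base_params.survival["breast"].five_year_survival == (0.993, 0.876, 0.595, 0.262)
        assert base_params.survival["ovarian"].five_year_survival == (0.871, 0.704, 0.350, 0.155)
        eff = base_params.effects
        assert (eff.rr_breast_pbm, eff.rr_breast_pbso, eff.rr_breast_both) == (0.070, 0.500, 0.039)
        assert eff.rr_ovarian_pbso == eff.rr_ovarian_both == 0.038
        assert eff.rr_ovarian_pbm == 1.0
        u = base_params.utilities
        assert u.u_well == 0.92
        assert u.u_detected["breast"] == (0.68, 0.61, 0.56, 0.42)
        assert u.u_detected["ovarian"] == (0.81, 0.72, 0.63, 0.55)
        assert u.u_remission == 0.83
        assert u.u_surgery == {"pbm": 0.88, "pbso": 0.95, "both": 0.84}
        c = base_params.costs
        assert c.c_surveillance == 608.0
        assert c.c_surgery == {"pbm": 9032.0, "pbso": 3099.0, "both": 12131.0}
        assert c.c_initial["breast"]["early"]["pbm"] == 14333.0
        assert c.c_initial["ovarian"]["late"]["pbso"] == 32666.0
        assert c.c_followup["breast"]["none"] == (595.0, 652.0, 589.0, 686.0)
        assert c.c_followup["ovarian"]["both"] == (910.0, 1942.0)
        assert c.c_palliative == {"breast": 12103.0, "ovarian": 12103.0}

    def test_combined_surgery_cost_is_sum_of_parts(self, base_params):
        c = base_params.costs.c_surgery
        assert c["both"] == c["pbm"] + c["pbso"]

    def test_undetected_utilities_default_to_detected(self, base_params):
        u = base_params.utilities
        assert u.u_undetected == u.u_detected


class TestInterpolateOnset:
    def test_band_endpoints_and_midpoint(self, base_params):
        sched = base_params.onset["breast"]
        assert interpolate_onset(sched, 30) == 0.0106
        assert interpolate_onset(sched, 39) == 0.0185
        expected = 0.0106 + (4 / 9) * (0.0185 - 0.0106)
        assert interpolate_onset(sched, 34) == pytest.approx(expected, abs=1e-15)

    def test_outside_range_raises(self, base_params):
        sched = base_params.onset["breast"]
        with pytest.raises(ParameterError):
            interpolate_onset(sched, 19)
        with pytest.raises(ParameterError):
            interpolate_onset(sched, 100)

    @given(age=st.integers(min_value=20, max_value=99))
    @settings(max_examples=80, deadline=None)
    def test_within_band_linearity(self, age):
        sched = b.load_parameters().onset["ovarian"]
        p = interpolate_onset(sched, age)
        assert 0.0 <= p <= 1.0
        band = next(bd for bd in sched.decade_bands if bd[0] <= age <= bd[1])
        lo, hi = min(band[2], band[3]), max(band[2], band[3])
        assert lo - 1e-15 <= p <= hi + 1e-15

    def test_noncontiguous_bands_rejected(self):
        with pytest.raises(ParameterError):
            b.AgeIncidenceSchedule("breast", ((20, 29, 0.1, 0.1), (31, 40, 0.1, 0.1)))


class TestAnnualSurvival:
    def test_certainty_preserved(self):
        assert annual_survival_from_5yr(1.0) == 1.0

    @pytest.mark.parametrize("s5", [0.993, 0.876, 0.595, 0.262, 0.155])
    def test_five_fold_product_roundtrip(self, s5):
        a = annual_survival_from_5yr(s5)
        assert a ** 5 == pytest.approx(s5, abs=1e-12)
        assert a == pytest.approx(math.exp(math.log(s5) / 5), abs=1e-15)

    def test_invalid_rejected(self):
        with pytest.raises(ParameterError):
            annual_survival_from_5yr(0.0)
        with pytest.raises(ParameterError):
            annual_survival_from_5yr(-0.1)


class TestBackgroundMortality:
    def test_trivial_cases(self):
        m = constant_mortality(0.01, 0.0)
        assert background_mortality(m, 50) == pytest.approx(0.01, abs=1e-15)
        m = constant_mortality(0.005, 0.005)
        assert background_mortality(m, 50) == pytest.approx(0.0, abs=1e-15)

    def test_rate_scale_subtraction(self):
        m = constant_mortality(0.010, 0.002)
        expected = 1 - math.exp(-(-math.log(1 - 0.010) + math.log(1 - 0.002)))
        assert background_mortality(m, 50) == pytest.approx(expected, abs=1e-15)

    def test_cancer_exceeding_all_cause_rejected(self):
        with pytest.raises(ParameterError):
            constant_mortality(0.001, 0.002)

    @given(q_all=st.floats(1e-6, 0.5), frac=st.floats(0.0, 1.0),
           bump=st.floats(1e-6, 0.2))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_both_arguments(self, q_all, frac, bump):
        q_cancer = q_all * frac
        base = background_mortality(constant_mortality(q_all, q_cancer), 50)
        more_all = background_mortality(
            constant_mortality(min(q_all + bump, 0.99), q_cancer), 50)
        assert more_all >= base - 1e-14
        more_cancer = background_mortality(
            constant_mortality(q_all, min(q_all, q_cancer + bump * frac)), 50)
        assert more_cancer <= base + 1e-14
        assert 0.0 <= base <= q_all + 1e-14


class TestLoaderValidation:
    def test_unknown_key_named_in_error(self):
        with pytest.raises(ConfigError, match="not_a_key"):
            b.load_parameters(overrides={"not_a_key": 1})

    def test_bad_probability_rejected(self):
        with pytest.raises(ParameterError):
            b.load_parameters(overrides={"detection": {"breast": [0.2, 0.5, 0.6, 1.7],
                                                       "ovarian": [0.15, 0.15, 0.72, 0.95]}})

    def test_severity_classes(self):
        assert [severity_class("breast", s) for s in range(4)] == \
            ["early", "early", "early", "late"]
        assert [severity_class("ovarian", s) for s in range(4)] == \
            ["early", "early", "late", "late"]

    def test_mortality_fixture_covers_horizon(self, base_params):
        m = base_params.mortality
        assert m.ages[0] <= 30 and m.ages[-1] >= 99
        assert np.all(m.q_cancer <= m.q_all)
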