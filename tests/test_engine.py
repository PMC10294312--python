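"""Cohort engine: transition mechanics, mass accounting, reward oracles."""

import numpy as np
import pytest

import brcaprev as b
from brcaprev.engine import (DEATH, N_STATES, SURVIVOR, WELL, det_index,
                             lifetime_outcomes, run_cohort, step, und_index)
from brcaprev.params import AnalysisConfig, with_updates
from brcaprev.strategies import modifiers_at
from tests.conftest import constant_mortality, toy_params, zero_costs_overrides


def _mods(params, strategy_id=1, age=50):
    s = b.get_strategy(strategy_id)
    return modifiers_at(s, age, params.effects, params.costs)


class TestStepMechanics:
    def test_zero_hazards_identity(self):
        p = toy_params()  # no onset, no mortality
        row = np.zeros(N_STATES)
        row[WELL] = 1.0
        new, fl = step(row, 40, _mods(p), p)
        assert np.allclose(new, row, atol=1e-15)
        assert fl.other_deaths == 0.0 and fl.onset == {"breast": 0.0, "ovarian": 0.0}

    def test_detection_first_then_progression_figo_iii(self, base_params):
        """FIGO III: detection 0.72 wins before progression 0.99 applies."""
        p = with_updates(base_params, mortality=constant_mortality(0.0))
        row = np.zeros(N_STATES)
        row[und_index("ovarian", 2)] = 1.0
        new, fl = step(row, 60, _mods(p), p)
        assert new[det_index("ovarian", 2, 1)] == pytest.approx(0.72, abs=1e-12)
        assert new[und_index("ovarian", 3)] == pytest.approx(0.28 * 0.99, abs=1e-12)
        assert new[und_index("ovarian", 2)] == pytest.approx(0.28 * 0.01, abs=1e-12)
        assert fl.diagnoses["ovarian"][2] == pytest.approx(0.72, abs=1e-12)

    def test_undetected_stage_iv_breast_fully_detected(self, base_params):
        p = with_updates(base_params, mortality=constant_mortality(0.0))
        row = np.zeros(N_STATES)
        row[und_index("breast", 3)] = 1.0
        new, _ = step(row, 60, _mods(p), p)
        assert new[det_index("breast", 3, 1)] == pytest.approx(1.0, abs=1e-12)

    def test_tunnel_year10_survivors_move_to_survivor_state(self):
        p = toy_params(survival_breast=0.9)
        row = np.zeros(N_STATES)
        row[det_index("breast", 1, 10)] = 1.0
        new, fl = step(row, 70, _mods(p), p)
        assert new[SURVIVOR["breast"]] == pytest.approx(0.9, abs=1e-15)
        assert new[DEATH["breast"]] == pytest.approx(0.1, abs=1e-15)
        assert fl.cancer_deaths["breast"] == pytest.approx(0.1, abs=1e-15)

    def test_onset_competes_by_rate_normalization(self):
        p = toy_params(onset_breast=0.3, onset_ovarian=0.2)
        row = np.zeros(N_STATES)
        row[WELL] = 1.0
        new, fl = step(row, 50, _mods(p), p)
        hb, ho = -np.log1p(-0.3), -np.log1p(-0.2)
        p_any = -np.expm1(-(hb + ho))
        assert fl.onset["breast"] == pytest.approx(p_any * hb / (hb + ho), abs=1e-14)
        assert fl.onset["ovarian"] == pytest.approx(p_any * ho / (hb + ho), abs=1e-14)
        assert new[WELL] == pytest.approx(1 - p_any, abs=1e-14)


class TestCohortInvariants:
    @pytest.mark.parametrize("strategy_id", [1, 2, 5, 8, 11, 12, 16])
    def test_mass_conservation_and_absorbing_monotonicity(self, base_params, strategy_id):
        trace = run_cohort(b.get_strategy(strategy_id), base_params)
        sums = trace.occupancy.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-10
        assert trace.occupancy.min() >= -1e-12
        dead = trace.occupancy[:, [DEATH["breast"], DEATH["ovarian"], DEATH["other"]]]
        assert np.all(np.diff(dead, axis=0) >= -1e-12)

    def test_rerun_bit_identical(self, base_params):
        t1 = run_cohort(b.get_strategy(11), base_params)
        t2 = run_cohort(b.get_strategy(11), base_params)
        assert np.array_equal(t1.occupancy, t2.occupancy)

    def test_combined_surgery_reduces_undetected_occupancy(self, base_params):
        """Risk-reducing surgery must thin the preclinical cancer pool."""
        t1 = run_cohort(b.get_strategy(1), base_params)
        t8 = run_cohort(b.get_strategy(8), base_params)
        i = 60 - t1.start_age
        und = [und_index(c, s) for c in ("breast", "ovarian") for s in range(4)]
        assert t8.occupancy[i, und].sum() < t1.occupancy[i, und].sum()


class TestLifeExpectancyOracles:
    def test_no_cancer_reduces_to_life_table_expectancy(self, base_params):
        """With onset zeroed, LY equals the survival-curve sum from age 30."""
        p = b.load_parameters(overrides={
            "onset": {"breast": [[20, 99, 0.0, 0.0]], "ovarian": [[20, 99, 0.0, 0.0]]}})
        trace = run_cohort(b.get_strategy(1), p)
        out = lifetime_outcomes(trace, p)
        lx = 1.0
        expected = 0.0
        for age in range(30, 100):
            expected += lx
            lx *= 1.0 - p.q_other(age)
        assert out.ly == pytest.approx(expected, abs=1e-10)
        assert out.cum_incidence == {"breast": 0.0, "ovarian": 0.0}

    def test_phase_type_expectation_on_toy_chain(self):
        """Engine LY matches the analytic absorbing-chain expectation.

        Toy chain: well -(p)-> undetected -(d)-> diagnosed tunnel (10 y,
        constant survival s) -> survivor, with constant other-cause
        mortality q everywhere outside the tunnels. Expected years lived
        equal alpha' (I-Q)^-1 1 of the transient submatrix.
        """
        pr, d, s, q = 0.10, 0.6, 0.9, 0.02
        p = toy_params(onset_breast=pr, q_all=q,
                       detection_breast=(d, 1.0, 1.0, 1.0),
                       survival_breast=s,
                       progression_breast=(0.0, 0.0, 0.0))
        cfg = AnalysisConfig(discount_rate=0.0, start_age=30, end_age=2000,
                             discount_origin_age=30)
        trace = run_cohort(b.get_strategy(1), p, cfg)
        out = lifetime_outcomes(trace, p, cfg)

        # transient states: well, undetected, tunnel years 1..10, survivor
        n = 13
        Q = np.zeros((n, n))
        Q[0, 0] = (1 - q) * (1 - pr)
        Q[0, 1] = (1 - q) * pr
        Q[1, 1] = (1 - q) * (1 - d)
        Q[1, 2] = (1 - q) * d
        for y in range(10):
            Q[2 + y, 3 + y] = s
        Q[12, 12] = 1 - q
        alpha = np.zeros(n)
        alpha[0] = 1.0
        expected = alpha @ np.linalg.inv(np.eye(n) - Q) @ np.ones(n)
        assert out.ly == pytest.approx(expected, abs=1e-8)


class TestDiscountingAndCosts:
    def _immortal(self):
        return b.load_parameters(
            overrides={"onset": {"breast": [[20, 99, 0.0, 0.0]],
                                 "ovarian": [[20, 99, 0.0, 0.0]]},
                       "utilities": {"well": 1.0},
                       **zero_costs_overrides()},
            mortality=constant_mortality(0.0))

    def test_discounted_qalys_equal_geometric_sum(self):
        p = self._immortal()
        cfg = AnalysisConfig(discount_rate=0.03, start_age=30, end_age=100,
                             discount_origin_age=30)
        out = lifetime_outcomes(run_cohort(b.get_strategy(1), p, cfg), p, cfg)
        expected = sum(1.03 ** -t for t in range(70))
        assert out.qaly_disc == pytest.approx(expected, abs=1e-10)
        assert out.qaly == pytest.approx(70.0, abs=1e-10)

    def test_zero_rate_discounted_equals_undiscounted(self, base_params):
        cfg = AnalysisConfig(discount_rate=0.0, start_age=30, end_age=100)
        trace = run_cohort(b.get_strategy(11), base_params, cfg)
        out = lifetime_outcomes(trace, base_params, cfg)
        assert out.ly_disc == pytest.approx(out.ly, abs=1e-12)
        assert out.qaly_disc == pytest.approx(out.qaly, abs=1e-12)
        assert out.cost_disc == pytest.approx(out.cost_undisc, abs=1e-9)

    def test_surveillance_cost_arithmetic(self):
        """Immortal cancer-free cohort pays exactly 608 EUR per model year."""
        doc = zero_costs_overrides()
        doc["costs"]["surveillance"] = 608.0
        p = b.load_parameters(
            overrides={"onset": {"breast": [[20, 99, 0.0, 0.0]],
                                 "ovarian": [[20, 99, 0.0, 0.0]]}, **doc},
            mortality=constant_mortality(0.0))
        out = lifetime_outcomes(run_cohort(b.get_strategy(1), p), p)
        assert out.cost_undisc == pytest.approx(608.0 * 70, abs=1e-9)

    def test_discounted_never_exceeds_undiscounted(self, base_outcomes):
        for o in base_outcomes.values():
            assert o.ly_disc <= o.ly + 1e-12
            assert o.qaly_disc <= o.qaly + 1e-12
            assert o.cost_disc <= o.cost_undisc + 1e-9
            assert o.qaly <= o.ly + 1e-12


class TestCumulativeRisk:
    def test_zero_onset_zero_risk(self):
        p = toy_params()
        trace = run_cohort(b.get_strategy(1), p)
        assert b.cumulative_risk_by_age(trace, "breast", 70) == 0.0

    def test_single_decade_closed_form(self):
        """Constant 1% onset over ages 30-39, no deaths: risk = 1 - 0.99^10."""
        p = b.load_parameters(
            overrides={"onset": {"breast": [[20, 29, 0.0, 0.0],
                                            [30, 39, 0.01, 0.01],
                                            [40, 99, 0.0, 0.0]],
                                 "ovarian": [[20, 99, 0.0, 0.0]]}},
            mortality=constant_mortality(0.0))
        trace = run_cohort(b.get_strategy(1), p)
        risk = b.cumulative_risk_by_age(trace, "breast", 40)
        assert risk == pytest.approx(1 - 0.99 ** 10, abs=1e-12)
        assert b.cumulative_risk_by_age(trace, "breast", 99) == pytest.approx(risk, abs=1e-12)

    def test_additivity_under_mutual_exclusivity(self, base_params):
        trace = run_cohort(b.get_strategy(1), base_params)
        out = lifetime_outcomes(trace, base_params)
        total = (b.cumulative_risk_by_age(trace, "breast", 100)
                 + b.cumulative_risk_by_age(trace, "ovarian", 100))
        assert total == pytest.approx(out.cum_onset["breast"] + out.cum_onset["ovarian"],
                                      abs=1e-12)
        assert total < 1.0 + 1e-12


class TestTraceExport:
    def test_tidy_frame_roundtrip(self, base_params):
        trace = run_cohort(b.get_strategy(1), base_params)
        df = trace.to_frame()
        assert set(df.columns) == {"age", "state", "occupancy"}
        assert len(df) == len(trace.ages) * N_STATES
        per_age = df.groupby("age")["occupancy"].sum()
        assert np.abs(per_age - 1.0).max() < 1e-10
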