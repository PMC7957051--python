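"""Costing, discounting and ICER arithmetic."""

import math

import pandas as pd
import pytest

from mmcea import ParameterSet, accumulate, cycle_cost, icer
from mmcea.economics import DrugLine, RegimenSchedule
from mmcea.markov import CohortTrace


def _toy_trace(rows):
    df = pd.DataFrame(rows, columns=["cycle", "age", "m_pfs", "m_pd", "m_dead", "m_pd_inflow"])
    return CohortTrace(df)


class TestCycleCost:
    def test_death_state_costs_nothing(self, params, schedules):
        assert cycle_cost("dead", "D-VMP", 3, params, schedules["D-VMP"]) == 0.0

    def test_daratumumab_infusion_ceiling_arithmetic(self, params):
        """16 mg/kg x 79 kg = 1264 mg -> 127 billable 10-mg units -> $7,120.00."""
        line = DrugLine("daratumumab", "per_kg", 16.0, 1.0)
        assert line.cost_per_cycle(0, params) == pytest.approx(127 * 56.063)
        assert line.cost_per_cycle(0, params) == pytest.approx(7120.00, abs=0.01)

    def test_exact_dose_flag_disables_ceiling(self, params):
        line = DrugLine("daratumumab", "per_kg", 16.0, 1.0)
        exact = line.cost_per_cycle(0, params.replace(exact_dose_costing=True))
        assert exact == pytest.approx(126.4 * 56.063)

    def test_progressed_state_cost_is_pd_plus_monitoring(self, params, schedules):
        got = cycle_cost("pd", "VMP", 5, params, schedules["VMP"])
        assert got == pytest.approx(16440.419 + 481.695)
        got_d = cycle_cost("pd", "D-VMP", 5, params, schedules["D-VMP"])
        assert got_d == pytest.approx(17766.986 + 481.695)

    def test_ae_cost_applies_only_on_treatment(self, params):
        sched = RegimenSchedule("VMP", (DrugLine("melphalan", "per_m2", 9.0, 3.0, 0, 12),))
        on = cycle_cost("pfs", "VMP", 0, params, sched)
        off = cycle_cost("pfs", "VMP", 20, params, sched)
        assert on - off == pytest.approx(
            params.ae_cost_vmp + math.ceil(9.0 * 1.91 / 2) * params.cost_melphalan * 3
        )

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError, match="unknown drug"):
            DrugLine("aspirin", "flat", 100.0, 1.0)


class TestAccumulate:
    def test_zero_discount_equals_plain_sums(self, params, schedules):
        tr = _toy_trace([(c, 71 + c / 12, 1.0, 0.0, 0.0, 0.0) for c in range(13)])
        p0 = params.replace(discount_rate=0.0)
        ly, qaly, cost = accumulate(tr, p0, schedules["VMP"], "VMP")
        assert ly == pytest.approx(1.0)
        assert qaly == pytest.approx(p0.u_pfs_vmp)

    def test_unit_utilities_make_qaly_equal_ly(self, schedules):
        params = ParameterSet(u_pfs_vmp=1.0, u_pd_vmp=1.0)
        tr = _toy_trace([(c, 71.0, 0.6, 0.3, 0.1, 0.0) for c in range(25)])
        ly, qaly, _ = accumulate(tr, params, schedules["VMP"], "VMP")
        assert qaly == pytest.approx(ly)

    def test_two_cycle_toy_qaly(self, schedules):
        """One month in PFS at utility 0.6, undiscounted: QALY = 0.6/12 = 0.05."""
        params = ParameterSet(u_pfs_vmp=0.6, discount_rate=0.0)
        tr = _toy_trace([(0, 71.0, 1.0, 0.0, 0.0, 0.0), (1, 71.1, 0.0, 0.0, 1.0, 0.0)])
        _, qaly, _ = accumulate(tr, params, schedules["VMP"], "VMP")
        assert qaly == pytest.approx(0.05)

    def test_discounting_reduces_totals(self, params, schedules):
        tr = _toy_trace([(c, 71 + c / 12, 0.7, 0.2, 0.1, 0.0) for c in range(120)])
        disc = accumulate(tr, params, schedules["VMP"], "VMP")
        undisc = accumulate(tr, params.replace(discount_rate=0.0), schedules["VMP"], "VMP")
        assert all(d <= u for d, u in zip(disc, undisc))

    def test_monthly_discount_is_compound_not_divided(self, params):
        assert params.monthly_discount == pytest.approx(1.03 ** (1 / 12) - 1)
        assert params.monthly_discount != pytest.approx(0.03 / 12, abs=1e-6)

    def test_one_off_pd_cost_charges_inflow_only(self, params, schedules):
        rows = [(0, 71.0, 1.0, 0.0, 0.0, 0.0)] + [
            (c, 71 + c / 12, 0.0, 1.0, 0.0, 1.0 if c == 1 else 0.0) for c in range(1, 25)
        ]
        tr = _toy_trace(rows)
        p0 = params.replace(discount_rate=0.0)
        _, _, per_cycle = accumulate(tr, p0, schedules["VMP"], "VMP")
        _, _, once = accumulate(tr, p0.replace(pd_cost_once=True), schedules["VMP"], "VMP")
        # rows 1..23 accrue PD occupancy (the final row is the horizon
        # boundary); one-off mode instead charges the single entry at cycle 1
        assert per_cycle - once == pytest.approx(22 * p0.pd_cost_vmp)


class TestICER:
    def test_published_per_arm_totals_reproduce_reported_ratios(self):
        res = icer((7.296, 4.373, 1_139_094.0), (10.300, 6.404, 1_927_635.0))
        assert res.d_cost == pytest.approx(788_541.0, abs=1e-6)
        assert res.d_ly == pytest.approx(3.004)
        assert res.d_qaly == pytest.approx(2.031)
        assert res.icer_per_qaly == pytest.approx(388_364.0, rel=1e-3)
        assert res.icer_per_ly == pytest.approx(262_526.0, rel=1e-3)

    def test_identical_arms_are_equivalent(self):
        res = icer((5.0, 3.0, 100.0), (5.0, 3.0, 100.0))
        assert res.dominance == "equivalent"
        assert res.icer_per_qaly is None

    def test_cheaper_and_better_is_dominant(self):
        res = icer((5.0, 3.0, 100.0), (6.0, 4.0, 90.0))
        assert res.dominance == "dominant"

    def test_worse_and_costlier_is_dominated(self):
        res = icer((5.0, 3.0, 100.0), (4.0, 2.0, 190.0))
        assert res.dominance == "dominated"
        assert res.icer_per_qaly is None

    def test_qaly_never_exceeds_ly_with_unit_bounded_utilities(self, calibrated):
        pipe, _ = calibrated
        res = pipe.evaluate()
        for arm in res.strategies:
            assert res.qaly[arm] <= res.ly[arm] + 1e-9


class TestParameterSet:
    def test_defaults_reject_out_of_range_values(self):
        with pytest.raises(ValueError):
            ParameterSet(u_pd_vmp=1.2)
        with pytest.raises(ValueError):
            ParameterSet(discount_rate=0.10)
        with pytest.raises(ValueError):
            ParameterSet(hr_os=-0.5)

    def test_yaml_roundtrip(self, tmp_path, params):
        p = tmp_path / "params.yaml"
        params.to_file(p)
        assert ParameterSet.from_file(p) == params
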