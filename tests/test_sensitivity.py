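"""One-way and probabilistic sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from mmcea import default_param_specs, owsa, psa, sample_params
from mmcea.sensitivity import ParamSpec, _beta_ab


class TestParamSpec:
    def test_bounds_must_bracket_base(self):
        with pytest.raises(ValueError, match="bracket"):
            ParamSpec("x", 1.0, 1.1, 1.2)

    def test_beta_base_must_be_a_fraction(self):
        with pytest.raises(ValueError):
            ParamSpec("x", 1.5, 1.2, 1.8, dist="beta")

    def test_beta_upper_bound_above_one_warns(self):
        with pytest.warns(UserWarning, match="upper bound"):
            ParamSpec("x", 0.9, 0.7, 1.1, dist="beta")


class TestSampling:
    def test_fixed_parameters_stay_constant(self):
        spec = ParamSpec("discount_rate", 0.03, 0.0, 0.05, dist="fixed")
        draws = sample_params([spec], 50, seed=1)
        assert (draws["discount_rate"] == 0.03).all()

    def test_degenerate_bounds_collapse_to_base(self):
        spec = ParamSpec("c", 10.0, 10.0, 10.0, dist="gamma")
        draws = sample_params([spec], 20, seed=1)
        assert (draws["c"] == 10.0).all()

    def test_gamma_moment_matching_recovers_mean(self):
        spec = ParamSpec("cost_daratumumab", 56.063, 0.8 * 56.063, 1.2 * 56.063, "gamma")
        draws = sample_params([spec], 10_000, seed=3)["cost_daratumumab"]
        assert draws.mean() == pytest.approx(56.063, rel=0.02)
        assert (draws > 0).all()

    def test_beta_hazard_ratio_draws_stay_in_plausible_range(self):
        spec = ParamSpec("hr_pfs", 0.42, 0.34, 0.51, "beta", "ci95")
        draws = sample_params([spec], 10_000, seed=4)["hr_pfs"]
        assert ((draws > 0.2) & (draws < 0.7)).mean() >= 0.99

    def test_beta_moment_matching_infeasible_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            _beta_ab(0.01, 0.5, "bad")

    def test_identical_seed_is_bit_reproducible(self):
        specs = default_param_specs()
        a = sample_params(specs, 100, seed=9)
        b = sample_params(specs, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def tornado(calibrated):
    pipe, _ = calibrated
    return owsa(default_param_specs(pipe.params), pipe), pipe


@pytest.fixture(scope="module")
def small_psa(calibrated):
    pipe, _ = calibrated
    specs = default_param_specs(pipe.params)
    return psa(specs, pipe, n_draws=150, seed=11), pipe


class TestOWSA:
    def test_rows_sorted_by_descending_icer_range(self, tornado):
        df, _ = tornado
        rng = df.loc[~df["dominance"], "range"].to_numpy()
        assert (np.diff(rng) <= 1e-9).all()

    def test_pd_utility_moves_icer_monotonically(self, tornado):
        """Raising the progressed-state utility of the intervention increases
        the QALY gain, so the ICER falls: ICER(high) < base < ICER(low)."""
        df, _ = tornado
        row = df[df["parameter"] == "u_pd_dvmp"].iloc[0]
        assert row["icer_high"] < row["icer_base"] < row["icer_low"]

    def test_inert_parameters_rank_last(self, tornado):
        """Subsequent-line unit prices do not enter the default schedules, so
        their tornado range is zero and they sort to the bottom."""
        df, _ = tornado
        ranked = df.loc[~df["dominance"], "parameter"].tolist()
        assert {"cost_lenalidomide", "cost_carfilzomib"} <= set(ranked[-3:])

    def test_every_owsa_icer_exceeds_willingness_to_pay(self, tornado):
        """No single-parameter swing brings the ICER below $150,000/QALY."""
        df, pipe = tornado
        ok = df[~df["dominance"]]
        assert (ok["icer_low"] > pipe.params.wtp).all()
        assert (ok["icer_high"] > pipe.params.wtp).all()


class TestPSA:
    def test_degenerate_specs_give_step_function_ceac(self, calibrated):
        pipe, _ = calibrated
        specs = [ParamSpec("discount_rate", 0.03, 0.0, 0.05, dist="fixed")]
        res = psa(specs, pipe, n_draws=5, seed=0)
        base_icer = pipe.evaluate().icer_per_qaly
        ceac = res.ceac
        assert (ceac.loc[ceac["wtp"] < base_icer, "p_intervention"] == 0.0).all()
        assert (ceac.loc[ceac["wtp"] > base_icer, "p_intervention"] == 1.0).all()

    def test_two_strategy_acceptabilities_sum_to_one(self, small_psa):
        res, _ = small_psa
        total = res.ceac["p_intervention"] + res.ceac["p_comparator"]
        assert np.allclose(total, 1.0)

    def test_ceac_monotone_in_willingness_to_pay(self, small_psa):
        res, _ = small_psa
        assert (np.diff(res.ceac["p_intervention"]) >= -1e-12).all()

    def test_mean_incrementals_near_base_case(self, small_psa):
        """Monte-Carlo mean tracks the deterministic base case (sanity, not
        equality: the map from parameters to outcomes is nonlinear)."""
        res, pipe = small_psa
        base = pipe.evaluate()
        assert res.draws["d_qaly"].mean() == pytest.approx(base.d_qaly, rel=0.25)
        assert res.draws["d_cost"].mean() == pytest.approx(base.d_cost, rel=0.25)

    def test_seeded_psa_is_bit_reproducible(self, calibrated):
        pipe, _ = calibrated
        specs = default_param_specs(pipe.params)
        a = psa(specs, pipe, n_draws=40, seed=21)
        b = psa(specs, pipe, n_draws=40, seed=21)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)
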