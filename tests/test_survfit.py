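"""Parametric survival fitting: MLE correctness, AIC/BIC, model selection."""

import numpy as np
import pytest
from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter

from mmcea import fit_all, fit_family, select_best, simulate_arm
from mmcea.km_ipd import ReconstructedIPD
from mmcea.survfit import FAMILIES, ParametricFit, SurvivalFunction


@pytest.fixture(scope="module")
def censored_arm():
    ipd, _, _ = simulate_arm(0.02, 1.1, 200, censor_frac=0.15, seed=77)
    return ipd


class TestMLE:
    def test_exponential_data_recovers_unit_shape(self):
        """On exponential data the Weibull shape is ~1 and the rate matches
        the closed-form exponential MLE (events / total time)."""
        ipd, _, _ = simulate_arm(0.1, 1.0, 1000, censor_frac=0.0, seed=0)
        fit = fit_family(ipd, "weibull")
        assert fit.params[1] == pytest.approx(1.0, abs=0.05)
        lam_closed_form = ipd.n_events / ipd.times.sum()
        assert fit.params[0] == pytest.approx(lam_closed_form, rel=0.15)

    def test_weibull_recovery_under_censoring(self):
        """Scale and shape recovered within 15% at trial-like sample size."""
        ipd, _, _ = simulate_arm(0.03, 1.3, 356, censor_frac=0.20, seed=1)
        fit = fit_family(ipd, "weibull")
        assert fit.params[0] == pytest.approx(0.03, rel=0.15)
        assert fit.params[1] == pytest.approx(1.3, rel=0.15)

    @pytest.mark.parametrize(
        "family,Fitter",
        [("weibull", WeibullFitter), ("lognormal", LogNormalFitter),
         ("loglogistic", LogLogisticFitter)],
    )
    def test_loglik_matches_lifelines(self, censored_arm, family, Fitter):
        """Independent MLE cross-check for the families lifelines implements."""
        fit = fit_family(censored_arm, family)
        ll = Fitter().fit(np.maximum(censored_arm.times, 1e-6), censored_arm.events)
        assert fit.loglik == pytest.approx(ll.log_likelihood_, abs=1e-3)

    def test_logistic_matches_r_survreg(self, censored_arm):
        """Frozen oracle: survreg(Surv(time,event)~1, dist='logistic') on the
        same seeded dataset gives mu=31.46572, s=15.45695, loglik=-812.3066."""
        fit = fit_family(censored_arm, "logistic")
        assert fit.params[0] == pytest.approx(31.46572, rel=1e-4)
        assert fit.params[1] == pytest.approx(15.45695, rel=1e-4)
        assert fit.loglik == pytest.approx(-812.3066, abs=1e-3)

    def test_local_optimality_of_weibull_fit(self, censored_arm):
        fit = fit_family(censored_arm, "weibull")
        t = np.maximum(censored_arm.times, 1e-6)
        ev = censored_arm.events.astype(bool)

        def loglik(lam, gam):
            sf = SurvivalFunction("weibull", (lam, gam))
            return (np.log(sf.density(t[ev])).sum() + np.log(sf(t[~ev])).sum())

        best = loglik(*fit.params)
        for fl in (0.9, 1.1):
            for fg in (0.9, 1.1):
                assert loglik(fit.params[0] * fl, fit.params[1] * fg) <= best + 1e-9

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (200, 5000):
            ipd, _, _ = simulate_arm(0.03, 1.3, n, censor_frac=0.1, seed=42)
            f = fit_family(ipd, "weibull")
            errs[n] = abs(f.params[0] / 0.03 - 1) + abs(f.params[1] / 1.3 - 1)
        assert errs[5000] < 0.10
        assert errs[5000] < errs[200]

    def test_all_censored_data_rejected(self):
        ipd = ReconstructedIPD([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            fit_family(ipd, "weibull")


class TestInformationCriteria:
    def test_bic_minus_aic_identity(self, censored_arm):
        """For k=2 parameters, BIC - AIC = 2*(ln n - 2) exactly."""
        for fam in FAMILIES:
            f = fit_family(censored_arm, fam)
            assert f.bic - f.aic == pytest.approx(2 * (np.log(f.n) - 2), abs=1e-9)
            assert f.aic == pytest.approx(4 - 2 * f.loglik, abs=1e-9)

    def test_survival_functions_are_valid(self, censored_arm):
        t = np.linspace(0, 200, 400)
        for fam in FAMILIES:
            s = fit_family(censored_arm, fam).survival(t)
            assert s[0] == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(s) <= 1e-12).all()
            assert s.min() >= 0 and s.max() <= 1


def _fit(family, aic, bic):
    ll = (4 - aic) / 2
    return ParametricFit(family, (0.1, 1.0), ll, aic, bic, n=356)


class TestSelection:
    def test_reported_aic_pattern_selects_weibull(self):
        """The published progression-free-survival AIC column: Weibull wins."""
        fits = [
            _fit("weibull", 2329.102, 2336.858),
            _fit("lognormal", 2381.626, 2389.382),
            _fit("loglogistic", 2355.820, 2363.576),
            _fit("logistic", 2423.814, 2431.570),
        ]
        assert select_best(fits).family == "weibull"

    def test_single_fit_returns_itself(self):
        f = _fit("lognormal", 100.0, 105.0)
        assert select_best([f]) is f

    def test_aic_tie_broken_by_bic_then_family_order(self):
        a = _fit("lognormal", 100.0, 104.0)
        b = _fit("loglogistic", 100.0, 103.0)
        assert select_best([a, b]).family == "loglogistic"
        c = _fit("weibull", 100.0, 103.0)
        assert select_best([a, b, c]).family == "weibull"

    def test_weibull_truth_selected_in_most_replicates(self):
        """Short selection study; the full 100-replicate version lives in the
        acceptance suite."""
        wins = sum(
            select_best(fit_all(simulate_arm(0.03, 1.3, 356, censor_frac=0.2,
                                             seed=6000 + s)[0])).family == "weibull"
            for s in range(20)
        )
        assert wins >= 17
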