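"""Fit the four candidate survival families and pick the best by AIC.

Reconstructs pseudo-IPD from a synthetic digitized curve and fits Weibull,
log-normal, log-logistic and logistic models by right-censored maximum
likelihood, mirroring the model-selection step of the analysis.
"""

from mmcea import fit_all, reconstruct_ipd, select_best, simulate_arm

_, curve, risk = simulate_arm(0.03, 1.3, n=356, censor_frac=0.20, seed=1)
ipd = reconstruct_ipd(curve, risk)

fits = fit_all(ipd)
best = select_best(fits)
print(f"{'family':12s} {'AIC':>10s} {'BIC':>10s}")
for f in sorted(fits, key=lambda f: f.aic):
    mark = "  <- selected" if f.family == best.family else ""
    print(f"{f.family:12s} {f.aic:10.3f} {f.bic:10.3f}{mark}")
lam, gam = best.params
print(f"\nselected Weibull S(t) = exp(-{lam:.4f} * t^{gam:.3f})  (truth: 0.0300, 1.300)")
# The generating family should win on AIC, and the fitted scale-rate/shape
# should sit near the simulating values despite digitization + reconstruction.
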