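"""Invert a digitized Kaplan-Meier curve back into pseudo patient records.

Simulates a trial arm from known Weibull truth, 'digitizes' its KM curve the
way one would from a published figure (step values at click points plus a
number-at-risk table), reconstructs per-patient (time, event) records, and
reports how closely the recomputed KM curve tracks the digitized one.
"""

from mmcea import km_estimate, reconstruct_ipd, simulate_arm
from mmcea.km_ipd import roundtrip_error

truth_lam, truth_gam = 0.05, 1.2
ipd_true, curve, risk = simulate_arm(truth_lam, truth_gam, n=356,
                                     censor_frac=0.15, grid_size=40, seed=3)

ipd = reconstruct_ipd(curve, risk)
print(f"digitized points: {len(curve.times)}, risk anchors: {len(risk.times)}")
print(f"true events: {ipd_true.n_events}, reconstructed events: {ipd.n_events}")
print(f"max |KM(reconstructed) - digitized| = {roundtrip_error(curve, ipd):.4f}")
km = km_estimate(ipd)
print(f"reconstructed KM at 12 months: {km.step_at([12.0])[0]:.3f} "
      f"(digitized: {curve.step_at([12.0])[0]:.3f})")
# A deviation well under 0.02 means the pseudo-IPD carries the same survival
# information as the published figure, so parametric models can be refitted.
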