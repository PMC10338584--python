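"""Fit a lognormal to week-12/baseline LDL-C response ratios.

Generates synthetic patient-level ratios at the two pooled-trial sample
sizes (n=1922 and n=399), fits by maximum likelihood, and shows the
recovered log-parameters against the generating truth.
"""

from lltsim import EfficacyPoolRule, fit_lognormal_ratios, generate_trial_ratios

rule = EfficacyPoolRule.default()
for name, pool, n in [
    ("moderate/high-statin pool", rule.pool_moderate_high, 1922),
    ("no/low-statin pool       ", rule.pool_none_low, 399),
]:
    ratios = generate_trial_ratios(pool, n=n, seed=7)
    fit = fit_lognormal_ratios(ratios)
    print(f"{name} (n={n}):")
    print(f"  truth      log_mean={pool.log_mean:+.4f}  log_sd={pool.log_sd:.4f}")
    print(f"  recovered  log_mean={fit.log_mean:+.4f}  log_sd={fit.log_sd:.4f}")
    print(f"  error      {abs(fit.log_mean - pool.log_mean):.4f} / "
          f"{abs(fit.log_sd - pool.log_sd):.4f}\n")
print("errors shrink as 1/sqrt(n): the larger pool recovers ~2x more tightly.")
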