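"""Calibration and power of the sympatry-allopatry comparison.

Checks that the nominal 5% tests reject about 5% of the time when the
two contexts truly share the same preference bias, then asks how often a
context effect of a given standardized size (Cohen's d) is detected.
"""

from reinfiso.calibration import null_rejection_rates, power_context_effect

cal = null_rejection_rates(n_per_group=18, n_sims=1000, seed=0)
print(f"Type-I error at n=18/group (nominal 0.05): "
      f"Mann-Whitney {cal.mann_whitney_rate:.3f}, context F {cal.context_f_rate:.3f}")

for d in (0.44, 0.75):
    p = power_context_effect(d, n_per_group=36, n_sims=500, seed=0)
    print(f"power to detect context effect d={d:.2f} at n=36/group: {p:.2f}")

print("A medium effect (d≈0.75, the female-sized contrast) is detected far "
      "more often than a small one (d≈0.44, the male-sized contrast) at the "
      "same sample size — matching a study that finds the signature "
      "significant in females but not males.")
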