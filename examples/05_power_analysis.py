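"""Minimal detectable attentional effect for the 28 paired distances.

With n = 8 stimuli there are n(n-1)/2 = 28 unique response distances.  A
two-sided one-sample z-test on the paired distance differences between two
attentional conditions, at alpha = 0.05 and target power 0.8, can detect an
effect of (z_0.975 + z_0.8) * sd / sqrt(28).
"""

from attnspace import PowerSpec, minimal_detectable_effect, power_of_effect

for sd_pct in (10.0, 20.0, 40.0):
    spec = PowerSpec(n=28, alpha=0.05, target_power=0.8, sd=sd_pct)
    delta = minimal_detectable_effect(spec)
    print(f"sd = {sd_pct:5.1f}% of mean distance -> minimal detectable "
          f"effect {delta:5.2f}%  (power at that effect: "
          f"{power_of_effect(delta, spec):.3f})")

spec = PowerSpec(n=28, alpha=0.05, target_power=0.8, sd=1.0)
print(f"\nstandardized (sd = 1): delta = {minimal_detectable_effect(spec):.5f}")
print("Effects smaller than delta would be missed more than 20% of the time "
      "at this sample size.")
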