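"""Score summiting per fly (summit metric) and compare two groups.

SM is the time-averaged, baseline-corrected speed over the summiting window
(which opens 2.5 h before death). The group comparison is the relative
effect (mean_exp - mean_ctrl) / mean_ctrl with a bootstrap distribution;
-1 means summiting is abolished.
"""

import numpy as np

from flysummit import GeneratorConfig, bootstrap_effect, cohort_sms, gen_cohort

ctrl = gen_cohort(GeneratorConfig(n_zombie=100, seed=21))
# same flies with every speed scaled by 1.5: true SM ratio exactly 1.5
exp = gen_cohort(GeneratorConfig(n_zombie=100, seed=21, speed_multiplier=1.5))

ctrl_sms = [r.sm for r in cohort_sms(ctrl).values()]
exp_sms = [r.sm for r in cohort_sms(exp).values()]
print(f"control: n={len(ctrl_sms)}, mean SM = {np.mean(ctrl_sms):.3f} mm/s")
print(f"experimental: n={len(exp_sms)}, mean SM = {np.mean(exp_sms):.3f} mm/s")

res = bootstrap_effect(exp_sms, ctrl_sms, n_boot=1000, rng=np.random.default_rng(1))
lo, hi = np.percentile(res.boot_effects, [2.5, 97.5])
print(f"relative effect = {res.effect_mean:+.3f} "
      f"(bootstrap 95% CI [{lo:+.3f}, {hi:+.3f}], t-test p = {res.p_value:.2e})")
print("the effect recovers the built-in +0.5 (SM ratio 1.5); per-fly SM is "
      "highly dispersed, so group sizes near 100 are needed for tight CIs.")
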