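"""Generate a synthetic cohort and summarize its circadian death timing.

Zombies (flies killed by the fungus) die on a circadian gate: the default
generator draws death times with mean ZT9:50 and ~90% of mass between ZT7
(mid-morning) and ZT12 (lights off).
"""

import numpy as np

from flysummit import GeneratorConfig, death_time_summary, gen_cohort

cfg = GeneratorConfig(n_zombie=40, n_survivor=40, n_unexposed=10, seed=0)
cohort = gen_cohort(cfg)

classes = [rec.fly_class for _, rec in cohort]
print(f"cohort: {len(cohort)} flies "
      f"({classes.count('zombie')} zombies, {classes.count('survivor')} survivors, "
      f"{classes.count('unexposed')} unexposed)")

summary = death_time_summary(cohort)
print(f"zombie deaths: mean ZT{summary['mean_zt']:.2f}, "
      f"central 90% in [ZT{summary['p5_zt']:.2f}, ZT{summary['p95_zt']:.2f}]")
print("with 40 zombies the sample moments wobble around the calibration "
      "targets (ZT9.83, [ZT7, ZT12]); they converge at larger n.")

speeds = np.concatenate([tr.speed for tr, rec in cohort if rec.fly_class == "zombie"])
print(f"max per-frame zombie speed: {speeds.max():.1f} mm/s "
      "(clean tracks never cross the 40 mm/s artifact threshold)")
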