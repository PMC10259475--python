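"""Call times of death and build death-aligned cohort speed traces.

Death is the last observed walking bout. Survivors get fictive death times
resampled from the zombie pool so both classes can be compared on a common
death-relative clock. The zombie trace shows the summiting signature: low
baseline speed until ~2.5 h before death, then a burst peaking ~1 h before.
"""

import numpy as np

from flysummit import (
    GeneratorConfig,
    align_to_death,
    assign_fictive_death,
    detect_death,
    gen_cohort,
)

cohort = gen_cohort(GeneratorConfig(n_zombie=30, n_survivor=30, seed=8))

errors = []
for traj, rec in cohort:
    if rec.fly_class == "zombie":
        det = detect_death(traj)
        errors.append(abs(det.frame - rec.death_frame) / 3.0)
print(f"automated death calls on 30 zombies: median |error| = "
      f"{np.median(errors):.1f} s vs generator ground truth")

rng = np.random.default_rng(0)
aligned = align_to_death(assign_fictive_death(cohort, rng), n_boot=200, rng=rng)
rel = aligned.rel_time_h
for cls in ("zombie", "survivor"):
    mean = aligned.mean_speed[cls]
    pre = np.nanmean(mean[(rel >= -12) & (rel <= -2.5)])
    peak_i = np.nanargmax(np.convolve(np.nan_to_num(mean), np.ones(901) / 901, "same"))
    print(f"{cls}: pre-burst mean speed {pre:.2f} mm/s; "
          f"5-min-smoothed peak at {rel[peak_i]:+.2f} h relative to death")
print("zombies sit near 0.18 mm/s then peak shortly before death; "
      "survivor peaks reflect crepuscular activity, not summiting.")
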