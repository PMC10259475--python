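"""Flag and repair wall-tracking artifacts.

Centroid trackers sometimes lock onto the arena's long edges, producing
single-frame teleports whose implied speed is impossible (> ~40 mm/s). A
trajectory with more than 20 such frames per tracked day is flagged; repair
narrows the accepted x-interval until the flag clears, mimicking trimming
the tracker's region of interest.
"""

import numpy as np

from flysummit import GeneratorConfig, flag_noisy, gen_cohort, inject_tracking_noise, repair

cohort = gen_cohort(GeneratorConfig(n_zombie=1, seed=3))
traj = cohort.trajectories[0]
print(f"clean trajectory: {flag_noisy(traj).violations_per_day:.1f} violations/day "
      f"-> {flag_noisy(traj).action}")

noisy = inject_tracking_noise(traj, spikes_per_day=30, spike_speed=50,
                              rng=np.random.default_rng(0))
report = flag_noisy(noisy)
print(f"after injecting 30 spikes/day: {report.violations_per_day:.1f} violations/day "
      f"-> {report.action}")

fixed, rep = repair(noisy)
print(f"repair: action={rep.action}, width retained={rep.width_retained:.2f}, "
      f"residual rate={rep.violations_per_day:.1f}/day")
print("the repaired track keeps >90% of the arena width because the spikes "
      "sit at the walls; artifacts spread across x would force a discard.")
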