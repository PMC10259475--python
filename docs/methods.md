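# Methods

This note documents the models, parameter choices and numerical conventions
behind `flysummit`, and what validation on synthetic cohorts does and does
not establish.

## Data model and units

A trajectory is one fly's time series at a nominal 3 Hz: time in seconds
from the first tracked frame, x (mm, across the 5-mm arena width), y_rel
(position along the 65-mm gravity axis rescaled to [0, 1], 0 at the food
end regardless of physical orientation), per-frame speed (mm/s), and a
validity mask. Lost-tracking frames are masked, never dropped, so frame
indices stay aligned with death annotations. Zeitgeber time of a frame is
`(zt0 + t/3600) mod 24`; recordings start in the evening (default
zt0 = ZT19). Speed is derived from positions: Euclidean displacement from
the nearest preceding valid frame divided by elapsed time, so masked gaps
are bridged rather than interpolated and cannot create artificial spikes.

## Synthetic cohorts

The generator provides ground truth for every downstream stage. It is a
statistical emulation of arena behavior, not a biomechanical model.

**Death times.** Zombie deaths are circadian-gated. The distribution is a
skew-normal on ZT hours with parameters solved numerically so that the mean
is 9.8333 h (ZT9:50), the 5th percentile 7 h and the 95th percentile 12 h;
the frozen solution is a = −3.0012844, loc = 11.6161294, scale = 2.3552113.
Only these three facts constrain the shape; the skew-normal family is this
package's choice. Draws outside the tracked window are redrawn (bounded).

**Locomotion.** A two-state move/rest renewal process at frame resolution:
geometric bout lengths (mean moving bout 5 s), rest→move hazard set so the
stationary moving fraction tracks a per-epoch target (0.25 for resting
zombies, ramping to 0.8 in the burst; 0.5 for survivors). Because geometric
bouts are memoryless, initializing from the instantaneous moving fraction
makes the chain stationary from frame 0, so the unconditional mean speed
equals the envelope exactly wherever the envelope is flat. While moving,
per-frame speed is log-normal (σ = 0.6) with conditional mean
envelope/moving-fraction. Each fly also gets a uniform activity multiplier
on [0.7, 1.3] (mean 1), so cohort means keep their calibration while
individual survivors and pre-burst zombies overlap behaviorally — without
this overlap a classifier separates the classes from the first frames,
which real cohorts do not allow.

**Zombie speed envelope.** Baseline 0.18 mm/s until 2.5 h before death,
linear rise to 0.87 mm/s at −1.4 h, flat top through −0.6 h, linear fall to
0 at death, zero afterwards. The envelope passes through the three
calibration landmarks (0.18 mm/s pre-burst, 0.87 mm/s at −1 h, 0 at death).
The flat top is deliberate: the headline "peak ≈ 0.87 mm/s" must survive
the same 1-h sliding-window smoothing the analysis applies, and a sharp
triangular peak smooths down to ~0.70 mm/s, whereas this shape smooths to
≈ 0.86 with its maximum near −1 h. Each zombie ends with a short forced
walking bout (12 frames at 0.7–0.9 mm/s) terminating exactly at the true
death frame — death is *defined* as the last observed walking, so the
generator makes that definition concrete and recoverable. After death the
centroid is frozen at the death position plus Gaussian jitter
(sd = 0.02 mm), small enough that jitter speed essentially never crosses
the 0.5 mm/s walking threshold.

**Survivor envelope.** Crepuscular: Gaussian bumps (σ = 1.2 h) at ZT0 and
ZT12 rising from a 0.25 mm/s base to a 0.8 mm/s peak mean speed. Only the
~0.8 mm/s peak is externally calibrated; the base level and bump width are
this package's choices and are not validated against real data.

**Positions.** Step lengths are speed·dt, split into lengthwise and
crosswise components with mostly-lengthwise headings (narrow corridor);
signed steps accumulate and are triangle-folded into residence bands: a
24-mm food-proximal band for resting zombies gliding up to a summit band
([40, 64] mm) across the burst rise, and per-fly mid-arena bands for
survivors. Folding alters a displacement only when a band edge is crossed
within one step, so derived speed stays within ~1% of the drawn speed —
measured cohort landmarks come out at ≈ 0.179 and ≈ 0.85 mm/s against
nominal 0.18 and 0.87. Reflecting bands (rather than biased walks against
walls) avoid wall pile-ups that would otherwise bleed speed near the
boundaries. The final bout is laid down as a straight run toward the band
center so edge-folding can never shave it below the walking threshold.

**Tracking noise.** Injected artifacts are single-frame teleports to a side
wall displaced far enough along the arena to imply ≥ 50 mm/s (default),
emulating edge-tracking failures; clean generator output never exceeds
40 mm/s. The injection rate is per tracked day; speeds are re-derived so
positions and speeds stay consistent.

**Determinism.** One child random stream per fly is spawned from the master
seed, so cohorts are bit-reproducible regardless of generation order. The
optional `speed_multiplier` scales the final speed channel, giving exactly
linear SM scaling for effect-size validation.

## Denoising

A trajectory is flagged when frames faster than 40 mm/s exceed 20 per
tracked day (strict inequality at the boundary). Repair emulates trimming
the tracker's region of interest: each iteration removes 5% of the current
accepted x-interval (half per side), masks frames outside it, re-derives
speed across the gaps, and recounts violations on the recomputed speed;
it stops when the flag clears or the retained width falls below 9/50
(≈ 0.18) of the original — the analogue of a nine-pixel floor on a ~50-px
arena image — at which point the fly is discarded. Because a gap-bridged
speed is a time-weighted average of the displacements it replaces, repair
can never raise the maximum frame speed, and the valid set only shrinks.

## Mortality analysis

`detect_death` automates "time of last walking": bouts are maximal runs of
speed ≥ 0.5 mm/s; a bout counts as walking if it lasts ≥ 2 s; death is the
last frame of the last walking bout. If that bout reaches into the final
10 min of recording, the fly is considered still alive (right-censoring
guard). The 0.5 mm/s / 2 s defaults were validated against generator
ground truth (≥ 99 of 100 default zombies recovered within ±2 min); manual
annotations always override detection. Fictive deaths for survivors are
drawn with replacement from the same-genotype zombie pool (replacement
keeps small pools usable). Death-aligned traces are per-frame class means
over a death-relative window (default 12 h); uncertainty bands are ±1 SD
of fly-bootstrapped means (default 1000 replicates), computed via
resampling weights so band computation is O(n_boot × frames).

## Summit metric

The window start is exactly death − 2.5 h (flies with less pre-death data
are excluded with a reason). Smoothing is a centered 1-h moving average
over valid frames, truncated at the series edges; with 10,800 frames per
window the interior response to a unit impulse is 1/10800. The smoothed
trace must strictly exceed baseline + 1e-9 mm/s before a return crossing
can close the window (avoiding a zero-length window from equality at
onset); if it never exceeds, the window is empty and SM = 0; if it never
returns, the window runs to the end of the recording — which may be after
death, a consequence of smoothing lag that is allowed deliberately. The
integrand is the *raw* (unsmoothed) baseline-corrected speed, integrated
by trapezoid over valid frames; smoothing only sets the baseline and the
window end. This is the most literal reading of the definition and is
flagged here as an interpretation. Note that per-fly SM is noisy by
construction: the first-return rule is a stopping time on a noisy smoothed
trace, so some flies close the window early and SM values near or below
zero occur; this matches the wide per-fly SM spread seen in real assays
and is why group comparisons bootstrap over ~100 flies.

Bootstrap effects resample experimental and control groups independently
(1000 replicates by default — a printed "1,00 resamplings" in the source
description is read as 1000); the point estimate uses the original samples
and significance is a two-tailed unpaired Welch t-test.

## Classifier

Labels: survivors are `never` at every frame; zombies are `pre` before
summiting onset, `during` from onset to death, `post` after. Onset
defaults to death − 2.5 h when no manual annotation exists, matching the
summiting-window definition. Features are causal by construction (nearest
valid frame at or before the requested time): observation hour, then y and
speed at 10 lookbacks geometric in time-before-observation between the
experiment start and 10 min (feature 2 = initial y, feature 11 = y ten
minutes ago), then y and speed at 20 uniform times over the last 10 min
(features 41/61 = current y/speed). Observation times are sampled
uniformly per fly (default 200) from 10 min after start — earlier times
have no full recent window — to the end of recording. The forest uses 300
trees, default depth, class-frequency-balanced subsampling; the train /
validation split (75/25) is stratified *by fly* so no fly contributes to
both sides. Hyperparameters are this package's choices; no search harness
is included.

## Real-time stage

Classification runs every 240 s — chosen so that the three-consecutive-
frame rule spans exactly 8 min — starting at the first multiple of the
period at least 10 min into the recording. A zombie flag fires at the
third consecutive frame with P(during) strictly above P(never); equality
breaks the streak. Causality is testable: predictions on a truncated
trajectory are bit-identical to the full run's prefix. The non-summiting
control score multiplies mean never-probability, one minus max
during-probability, an at-least-10%-of-frames-moving indicator (threshold
0.5 mm/s, shared with death detection), and the fly's current speed
percentile across the cohort at the current frame (cohort-wise rather than
self-history; switchable). Control selection takes the top five unflagged
flies, ties broken by fly id. Alerts are returned as event records (log
sink); no messaging infrastructure is included.

## What synthetic validation shows — and does not

Passing tests establish that the implementation computes what it claims:
calibration targets are recovered, the SM matches independent integration
to 1e-6 on the frozen noiseless burst, known effect sizes are recovered,
and the flag rule has its stated timing. They do *not* establish field
performance: synthetic zombies are more stereotyped than real ones (the
classifier reaches near-perfect held-out precision here, which real data
will not reproduce), pre-summiting cues are still somewhat stronger than
in real cohorts (real-time flags often land tens of minutes before nominal
onset), the survivor envelope away from its peak is uncalibrated, and
tracking noise beyond single-frame wall spikes (e.g. sustained occlusions)
is not modeled. Problem sizes in the test-suite were chosen to keep runs
desk-scale: 10,000 death-time draws, 200-zombie cohorts for aligned
traces, 100 flies per group for effect recovery, 100 zombies for death
detection, and reduced cohorts (tens of flies) for classifier end-to-end
checks.
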