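"""Train the summiting classifier and replay it as a real-time detector.

Each fly's history is summarized in 61 causal features (observation time,
log-spaced historical y/speed, 20-point recent y/speed). A random forest
predicts one of four states: never / pre / during / post summiting. In the
real-time replay a fly is called a zombie when P(during) > P(never) on
three consecutive 240-s classifications (an 8-minute span).
"""

import numpy as np

from flysummit import (
    GeneratorConfig,
    gen_cohort,
    run_realtime,
    sample_training_set,
    score_realtime,
    train,
)

cohort = gen_cohort(GeneratorConfig(n_zombie=12, n_survivor=18, seed=33))
training = sample_training_set(cohort, n_per_fly=100, rng=np.random.default_rng(0))
model, report = train(training, rng=np.random.default_rng(1), n_trees=150)
print(f"trained on {len(training)} examples; held-out recall per class: "
      + ", ".join(f"{c}={v:.2f}" for c, v in sorted(report.recall.items())))

# replay on a fresh cohort the model has never seen
test = gen_cohort(GeneratorConfig(n_zombie=12, n_survivor=18, seed=34))
_, events = run_realtime(test, model, period_s=240.0)
summary = score_realtime(events, test.records)
print(f"real-time calls: precision={summary['precision']:.2f}, "
      f"recall={summary['recall']:.2f}, "
      f"median flag time = {summary['latency_median_s']/60:+.0f} min "
      "relative to nominal summiting onset (death - 2.5 h)")
print("zombies are called around the onset of summiting -- often slightly "
      "before it, because synthetic pre-summiting flies already carry "
      "food-proximal low-activity cues that real flies show more weakly.")
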