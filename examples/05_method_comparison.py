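"""Significance protocols: paired half-subsample tests and the null interval.

Two predictions at different noise levels are compared with a paired t-test
over 100 random 50% subsets, and each is placed against the shuffle null's
99.9% interval.
"""

from ionml import (
    SyntheticSpec,
    compare_methods,
    compare_to_random,
    gen_benchmark,
    gen_propensities,
    predict_dataset,
)

dataset = gen_benchmark(SyntheticSpec(seed=7))
truth = dataset.truth_map()

pred_good = predict_dataset(dataset, gen_propensities(dataset, noise=0.3, seed=1))
pred_poor = predict_dataset(dataset, gen_propensities(dataset, noise=0.9, seed=1))

result = compare_methods(truth, pred_good, pred_poor, n_splits=100, frac=0.5,
                         alpha=0.001, seed=2, method_a="noise-0.3", method_b="noise-0.9")
print("paired comparison over 100 half-subsets (verdict: + means A better):")
for name, comp in result.metrics.items():
    print(f"  {name:<9} A={comp.mean_a:5.1f}  B={comp.mean_b:5.1f}  "
          f"diff={comp.mean_diff:+6.2f}  p={comp.p_value:.2e}  verdict {comp.verdict}")

versus_null = compare_to_random(truth, pred_poor, reps=1000, seed=3)
print("\nnoise-0.9 prediction vs the shuffle null (99.9% interval):")
print("  overall verdicts:", versus_null["overall"])

# a verdict of '=' against the null means the prediction is statistically
# indistinguishable from shuffling the annotations
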