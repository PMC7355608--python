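# ionml — multi-label prediction of ion channels, their types and subtypes

Ion channels are membrane proteins classified by gating mechanism
(voltage- vs ligand-gated) and by the transported ion (Na⁺, K⁺, Ca²⁺,
anions). Some channels transport several ion types, so their annotation is
inherently **multi-label**: a protein carries a set of labels drawn from a
nine-label universe — `non-ion` plus the eight (gating × ion) channel
labels. `ionml` is a toolkit for building, evaluating and stress-testing
*sequential multi-label* predictors of this taxonomy. It is aimed at
computational biologists who work with channel-prediction pipelines and
need the aggregation rule, the evaluation protocol and the null models in
one tested, scriptable package.

## The method

Three base models provide propensities in [0, 1] for a protein *p*:
`p_ion` (channel vs non-channel), `p_voltage` (voltage- vs ligand-gated;
the ligand propensity is `1 − p_voltage`) and `p_subtype[s]` for the four
ion subtypes. The sequential multi-label rule aggregates them:

1. if `p_ion < 0.5`, predict `{non-ion}`;
2. otherwise form the eight subtype scores
   `score(T, s) = p_T · p_subtype[s]`, sort them, take the gating type *T\**
   of the highest-scoring non-zero combination, and output every non-zero
   `(T*, s)` as the label set.

A single-label mode stops at the top-scoring combination. Predictions are
scored with the example-based multi-label metrics over a dataset
*D* = {(pᵢ, lᵢ)} with predictions zᵢ:

```
Accuracy  = 1/|D| Σ |lᵢ∩zᵢ|/|lᵢ∪zᵢ|      Precision = 1/|D| Σ |lᵢ∩zᵢ|/|zᵢ|
Recall    = 1/|D| Σ |lᵢ∩zᵢ|/|lᵢ|         F1 = 2·P·R/(P+R)
```

The package also implements a domain-content baseline (label transfer via
shared Pfam accessions between test proteins and per-label training domain
sets), the label-shuffling null predictor with its closed-form per-label
expectation `100·n_L/N`, and the two significance protocols used in this
field: position against the null's 99.9% interval over 1000 shuffles, and
paired t-tests over 100 random 50% subsamples. A synthetic generator
produces benchmark-shaped datasets (221 proteins, 111 non-ion, 110 channels
carrying 180 subtype labels, 29 multi-label; mean cardinality 1.32),
propensity streams with a noise dial from perfect to random, and paired
synthetic domain annotations.

## Worked example

```python
from ionml import (SyntheticSpec, gen_benchmark, gen_propensities,
                   predict_dataset, evaluate, shuffle_baseline)

dataset = gen_benchmark(SyntheticSpec(seed=7))   # 221 proteins, preset marginals
truth = dataset.truth_map()
scores = gen_propensities(dataset, noise=0.5, seed=11)
pred = predict_dataset(dataset, scores, mode="multi")
print(evaluate(truth, pred).overall)
print({k: round(v.mean, 1) for k, v in shuffle_baseline(truth, 1000, seed=3).overall.items()})
```

prints

```
OverallMetrics(accuracy=70.58..., precision=70.58..., recall=100.0, f1=82.75...)
{'accuracy': 29.9, 'precision': 31.5, 'recall': 31.5, 'f1': 31.5}
```

At noise 0.5 the propensities still rank the true gating type first for
almost every channel but over-predict subtypes, so recall stays at 100
while precision drops to ~71; the shuffle null's ~31.5 shows how much of
that F1 is signal rather than label-frequency artefact. The scripts in
`examples/` walk through each capability (generation, prediction and
evaluation, null baselines, the domain baseline, significance testing).

A thin CLI mirrors the library:

```bash
ionml synth benchmark --seed 7 --out-labels labels.tsv
ionml synth scores --labels labels.tsv --noise 0 --seed 1 --out scores.json
ionml predict --scores scores.json --labels labels.tsv --out preds.tsv
ionml evaluate --truth labels.tsv --pred preds.tsv
```

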