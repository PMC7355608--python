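# Methods

## Label taxonomy and data model

The label universe has nine members: `non-ion` and the eight channel labels
obtained by crossing gating type (voltage- vs ligand-gated) with the
transported-ion subtype (sodium, potassium, calcium, anion). A protein's
annotation is a non-empty label set obeying two structural rules: `non-ion`
is exclusive, and all channel members of one annotation share a single
gating type (channels are curated with one gating mechanism, possibly
several ion selectivities, so cardinalities run 1–4). A canonical total
order — `non-ion`, then the voltage block, then the ligand block, each
ordered Na, K, Ca, anion — fixes serialization and every tie-break.

The domain-content baseline is the one deliberate exception: its transfer
rule can fire across gating types, so its outputs use a *relaxed* label-set
variant that lifts the single-gating constraint (still excluding `non-ion`
from mixed sets). Evaluation treats relaxed and strict sets identically;
they serialize with a `mixed` type token.

## Sequential aggregation rule

A profile holds `p_ion`, `p_voltage` and four subtype propensities, all
independent values in [0, 1] (no normalization across subtypes is assumed;
upstream binary discriminators need one scalar each, hence ligand = 1 −
voltage). Prediction: if `p_ion` is below the decision threshold (default
0.5, configurable — a propensity threshold stands in for the upstream
classifier's decision function, keeping the branch model-agnostic), output
`{non-ion}`. Otherwise the eight products `p_gating · p_subtype[s]` are
sorted descending with ties broken by canonical order; the gating type of
the best combination with score above `zero_tol` (default 1e-9, guarding
against floating-point dust) wins, and every non-zero combination of that
gating type is emitted. Restricting the output to the winning gating type
keeps predictions consistent with the single-gating annotation rule.

Two boundary choices were genuinely open and are package decisions:

* **All-zero fallback.** If the channel branch fires but every combination
  is numerically zero, the tie-ordered top combination is returned as a
  singleton rather than `{non-ion}` — the first stage has already committed
  to "ion channel", and contradicting it would let numerical dust flip a
  categorical decision.
* **Ties** are resolved by the canonical order so identical inputs always
  produce identical outputs.

The implementation is verified against an independent brute-force oracle
that enumerates all 2⁸ combination subsets and keeps the unique subset that
is non-zero, single-gating, contains the top combination and is maximal.

## Metrics

Overall metrics are example-based set-overlap ratios (Jaccard accuracy,
precision |l∩z|/|z|, recall |l∩z|/|l|) averaged over proteins and reported
as percentages; F1 is the harmonic mean of the *aggregate* precision and
recall, not an average of per-example F1 values — the identity
2·53.4·58.3/(53.4+58.3) = 55.7 on the published aggregates confirms this
reading. Per-label metrics count proteins: recall_L is the fraction of
truth carriers of L that are predicted with L, precision_L the fraction of
predicted carriers that truly carry it; zero-denominator ratios are
reported as 0 with an `undefined` flag rather than NaN. The domain
baseline's summary metric is the average correct-prediction rate: the mean
of |l∩z|/|z| over the truth carriers of a label.

## Null models and significance

The random baseline permutes the truth label sets uniformly across proteins
and re-evaluates every metric per repetition (default 1000, seeded). Whole
sets are permuted, not individual labels, preserving the cardinality
distribution. Under a uniform permutation the probability that any protein
receives a set containing L is the prevalence n_L/N, giving the closed-form
expectation 100·n_L/N for per-label recall and precision; the simulation is
required to agree with it within four standard errors.

The reported 99.9% interval is a **distribution interval**, mean ±
z(0.999)·sd over the repetitions, not a standard-error band: the interval
is used to judge whether a *single* method's metric is distinguishable from
a *single* draw of the null, for which the per-repetition spread is the
relevant scale (an SE band would shrink to ±~0.3 points at 1000 repetitions
and declare essentially any method "different from random", including ones
weaker than the null's own spread). The standard error is stored alongside
for convergence checks against the closed form.

Method-vs-method comparison evaluates both predictions on the same random
⌊N/2⌋-protein subset, repeated 100 times without stratification, and
applies a two-sided paired t-test per metric at α = 0.001, the sign of the
mean difference giving the direction. All-identical differences yield p = 1
with a zero-variance flag ("=": no evidence of a difference), avoiding a
0/0 t statistic.

## Domain-content baseline

Training domain sets are unions of the domain accessions of each channel
label's training proteins (version suffixes stripped at parse; matching is
exact on the family accession — clan-level grouping is out of scope). A
test protein receives every label whose set intersects its domains, and
`non-ion` when nothing intersects or it has no domains. Labels with no
training domains produce a warning, not an error, since an empty set is a
legitimate (if useless) model.

## Synthetic generator

`gen_benchmark` realizes exact label marginals. Defaults are the published
benchmark's structure: 111 non-ion, 110 channels, subtype label counts
19/26/28/22 (voltage Na/K/Ca/anion) and 20/18/41/6 (ligand), 29 multi-label
proteins — totals 221 proteins, 291 labels, mean cardinality 1.3167 ≈ 1.32,
median 1. Only marginals are published, so per-protein combinations are
sampled: the generator searches all (voltage-channel, voltage-multi-label)
splits that pass per-block feasibility — extras within [m, 3m] and the
Gale–Ryser realizability conditions for the evenly spread cardinality
sequence against the subtype counts — picks one split at random, spreads
the extra labels as evenly as possible over the multi-label proteins (2–4
labels each, evenness maximizes realizability), and assigns subtypes
largest-remaining-first with seeded tie shuffles. Infeasible requests fail
with the violated inequality. Decoy sequences (uniform random 100–600 aa)
are attached purely for FASTA round-trips and carry no signal.

`gen_propensities` mixes a noise-free truth encoding (`p_ion` = 1 for
channels else 0, `p_voltage` = 1/0 by gating, subtype indicators) with
i.i.d. uniform draws: value = (1−noise)·clean + noise·U(0,1). Noise 0 is
recovered exactly by the aggregation rule; noise 1 is pure noise whose F1
lands inside the shuffle null's 99.9% interval. One consequence worth
knowing: at any intermediate noise all four subtype propensities are almost
surely non-zero, so channel predictions become full gating quartets —
recall saturates while precision degrades, and the mean F1 curve is
non-increasing in noise but can plateau between adjacent noise levels whose
decision boundaries no draw crosses.

`gen_domains` pairs the benchmark with a freshly generated, id-disjoint
training dataset of the same marginal structure. Each channel label owns a
pool of shared domain families; training channels carry their labels' full
pools (so fitted sets cover every shared family deterministically). Each
benchmark channel either draws one shared family per truth label (with
probability `sharing`) or receives decoy families unseen in training;
non-ion proteins get decoys, occasionally none, emulating incomplete
domain coverage. At `sharing` = 1 the baseline's per-label recall is 100
(precision may be lower because multi-label training proteins merge pools
across their labels); at 0 every protein is predicted `non-ion`.

## What the synthetic fixtures do and do not show

The generator emulates the benchmark's *label structure* and the base
models' *output interface*, not protein biology: decoy sequences carry no
channel signal, synthetic domain families have no Pfam semantics, and the
noise model is a convex mixture rather than a calibrated SVM error profile.
Passing tests therefore demonstrate that the aggregation rule, metrics and
protocols are implemented correctly and behave sensibly across the
signal-to-noise range — not that any particular accuracy is attainable on
real sequences, which depends on trained base models outside this package's
scope.

## Problem sizes and numerics

Default study sizes follow the protocols they model: 221-protein datasets,
1000 shuffle repetitions, 100 half-subsample splits, 10⁴ random profiles
for the oracle equivalence and 20 seeds × 5 noise levels for the
degradation curve; all fit comfortably in seconds on one core. Every
stochastic routine takes an explicit integer seed and uses a single
`numpy.random.default_rng` stream; metrics are plain double-precision set
arithmetic with no tolerance beyond `zero_tol` above.

## Known limitations

* Base-model propensities are consumed, never produced: feature extraction
  and classifier training are explicitly out of scope.
* Whether upstream subtype scores are normalized across subtypes is
  treated as unknown; scores are taken as independent [0, 1] values.
* The per-label metric definitions are a reconstruction consistent with the
  published per-label tables; other conventions (label-occurrence counting)
  would differ on multi-label data.
* Truth files mixing gating types in one row are rejected rather than
  split; a permissive ingestion mode is intentionally absent.
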