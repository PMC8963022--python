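# harsample

Hybrid synthetic oversampling for imbalanced wearable-sensor activity
recognition.

Human activity recognition (HAR) datasets collected from body-worn
accelerometers are almost always imbalanced: people walk far more than they
climb stairs, so classifiers trained on pooled windows recognize the frequent
activities well and the rare, often clinically interesting ones poorly.
`harsample` is a toolkit for studying and mitigating this problem. It is
aimed at HAR / mobile-sensing researchers who want leakage-safe, reproducible
resampling experiments on window-level feature tables.

It provides:

* **Six SMOTE-family oversamplers**, implemented from scratch with full
  per-row provenance: SMOTE, Random_SMOTE, SMOTE_TomekLinks, MSMOTE, CBSO
  (cluster-based synthetic oversampling) and ProWSyn (proximity-weighted
  synthetic oversampling).
* **Three hybrid combinators** that concatenate the synthetic outputs of two
  constituents run independently on the same training split:
  `DBM = SMOTE + Random_SMOTE` (distance-based),
  `NDBM = SMOTE_TomekLinks + MSMOTE` (noise-detection-based),
  `CBM = ProWSyn + CBSO` (cluster-based).
* **Accelerometer preprocessing**: orientation-invariant magnitude
  `sqrt(x² + y² + z²)`, non-overlapping windows, six time-domain features
  (mean, std, min, max, median, range).
* **A leakage-safe evaluation harness**: stratified k-fold cross-validation
  with oversampling applied strictly inside the training fold, a provenance
  audit (leakage guard) on every fold, and class-frequency-weighted
  F1 = Σᵢ 2 wᵢ Pᵢ Rᵢ / (Pᵢ + Rᵢ), wᵢ = nᵢ/N.
* **Statistical comparison machinery**: Anderson–Darling normality gate
  routing to one-way ANOVA or the Friedman test
  χ² = 12/(n k (k+1)) Σⱼ Rⱼ² − 3 n (k+1) with per-classifier rank tables.
* **A synthetic-data generator** (raw tri-axial streams and Gaussian feature
  clouds with exact class counts), so everything is testable without
  downloading any benchmark dataset.

Every sampler generates `round(alpha × (majority − minority))` rows per
class; at the default `alpha = 1` single methods balance every class exactly
to the majority count, while the hybrids deliberately fill the gap twice
(their two constituents' outputs are concatenated over a single copy of the
originals).

## Worked example

```python
import harsample as hs

# an imbalanced 5-activity feature dataset (counts 100/20/12/8/5, d = 6)
ds = hs.generate_feature_dataset(hs.default_scenario(), hs.make_rng(0))
print(hs.class_counts(ds))
# ({'walking': 100, 'standing': 20, 'sitting': 12,
#   'ascending_stairs': 8, 'descending_stairs': 5}, 'walking')

# cluster-based hybrid: ProWSyn + CBSO, each filling the gap once
res = hs.hybrid_oversample(ds, "cbm", alpha=1.0, rng=hs.make_rng(0))
print(res.class_counts)
# {'walking': 100, 'standing': 180, 'sitting': 188,
#  'ascending_stairs': 192, 'descending_stairs': 195}
```

Each constituent contributed 355 synthetic rows (the total majority–minority
gap), nothing was removed, and every minority class ends at
`count + 2 × (100 − count)` — the documented hybrid overshoot. The counting
identity `|augmented| = |train| − |removed| + |batch_A| + |batch_B|` holds on
every run, and `res.batches[*].provenance` records the seed row, partner row
and uniform draw behind every synthetic sample.

The statistical layer reproduces published worked examples exactly — a
bundled 5-classifier × 9-sampler rank table from the ADL benchmark gives:

```python
from harsample.benchmarks import ADL_RANKS
from harsample.stats import friedman_test

result, ranks = friedman_test(ADL_RANKS)
print(result.statistic, result.df, round(result.pvalue, 4))
# 21.8133 8 0.0053
print(int(ranks.rank_sums["CBM"]))
# 37
```

A χ² of 21.81 on 8 degrees of freedom (p ≈ 0.005) rejects the hypothesis
that all nine sampling methods perform alike across the five classifiers;
the rank sums identify the cluster-based hybrid as the top-ranked method.

A thin CLI covers the same pipeline from the shell:

```bash
harsample simulate --mode recording --seed 1 --out rec.csv
harsample features --input rec.csv --window-seconds 2 --out features.csv
harsample resample --input features.csv --method cbm --seed 1 \
    --out augmented.csv --log cleaning.json
harsample evaluate --config experiment.yaml --out scores.json
harsample compare-stats --scores scores.json --out report.json
```

## Layout

```
src/harsample/
  datasets.py        data model, RNG contract, CSV dialects
  preprocessing.py   magnitude, windowing, time-domain features
  samplers/          SMOTE family (distance / noise / cluster based)
  hybrids.py         DBM, NDBM, CBM + leakage guard
  evaluation.py      folds, classifiers, weighted scores, experiment runner
  stats.py           Anderson–Darling, ANOVA, Friedman, routing
  synthetic.py       scenario generators
  benchmarks.py      bundled worked-example rank tables
  cli.py             command-line interface
docs/methods.md      the full methods note
```
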