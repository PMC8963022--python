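# Methods

`harsample` studies between-class imbalance in wearable-sensor human activity
recognition (HAR): some activities (walking) dominate a recording while
others (stair descent, short gestures) are rare, and classifiers trained on
pooled windows systematically under-serve the rare classes. The package
implements six SMOTE-family oversamplers, three hybrid combinators built on
them, the accelerometer preprocessing that produces the feature tables they
consume, a leakage-safe evaluation harness, and the statistical machinery for
comparing sampling methods across classifiers.

## Sampling model

All samplers operate per minority class on an `(n, d)` feature matrix. The
number of rows synthesized for class *c* is

    n_synth(c) = round(alpha * (n_majority − n_c))

so `alpha = 1` (the default, the "sampling percentage 100%" convention)
brings every class exactly to the majority count. Every synthetic row is a
convex combination of real rows of the same class:

* **SMOTE** — seed `x` uniform over the class; partner `x_k` uniform over the
  seed's `k` nearest same-class neighbors (Euclidean); output
  `x + u (x_k − x)`, `u ~ U[0, 1)`. Outputs lie on closed seed–neighbor
  segments; they never extrapolate.
* **Random_SMOTE** — two further class members `x1, x2` (distinct, both ≠ x)
  define `x_tmp = x1 + u1 (x2 − x1)`; output `x + u2 (x_tmp − x)` lies in the
  closed triangle `(x, x1, x2)`. Classes with fewer than 3 rows fall back to
  SMOTE with `k = 1`.
* **SMOTE_TomekLinks** — SMOTE first, then every Tomek link (cross-class
  mutual-nearest-neighbor pair) found in the *augmented* set is removed, both
  endpoints. Output size can therefore sit off perfect balance by exactly
  the logged removals.
* **MSMOTE** — each minority row is typed by its `k` nearest all-class
  neighbors: *safe* (all same class), *noise* (none), *border* (mixed). Safe
  seeds interpolate toward one of their `k` nearest same-class neighbors,
  border seeds only toward the single nearest, noise rows are neither seeds
  nor interpolation partners. A class typed entirely as noise raises
  "no eligible seeds" — on heavily overlapped, very small classes this is the
  method's defined behavior, not an implementation limit.
* **CBSO** — average-linkage agglomerative clustering of the minority class,
  cut at `T = c_th ×` (mean nearest-neighbor distance within the class),
  `c_th = 3`. Seeds are drawn proportionally to a border weight (fraction of
  the row's `k` all-class nearest neighbors with a different label; uniform
  when all weights vanish); the partner is uniform over the seed's own
  cluster, so synthesis never bridges clusters. Singleton clusters duplicate
  their seed.
* **ProWSyn** — proximity levels by iterative peeling: level `l` collects the
  not-yet-assigned minority rows appearing among the `k` nearest minority
  neighbors of any opposite-class row; after `max_levels − 1` rounds the
  remainder gets the top level. Level weights `w(l) ∝ exp(−θ (l−1))`
  (`θ = 1`, `max_levels = 5`); the synthetic budget is split across levels
  proportionally to (level size × weight) with largest-remainder rounding,
  and generated by SMOTE-style interpolation *within* each level.

A note on the generation rule: the SMOTE-family recurrences are often printed
with a scalar norm, `x + ||x_k − x|| · rand`. For `d > 1` a scalar offset
cannot place the output on the line between the two points, which is the
stated geometric intent, so this package implements the componentwise form
`x + u (x_k − x)` throughout. Neighbor searches use exact pairwise distances
with a stable argsort (feature tables here are small, and stable ordering
makes tie-breaks reproducible) on raw, unstandardized features.

**Multi-class reading.** The constituent methods are described for binary
problems. Here, for a minority class *c*, the "majority side" used by Tomek
links, MSMOTE typing, CBSO border weights and ProWSyn peeling is *every row
with a different label*, while interpolation partners always come from class
*c* itself. Majority ties are broken by `class_names` order.

## Hybrid combinators

DBM = SMOTE + Random_SMOTE, NDBM = SMOTE_TomekLinks + MSMOTE,
CBM = ProWSyn + CBSO. Both constituents run independently on the same
training split with the same `alpha`, on independent random substreams
spawned from one master generator; their synthetic outputs are concatenated
over a **single** copy of the original rows. Duplicating the originals would
silently double-weight real samples, so at `alpha = 1` each minority class
receives the majority–minority gap twice and deliberately overshoots the
majority count (counts `{A: 20, B: 5}` give `B = 5 + 15 + 15 = 35` under
DBM); no rebalancing is applied. For NDBM, rows deleted by the Tomek step
are removed from the shared original copy; MSMOTE's noise rows are merely
unused, never deleted. The exact counting identity

    |augmented| = |train| − |removed| + |batch_A| + |batch_B|

holds on every run, and DBM/CBM always have `removed = ∅`.

## Preprocessing

Raw tri-axial streams are reduced to the Euclidean norm
`sqrt(x² + y² + z²)` — invariant under sensor rotation — then segmented into
non-overlapping windows (trailing partial window discarded). Each window is
summarized by six time-domain features of the magnitude channel: mean,
standard deviation, minimum, maximum, median, range (`d = 6`). Numerical
conventions, fixed for bit-reproducibility where the procedure is otherwise
underdetermined: population standard deviation (divide by `n`); even-length
median = mean of the two central order statistics; mixed-label windows keep
the modal per-sample label with ties going to the earlier class in
`class_names`; windows whose modal label is the null class are dropped before
sampling or classification.

## Evaluation harness

Pooled-subject stratified k-fold cross-validation (default 3 folds — rare
classes cannot support more — repeated 30 times with fresh random fold
assignments). Oversampling is applied to the training fold only; a leakage
guard audits every (repetition, fold, method) run: all synthetic provenance
must point at training rows and no test row may enter the augmented training
set (exact duplicates explainable by training-side provenance are recorded as
coincidences). Stratification is used because unstratified 3-fold splits of a
20:1 dataset can lose a class entirely.

Scores are class-frequency-weighted F1 / recall / precision computed from the
confusion matrix, with weights `w_i = n_i / N` taken from the true labels,
precision 0 for never-predicted classes and a per-class F1 term of 0 when
`P + R = 0`. Under these weights the weighted recall equals plain accuracy
(asserted numerically in the tests). Cells aggregate as mean over folds, then
mean ± sd over repetitions.

Classifier roster (pluggable fit/predict factories): KNN, logistic
regression, SVM, random forest at library defaults (LR with a raised
iteration cap), and an MLP with one hidden layer of 100 ReLU units, Adam,
learning rate 0.001, L2 penalty and 200 epochs. Every source of randomness —
fold assignment, sampler draws, classifier initialisation — derives from one
master seed, so experiments are bit-reproducible.

## Statistical comparison

An Anderson–Darling normality test (case 3, estimated mean/variance;
small-sample correction `A*² = A² (1 + 4/n − 25/n²)`; p-values from the
standard piecewise exponential approximation) runs on the flattened
classifier × method score cells. If normality is not rejected (p > 0.05) the
methods are compared by one-way ANOVA over method columns; otherwise by the
Friedman test: within-classifier ranks 1 (lowest) to k (highest), average
ranks on ties, χ² approximation with `df = k − 1` and no tie correction.
Two published 5 × 9 rank tables (ADL and Opportunity HAR benchmarks) are
bundled as worked examples; the implementation reproduces their χ² statistics
(21.8133 and 24.2133, df 8) and rank-sum rows exactly, including the
grand-sum invariant `n·k(k+1)/2 = 225`.

## Synthetic data

Two generator tiers. The raw tier emits labeled tri-axial streams —
per-activity sinusoids (activity-specific amplitude and frequency, fixed
per-axis scaling, random phase) on a 9.81 m/s² gravity offset plus Gaussian
noise — to exercise the preprocessing chain. The feature tier draws
window-level vectors from class-specific spherical Gaussians with exact class
counts, giving precise control of geometry for the sampler oracles.

The default scenario is five activities with counts (100, 20, 12, 8, 5) —
20:1 majority:minority — in `d = 6`, class means on distinct axes at 3 noise
standard deviations. Separation 3 is the moderate-overlap regime in which the
whole sampler roster remains well-defined: below ≈2.6 the 5-row rarest class
is regularly typed all-noise by MSMOTE inside 3-fold training splits, which
is that method's defined failure mode. The scenario is sized so the full
30-repetition × 3-fold MLP experiment completes in a few minutes on one CPU.

**What passing tests do and do not show.** The generator reproduces the
*structure* of imbalanced HAR data (multi-class, long-tailed counts, window
features, class overlap) but not several features that make oversampling
profitable in practice: within-class multimodality, minority mass
concentrated at class boundaries, label noise, and subject-level variability.
On equal-covariance Gaussian clouds the baseline MLP is close to the optimal
rule, so oversampling has little room to help: in the bundled experiment the
hybrids track their constituents closely (mean weighted F1 within ~0.02) but
minority-class F1 does not uniformly exceed the baseline — mid-size minority
classes typically trade precision for recall, while only the rarest class
tends to gain. The directional comparison is therefore *reported* by the
acceptance checks rather than asserted: it characterizes this synthetic
world, not a contract of the algorithms. Tests of the samplers' geometry,
balance accounting, determinism and leakage safety are exact and are
asserted.

## Known limitations

* Tomek-link search is O(n²) in memory and time — fine for window-level
  feature tables (thousands of rows), not for raw-sample scales.
* No frequency-domain features, no resampling of sample rates, no
  multi-sensor fusion, no leave-one-subject-out protocol, no post-hoc
  pairwise tests after the omnibus Friedman test, and no parsers for the
  native layouts of public HAR benchmark datasets (their data can be supplied
  through the generic `t,x,y,z,label` / feature-table CSV dialects).
* MSMOTE on a minority class whose every row is noise-typed raises rather
  than silently producing nothing; callers who need robustness to that case
  should catch the error and fall back to another sampler.
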