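# Methods

## Data model and preprocessing

A `SensorFeatureTable` is a samples × channels matrix of extracted sensor
intensities (the 30 s e-tongue reading and the 60 s e-nose reading of a
typical acquisition, extracted upstream of this package) with class labels
and per-channel modality tags.  Feature-level fusion is plain column
concatenation after verifying that both tables list the same samples in the
same order; nothing is reordered silently.

Scaling maps each channel onto (−1, +1) with `x' = −1 + 2(x − min)/(max −
min)`.  By default min/max are taken from the training partition only and
applied to both partitions; values of held-out samples may leave the
interval, and they are not clipped.  The alternative — fitting the scaler on
all samples before splitting, as fusion studies often do — is available as
`normalize_scope="all"`, but the train-scoped default avoids information
leaking from test to train.  A constant channel raises an error rather than
being mapped to zero: a dead sensor should be noticed, not hidden.

The 72/18 train/test split is stratified by class with largest-remainder
rounding of the per-class quotas (90 × 0.8 gives a fractional 14.4 per
class; remainder ties are resolved in class order, so two classes contribute
15 training samples and three contribute 14).

## PLS-DA, CV%, RMSECV, VIP

PLS-DA is multi-response PLS2 on one-hot class membership (K columns, not
K − 1; column centering removes the redundancy and keeps decoding trivial).
Components are extracted sequentially: the unit-norm X-weight vector is the
dominant left singular vector of the deflated cross-covariance X'Y — the
NIPALS fixed point, computed without power iteration so results are exact
and deterministic (sign fixed by making the largest-magnitude weight
positive).  Both blocks are deflated by the rank-one score contribution.
Prediction decodes the regression estimate of the one-hot response by
argmax; exact ties go to the lowest class index.

Cross-validation uses class-stratified folds (plain k-fold when
stratification is impossible, leave-one-out when folds = n) and accumulates
PRESS for every component truncation in one pass.  Two summaries are
reported, both monotone in the same PRESS:

* `CV% = 100 (1 − PRESS/TSS)`, TSS of the centered one-hot response;
* `RMSECV = sqrt(PRESS / (n·m))`, m = number of classes.

The component count is chosen to maximize CV% over A ∈ 1..min(p, n−1, 15).

VIP for channel j is `sqrt(p · Σ_a SS_a w_aj² / Σ_a SS_a)` with
`SS_a = (Σ_k q_ka²)·(t_a't_a)`; since weights are unit-norm, Σ_j VIP_j² = p
holds identically and is asserted to 1e−8.  Ranking is descending with
stable ties (original column order).

## GA-PLS and the randomization test

Wrapper selection searches binary inclusion masks with a generic GA:
tournament selection of size 2, uniform crossover (applied with probability
0.9, per-gene swap probability 0.5), per-bit mutation 1/p, elitism 1,
population 30, 100 generations.  Fitness is the masked model's best CV%
(component count auto-chosen per mask, capped at the mask size); the fold
plan is fixed once per run so fitness values are comparable across masks and
identical to what `exhaustive_pls_search` computes for the same seed — the
basis of the small-p oracle-equivalence test.  Fitness values are cached by
mask; caching cannot change results because the fold plan is frozen.
Envelope curves record, per subset size, the best CV% seen and the RMSECV of
that same mask, so the size maximizing CV% is exactly the size minimizing
RMSECV.

Before the search, a response-randomization test guards against wrapper
overfitting: class labels are permuted n_perm times (default 100), the
full-model CV% is recomputed at the component count chosen on the true
labels, negative values are floored at zero, and the mean must stay below 5.
Only the threshold is conventional; the statistic (mean permuted CV%) is
this package's choice and is isolated behind `RandomizationResult` so other
definitions can be substituted.  With 90 samples and 20 channels the
statistic is essentially zero; it becomes large — and the test correctly
refuses the wrapper — when the variable count rivals the sample count.

## Evaluator families

**RBF-SVM.**  The Gaussian kernel `exp(−g‖xᵢ−xⱼ‖²)` is the default reading
of the width convention; an exponential variant `exp(−2g‖xᵢ−xⱼ‖)` is kept
behind `kernel_variant="literal"` for auditability.  Multi-class is explicit
one-vs-one: each class pair gets its own soft-margin dual (solved by libsvm
at tolerance 1e−6 through scikit-learn's `SVC` with our kernel callable),
votes are tallied, ties decode to the lowest class.  After every fit the
dual constraints (Σᵢ aᵢyᵢ = 0, 0 ≤ aᵢ ≤ c) are checked to 1e−6 and the
residuals stored on the model.  (c, g) are tuned by a real-coded GA —
tournament 2, BLX-0.5 blend crossover, Gaussian mutation at 10% of the
range, elitism 1 — with 5-fold stratified CV accuracy as fitness, searching
c ∈ [0, 100] and g ∈ [0, 1000] with 100 generations × 20 individuals by
default.  On (−1, +1)-scaled data the useful widths live orders of
magnitude below 1000, so `g_scale="log"` searches log₁₀ g uniformly; the
fast protocol mode uses it.

**Random forest.**  Bootstrap-sampled, Gini-split, fully grown (unpruned)
trees with mtry = ⌊√p⌋ candidate variables per split, via scikit-learn's
`RandomForestClassifier`; its probability-argmax vote resolves ties to the
lowest class, matching the package's convention.  The mtry rule gives 4 for
the 20-channel fusion set, 3 for 10- and 12-channel sets, and the bands
1/2/3/4 over ladder sizes 1–3, 4–8, 9–15, 16–20.

**ELM.**  A single hidden layer with weights and biases drawn uniformly on
[−1, 1] (never trained), logistic-sigmoid activation by default, and the
readout solved in closed form as β = H⁺T with the Moore–Penrose
pseudoinverse on one-hot targets — the minimum-norm least-squares solution,
asserted against an independent `lstsq` oracle to 1e−8.

**Sweep-and-average.**  RF tree counts and ELM hidden-neuron counts are
swept over 2–100 in steps of 2 (50 points); at each point 10 models with
distinct derived seeds are trained and their mean test accuracy recorded;
the best grid point is the argmax, smallest value on ties.

## Variable accumulation and protocol modes

The ladder S_k = top-k VIP channels is evaluated subset by subset; per
subset, mtry is recomputed as ⌊√k⌋.  The best subset per evaluator is the
smallest k attaining the maximum mean accuracy — the fewest-channels
tie-break reflects the point of the exercise, reducing detection effort.

Two protocol modes:

* `mode="full"` mirrors the per-set protocol: the SVM is GA-retuned per
  subset and repeat, RF and ELM are swept over their full grids, and the
  best grid point's mean is reported.
* `mode="fast"` tunes once on the full-channel training set with a reduced
  budget (GA 15 × 10 with log-scale g for the SVM, a fixed 100-tree forest,
  a coarse ELM sweep) and reuses those settings for every subset.  This is
  the mode used by the shipped recovery experiments; it biases slightly in
  favor of larger subsets (the SVM width is tuned at p = 20), which makes
  the observed best-subset sizes conservative.

Repeats either re-seed the models on one fixed split (default, the
convention of repeated-model-averaging protocols) or re-split the data per
repeat (`resplit=True`).  With an 18-sample test set a single split
quantizes accuracy to 5.56-point steps, so recovery experiments use
`resplit=True`: averaging ten 72/18 splits gives 0.56-point resolution and a
much more stable argmax.  Every random draw — splits, folds, GA streams,
forests, ELM weights — derives from one master seed via named
`SeedSequence` spawn keys, making whole runs byte-reproducible.

## The synthetic generator

The generator emulates the study design the pipeline assumes: 5 classes × 18
samples, 10 taste + 10 gas channels, 12 informative channels (defaults match
the channel names above), Gaussian within-class noise of unit standard
deviation, and aftertaste channels whose *noise* is correlated (ρ = 0.6)
with the parent taste channel's noise.  Correlating the noise rather than
the full signal keeps the defining invariant of the design — non-informative
channels have identical population means in every class — while still
making cpa channels partly redundant with their parents.

Class means live only on the informative channels.  Each informative
channel separates a balanced bipartition of the classes (a centered ±1 code
over a ⌊K/2⌋-subset, cycling through all distinct bipartitions), so a
single channel never identifies a class outright and class information
accumulates gradually over channels — the regime in which forward
accumulation is informative, and a reasonable caricature of cross-sensitive
sensor arrays.  For fewer informative channels than classes a projected
centered identity is used instead.  The pattern is scaled so the minimum
pairwise centroid distance is `separation` (default 5.0, calibrated once so
one-nearest-centroid accuracy is ≈ 99% at unit noise).

What the generator does **not** model: sensor drift, humidity and
temperature effects, non-Gaussian heavy-tailed noise, nonlinear channel
interactions, and batch structure.  Passing recovery tests therefore show
that the pipeline finds planted linear-Gaussian structure at realistic
sample sizes — not that it is robust to instrument pathologies.

## Numerical choices and limitations

* Rank checks: requesting more PLS components than the centered training
  matrix's rank is an error, never a silent cap (inside cross-validation the
  effective count is capped at the smallest training-fold rank and
  recorded).
* Degenerate inputs: empty masks, single-class fits, single-sample classes,
  constant channels, out-of-range thresholds and fold counts all raise
  informative errors.
* All decode ties (PLS-DA, ELM argmax, SVM votes, RF votes, sweep argmax,
  best-subset argmax) resolve to the lowest index, documented per model.
* Reported accuracies are rounded to 2 decimals in tables, matching the
  granularity an 18-sample test set supports.
* The recovery experiments ship at sizes chosen for a desktop single-CPU
  run (fast mode, 10 master seeds, 10 split-repeats); the full per-subset
  re-tuning protocol is implemented but several orders of magnitude more
  expensive, and its Monte-Carlo behavior has not been characterized here.
* The best-subset location on a flat accuracy plateau is intrinsically
  noisy: when several subset sizes are statistically indistinguishable, the
  smallest-argmax rule can wander by a few positions between reruns with
  different seeds.
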