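# Methods

## Problem setting

A metal-oxide-semiconductor (MOS) electronic nose samples the headspace of a
liquor at 1 Hz for 100 s on a ten-sensor array (PEN3 layout: W1C, W5S, W3C,
W6S, W5C, W1S, W1W, W2S, W2W, W3S). Each measurement is therefore a 100x10
matrix of dimensionless conductivity-ratio responses. The task is nine-way
classification: six unblended base liquors distinguished only by aging
duration (3-13 years) and three commercial blends of those bases. The
acquisition protocol is 25 days x 9 liquor types x 9 replicates = 2025
measurements; dataset variant A keeps the six base liquors (1350), B the
three commercial liquors (675), C everything (2025).

Generalization is assessed across *acquisition days*: the first 20 days
train, the last 5 test. MOS sensors drift day to day, so a day-based split
is the honest protocol — a random split would leak day effects between
train and test.

## The hybrid classifier

The core model is a convolutional feature extractor feeding a
gradient-boosted-tree classifier:

1. **Tensorization.** Each sensor's 100 response points are reshaped
   row-major in time into a 10x10 map, giving a 10-channel 10x10 input
   (element (i, j) of channel s is the response of sensor s at
   t = 10 i + j + 1). The reshape is bijective and the package ships the
   exact inverse. The layout within a channel is a convention; we fix it and
   lock it with tests so that serialized models stay portable.

2. **Residual backbone.** An 18-layer residual network: a 7x7/stride-2
   stem (64 filters, batch norm, ReLU, 3x3/stride-2 max pool), four stages
   of two residual blocks with widths 64/128/256/512, global average
   pooling. The first block of stages 2-4 downsamples with a stride-2 3x3
   convolution and a 1x1 stride-2 projection shortcut (padding 0 — any
   positive padding on a 1x1 stride-2 kernel would make the shortcut map
   larger than the main path, so the branches could never be summed). For
   10x10 inputs the spatial trace is 5, 3, 3, 2, 1, 1; for 224x224 inputs
   the classical 112, 56, 56, 28, 14, 7. The backbone is implemented
   directly in numpy (im2col convolutions, explicit backpropagation, Adam);
   it is CPU-only and bit-deterministic given the seed.

3. **Training and freezing.** The backbone trains end to end with a C-way
   linear head and cross-entropy (default: Adam, learning rate 1e-3,
   batch 32, 60 epochs — all configurable). After training the head is
   discarded and batch-norm statistics are frozen, so feature extraction is
   a pure function. The trained-then-frozen protocol is forced by the tree
   head: trees cannot backpropagate a gradient into the network.

4. **Boosted-tree head.** A LightGBM multiclass model on the 512-dim pooled
   embeddings. Its two structural hyperparameters are selected by exhaustive
   grid search — num_leaves in {8, 16, 32, 64, 128}, learning_rate in
   {0.001, 0.01, 0.1, 0.5, 1} — scored by stratified 5-fold CV accuracy on
   the *training* features only. Ties break toward the smaller leaf count,
   then the smaller rate, making the selection independent of enumeration
   order (on cleanly separable features many grid points tie at CV
   accuracy 1, so a deterministic tie-break matters). Boosting rounds are
   not part of the published grid; we fix 100 rounds (configurable).

## Baselines

Six reference classifiers consume *per-timepoint* steady-state rows: the
10-vector of channel responses at each of t = 81..100, i.e. 20 rows per
measurement (sensors have saturated by 80 s, so these rows carry the plateau
signature). Published hyperparameters are used where stated: RBF-SVM with
C = 100, gamma = 1; a 10-tree random forest with sqrt-features per split;
k-NN with k = 3; XGBoost with the boosted-tree grid defaults. Two
literature methods are re-implemented with the details left open in the
source: the scaling+SVM baseline uses classical (Torgerson) scaling, which
coincides with projection onto the top principal axes and therefore has a
natural out-of-sample extension (centre with the training mean, project,
classify); its embedding dimension defaults to 3. The backprop network is a
single hidden layer of 64 rectified units. Rows are classified
independently by default (matching the datasets' row accounting:
27,000 rows for variant A); per-measurement majority voting is available as
an option.

The originally reported random-forest configuration is internally
inconsistent (a sqrt-of-features rule stated next to a count of 10); we use
10 trees with sqrt-features per split.

## Metrics

All five metrics derive from the C x C confusion matrix by one-vs-rest
marginalization: accuracy (trace/N), macro sensitivity (mean per-class
recall), macro precision, macro F1 (mean of per-class F1, not the harmonic
mean of the macro aggregates — the two disagree in general and reported
aggregate metrics alone cannot disambiguate; we document our choice), and Cohen's kappa
computed from the full matrix, kappa = (p0 - pe)/(1 - pe) with
pe = sum_c rowsum_c * colsum_c / N^2. With balanced test classes macro
sensitivity equals accuracy identically, which is why those two columns
coincide in day-split evaluations of a balanced protocol. A class with no
true items is excluded from the macro averages with a warning; a class
never predicted contributes precision 0.

## The synthetic protocol

No public e-nose recording accompanies the package, so every stage is
exercised on a simulator that reproduces the *statistical* structure the
pipeline assumes. Channel s of class c at second t responds as

    r(t, s) = 1 + A[c, s] (1 - e^(-t/tau_s)) (1 + d_day) (1 + e_rep) + eps

with plateau amplitudes A (the class signature), channel time constants
tau_s in 4-16 s (every channel saturated well before 80 s), a gain-like
day effect d_day ~ N(0, sigma_day) shared by all measurements of one day
(MOS drift is typically multiplicative), a replicate gain
e_rep ~ N(0, sigma_rep) per measurement, and i.i.d. sampling noise.
Defaults: sigma_noise = 0.02, sigma_day = 0.03, sigma_rep = 0.02,
unit-scale amplitudes (no quantitative response magnitudes are published;
amplitudes are unit-scale by fiat). Responses are clipped at a positive
floor of 1e-3, as conductivity ratios must stay positive. Each
measurement's noise stream is keyed by (seed, class, day, replicate), so
any subset regenerates identically regardless of generation order.

Two stock signature matrices are provided: *well-separated* (pairwise row
distances at least 5 x the noise scale; classifiers that use the plateau
information recover the classes almost perfectly) and *overlapping* (rows
within the noise scale; near-chance recovery, used for null checks).

What the simulator does **not** model: desorption/flushing transients (only
the 100 s collection stage is recorded), humidity and temperature
covariates, sensor-specific drift direction, cross-sensitivity
nonlinearities, or long-term sensor poisoning. Consequently, passing tests
show that the *pipeline* recovers the structure it assumes — they say
nothing about instrument-specific behaviour of real liquor data. On the
well-separated defaults essentially every competent classifier saturates
near accuracy 1, so the ablation ordering (hybrid >= backbone alone >=
trees alone) holds near the ceiling rather than with the large margins seen
on real recordings — and at that ceiling the ordering is fragile at
single-sample resolution: one drifted test measurement landing on a
decision boundary can invert two arms by one count, which is sampling
noise, not a component effect.

## Study runner and problem sizes

`enoseml.study.run_study` replicates the experimental design end to end on
one simulated protocol: grid search on dataset A's training embeddings,
selection reused for B and C (as in the original experiments), the
three-arm ablation per variant, a label-permutation null on dataset C, and
PCA screening of all 40,500 steady-state rows. The runner's backbone
schedule is 12 epochs at batch 128: the simulated classes are learned to
saturation well before 12 epochs, and the shorter schedule keeps a full
study run on a single CPU core in the ten-to-twenty-minute range. The
permutation null re-runs the identical pipeline on shuffled training
labels; its test accuracy should sit near 1/C and its kappa near 0.

## Numerical choices and degenerate inputs

* float32 parameters and activations in the backbone; float64 features
  downstream.
* Batch norm: eps 1e-5, running-statistics momentum 0.1; statistics frozen
  at extraction time so embeddings are deterministic. After the optimizer
  finishes, running statistics are replaced by exact population statistics
  of the final parameters via one deterministic pass over the training set
  (the momentum averages accumulated during short schedules lag behind the
  fast-moving activations badly enough to corrupt frozen-statistics
  inference; the recalibration pass is the standard cure).
* He-normal initialization; Adam (0.9, 0.999), eps 1e-8.
* CSV round-trips use full-precision floats (`float_precision="round_trip"`
  on read); a written measurement set re-reads bit-identically.
* PCA mean-centres but does not standardize columns (all ten channels are
  on the same response-ratio scale); explained-variance ratios of
  rank-deficient input are reported as trailing zeros rather than errors.
* Grid-search fold count drops to the rarest class size with a warning when
  a class has fewer members than the requested folds.
* Responses must be finite and positive; measurement sets reject duplicate
  ids; day splits reject overlapping day sets.

## Known limitations

* The published headline accuracies were obtained on the instrument's real
  recordings, which are not bundled; on synthetic data the corresponding
  quantities are properties of the simulator, not reproductions of the
  published tables. The documented screening pipeline (last-20 rows, PCA,
  three components) can be pointed at the deposited recordings by loading
  them through `read_measurement_table` once converted to the package's CSV
  dialect.
* The reshape order within a channel and the PCA preprocessing are fixed
  conventions in this package; other conventions would yield different
  (equally valid) embeddings and slightly different component spectra.
* The backbone is a from-scratch numpy implementation tuned for 10x10
  inputs on CPU; it is not meant for large images or GPU workloads.
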