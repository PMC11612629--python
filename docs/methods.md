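# Methods

This note documents the model, the conventions chosen where the method left
details open, the synthetic data the tests rely on, and the known
limitations.

## Problem and pipeline

The package detects epileptic activity in single-channel EEG by classifying
fixed-length signal segments into three states: *healthy*, *interictal*
(between seizures) and *ictal* (during a seizure). The pipeline has four
stages:

1. **Preprocessing** — fourth-order Butterworth bandpass 0.5–70 Hz plus a
   50 Hz mains notch (quality factor 30), both applied forward–backward so
   the output is zero-phase; segmentation into windows of 1,024 samples with
   64 shared samples between consecutive windows (stride 960); stratified
   90/5/5 train/validation/test split with floor allocation and remainders
   assigned train → val → test.
2. **Feature extraction** — 35 features per segment (below).
3. **Feature selection (PMPSO)** — a modified binary particle swarm (MPSO)
   wrapper stage followed by a Pearson redundancy filter.
4. **Classification** — SVM, ANN, random forest or XGBoost, evaluated with
   stratified 10-fold cross-validation.

## The 35 features

A 5-level discrete wavelet decomposition (default `db4`, the standard
choice in epilepsy EEG work) yields six coefficient sets D1…D5 and A5.
Five statistics are computed on each set *i* with coefficients
c_j, j = 1…N:

* `LSWT_i` = Σ ln|c_j| (log-sum; |c_j| clamped to ε = 1e−12),
* `MEAN_i` = (1/N) Σ |c_j| (mean absolute value),
* `ABS_i` = (1/N) Σ c_j² (mean power — the name is the field's, not ours),
* `STD_i` = sqrt((1/N) Σ (c_j − MEAN_i)²) — note the centering on the mean
  of **absolute** values; this is deliberate and matches the method's
  printed definition. The conventional signed-mean variant is available via
  `center_mode="conventional"`.
* `RAT_i` = Σ|c_j in band i| / Σ|c_j in band i+1| — ratio of absolute sums
  of adjacent sub-bands; `RAT_6` closes the ring (A5 against D1) so that six
  sets yield six ratios and the feature count is 30 + 5 = 35. A
  `rat_mode="adjacent5"` option drops the cyclic closure (34 features).

The remaining five features are natural-log band powers from a Welch PSD
(Hamming window, sub-segments of M = 256 samples, 50% overlap, per-segment
periodograms normalized by the window power U = (1/M) Σ w(n)² and averaged;
density scaling, no detrending): delta 0.1–4 Hz, theta 4–8, alpha 8–12,
beta 12–30, gamma 30–70 Hz, half-open intervals so contiguous bands never
share a bin, gamma capped at 0.99 × Nyquist. Band log-power is
ln Σ P(ω) over the bins in the band, clamped at ε before the log.

Scaling laws (verified by property tests): scaling the signal by s
multiplies MEAN and STD by s, ABS by s², leaves RAT unchanged, adds
N·ln s to each LSWT and ln s² to each band log-power.

## PMPSO feature selection

**Stage 1 — MPSO.** Each of n particles carries a real position x ∈ R^35 and
velocity v. A binary mask is drawn per iteration by the stochastic sigmoid
transfer (bit j is 1 with probability 1/(1+e^(−x_j)); an all-zero draw is
retried once, then the largest-position dimension is forced on). Mask
fitness is the mean 3-fold stratified cross-validated accuracy of a small
random forest (15 trees, seed-fixed) trained on the masked columns of the
*training* partition only. Personal/global bests are replaced when the
candidate is strictly more accurate, or equally accurate (tolerance 1e−12)
with a strictly smaller subset. The velocity update is

    v' = w·v + φ[c1 r1 (pbest − x) + c2 r2 (gbest − x)],   x' = x + v'

with the Clerc–Kennedy constriction factor
φ = 2 / |2 − c − sqrt(c² − 4c)|, c = c1 + c2 (φ ≈ 0.7298 at the default
c1 = c2 = 2.05; φ is forced to 1 with a warning when c ≤ 4, which is also
the "baseline PSO" comparator), inertia w decaying linearly 0.9 → 0.4, and
per-element clamping to ±v_max = 4. The run stops at `max_iters` (default
50) or when the global best has not improved for `stall_window` (15)
iterations.

**Importance and top-k.** After the run, feature j's importance is the
fitness-weighted frequency with which j appears in the recorded per-iteration
personal bests, normalized to a maximum of 1. This aggregation is a
declared convention (the method's original rule is not documented). The
top k = 10 features by weight (ties broken by canonical feature order)
proceed to stage 2.

**Stage 2 — Pearson redundancy filter.** Scanning the top-10 in descending
importance, a feature is kept iff its absolute Pearson correlation with
every already-kept feature is ≤ δ = 0.6; the first feature is always kept,
zero-variance columns are dropped with a warning, and all examined pairs are
recorded. By construction the final subset is pairwise |r| ≤ δ.

The selector is exposed as `PMPSOSelector`, an sklearn `SelectorMixin`
estimator (`fit`/`transform`/`get_support`), so it composes with pipelines
and model selection; `pmpso()` is the functional equivalent.

### A note on variance

The filtered subset is assembled from a ranking and is never itself
re-scored by the wrapper fitness. When the top-10 happens to be dominated by
mutually correlated features, the filter can prune it to only two survivors,
and end-to-end accuracy drops from the typical 97–99% to around 90%. This
is a property of the two-stage composition, not of the implementation; the
`SelectionResult` retains `gbest_mask` so callers can compare the swarm's
own best subset against the filtered one.

## Classifiers and metrics

* SVM: polynomial kernel of degree 5, gamma = 0.1, C = 1, standardized
  inputs (scaler fit on the training fold only).
* ANN: one hidden layer of 19 units, softmax output; adam with initial
  learning rate 0.01, early stopping (10% validation split, patience 25),
  at most 600 epochs; standardized inputs. These training details are the
  package's choices.
* Random forest: 50 trees (seed-fixed). XGBoost: 60 rounds, depth 4,
  learning rate 0.3. Tree models consume raw features.

Metrics are computed one-vs-rest per class from the pooled cross-validation
confusion matrix, in percent: SE = TP/(TP+FN), SP = TN/(TN+FP),
AC = (TP+TN)/n, and **two F1 variants that must not be confused**:
`f1_paper` = 2·AC·SE/(AC+SE) — the harmonic mean of accuracy and
sensitivity, exactly as the method defines it — and `f1_conventional`, the
textbook precision/recall harmonic mean. Macro averages are unweighted
means over classes; degenerate denominators yield NaN (with a warning) and
are excluded, never silently reported as zero. The pooled ("micro")
accuracy is also reported, since it is ambiguous which of the two a
headline three-class accuracy refers to. The 95% confidence interval is a
Student-t interval over the per-fold accuracies (a declared convention),
clipped to [0, 100].

## Synthetic data

`gen_eeg_record` builds one surrogate record as a sum of band-limited
Gaussian noise components (white noise bandpassed into each clinical band,
unit-variance normalized, scaled by a per-band amplitude), Poisson-timed
3 Hz biphasic spike-wave transients, and white measurement noise — all
reproducible from the seed. Class recipes: *healthy* is alpha-dominant with
no spikes; *interictal* has a mixed slow background with sporadic spikes;
*ictal* has a dominant high-amplitude delta rhythm with dense spiking.
Records default to 4,097 samples at 173.61 Hz so they flow through the same
reader/segmentation path as real single-channel records.

`gen_eeg_dataset` adds two per-record lognormal jitters: an independent
per-band amplitude jitter (sd 0.4, spectral-shape variability) and a global
gain jitter (sd 0.3, emulating electrode gain/impedance variability). The
global gain is what makes any single amplitude-dependent feature a weak
classifier on its own (best single-feature CV accuracy ≈ 0.8) while leaving
relative spectral structure — and hence multivariate separability,
≈ 97–99% — intact. That balance is deliberate: it makes the selection stage
genuinely necessary in end-to-end tests.

What the surrogate does *not* emulate: multi-channel spatial structure,
artifacts (ocular, muscle), within-record non-stationarity, realistic
spike-wave morphology variability. Passing end-to-end tests therefore
demonstrates that the pipeline machinery works and that selection recovers
planted structure — not clinical performance.

`gen_feature_table` builds labeled Gaussian tables with known ground truth:
informative columns receive one-vs-rest class contrasts of a stated effect
size (so no single column separates all classes), designated copy columns
are ρ-correlated duplicates of their sources (exact duplicates at ρ = 1),
and the rest is pure noise.

## Problem sizes used by the tests and the acceptance script

Chosen once as the package's study scale: the swarm-vs-exhaustive check
uses an 8-feature, 150-row table (all 255 subsets scored by the identical
cached fitness) with 10-particle, 12-iteration swarms over 10 seeds;
recovery uses a 12-feature table with three exact-duplicate pairs
(12 × 15 swarms, 10 seeds); the selection-vs-all-features comparison uses
35-feature, 240-row tables with planted redundant pairs (10 seeds); the
end-to-end run uses 100 records per class (1,200 segments) with a
20-particle, 20-iteration swarm. Library defaults remain 30 particles ×
50 iterations.

## Numerical conventions

Natural logarithms everywhere; clamp floor ε = 1e−12 for logs and ratio
denominators; accuracy tie tolerance 1e−12 in best-replacement; band
intervals half-open; the bandpass upper edge is clamped to 0.99 × Nyquist
when the sampling rate makes 70 Hz infeasible; fitness of an empty mask is
defined as 0 without training. One master seed fans out to per-stage seeds
by fixed offsets (synthesis +0, split +1, swarm +2, evaluation +3).

## Known limitations

* The importance aggregation and the binarization transfer are declared
  conventions; other choices would change which features are ranked high.
* The Pearson stage can over-prune when the retained top-10 is homogeneous
  (see "A note on variance").
* Bonn-style records at 173.61 Hz place the 70 Hz band edge close to the
  86.8 Hz Nyquist frequency; the gamma band is intentionally capped rather
  than resampled.
* EDF support covers ordinary EDF signals read via mne; EDF+ annotations
  embedded in the file are not parsed — seizure intervals come from a
  tab-separated sidecar.
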