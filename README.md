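# pmpso — EEG seizure detection with multi-domain features and swarm-selected subsets

Epileptic seizures leave characteristic traces in scalp EEG: ictal segments
show high-amplitude slow rhythms and dense spike-wave discharges, interictal
segments show sporadic spikes on a mixed background, and healthy recordings
are dominated by the alpha rhythm. This package implements a complete
three-class detection pipeline for single-channel EEG, aimed at researchers
who want the classical feature-engineering route (as opposed to end-to-end
deep learning) with a fully reproducible, testable implementation:

1. **I/O and preprocessing** — readers for plain-text records (one sample
   per line, e.g. the Bonn dialect at 173.61 Hz) and EDF recordings (e.g.
   CHB-MIT at 256 Hz, via mne); zero-phase 4th-order Butterworth bandpass
   0.5–70 Hz plus a 50 Hz notch; segmentation into 1,024-sample windows
   with 64 shared samples; stratified 90/5/5 splitting.
2. **Feature extraction** — 35 features per segment: five statistics
   (log-sum LSWT, mean absolute MEAN, mean power ABS, STD, adjacent-band
   ratio RAT) over six discrete-wavelet coefficient sets D1…D5 + A5, plus
   Welch log band powers in the five clinical bands
   (δ 0.1–4, θ 4–8, α 8–12, β 12–30, γ 30–70 Hz).
3. **PMPSO feature selection** — a binary particle swarm whose fitness is
   the cross-validated accuracy of a classifier on the candidate subset,
   damped by the Clerc–Kennedy constriction factor
   φ = 2/|2 − c − √(c² − 4c)| with c = c₁ + c₂ > 4, with ties between
   equally accurate subsets broken toward the smaller one; followed by
   importance ranking, top-10 retention, and a Pearson redundancy filter
   that keeps a feature only if |r| ≤ δ = 0.6 against everything already
   kept.
4. **Evaluation** — SVM / ANN / random-forest / XGBoost classifiers,
   stratified 10-fold cross-validation, sensitivity/specificity/accuracy
   and two F1 variants (`f1_paper` = harmonic mean of accuracy and
   sensitivity, as the method defines it; `f1_conventional` =
   precision/recall), with Student-t confidence intervals over folds.

A first-class synthetic-data module generates surrogate EEG with known
class structure and labeled feature tables with planted informative and
redundant columns, so every stage is testable without downloading clinical
data. See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

```python
from pmpso import (gen_eeg_dataset, apply_filters, segment_record,
                   extract_feature_matrix, SwarmConfig, pmpso,
                   kfold_cv, ModelSpec)
from pmpso.io import concat_segment_sets

records = [apply_filters(r) for r in gen_eeg_dataset(30, seed=0)]
segments = concat_segment_sets([segment_record(r) for r in records])
X, y = extract_feature_matrix(segments)           # (360, 35) DataFrame

result = pmpso(X, y, SwarmConfig(n_particles=20, max_iters=20, seed=0))
print(result.ranked_top_k)    # the 10 features entering the Pearson stage
print(result.final_subset)    # the redundancy-filtered subset

report = kfold_cv(X[result.final_subset], y, ModelSpec("rf"), k=10, seed=0)
print(f"pooled 10-fold accuracy: {report.micro_accuracy:.2f}%")
print(f"95% CI: ({report.ci95[0]:.2f}, {report.ci95[1]:.2f})")
```

Output:

```
['LSWT_1', 'power_delta', 'RAT_4', 'power_theta', 'MEAN_1', 'ABS_6',
 'ABS_2', 'RAT_3', 'power_gamma', 'STD_2']
['LSWT_1', 'power_delta', 'ABS_6']
pooled 10-fold accuracy: 92.78%
95% CI: (88.46, 97.09)
```

Thirty records per class give 360 segments; the swarm's importance ranking
retains ten features, of which three survive the |r| ≤ 0.6 filter, and a
random forest on those three classifies healthy/interictal/ictal segments
at 92.8% pooled accuracy (97–99% is typical at 100 records per class —
more segments stabilize both the ranking and the folds).

The selector is also available as an sklearn estimator:

```python
from pmpso import PMPSOSelector
selector = PMPSOSelector(n_particles=20, max_iters=20, random_state=0)
X_selected = selector.fit_transform(X, y)         # keeps final_subset columns
selector.get_support()                            # boolean mask over 35 columns
```

## Command line

`pmpso simulate | extract | select | train | evaluate | ablation | compare |
reproduce-bonn` — thin wrappers over the library; `pmpso simulate` writes
synthetic records in the plain-text dialect so they flow through the same
reader path as real data, and `pmpso reproduce-bonn --data-path DIR` runs
the full pipeline on a user-supplied copy of the Bonn subsets (never
downloaded automatically; no particular numeric outcome is promised, since
results depend on pipeline constants the method leaves open).

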