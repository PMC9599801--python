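# plimci

Resting-state EEG functional-connectivity analysis for discriminating
mild cognitive impairment (MCI) in type 2 diabetes, built around the
**phase lag index** (PLI) — with a synthetic EEG cohort generator that has
analytically known ground truth, so every stage of the analysis is
testable end to end.

## The problem and the method

Reduced alpha-band synchronization between cortical areas is a candidate
EEG biomarker of early cognitive decline in diabetic patients.  The PLI
quantifies phase synchronization between two channels while ignoring the
zero-lag coupling that volume conduction fabricates:

    PLI = | ⟨ sign(Δφ(t_k)) ⟩ |,   Δφ = instantaneous phase difference,
                                    wrapped to (−π, π]

PLI = 0 for symmetric phase differences (including spurious zero-lag
mixing), 1 for a perfectly consistent non-zero lead or lag.  The package
implements:

* **synthesis** (`plimci.synth`) — two cohorts of 30 subjects (patients /
  controls) with band-limited shared oscillators, per-channel phase lags,
  1/f noise, Table-1-like clinical covariates, and MoCA scores generated
  conditionally on each subject's *true* global alpha PLI (computed in
  closed form from the complex-Gaussian phase-difference distribution);
* **preprocessing** (`plimci.preprocess`) — EOG drop, linked-mastoid
  re-reference, zero-phase 0.1–30 Hz band-pass, 48–52 Hz notch,
  downsampling, 3 s epochs, amplitude-based epoch rejection;
* **connectivity** (`plimci.pli`) — Hilbert-phase PLI per epoch, averaged,
  for delta/theta/alpha/beta; 62 × 62 matrices, global (upper-triangle
  mean) PLI, and eight named electrode pairs;
* **statistics** (`plimci.stats`) — t / χ² / Wilcoxon rank-sum /
  Shapiro–Wilk / Pearson correlation, plus per-pair group comparison;
* **classification** (`plimci.classify`) — IRLS logistic regression,
  stratified 10-fold CV pooled over folds, ROC/AUC, and the empirical
  chance level (95th percentile of accuracy under 5000 label
  permutations);
* **orchestration** (`plimci.pipeline`, `plimci.cli`) — one config, full
  report bundle, byte-reproducible under a fixed seed.

See `docs/methods.md` for the model, the ground-truth derivation and all
numerical choices.

## Worked example

The numbered scripts under `analysis/` run the study on the reduced
16-channel configuration (`configs/reduced.toml`); `configs/default.toml`
holds the full 62-channel scale.

```bash
python analysis/01_simulate_cohort.py
python analysis/02_connectivity.py
python analysis/03_group_statistics.py
python analysis/04_classification.py
python analysis/05_moca_correlation.py
```

Output of a run with the default seed:

```
ground-truth global alpha PLI: MCI 0.231 +/- 0.051, NC 0.354 +/- 0.072
MoCA: MCI 21.22 +/- 2.74, NC 28.02 +/- 1.42
...
delta: MCI 0.269 vs NC 0.271 (z = -1.53, p = 0.1260)
theta: MCI 0.266 vs NC 0.266 (z = -0.27, p = 0.7845)
alpha: MCI 0.284 vs NC 0.380 (z = -5.57, p = 0.0000)
 beta: MCI 0.147 vs NC 0.150 (z = -3.64, p = 0.0003)
...
accuracy 85.00% (empirical chance level 61.67%)
sensitivity 90.00%, specificity 80.00%, AUC 0.879
...
MCI: r = 0.6792, p = 0.0000 (n = 30)
NC: r = 0.3140, p = 0.0911 (n = 30)
```

Reading: the alpha band separates the groups strongly (the planted
effect; the small beta difference is alpha-source spectral leakage
through the adjacent filter skirt); the classifier beats its permutation
chance level decisively; and MoCA correlates with alpha PLI in the
patient group but not significantly in controls — the qualitative
signatures the analysis is designed to detect.  Exact numbers vary with
the seed and scale.

The same study runs from one command:

```bash
plimci run-all --config configs/reduced.toml --seed 0
plimci validate-table1   # desk check of the printed clinical-table statistics
```

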