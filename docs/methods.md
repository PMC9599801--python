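# Methods

`plimci` implements a resting-state EEG functional-connectivity analysis:
phase lag index (PLI) connectivity in the four classical frequency bands,
group comparison between type-2-diabetes patients with mild cognitive
impairment (MCI) and cognitively normal diabetic controls (NC),
cross-validated logistic-regression discrimination with a permutation-based
empirical chance level, and correlation of the alpha-band PLI with the
MoCA cognitive score.  Because no patient recordings are available, a
synthetic cohort generator with analytically known ground truth stands in
for the data; every downstream claim the package makes is therefore
checkable against that ground truth.

## Phase lag index

For two signals with instantaneous phases φ_i(t_k), φ_j(t_k) the PLI is

    PLI = | ⟨ sign(Δφ(t_k)) ⟩_k |,   Δφ wrapped to (−π, π],  sign(0) = 0.

PLI is 0 when the phase-difference distribution is symmetric around zero —
in particular for the spurious zero-lag coupling produced by volume
conduction — and 1 for a perfectly consistent non-zero lead or lag.  (The
common informal phrasing that "0 denotes complete synchronization" refers
to zero-*lag* synchronization, which PLI deliberately ignores; we implement
the standard definition.)

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) of the band-filtered epoch.  Choices:

* **Band filters**: 4th-order Butterworth, zero phase (forward–backward),
  bands delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz.
* **Edge trim**: 10 % of samples per epoch end (configurable) absorbs
  filter and Hilbert edge artifacts; residual phase error at the trim
  boundary is ≲ 0.03 rad on pure tones.
* **Aggregation**: PLI is computed within each 3 s epoch and averaged
  across epochs (pooling all samples first is available behind a flag).
  Epoch-averaged PLI of uncoupled channels has a positive floor ≈
  √(2/(πN_eff)) with N_eff the number of *independent* phase samples per
  epoch; for band-limited signals N_eff is far below the sample count
  (bandwidth-limited decorrelation), so uncoupled 3 s alpha epochs sit
  near PLI ≈ 0.2, not at the i.i.d.-floor value.  For truly independent
  per-sample phases the i.i.d. formula √(2/(πN)) is exact and is verified
  to Monte-Carlo precision in the tests.
* **Global synchronization**: mean over the strict upper triangle of the
  channel × channel matrix.

## Preprocessing

Fixed order, mirroring standard resting-EEG practice: drop EOG channels
(HEO/VEO) → re-reference to the linked-mastoid average (M1/M2, A1/A2
accepted; mastoids dropped afterwards) → 0.1–30 Hz band-pass → 48–52 Hz
band-stop → downsample to 500 Hz (integer decimation; the 30 Hz low-pass
is the anti-alias guard) → 3 s epochs → peak-amplitude epoch rejection
(default threshold 100 amplitude units).  Whether downsampling precedes
epoching is an implementation detail with no effect on non-overlapping
epochs; we downsample first.

All filters run forward–backward, one second-order section at a time, with
Gustafsson initial conditions.  This matters: the 0.1 Hz high-pass corner
has a seconds-long impulse response, and padding-based edge handling
(plain `filtfilt`/`sosfiltfilt`) leaks slow edge transients that can
dominate short recordings; the Gustafsson method chooses initial
conditions that minimize exactly these transients (measured stop-band
attenuation ≥ 60 dB at 80 Hz even on 4 s fixtures).

Component-based artifact removal (ICA) is not reimplemented: it is
irrelevant to synthetic fixtures and orthogonal to the method under study.
The amplitude-threshold rejection preserves the pipeline-stage contract
(epochs in, fewer epochs out, indices traceable).

## Synthetic cohort generator

Each channel is a sum of band-limited shared oscillators plus independent
1/f noise:

    x_i(t) = Σ_b κ_b · g_i^b · s_b(t + τ_i^b) + n_i(t)

* `s_b`: unit-variance Gaussian noise band-filtered to the oscillator band
  (delta 2.5 ± 1.5, theta 6 ± 2, alpha 10.5 ± 2.5, beta 21.5 ± 8.5 Hz).
* `κ_b`: coupling strength per band relative to unit noise
  (defaults 0.25 / 0.25 / 0.32 / 0.20; alpha dominates, as in eyes-closed
  rest).
* `g_i^alpha`: posterior/central channels (P, PO, C, CP prefixes) carry a
  1.3× alpha gain, mimicking the parieto-occipital concentration of
  resting alpha synchrony.
* `τ_i^b = φ_i / (2π f_c^b)`: a per-channel time shift realising phase lag
  φ_i at the band centre.  Default lags follow a golden-ratio sequence in
  (−π/4, π/4] — quasi-uniform, no accidental structure.  A time shift (not
  a phase rotation of the analytic signal) is used because it is the
  physical mechanism; it makes pairwise coherence slightly less than 1
  even without noise (the source decorrelates over the lag), which the
  ground-truth computation accounts for.
* `n_i`: independent pink noise (PSD ∝ 1/f above 1 Hz), sd 1.0; white
  noise available for unit fixtures.  Optional auxiliary channels (M1/M2
  reference noise, HEO/VEO slow drifts) exercise the preprocessing stages;
  re-referencing then injects a common zero-lag component that the PLI
  must — and does — ignore.

### Analytic ground truth

All model components are Gaussian, so the analytic-signal samples of two
band-filtered channels are correlated complex Gaussians.  Their
phase-difference density has the classical closed form in the complex
coherence γe^{iθ}:

    p(ψ) = (1−γ²)/(2π) · (1−d²)^{-1} · [1 + d·arccos(−d)/√(1−d²)],
    d = γ cos(ψ−θ),

and the infinite-data PLI of a pair is |2P(ψ>0) − 1|, one numerical
integral.  The coherence is computed by integrating the actual generator
and analysis filter responses (|H|⁴ for forward–backward filtering)
against the source and noise spectra — every shared oscillator contributes
to cross- and auto-spectra, noise only to auto-spectra, and the
per-channel lags enter through the source's complex autocovariance at the
pair's lag difference.  The density, the integral and the coherence are
each verified against independent Monte-Carlo oracles in the tests.

A subject's **true global alpha PLI** — the mean of the pair-level
infinite-data PLI — is stored in the cohort table, giving every recovery
test an exact target.  The finite-epoch estimator is upward-biased at low
coupling (the floor above), so measured values sit slightly above truth;
truth and measurement correlate at r ≈ 0.99 at the reduced scale.

### Cohort model

Two groups of 30.  Per subject, the alpha coupling is
κ_alpha · effect · exp(N(0, 0.2)), with effect = `group_effect` (default
0.7) for patients and 1 for controls.  Clinical covariates (age,
education, sex, diabetes duration) are drawn from group-specific
normal/Bernoulli models matching the study cohort's printed summaries.
MoCA is drawn conditionally on the subject's true global alpha PLI:

    MoCA = intercept + slope · PLI_true + N(0, σ),  clipped to [0, 30]

so the implied correlation is closed-form,
r = slope·sd(PLI) / √(slope²·var(PLI) + σ²).  The defaults
(MCI: 16.96 + 20.2·PLI ± 1.96; NC: 25.99 + 5.8·PLI ± 1.36) were set once
from the ground-truth PLI spread of each group at the default 62-channel
spec (MCI 0.254 ± 0.053, NC 0.358 ± 0.064) to imply r ≈ 0.48 (patients) /
0.26 (controls) and the printed MoCA means/sds.  Clipping at 30 censors
~9 % of control scores (as a bounded screening instrument does in
reality), slightly attenuating the control-group correlation; the
patient-group correlation — the scientifically relevant one — is
essentially unaffected, and recovery tests target it.

`group_effect = 0.7` and the subject coupling spread 0.2 were calibrated
once, by simulation at the reduced scale, to the detection-power property
(rank-sum rejection of equal group medians in ≥ 90 % of cohorts at
n = 30+30; measured power is ≈ 100 % with typical p ≈ 10⁻⁸, and empirical
type-I error ≈ 5 % with the effect removed).  They were not adjusted
afterwards.

Seeding: one master seed; per-subject streams derive from it by a counter
scheme (`SeedSequence(master, spawn_key=(subject_index,))`), so any
subject is independently regenerable and all outputs are bit-reproducible.

## Statistics

Student's pooled-variance t (df = n₁+n₂−2) for normal covariates, Pearson
χ² without continuity correction for sex (this convention reproduces the
printed cohort-table value 0.601 exactly), Wilcoxon rank-sum with
tie-corrected normal approximation and continuity correction for
non-normal outcomes (exact enumeration for tie-free n ≤ 10, which the
enumeration oracle test exercises), Shapiro–Wilk at α = 0.05 as the
normality screen routing t vs rank-sum, and Pearson correlation with the
t-transform p (df = n−2).  Per-pair band comparisons report raw p-values
(1891 tests at 62 channels); a Benjamini–Hochberg column is available but
off by default, since the primary analysis is deliberately uncorrected.

Two cells of the printed clinical table (age and MoCA t-values) cannot be
recovered from their own rounded summaries (they recompute to −0.509 and
−12.42 against printed −0.515 and −11.350, presumably rounding of the
underlying data); the reproduction check reports them as informational and
excludes them from pass/fail.

## Classifier evaluation

Logistic regression fit by iteratively reweighted least squares with an
L2 ridge of 10⁻⁶ on the slopes (never the intercept) for stability under
near-separation; a ridge-0 request that diverges is refit with the default
ridge and flagged.  The fit matches scikit-learn's LBFGS solution to
~10⁻⁸ on test problems.

Evaluation: stratified 10-fold cross-validation (seeded shuffling),
features z-scored on the training fold only (no leakage), patient class
positive.  Accuracy, sensitivity, specificity, precision and F1 come from
one confusion matrix pooled over all held-out folds; AUC from the pooled
held-out probabilities via the rank (Mann–Whitney) formulation with ties
counted ½ — identical to the O(n²) concordant-pair count, which the
property tests assert exactly.  Default feature set: global alpha PLI plus
the eight named electrode pairs (9 features); global-only and all-pairs
modes are configurable.

The **empirical chance level** is the 95th percentile of the pooled-CV
accuracy distribution under uniformly random label permutations (default
5000; the reduced config uses 500).  Finite samples inflate it well above
50 % — for balanced n = 60 it falls in (50 %, 75 %) — and by construction
uninformative data beat it in ≈ 5 % of replicates, which the calibration
test checks.

## Problem sizes

Defaults mirror the full study (62 channels, 1000 Hz, 300 s, 30+30
subjects, 5000 permutations).  Simulation-based tests and the worked
example run a reduced scale chosen as the smallest preserving every
statistical property: 8–16 channels, 250 Hz, 180 s (60 three-second
epochs), 30+30 subjects, 500 permutations.  Power/type-I use 16/48
replicate cohorts; correlation recovery uses 100 table-only cohorts (the
ground truth needs no signal synthesis); the estimator-floor check uses
10⁴ replicates of N = 1500 phases.

## Known limitations

* The generator's stationary Gaussian model omits non-stationarity,
  artifacts beyond amplitude spikes, heavy-tailed noise and genuine
  biophysics (no head/forward model); passing tests demonstrate estimator
  and pipeline correctness under the stated model, not clinical validity
  on real EEG.
* Only an amplitude-threshold stand-in for artifact rejection; no ICA,
  no bad-channel interpolation, linked-mastoid reference only.
* Regional structure is a single posterior alpha-gain multiplier, not a
  connectome.
* Epoch-averaged PLI is floor-biased at low coupling; group contrasts are
  unaffected (both groups share the bias) but absolute PLI levels should
  not be compared across epoch lengths.
* The alpha oscillator leaks through the skirts of the adjacent band
  filters, so the alpha group effect can surface as a small (marginally
  significant at n = 60) reduction of measured beta- and theta-band PLI
  in patients — a faint echo, in the right direction, of the marginal
  non-alpha differences such cohorts show; only the alpha contrast is a
  planted effect.
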