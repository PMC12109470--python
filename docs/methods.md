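# Methods

`eegmdd` implements a complete resting-state EEG analysis for two-group
(major depressive disorder vs. healthy control) detection: synthetic cohort
generation, signal cleaning, epoch extraction with amplitude quality
control, a region-wise feature schema, significance-routed feature
selection, a stacking ensemble classifier, and per-region ablation. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic benchmark does and does not demonstrate.

## Montage, regions, and bands

Recordings are 19-channel 10–20 montages sampled at 256 Hz, in microvolts
throughout. The scalp is partitioned into five disjoint regions:

| Region | Channels |
|---|---|
| Frontal | Fp1, Fp2, F3, F4 |
| Left Temporal | F7, T3, T5 |
| Parietal–Occipital | P3, P4, O1, O2 |
| Right Temporal | F8, T4, T6 |
| Central | C3, C4, Fz, Cz, Pz |

The default band scheme is δ 0.5–4, θ 4–8, α 8–13, β1 13–21, β2 21–30,
γ 30–48 Hz (`BANDS_STANDARD`). A narrow-edge preset with gaps between
bands (δ 1–3, θ 4–7, α 8–11, β1 12–20, β2 21–29, γ 30–48) ships as
`BANDS_NARROW` for comparison runs; the contiguous scheme is the default
because it partitions the filtered passband without dead zones.

## Synthetic cohort generator

Each subject's signal is the sum of

* six band-limited noise carriers (white noise FFT-masked to each band),
  with healthy-baseline RMS amplitudes δ 10, θ 6, α 8, β1 3, β2 2, γ 1 µV —
  a posterior-dominant, eyes-closed-like spectrum whose summed RMS
  (~15 µV) keeps epoch peaks comfortably under the 100 µV rejection
  threshold, as real accepted epochs are;
* 1/f^β broadband background (β = 1, 5 µV RMS over 0.5–48 Hz);
* frontal blink transients: half-cosine pulses of 0.3–2 s and 80–150 µV on
  Fp1/Fp2, scaled 0.3 on F3/F4 and 0.05 elsewhere (a rank-one spatial
  pattern, so ICA can isolate it), at 10 events/min;
* a 50 Hz sinusoid (2 µV) with random phase.

Carriers are noise rather than pure tones so the nonlinear features
(sample entropy, fractal dimension) are non-degenerate. Group effects are
multiplicative factors on the patient group's carrier amplitudes
(power scales with the square), optionally restricted to a subset of
regions; this keeps variances positive and makes relative-power effects
monotone in the factor. The default effect map raises θ and α by 1.3×,
β1/β2 by 1.2×, lowers γ to 0.8×, and leaves δ untouched — the direction of
group differences the analysis is designed to detect. Every subject's
stream is spawned from the cohort master seed, so cohorts are bit-reproducible.

What the generator does **not** emulate: neural-mass dynamics, non-stationary
band power, topographic correlation structure between channels (carriers are
independent per channel), realistic inter-subject variability beyond
realization noise, muscle/cardiac artifacts, or eyes-open/task conditions.
Consequently, passing tests demonstrate that the pipeline recovers planted
spectral group differences with controlled error rates — not that the
classifier accuracies transfer to clinical recordings.

## Preprocessing

* **Average reference**: subtract the instantaneous cross-channel mean;
  the per-sample channel mean is zero afterwards (≤1e−9 µV).
* **Filtering**: zero-phase (forward–backward) FIR band-pass 0.5–50 Hz,
  Hamming design, ~0.5 Hz transition at the low edge (~1690 taps at
  256 Hz), plus a 49–51 Hz FIR band-stop. Filtering is applied by FFT
  convolution with odd-reflection edge padding; forward–backward
  application squares the magnitude response, so mains attenuation far
  exceeds 20 dB while passband gain stays ≈1.
* **ICA artifact removal**: FastICA with one component per channel,
  *capped at the numerical rank of the data* — average-referenced data are
  rank-deficient by one, and whitening a singular covariance both stalls
  convergence and corrupts reconstruction. The unmixing is estimated on a
  decimated copy (≥20 k samples kept) and applied at full rate;
  deterministic given the seed. A component is removed when the absolute
  Pearson correlation between its time course and the frontal proxy (mean
  of Fp1 and Fp2 before decomposition) reaches the threshold (default
  0.7). Non-convergence is flagged in the `ArtifactReport` rather than
  raised: most background sources are near-Gaussian, for which full ICA
  rotation is unidentifiable in principle, while the spiky ocular
  component is identified long before formal convergence.

## Segmentation and QC

Recordings are cropped to 30–155 s, then cut into 32 s epochs with 1 s
overlap: epoch k starts at k·31 s, giving ⌊(125−32)/31⌋+1 = 4 epochs per
subject. An epoch is retained iff every channel's maximum absolute
amplitude is ≤100 µV **and** every channel's peak-to-peak amplitude is
≥1 µV. "Exceeding 100 µV" is interpreted as per-channel max-absolute and
"below 1 µV" as per-channel peak-to-peak — the usual epoch-rejection
semantics. QC only updates the retention mask and is idempotent.

## Feature schema (19 features × 5 regions = 95 columns)

All features are computed per channel on each retained epoch and
arithmetically averaged over the region's channels (not computed on the
region-mean signal, which would be sensitive to polarity cancellation).

**Spectral (9).** One full-range Welch PSD per channel-epoch (4 s Hann
segments, 50% overlap, density scaling, so the Simpson-integrated PSD of
white noise recovers its variance). From it: spectral centroid
(Simpson ∫f·S(f)df / ∫S(f)df), PSD-argmax frequency (ties to the lower
bin), six absolute band powers (Simpson over [f_lo, f_hi) on the grid), and
total power (Simpson over the full estimated range). A single PSD for all
bands keeps relative powers internally consistent. Absolute powers are the
stored features; relative powers are derived for the band-power report
(total power is itself a column, so nothing is lost).

**Temporal (3).** Skewness, Fisher kurtosis, and peak absolute amplitude.
Zero-variance epochs report (0, 0, peak) with a degeneracy flag.

**Nonlinear (5).**

* *Sample entropy* −ln(A/B), Chebyshev distance, self-matches excluded,
  m = 2, r = 0.2 × epoch SD. B = 0 returns +inf (capped to ln(N−m) in
  table assembly); A = 0 with B > 0 is capped at ln B + ln(N−m) so tables
  stay finite. The O(N²) pair count is numba-compiled (N = 8192 per
  epoch).
* *Higuchi fractal dimension*: curve lengths L(m,k) for offsets m = 1..k,
  averaged to L(k), k = 1..10; D = −slope of log L(k) on log k, reported
  clipped to [1, 2].
* *Hurst exponent* by rescaled range: for ~10 log-spaced window sizes from
  16 to N/2, the series is partitioned into disjoint windows from **both
  ends** (making the estimate invariant under time reversal); each window
  contributes (range of cumulative mean deviation)/SD, and H is the slope
  of log R/S on log n.
* *Shannon entropy* of a 128-bin equal-width amplitude histogram over
  [min, max] (scale-invariant by construction), in nats.
* *C0 complexity*, default mode: the maximum single-sided FFT amplitude
  2|X_k|/N (1.0 for a unit grid-frequency sinusoid). A `standard` mode —
  the fraction of spectral power carried by components at or below the
  mean spectral power — is available, since the field's usual C0 differs
  from the amplitude reading; the literal reading is the default.

**Time-frequency (2).** Mean and maximum of the magnitude-squared
spectrogram (1 s Hann windows, 50% overlap).

## Feature selection

Per feature: Shapiro–Wilk normality in both groups and median-centered
Levene variance homogeneity, all gated at 0.05. If all three pass, a
two-group one-way ANOVA (equivalent to the pooled t-test, F = t²);
otherwise a two-sided Mann–Whitney U. Raw p-values are Bonferroni-adjusted
over the tested family (adjusted = min(1, m·p)); a feature is kept iff
adjusted p < α (default 0.05; α ≥ 1 vacuously keeps everything). Normality
must hold in *both* groups for the parametric branch. Bonferroni controls
the family-wise error rate; an optional Benjamini–Hochberg mode exists but
is off by default. Selection operates on epoch-level rows by default
(each retained epoch is a sample); a `subject_mean` mode averages epochs
within subject first to guard against pseudo-replication.
`SignificanceFeatureSelector` exposes the same procedure as a
scikit-learn transformer.

## Classification

Eight fixed-parameter baselines: decision tree (depth 20, min split 10),
KNN (k = 5, distance weights), random forest (depth 10, 200 trees), RBF
SVM (C = 1, gamma auto), LightGBM (lr 0.1, 500), XGBoost (lr 0.05, 1000),
gradient boosting (lr 0.1, 200), MLP (50, 50; 1000 iterations). No
hyperparameter search is performed.

The stacking ensemble uses KNN (k = 5), a depth-5 decision tree and a
small XGBoost (lr 0.01, depth 3, 100 trees) as bases and a decision tree
as meta-learner. Bases emit positive-class *probabilities* (strictly more
informative than hard labels) as out-of-fold predictions over 5 internal
stratified folds — refit-on-train meta-features would leak. The
meta-feature matrix is [3 base scores ‖ original features] under
passthrough (59 columns for a 56-feature input); bases are refit on the
full training data for inference. Decision threshold 0.5.

Cross-validation is stratified 5-fold; the default grouping is by
*subject* (no subject's epochs span folds), which prevents identity
leakage — an epoch-level mode exists for comparison, and the leakage gap
between the two is itself bounded and tested. AUC is rank-based
(ties ½) and reported both pooled over folds and as the mean of fold AUCs.

## Region ablation and band report

Ablation restricts the table to one region's 19 columns, reruns selection
(Bonferroni m = 19) and the stacking CV, and ranks regions by accuracy; a
region where nothing survives selection falls back to its raw columns with
a flag. The band-power report derives relative powers per region
(band power / total power of the same region — note: the region mean of
per-channel ratios and the ratio of region means differ slightly; the
latter is used, being derivable from stored columns), and emits median,
Q1, Q3 (linear-interpolation quartiles), 1.5-IQR outliers, and a
Mann–Whitney p per region × band, with grouped box plots.

## Problem sizes in tests and the acceptance script

The full-scale protocol (19 ch × 256 Hz × 160 s, 32 s epochs) is exercised
by the schema, segmentation and end-to-end smoke tests. Monte-Carlo suites
(family-wise error, effect recovery, stacking no-harm) run on scaled-down
cohorts — 8–10 subjects per group, 17–24 s recordings at 128 Hz, 8 s
epochs with 1 s overlap, nuisance sources disabled where preprocessing is
skipped — chosen so each suite completes in minutes while keeping the
per-group sample sizes large enough for the tested error rates to be
meaningful. The acceptance script uses 12 MDD / 10 HC full-scale subjects,
a scaled-down cohort of the 34/30 defaults, with the complete
preprocessing chain including ICA.

## Known limitations

* Channel-independent carriers make region effects easier to localize than
  in real EEG, where volume conduction correlates neighbors.
* Classifier metrics on synthetic cohorts characterize the pipeline, not
  clinical performance; epoch-level CV in particular is optimistic when
  epochs of one subject land in both train and test folds.
* The ICA criterion targets ocular artifacts only; muscle/cardiac sources
  have no detector (and no generator model).
* Sample-entropy saturation (A = 0) and the B = 0 sentinel are rare on
  EEG-scale epochs but matter for very short or very regular inputs.
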