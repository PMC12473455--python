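# Methods

This note records the models, parameter choices and numerical decisions
behind `leadii`, and what the synthetic test bed does and does not establish
about real data.

## Data model and taxonomy

A subject is a 10 s, 500 Hz, 12-lead recording (5000 × 12 matrix, millivolts)
plus a diagnostics row: rhythm code, age, sex and eleven vendor-computed
(GE-MUSE-style) waveform attributes (ventricular/atrial rate, QRS duration,
QT, QTc, R/T axis, QRS count, Q onset/offset, T offset). Only lead II is
analysed; the MUSE attributes are trusted metadata and never re-derived from
signal. Q onset/offset/T offset are carried as opaque numeric features: their
sampling grid is not defined by the data dictionary, and nothing downstream
interprets their units.

Three label schemes: `eleven` (identity), `eight` (drops AVNRT, SAAWR, AVRT —
the rhythms with fewer than 20 subjects in the source corpus, too small for
per-class holdout), and `four` (AFIB ∪ AF → AFIB; SB; SA ∪ SR → SR; all
supraventricular tachycardias → GSVT). The four-group scheme maps all eleven
codes; exclusion is a property of the eight-class scheme only.

## Denoising chain

`bandpass → loess_baseline → nlm_denoise`, all length-preserving and
deterministic.

* **Band-pass**: 4th-order Butterworth, 0.5–50 Hz, applied forward–backward
  (zero phase). The designed zero-phase response is −15.3 dB at 60 Hz and
  −29 dB at 100 Hz; DC and sub-0.5 Hz wander are suppressed below 10⁻⁶.
  Note that a zero-phase high cut at 50 Hz also removes genuine QRS energy
  above 50 Hz; comparisons against a clean reference are therefore made
  mean-free and tolerate this fixed distortion floor.
* **LOESS baseline**: local-linear fit with tricube weights, span 1.5 s
  (750 samples). Degree 1 reproduces linear trends exactly and passes wander
  below ≈0.5 Hz into the baseline while leaving QRS complexes in the
  residual. Implemented via statsmodels `lowess` with robustness iterations
  off and linear interpolation between anchors (exact for degree-1 fits).
* **Non-local means**: patch half-width 10 samples (21-sample patches),
  search half-width 500 samples (option `"full"` scans the entire signal at
  O(N²)), weights `exp(−d² / (h²·L))` with `d²` the summed squared patch
  difference, `L` the patch length and `h = 0.6·σ̂`,
  `σ̂ = median|Δx| / 0.6745 / √2` (robust to QRS spikes). The centre sample's
  self-weight is the maximum off-centre weight, so no sample is averaged
  predominantly with itself. Output samples are convex combinations of input
  samples. If every candidate weight underflows (essentially noise-free
  input), the sample passes through unchanged. A second pipeline pass changes
  the output by ~9% RMS on the standard noisy fixture — the residual of
  in-band noise — and the change shrinks on each further pass.

## Feature bank (25 signal descriptors)

Time-domain definitions are exact formulas on the denoised trace; windowed
variants use non-overlapping windows (PPA: 1 s ranges; RMS2: 2 s RMS values,
both averaged). SNEO smooths the Teager energy with a normalized 7-point
Bartlett window. Two features in the source literature share the MSI
acronym (median stepping increment; Poincaré median successive increment):
on the identity-lagged Poincaré plot these coincide up to √2, so a single
MSI column (median |Δx|) is emitted — this is also the only reading
consistent with a 38-column table.

Spectra are Welch averaged modified periodograms: 2048-point Hamming
segments, 50% overlap, `scaling="spectrum"`, no detrending (the band-pass
already removed DC); amplitude is √power. Analysis band 0.5–50 Hz, matching
the filter. Shorter inputs are zero-padded to one segment and flagged.
Definitions for the under-specified descriptors: PSA = mean band power
(ENRG / #band bins); CP = power at the bin nearest CF. SFM and CP sit on the
leakage floor between spectral peaks and are phase-sensitive at the tens of
percent level; CF/PF are stable to one bin (fs/2048 ≈ 0.244 Hz) under
circular time shifts.

Nonlinear group:

* **Hurst (R/S)**: mean rescaled range over non-overlapping dyadic windows
  16 … N/4, divided by the Anis–Lloyd–Peters white-noise expectation;
  H = 0.5 + slope of log(R/S / E[R/S]) vs log window. The correction removes
  the small-window upward bias; measured calibration (50 seeds, N = 5000):
  white noise 0.50 ± 0.03, random walk 0.95 ± 0.01.
* **DFA-1**: integrate the mean-removed signal, linearly detrend
  non-overlapping boxes of ten log-spaced sizes 4–64, slope of log F(n).
  Calibration: white 0.54, integrated 1.50, 1/f surrogate 1.01.
* **LAC**: log₁₀ Σ₁⁵⁰ |ρ(k)| of the mean-removed signal.
* **Entropies**: WE = Shannon entropy of relative subband energies of a
  5-level db4 wavelet decomposition, normalized to [0, 1]; SpeEnt =
  normalized Shannon entropy of band power (clamped into [0, 1]: it is
  exactly 1 on a flat spectrum up to an ulp); ApEn(m=2, r=0.2·SD, Chebyshev
  distance, self-matches included) and FuzzyEn (same m, r; baseline-removed
  templates, membership `exp(−(d/r)²)`, self-matches excluded). ApEn and
  FuzzyEn run on the signal decimated (anti-aliased) to 125 Hz: the template
  search is quadratic in length and the descriptors target sub-50 Hz
  regularity.

Degenerate inputs (constant signal, zero band power) yield `nan` plus a
`DegenerateSignalWarning`; imputation happens only inside model training
(per-feature training-fold medians), never at load or extraction time.

The table is 13 metadata + 25 signal features; named subsets `general4`
(age, sex, ventricular/atrial rate), `morph13` (all metadata), `ours29`
(general4 + signal), `all38`. Sex is coded female = 0, male = 1.

## Feature ranking

MRMR: continuous features are discretized into 10 equal-frequency bins
(rank-based, hence invariant to strictly monotone transforms; missing values
form their own bin); plug-in MI in bits; greedy selection by the quotient
criterion relevance / mean-redundancy (MIQ; MID available), ties broken by
column order. ReliefF: range-normalized features, every sample an anchor,
10 nearest hits and per-class nearest misses by Manhattan distance, miss
terms weighted by `P(class)/(1 − P(anchor class))`.

## Separability

Indices are computed on the z-scored, median-imputed feature matrix against
ground-truth labels (the report carries a standardization tag so alternative
preprocessing is auditable). Silhouette requires ≥ 2 members per class;
Davies–Bouldin permits singletons but rejects coincident centroids;
Calinski–Harabasz flags zero within-scatter as infinite. PCA projections are
deterministic (full SVD of the standardized matrix); t-SNE (perplexity 30,
capped at (n−1)/3, fixed seed) is visualization plumbing, not a quantitative
surface.

## Evaluation protocol

Balanced holdout: exactly `n_test_per_class` uniformly sampled test examples
per class, complement trains; chance accuracy is 1/k regardless of the
original imbalance. An 80:20 stratified split is available as a variant.
Imputation and (for distance/gradient models) standardization are fitted on
training rows only, inside one sklearn pipeline. Families approximate
default-settings classifiers: 30 bagged unpruned trees; one-hidden-layer
MLPs with 10 ("narrow") or 100 ("wide") units, iteration cap 1000; 10-NN
(neighbour count clamped to the training size on tiny cohorts); linear SVM.
No tuning — these are deliberate defaults, not claims of bit-compatibility
with any other toolbox. Repetition r of an experiment uses seed
`base + r` for both split and estimator. Macro metrics average per-class
values unweighted (the balanced test set makes weighting moot); a class with
no predicted positives contributes precision 0 with a warning; AUC is
one-vs-rest on continuous scores.

## Synthetic cohort generator

Beats are sums of five Gaussian kernels (P, Q, R, S, T; R dominant) placed
at times whose RR intervals are i.i.d. lognormal with class-conditional mean
heart rate and coefficient of variation; the whole record is a pure function
of (model, template, noise, seed). Fast rhythms compress the beat template
(factor min(1, RR/0.8 s)) so adjacent beats stay ordered; a mean RR shorter
than the QRS support raises an infeasibility error. Class parameters (an
invented fixture): SB 50±5 BPM regular; SR 75±8 mild variation; SA 70±8 with
RR CV 0.12; ST 120±15; SVT 180±20 and AVNRT/AVRT ~170, all without P waves;
AT 140±15; AFIB 110±20 with RR CV 0.25, no P wave, three-tone 4–9 Hz
fibrillatory baseline; AF (flutter) 110±15 with a 300/min sawtooth; SAAWR
90±15. Noise is additive: wander sinusoid (default 0.10 mV at 0.25 Hz),
50 Hz powerline tone (0.03 mV; the corpus region uses 50 Hz mains), white
noise (0.03 mV SD). Diagnostics are derived from generator truth
(ventricular rate = 60/mean RR, QRS count = beats placed, QT from template
geometry, QTc = QT/√RR); the other 11 lead columns are scaled copies of
lead II — plumbing to satisfy the file format, not vectorcardiographically
consistent.

`generate_feature_table` bypasses signals entirely: class-conditional
Gaussian features with specified mean shifts plus pure-noise null features,
for testing ranking and classification against known ground truth.

**What the synthetic bed shows and does not show.** Passing tests establish
that the machinery is correct (formulas match brute-force oracles, the
protocol is leak-free and balanced, rankers recover planted signal, the
qualitative 8-vs-4-class separability ordering emerges). They do not
establish clinical performance: real ECGs have morphology variation,
artefacts, inter-patient variability and label noise that the generator does
not emulate, and the synthetic classes are more separable than real rhythm
classes. Real-data numbers must be obtained by pointing the loaders at the
actual corpus.

## Problem sizes

The default test suite and the acceptance script are sized for a single CPU:
cohorts of 12–16 records per class, NLM search half-width 120–200 samples in
fixtures (500 remains the analysis default), 50-seed estimator calibrations
at N = 5000, and 100-seed selection-recovery runs at 120 × 20 tables. These
sizes were chosen so each check's statistical resolution comfortably exceeds
the margin it asserts.

## Known limitations

* NLM with the default 500-sample search window is "semi-local"; `"full"`
  search honours the whole-signal definition at quadratic cost.
* The 60 Hz rejection of the default band-pass (~15 dB zero-phase) is modest;
  records from 60 Hz-mains regions may retain a powerline residual (the
  generator emits 50 Hz interference).
* MUSE attribute sanity checks are advisory; implausible metadata is kept
  (as `nan` only when absent), matching the source data's behaviour.
* Classifier families approximate, but do not replicate, any particular
  toolbox's default implementations.
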