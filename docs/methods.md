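# Methods

This note documents the models, algorithms, parameter choices and
limitations of the seizurekit pipeline, in the order data flows through it.

## Synthetic EEG cohorts

The generator produces annotated multi-channel recordings whose statistical
structure matches what the pipeline assumes, not a biophysical simulation.

**Background.** Each channel is Gaussian noise shaped to a 1/f^α power
spectrum (α = `background_spectral_slope`, default 1.0), scaled to a target
RMS of 20 µV. Two per-patient factors are drawn once per patient and shared
by all of that patient's recordings:

- a multiplicative amplitude factor, lognormal with log-sd
  `baseline_offset_sd` (default 0.5, i.e. patients typically differ by
  factors of ~0.6–1.6 in amplitude and hence ~0.4–2.7 in power), and
- a spectral-slope offset, Gaussian with sd `spectral_slope_sd`
  (default 0.3, floored at slope 0.2).

Together these emulate inter-patient baseline amplitude *and* spectral
shape differences. Both matter: amplitude shifts confound power-type
features, slope shifts confound scale-invariant shape features
(zero-crossing rates, Hjorth mobility, spectral edge frequencies), and the
feature baseline correction stage must remove both kinds of offset.
Setting both sds to 0 disables shift injection, which is the control
condition used in tests.

**Seizures.** Each recording contains max(1, Poisson(`seizure_rate`))
seizures (default rate 2; draws that do not fit the recording are truncated
to the largest count that fits, never below 1). A seizure is an
amplitude-ramped sinusoid (Tukey envelope, 25 % taper per side) at a
frequency drawn from `seizure_freq_hz`, added either to all channels
(generalized, probability 0.5) or to a random half of the channels (focal),
with amplitude 2× the patient's background RMS. The neonatal-like preset
(9 channels, 1–3 Hz, 30–120 s, plus a half-amplitude second harmonic for
the more complex neonatal waveform morphology) and the adult-like preset
(19 channels, 3–7 Hz, 20–90 s, no harmonic) differ in montage, rhythm and
waveform complexity. Seizure onsets never occur in the first 180 s, so a
clean baseline window always exists. Annotations are global half-open
`[start_s, end_s)` intervals; the channel subset carrying each discharge is
recorded but not exported, matching annotation practice where seizures are
marked in time rather than per channel.

Generation is a pure function of (config, patient index, record index);
seeds derive from `numpy.random.SeedSequence` keyed on the config seed, a
CRC of the cohort name, and the indices.

**What the generator does not model:** artefacts (eye blinks, ECG,
movement, electrode pops), medication/vigilance drift over hours,
non-stationary background states (trace alternant, burst suppression),
realistic seizure evolution (frequency gliding, spike-wave morphology),
or channel-to-channel correlation structure. Passing tests therefore show
that the pipeline's mechanisms work when its assumptions hold — notably
that baseline offsets are per-patient and approximately multiplicative —
not that clinical performance figures transfer.

## Preprocessing

Order fixed: band-pass → down-sample → epoch. The band-pass is a 4th-order
zero-phase Butterworth (forward–backward), default 0.5–32 Hz. Down-sampling
(default 25 Hz) applies an 8th-order zero-phase Butterworth low-pass at
0.45·f_target before polyphase decimation; a printed 0.5–32 Hz band
followed by 25 Hz sampling would otherwise alias (Nyquist 12.5 Hz). The
anti-alias stage can be disabled (`antialias=False`) for signals already
band-limited. Epochs are 10 s with a 5-s stride; epoch count =
floor((duration − length)/stride) + 1. An epoch is labelled seizure iff its
overlap with the union of annotated intervals is ≥ 50 % of the epoch length
(inclusive at the boundary); the fraction is configurable in (0, 1].

## Feature battery (103 per epoch per channel)

Spectral estimates use a Welch periodogram with 2-s Hamming windows and
50 % overlap (0.5-Hz resolution at 25 Hz). Band powers integrate the PSD by
the trapezoid rule; bands extending past the effective Nyquist are clipped
and return the energy actually present (≈0). The itemization, in manifest
order: total power 0–12 Hz (1); peak frequency (1); SEF 80/90/95 % (3);
2-Hz subband powers 0–2 … 10–12 Hz (11) and the same normalized by total
power (11); Db4 wavelet detail energies at levels D4 (≈0.78–1.56 Hz) and D3
(≈1.56–3.13 Hz), the two scales bracketing the 1–2 Hz delta band at 25 Hz
(2); curve length Σ|Δx| (1); counts of local maxima and minima (2); RMS
(1); Hjorth activity/mobility/complexity (3); zero-crossing rates of x, Δx,
ΔΔx about their means (3); variances of Δx and ΔΔx (2); Burg AR residual
variance for orders 1–9 from a single lattice recursion (9); skewness and
kurtosis (2); mean Teager energy x²ₙ − xₙ₋₁xₙ₊₁ (1); Shannon entropy of the
normalized squared amplitudes, spectral entropy of the normalized PSD
(nats), SVD entropy and Fisher information of the normalized singular-value
spectrum of the delay-embedding matrix (dimension 20, delay 1) (4); 15-band
linear filter-bank energies 0–2 … 14–16 Hz (15); 15 cepstral coefficients
(orthonormal DCT-II of the log filter-bank energies, ε = 1e-12 inside the
log) (15); 15 frequency-filtered energies (first-order differences of
neighbouring log energies, zero-padded at the edges) (15); peak–peak
voltage (1). Total 103; names, groups and parameters are exposed as a
versioned machine-readable manifest.

Degenerate inputs never produce NaN/Inf: a constant epoch returns 0 for
curve length, Δ-variances, Hjorth parameters, entropies, skewness,
kurtosis, peak frequency and SEFs (its DC band power is still reported as
the real power present).

Scale behaviour is part of the contract and is asserted per feature group:
multiplying an epoch by k scales power-type features by k², amplitude-type
features by k, and leaves normalized subbands, ZCRs, Hjorth
mobility/complexity, entropies, skewness and kurtosis invariant.

## Feature baseline correction

FBC subtracts an estimate of each feature's optimal detection threshold,
per patient and channel, so that after correction the threshold is the same
(≈0) everywhere.

- **Orientation.** A global per-feature sign (+1 if the feature is on
  average higher during seizure on the training data, −1 otherwise) maps
  all features to "higher = more seizure-like" before thresholding.
- **Optimal threshold.** Maximizes Youden's J (sensitivity + specificity −
  1) for the rule "seizure iff value ≥ threshold"; candidates are midpoints
  between adjacent sorted unique values; ties on J return the midpoint of
  the lowest and highest tied candidates. In the perfectly separable case
  this is the midpoint of the separating gap.
- **Baseline.** aNS is the mean over the first 10 non-seizure epochs whose
  start lies in the first 180 s (count and window configurable; fewer
  available epochs are used as-is and recorded). Baseline epochs are chosen
  automatically by the annotations rather than visually.
- **Regression.** For each feature, ordinary least squares of Tr on aNS
  over all training (patient, channel) points where a Tr is computable,
  pooled across channels. Features with fewer than 2 distinct aNS values
  fall back to slope 0 / mean-Tr intercept, or to slope 1 / intercept 0
  (pure aNS subtraction) when no points exist.
- **Application.** corrected = sign·feature − Tr, where Tr is the
  annotation-derived value in the training phase (channels where
  computable, regression estimate elsewhere) and always the regression
  estimate slope·aNS + intercept at test time.

With only a handful of training patients the Tr~aNS regression residual is
large relative to the within-patient spread of weakly informative features,
and the train/test threshold mismatch can hurt; the benefit appears
reliably from roughly 6–8 training patients upward in the synthetic world.

## Classifier

Soft-margin SVM with Gaussian kernel k(u, v) = exp(−‖u−v‖²/(2σ²)) (so the
scikit-learn `gamma` is 1/(2σ²)); decision values are signed distances from
the decision surface. Features are standardized to zero mean and unit
(population) sd with training-set parameters only; constant features get an
sd guard of 1.

Training sets are sampled so each patient contributes equally:
largest-remainder quotas of the target counts (defaults 4500 seizure / 9000
non-seizure feature vectors), seizure draws capped at 24 per patient per
channel, sampling without replacement within a patient, fully reproducible
from the spec seed. Shortfalls take everything available and are recorded.

Grid search selects (C, σ) maximizing mean AUC over 5-fold patient-grouped
inner cross-validation of the training set; ties break toward smaller C
then smaller σ. Default grids C ∈ {10, 20, 40, 50, 100},
σ ∈ {4, …, 9} contain the published per-scenario optima, which also ship
as named presets used by the experiment matrix.

Support-vector composition reports, for a classifier trained on a combined
cohort, each cohort's share of the support vectors, the share per
(cohort, class), and the fraction of each subset's training vectors that
became support vectors — the margin-region diagnostic for which cohort
contributes the harder examples.

## Post-processing

Per epoch, channel outputs are sorted ascending; the value at rank k over
time forms the k-th sorted output series (the only reading under which
"sorted output time series" are well-defined objects to filter). Each rank
series is smoothed by a causal scalar Kalman filter with random-walk state
(x_k = x_{k−1} + w, w~N(0, q)) and white measurement noise (r), defaults
q = 0.01, r = 1 — the minimal "remove random noise" smoother, with
closed-form limits used as oracles (constant-input fixed point; q = 0 with
a diffuse prior equals the running mean; steady-state gain from the Riccati
equation). The posterior variance is updated as gain·r, which is exact
algebraically and avoids the catastrophic cancellation of (1 − gain)·p for
diffuse priors. Filtering is causal only (online monitoring is the intended
use); configurable to filter all ranks (default), only the top rank, or
none (q→∞ and "none" both reduce to the raw per-epoch max). The
multi-channel score is the per-epoch maximum over filtered ranks —
detection in at least one channel — and decisions are score ≥ threshold.

## Evaluation

- **Balancing.** Per patient, seizure and non-seizure epochs are resampled
  *with replacement* up to Nmax-S and Nmax-NS (the largest per-patient
  counts), keeping every original epoch and topping up with random copies;
  seeded. Patients missing a class contribute only the class they have.
- **ROC/AUC.** All distinct thresholds, trapezoidal area, equal to the
  normalized Mann–Whitney U statistic with ties half-weighted.
- **Vertical averaging.** Sensitivities interpolated onto a specificity
  grid (0 to 1, step 0.01) and averaged pointwise across Monte-Carlo runs.
- **Event metrics.** A false detection is a maximal run of positive epochs
  none of which overlaps (half-open epoch intervals, any overlap counts)
  an annotated seizure; FD/h divides by total recording hours. A seizure is
  detected if at least one positive epoch overlaps it (SDR = detected /
  total). The operating threshold is the largest achieving ≥ 80 % epoch
  sensitivity, chosen per run (per-run and averaged-curve choices both
  exposed).
- **Statistics.** Shapiro–Wilk on each group at α = 0.05; both compatible
  with normality → two-sample t test, otherwise Wilcoxon rank-sum;
  significance at p < 0.05.

## Protocols and reproducibility

Leave-one-patient-out is used whenever the test cohort contributes to
training; the held-out patient enters no fitted component (orientation,
baselines, FBC regression, standardizer, grid search, SVM). In combined
training the other cohort joins every fold's training set. Cross-cohort
evaluation trains a single classifier per run. Monte-Carlo repetition
(default 10 runs) re-samples the training set each run with seeds derived
from the master seed by a splitmix64-style hash (kept below 2³¹); annotated
per-patient thresholds are memoized across folds and runs (they depend only
on the patient's own data and the global orientation, so sharing them moves
no information across patients). The full experiment matrix is 3 training
compositions × 2 test cohorts × {FBC, no FBC} = 12 cells.

## Problem sizes used in tests and examples

Cohort-config defaults remain at registration scale (20-min recordings,
250 Hz, 9/19 channels, ~40-patient cohorts are feasible). The shipped tests
and examples run smaller worlds, chosen as the package's own desk scale:
unit tests use a 3-patient, 240-s neonatal-like cohort; the end-to-end
FBC-mechanism test uses two cohorts (5 neonatal-like + 4 adult-like
patients, 480-s recordings), pooled leave-one-patient-out with training
targets 600/1200 feature vectors and the combined-training preset
C = 50, σ = 6, over 10 Monte-Carlo runs, against the same world with shift
injection disabled; the 12-cell matrix smoke test uses 2 patients per
cohort, 240-s recordings and 2 Monte-Carlo runs.

## Known limitations

- The synthetic world's Tr~aNS linearity is partly by construction
  (multiplicative amplitude shifts); real EEG satisfies it only
  approximately and feature-dependently.
- FBC with a fixed baseline is not suited to multi-day monitoring where
  the baseline itself drifts; no baseline-update mechanism is provided.
- FD/h ignores the duration of each false detection.
- The EDF writer emits plain EDF (16-bit, 1-s records) without EDF+
  annotation channels; annotations travel in a CSV sidecar.
- Epoch labelling uses a global (not per-channel) seizure annotation, so a
  focal seizure labels all channels' feature vectors of that epoch as
  seizure.
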