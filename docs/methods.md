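# Methods

This note documents the models, parameter choices and numerical decisions
behind `ppgbp`, and what the synthetic cohort does and does not emulate.

## Signals and references

A record is a single-channel PPG waveform (arbitrary units, 100–125 Hz
typical) with a reference blood pressure. The reference comes from one of:
a co-recorded arterial pressure waveform (reference SBP = mean of detected
ABP peaks, DBP = mean of troughs, every detected beat over the whole
record), a beat-by-beat SBP/DBP series (component-wise means), or a
directly supplied pair. Records shorter than 60 s are rejected with a
warning — below that the spectral dynamics features are undefined.
Delimited text is comma-separated, "." decimal, UTF-8; feature tables carry
a mandatory header and round-trip at 12 significant digits.

## Synthetic cohort generator

Clinical waveform databases cannot be redistributed with the package, so
the test bed is a generative model whose ground truth is known exactly.

Each subject is assigned (SBP, DBP) uniformly from (105–152, 54–73) mmHg.
A unit-amplitude pulse template on beat phase [0, 1) has a cosine systolic
upstroke peaking at fraction u, a cosine-power diastolic decay with
exponent p, and an optional broad Gaussian dicrotic wave (centred at 50% of
diastole, width 0.18 of diastole, sine-windowed so the template starts and
ends at zero). The couplings are affine and fixed:

| quantity | coupling | direction |
|---|---|---|
| upstroke fraction | u = 0.42 − 0.0025 (SBP − 100) | ↓ with SBP |
| decay power | p = 2.2 − 0.02 (DBP − 50) | ↓ with DBP (fatter tail) |
| dicrotic amplitude | a = 0.04 + 0.002 (DBP − 50) | ↑ with DBP |
| mean IBI (s) | m = 1.05 − 0.004 (SBP − 100) | ↓ with SBP |
| IBI jitter SD (s) | j = 0.008 + 0.0004 (DBP − 50) | ↑ with DBP |

The IBI sequence is m plus LF (0.1 Hz, 0.02 s) and HF (0.25 Hz, 0.015 s)
sinusoidal modulation plus Gaussian jitter; onsets are cumulative sums, and
any parameterisation producing an interval ≤ 0.25 s is rejected. The PPG is
the template resampled to each beat's interval plus optional additive
Gaussian noise; the ABP channel is `dbp + (sbp − dbp) · template`, so every
beat's extremes equal the assigned pressures — the basis of the
reference-recovery checks. The dicrotic wave is deliberately broad and
low-amplitude, as physiological dicrotic waves are; a narrow bump would
carry upstroke-grade derivative energy and is not a realistic pulse.

Per-subject seeds are spawned deterministically from the master seed, so a
cohort of any size is reproducible byte-for-byte.

What the generator does **not** emulate: sensor optics, motion artifacts,
baseline wander, arrhythmias, or the physiological transfer from pressure
to peripheral blood volume. Passing parameter-recovery tests therefore
demonstrates the pipeline's internal correctness (features measure what
they claim; estimators recover a learnable coupling; no leakage), not
clinical accuracy on real patients.

## Fiducial detection

The peak detector adapts the Pan–Tompkins QRS pipeline to PPG pulse rates;
every constant is a config field:

* band-pass 0.5–8 Hz (2nd-order Butterworth, zero-phase),
* derivative → squaring → 150 ms moving-window integration,
* adaptive dual thresholds (running signal/noise peak estimates with 0.125
  update weight, acceptance at noise + 0.25·spread), 250 ms refractory,
  and missed-beat search-back at 1.66× the running mean interval with a
  half threshold,
* crest refinement: the integrated-energy burst sits mid-upstroke, roughly
  half the systolic upstroke time *before* the raw peak, so the refinement
  window is forward-biased (−100/+300 ms). Within it, the argmax of a
  40 ms moving average seeds a cubic-polynomial fit over ±96 ms whose
  interior local maximum is the peak. A cubic (not a parabola) is used
  because the crest's curvature differs on its systolic and diastolic
  sides; a parabola vertex is biased toward the flatter side by several
  samples at sharp-upstroke/slow-decay pulse shapes, while the cubic keeps
  the worst-case noiseless bias at ≤ 2 samples across the generator's full
  BP range and ≥ 95% of peaks within ±3 samples at 20 dB SNR.

All thresholds are relative, so detection is invariant to positive
amplitude scaling. Troughs are defined as inter-peak minima (plus a leading
trough when a minimum exists in the 1.5 s before the first peak), which
guarantees strict peak/trough interleaving. IBIs outside [0.3, 2.0] s are
dropped by the physiologic screen (count reported) — this stands in for the
upstream curation that clinical databases receive.

Pulse quality is screened by adjacent-pulse correlation: segments are
linearly time-normalised to a common length and each pulse's mean Pearson
correlation with its neighbours must reach 0.9 (configurable). This
replaces manual visual inspection with the successive-pulse
autocorrelation rule used by clinical data providers.

## Morphology features

Pulse height is measured from the segment-onset amplitude to the peak —
within one pulse, not from a global baseline. Level crossings at fraction h
of the height are linearly interpolated between bracketing samples, which
removes sampling-rate dependence; the systolic width takes the *last*
upward crossing before the peak and the diastolic width the *first*
downward crossing after it, so dicrotic re-crossings resolve to the points
nearest the peak. A pulse that never crosses a level on one side is
excluded from the record mean and counted, never imputed. Diastolic time is
measured peak-to-segment-end (so CP = SUT + DT exactly); the
peak-to-dicrotic-notch alternative is noted but not used. The mPTP average
spans the whole record.

Invariants the tests enforce: time-scale equivariance (compressing a pulse
by c scales all durations by c and leaves ratios unchanged), amplitude
invariance, monotone decrease of widths in h, and agreement of the
interpolated crossings with a brute-force scan of a 100×-oversampled pulse
to within one fine-grid step.

## Dynamics features

Population (n-denominator) variance is used throughout, making the
Poincaré identities exact: SD1² = ½·Var(ΔIBI), and generally
SD1² = ½(RMSSD² − mean(Δ)²). NNx uses x = 50 ms with strict inequality (the
HRV-standard convention; configurable since other choices exist). The
histogram-geometry features use a 1/128 s bin aligned to multiples of the
bin width; TINN is the base of the least-squares triangle with apex fixed
at the mode. Spectral features cubic-interpolate the tachogram to 4 Hz,
remove the mean, and integrate a Welch periodogram (120 s segments, 50%
overlap, Hann window) over 0.04–0.15 Hz (LF) and 0.15–0.40 Hz (HF); LF/HF
is flagged undefined when HF is zero. SampEn uses m = 2,
r = 0.2 × population SD, Chebyshev distance, self-matches excluded; a
constant series (r → 0) or zero match count at length m+1 is undefined,
reported as missing.

DFA integrates the mean-centred series and detrends linearly per
non-overlapping box; α1 fits boxes 4–16 (needs ≥ 100 intervals) and α2
boxes 16–64 (≥ 300 intervals). The fluctuation function carries the exact
finite-size deflation n/√(n²−4): for an uncorrelated series
E[F²(n)] = σ²(n²−4)/(15n) under linear detrending, so without the factor
the white-noise slope over boxes 4–16 is ≈ 0.58–0.6 even asymptotically.
With it, white noise yields α1 = 0.50 ± 0.03 (SD over seeds, n = 1000)
while integrated noise yields ≈ 1.41 ± 0.05 — the correction is exact only
for memoryless series, and strongly correlated processes remain slightly
deflated at these box sizes. A series whose integrated profile vanishes
(constant input) has F ≡ 0 and its exponents are undefined.

Every undefined feature propagates as NaN with a reason string; the models
reject rows containing missing values rather than imputing.

## Estimators and training

Architectures (all linear mmHg outputs):

| name | layout | hidden activation |
|---|---|---|
| `morph_ffnn` | 21 → 35 → 20 → 2 | sigmoid |
| `morph_deep` | 7 → 70 → 100 → 150 → 2 | sigmoid |
| `morph_lstm` | 7 → LSTM(64) → LSTM(512) → 2 | ReLU |
| `morph_gru` | 7 → GRU(128, 256, 512) → 2 | ReLU |
| `final_sbp` / `final_dbp` | 8 → 10 → 1 | sigmoid |

The recurrent models treat each subject's static 7-vector as a length-1
sequence with zero initial state — the only reading consistent with one
feature vector per subject. Under it the hidden-to-hidden weights (and the
LSTM forget gate) receive no gradient and cannot affect the output, so they
are omitted from the parameterisation; the gated input transforms remain.

Training is full-batch Adam (lr 1e-2) on mean-squared error summed over
outputs, with L2 weight decay (1e-4) on weights (not biases), a seeded
85/15 train/validation split, early stopping with patience 50 (best
validation weights restored), and a 2000-epoch cap. The learning rate is
larger than the common 1e-3 default because targets stay in natural mmHg
units (no target scaling; the output bias is initialised at the
training-target mean) and the linear output layer must traverse tens of
mmHg within the epoch budget. The z-score feature scaler is fit on the 85%
training split only; tests assert the scaler equals the training-split
statistics exactly. (data, config, seed) fully determine the trained
weights; backpropagation is verified against numerical gradients for all
three layer types.

An optional MacKay-style Bayesian-regularisation trainer (Gauss–Newton /
Levenberg–Marquardt with evidence-driven re-estimation of the prior and
noise precisions) is provided for the small single-hidden-layer final nets,
where the 101-parameter Hessian is cheap; the default trainer is Adam with
validation-based early stopping for all architectures.

The composite model trains the deep morphology net first, then feeds its
in-sample estimates (alongside the dynamics features) to the final nets —
peak-IBI dynamics to the SBP net, trough-IBI dynamics to the DBP net.
Leave-one-out evaluation retrains everything per fold; the held-out
subject never enters its fold's training or validation split, and a
training row identical to the held-out row raises a leakage error.

## Fusion and selection

Inverse-variance fusion follows the minimum-variance combination of
independent estimates; fusing k methods pairwise is associative and equals
the precision-weighted mean. Method variances are population variances of
(estimate − reference) computed on training-fold subjects only — never the
evaluation subject — and floored at 1e-6 mmHg² before inversion to guard
the degenerate perfect-method case. Greedy forward wrapper selection adds
features by 5-fold subject-level cross-validated MAE of the wrapped
estimator (ordinary least squares by default; any fit/predict callable can
be wrapped), stopping when the improvement falls below 1e-3 mmHg or the
feature budget is reached.

## Evaluation conventions

Errors are oriented estimate − reference. SDE uses the population
(n-denominator) SD, consistent with the variance conventions above, and
Bland–Altman limits of agreement are bias ± 1.96 × population SD. The
identity SDE² = mean(e²) − ME² is asserted to 1e-12.

## Problem sizes

Cohort-level tests and the acceptance script use 100 noiseless subjects
with 360 s records at 125 Hz (the generator default record length is
480 s). 360 s keeps ≥ 300 beats per subject at the slow end of the coupled
heart-rate range, so DFA α2 stays defined for every subject; held-out
evaluation uses a 75/25 split and leave-one-out runs use a 30-subject
sub-cohort. On one CPU the full test suite runs in under two minutes and
the acceptance script in under one.

## Known limitations

* The generator's affine BP→shape couplings are a device for provable
  parameter recovery, not a physiological model; absolute error levels on
  synthetic cohorts say nothing about clinical performance.
* DFA α for strongly correlated series is slightly deflated at the small
  α1 box sizes (see above); comparisons should use the same estimator.
* The wrapper selection's internal CV scheme and the NNx threshold are
  field conventions, not uniquely determined choices; both are exposed in
  config.
* Recurrent architectures add capacity but no sequence information under
  the length-1 reading; they are included for architectural completeness.
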