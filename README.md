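# ppgbp — calibration-free cuffless blood pressure estimation from a single PPG channel

`ppgbp` implements an end-to-end pipeline that estimates systolic and
diastolic blood pressure (SBP/DBP, mmHg) from a single photoplethysmogram
(PPG) waveform, with no per-subject cuff calibration at use time. It is
aimed at physiological-signal researchers who want a fully testable,
deterministic reference implementation of the morphology + cardiovascular-
dynamics approach to cuffless BP, including a synthetic coupled PPG/ABP
cohort generator so that every stage can be exercised and validated without
access to clinical waveform databases.

## The method

1. **Fiducial detection.** Pulse peaks are found with a Pan–Tompkins-style
   detector adapted to the PPG band (0.5–8 Hz band-pass → derivative →
   squaring → 150 ms moving-window integration → adaptive dual thresholds
   with a 250 ms refractory period and search-back → crest refinement).
   Troughs are the inter-peak minima. Interbeat intervals (IBIs) from peaks
   feed the systolic path; IBIs from troughs feed the diastolic path.
2. **Morphology features (mPTP).** Each trough-to-trough pulse yields 21
   features: cardiac period CP, systolic upstroke time SUT, diastolic time
   DT, and — at h ∈ {10, 25, 33, 50, 66, 75}% of pulse height — the
   diastolic width DW(h), the width sum SW(h)+DW(h) and the ratio
   DW(h)/SW(h). Features are averaged over all quality-passing pulses in
   the record ("mean point-to-point"). A 7-feature subset
   {CP, DT, DW25, DW75, SW33+DW33, SW75+DW75, DW10/SW10} feeds the deep
   estimators.
3. **Dynamics features.** From each IBI series: mean IBI, SDNN, RMSSD,
   NNx/pNNx, triangular index and TINN, LF and HF band powers
   (0.04–0.15 / 0.15–0.40 Hz) with LF/HF, Poincaré SD1/SD2, sample entropy
   SampEn(2, 0.2·SD), and DFA scaling exponents α1/α2.
4. **Neural estimators.** Small fully-connected and gated networks
   (sigmoid/ReLU hidden layers, linear mmHg outputs) trained by full-batch
   Adam with early stopping on a 15% validation split and L2 weight decay;
   feature z-scoring is fit on the training split only. The headline
   *composite* estimator chains three subnetworks: a deep 7→70→100→150→2
   morphology net produces a first (SBP, DBP) estimate, then two 8→10→1
   nets map [7 dynamics features + the corresponding morphology estimate]
   to the final pressures.
5. **Fusion and evaluation.** Estimates from different methods can be
   combined by inverse-variance (precision-weighted) fusion
   x₃ = σ₃²(x₁/σ₁² + x₂/σ₂²), σ₃² = (σ₁⁻² + σ₂⁻²)⁻¹. Accuracy is reported
   as ME (mean error), SDE (population SD of error) and MAE, plus
   Bland–Altman bias and 95% limits of agreement; models are evaluated
   leave-one-subject-out or on held-out subjects.

The synthetic cohort generator produces coupled PPG + arterial-pressure
records whose pulse geometry and IBI statistics depend monotonically on an
assigned (SBP, DBP) pair, so the whole chain can be checked by parameter
recovery: the ABP channel's beat peaks/troughs equal the assigned pressures
by construction.

## Worked example

Simulate a 40-subject cohort (360 s records at 125 Hz), extract features,
train the composite estimator on 32 subjects and evaluate on the held-out 8:

```sh
ppgbp run --n 40 --duration 360 --seed 7 --out runs/demo
```

which prints (mmHg):

```
                   SBP_ME  SBP_SDE  SBP_MAE  DBP_ME  DBP_SDE  DBP_MAE
composite_holdout    0.55     4.26     3.34   -0.24     0.99     0.90
```

ME near zero means the estimator is unbiased on held-out subjects; the MAE
of 3.3 mmHg (SBP) / 0.9 mmHg (DBP) measures how well the composite model
recovers the pressures that generated each record's pulse shape and rhythm.
`runs/demo/` also contains `features.csv` (per-subject feature table),
`results.csv`, and `manifest.json` (config hash + seed: rerunning with the
same seed reproduces every file byte-for-byte).

The same stages are available individually (`ppgbp simulate`,
`ppgbp fiducials`, `ppgbp morphology`, `ppgbp dynamics`, `ppgbp train`,
`ppgbp estimate`, `ppgbp fuse`, `ppgbp evaluate`) and as library functions
(`ppgbp.detect_fiducials`, `ppgbp.mptp_average`, `ppgbp.extract_dynamics`,
`ppgbp.CompositeModel`, `ppgbp.fuse`, `ppgbp.bland_altman`, …).

## Limitations

The generator emulates the geometry and rhythm of real PPG, not its optics
or artifacts; results on synthetic cohorts demonstrate the pipeline's
correctness and parameter-recovery behaviour, not clinical accuracy. See
`docs/methods.md` for the model details, parameter defaults and the design
decisions behind them.
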