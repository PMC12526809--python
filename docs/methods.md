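# Methods notes

This note records the modeling assumptions, parameter choices and known
limitations behind `posturehrv`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and sign conventions

Device axes are assumed body-aligned: X positive toward the head, Y toward
the subject's right, Z toward the front (chest-outward). The "gravity
vector" is the low-passed accelerometer *reaction* vector, which points
skyward at rest. This is the unique sign convention under which the
published angle rules behave sensibly: back-lying puts the sky along +Z
(θ_Z = 0 → supine) and lying on the left side puts the sky along +Y
(θ_Y < 65° → left lateral). Times are seconds since midnight of the first
recording day; recordings crossing midnight continue past 86 400 s so the
22:00–08:00 night window stays one contiguous interval.

## Posture classification

* Filters: 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`) for zero phase — band-pass 2–3 Hz for movement, low-pass
  0.1 Hz for gravity. Only the corner frequencies are prescribed by the
  method; order and topology are this package's choice and are echoed in
  the log line of every pipeline stage.
* The lying test "84° ± 36°" is read as the closed interval [48°, 120°];
  the lateral/supine thresholds use the strict inequalities as printed
  (< 65°, > 111°, < 60°), with values exactly at a threshold falling
  through to the next clause. These are measure-zero choices on real data.
* Movement detection precedes posture labeling: a movement epoch is never
  posture-labeled. A modal-posture tie at exactly 50 % is a transition
  (the rule requires *more than* half). "mG" is read as 10⁻³ g.
* Epoch boundaries are computed in time, not by a fixed sample count: at
  31.25 Hz an epoch is 937.5 samples, and a fixed 938-sample stride would
  drift by half an epoch across a night.
* Per-sample labels are majority-voted per epoch. Classifying the
  epoch-mean gravity vector instead would be a defensible alternative; the
  majority vote follows directly from the "> 50 % of the segment" rule.

## HRV indices

* NN intervals: an interval is normal-to-normal when both its endpoints are
  sinus (N) beats. Epoch HR/SDRR require at least 10 NN intervals
  (configurable); no minimum is prescribed by the method — this bounds
  estimator variance in 30 s epochs.
* The tachogram assigns each interval to its terminating beat time and is
  cubic-spline interpolated onto a 2 Hz grid. Annotation gaps ≤ 5 s are
  bridged by the spline; longer gaps invalidate overlapping epochs
  (conservative default, configurable).
* Complex demodulation uses the arithmetic band center as f₀ and a
  zero-phase 4th-order Butterworth low-pass at half the bandwidth. The
  amplitude convention is amp = 2·|y_lp|, so a sinusoid of peak amplitude
  A ms reads A. Instantaneous frequency is f₀ plus the unwrapped-phase
  derivative (central differences), clamped to the band; where the band
  amplitude vanishes the frequency is reported as f₀.
* Forward–backward filtering squares the magnitude response, so a tone at
  the band edge (= the filter cutoff) is attenuated to ~50 % power. Tone
  recovery within 5 % therefore holds on the band *interior*, taken here as
  the central 60 % of each band; this attenuation is inherent to any
  band-splitting scheme, not a defect of the demodulator.
* LF/HF defaults to the squared amplitude ratio (power convention), the
  mainstream unit for this ratio; the plain amplitude ratio is available
  via `lfhf_convention: amplitude` since the original convention is not
  stated.
* Hsi: 512-point (256 s) windows stepped 30 s, linear detrend, Hann window,
  FFT power at 1/256 Hz resolution; the HF band spans 64 bins. Hsi = 100 ×
  power in peak ± W bins / total HF power, assigned to the 30 s epoch under
  the window center. W defaults to 5 bins (≈ ±0.0195 Hz); the source index
  definition's exact width is not reprinted, so W is a config knob and the
  tests assert monotonicity in respiratory stability rather than absolute
  values. The numerator is clipped to the HF band so Hsi ≤ 100 by
  construction. Note that for a flat (white-noise) HF spectrum the expected
  Hsi exceeds the naive (2W+1)/64 ≈ 17 %: the peak bin is selected as the
  largest of 64, and the Hann window correlates neighboring bins, which
  together push the typical value to roughly 20–30 %.

## CVHR detector

The published screening method references a proprietary waveform-analysis
algorithm whose internals are not reprinted; the detector here is this
package's own concrete design with the same interface and intent:

1. baseline = 130 s moving median of the 2 Hz NN series;
2. candidate dips = local maxima of (baseline − RR) with depth ≥ 50 ms and
   full width at half depth between 10 and 120 s; the reported nadir is the
   raw RR minimum within the dip (the deficit maximum is skewed by the
   sloping baseline at train edges);
3. cyclicity: dips form a train when ≥ 3 consecutive dips keep spacings in
   25–130 s with neighbor-spacing ratios in 0.5–2; only train members count
   as CVHR.

All five parameters are configuration knobs. Validation is parameter
recovery on synthetic dip trains — never agreement with the proprietary
detector, whose criteria are unavailable. Estimated AHI divides
train-member dips with nadirs inside lying epochs by lying hours; the
moderate-to-severe boundary (15/h) is inclusive.

## Eligibility and aggregation

"80 % of nighttime lying data in sinus rhythm" is interpreted as the
beat-count fraction of N-labeled beats within night-window lying epochs; a
duration-weighted alternative is available (`sinus_rule: time`) since the
original basis is not stated. Night-window membership is decided by epoch
start time. Per-posture means require ≥ 10 epochs in that posture
(configurable); missing epochs are excluded from numerator and denominator.

## Cohort statistics

The repeated-measures ANOVA is a split-plot decomposition with posture as
the single within-subject factor and one optional between-subject factor,
on complete cases (subjects observed in all four postures). The full
unbalanced multi-way GLM machinery of the original analysis (Type III sums
of squares, multiple covariates) is deliberately not replicated; for the
synthetic recovery experiments a one-within + one-between layout is
sufficient, and the implementation is cross-checked against an independent
ANOVA library in the tests. η² is population eta squared,
SS_effect / SS_total, with its one-way F-test p-value.

## Synthetic data: what it does and does not emulate

The generator emulates posture schedules with bout-to-bout orientation
jitter, sensor noise, and 2.5 Hz movement bursts at posture changes (people
move when turning, which is why validation schedules place a burst at every
transition); RR series as a mean level plus sinusoidal VLF/LF components,
respiratory sinus arrhythmia with a slowly wandering respiratory frequency,
Gaussian CVHR dip trains (RR *shortening*, matching the tachycardic phase
that dip detectors target; dips per train defaults to 5), and random
ectopic beats shortened by 30 % so they are guaranteed to break the NN
rule. Cohorts add age/sex strata, posture preferences (default 40/25/25/10
supine/right/left/prone), a per-subject base heart rate of 62 ± 3 bpm, and
injectable posture-specific HR offsets. Each synthetic night opens with one
bout of every posture so per-subject per-posture means exist.

It does **not** emulate: real accelerometer artifacts (sensor detachment,
oblique postures, non-lying activity), sleep-stage structure, realistic
ectopy morphology, apnea-driven oxygen desaturation, or the covariance
structure of real HRV. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated model, not clinical performance.

## Problem sizes

The classifier validation uses 4 blocks × 55 epochs per posture (≥ 200
clean truth epochs per posture after movement exclusion, ~7.3 h at
31.25 Hz). The end-to-end cohort experiment uses 22 subjects × 5.6 h
nights, chosen so every age decade holds ≥ 10 subjects; power and
permutation-null experiments for the ANOVA use summary-level simulation
(n = 40 subjects, 100 and 500 replicates). These sizes give stable
statistics at desk scale; all are parameters of the corresponding
functions.
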