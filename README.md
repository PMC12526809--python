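# posturehrv

Sleep posture shapes autonomic cardiovascular control, but it is rarely
measured in clinical heart-rate-variability (HRV) work. `posturehrv` is a
Python library for analyzing overnight Holter-style recordings that carry
both an ECG-derived beat series and chest-worn triaxial accelerometry: it
classifies the sleeping posture of every 30 s epoch from the accelerometer,
computes posture-resolved HRV indices, screens for sleep apnea from cyclic
variation in heart rate, and aggregates subjects into age/sex-stratified
cohort tables with repeated-measures tests and η² effect sizes. Because
clinical Holter databases cannot be redistributed, the package ships a
synthetic-data generator that produces acceleration and RR series with
known ground truth, so every stage is testable end to end.

## Methods in brief

* **Posture classification** — each acceleration axis (X head–foot,
  Y left–right, Z front–back, in g at 31.25 Hz) is band-pass filtered at
  2–3 Hz; epochs whose peak composite magnitude √(x²+y²+z²) reaches 20 mG
  are movement epochs. A 0.1 Hz low-pass recovers the gravity vector g;
  with θ_axis = arccos(ĝ·ê_axis), an epoch is *lying* when θ_X = 84° ± 36°,
  then *left lateral* if θ_Y < 65°, *right lateral* if θ_Y > 111°, else
  *supine* if θ_Z < 60° and *prone* otherwise. A non-movement epoch takes
  the posture held by > 50 % of its samples, or *transition*.
* **HRV indices** — per epoch, HR = 60000 / mean(NN) and SDRR (sample SD of
  NN intervals), using normal-to-normal intervals only. The NN tachogram is
  cubic-spline resampled at 2 Hz; complex demodulation (multiply by
  e^(−i2πf₀t), low-pass at half bandwidth) yields time-resolved amplitude
  and instantaneous frequency for VLF (0.003–0.04 Hz), LF (0.04–0.15 Hz)
  and HF (0.15–0.40 Hz), plus LF/HF. The HF spectral concentration index
  Hsi — power within ±5 bins of the HF spectral peak over total HF power in
  overlapping 256 s FFT windows — quantifies respiratory-frequency
  stability.
* **Apnea screening** — RR dips (transient heart-rate accelerations)
  relative to a 130 s moving-median baseline, kept when ≥ 50 ms deep and
  10–120 s wide, count as cyclic variation in heart rate (CVHR) when they
  form regular trains (spacing 25–130 s, neighbor-spacing ratio 0.5–2,
  ≥ 3 dips). Train dips per lying hour estimate the apnea–hypopnea index;
  ≥ 15/h flags moderate-to-severe apnea.
* **Cohort statistics** — eligibility (> 5 h lying between 22:00–08:00,
  ≥ 80 % sinus beats), per-posture index means per subject, AGE10 decade
  bins, repeated-measures ANOVA for the posture effect, and
  η² = SS_effect / SS_total.

## Worked example

`examples/apnea_screening.py` injects three 8-dip CVHR trains into a
synthetic night and screens it:

```text
injected dips: 24
detected train-member dips in lying epochs: 24
estimated AHI: 16.0 /h -> moderate_to_severe
apnea-positive epochs: 24 of 180
```

All 24 injected dips are recovered; 24 dips over 1.5 lying hours give an
estimated AHI of 16.0/h, just above the 15/h moderate-to-severe cutoff, and
each dip marks its 30 s epoch apnea-positive. The other examples cover
posture classification (`classify_posture.py`), the per-epoch HRV indices
(`hrv_demodulation.py`) and a full cohort analysis that recovers an
injected −3 bpm left-lateral heart-rate offset (`cohort_laterality.py`):

```text
posture effect: F = 323794.83, p = 3.9e-49
eta-squared (between-posture share of HR variance): 0.192
```

## Layout

```
src/posturehrv/
  core.py        containers: AccelSeries, BeatSeries, 30 s epoch grid
  io_formats.py  CSV/YAML readers and writers, parameters, logging
  synthetic.py   ground-truth generators: schedules, RR models, cohorts
  posture.py     movement detection, gravity, angle rules, epoch labels
  hrv.py         NN filtering, 2 Hz resampling, complex demodulation, Hsi
  cvhr.py        dip detection, train clustering, apnea screening
  aggregate.py   eligibility, per-posture subject summaries
  cohort.py      AGE10 strata, repeated-measures ANOVA, eta squared
  pipeline.py    subject/cohort drivers chaining the stages
examples/        one narrative script per capability
docs/methods.md  modeling assumptions, parameter choices, limitations
```
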