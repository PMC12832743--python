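# Methods

This note documents the models, estimators and numerical choices behind
`sonopupil`, and what the synthetic experiments do and do not establish.

## Reflex waveform model

The pupil diameter is modelled as four phases: a constant baseline until
`stimulus_onset + latency`; a descent from `baseline_diameter` to
`min_diameter` over `constriction_duration`; a partial redilation regaining
`recovery_fraction` of the amplitude over `recovery_duration`; and a
constant plateau thereafter. Segments are piecewise linear by default; an
exponential mode uses normalised exponentials
`(1 − e^{−t/τ}) / (1 − e^{−T/τ})` so each segment reaches its endpoint
exactly at the phase boundary, keeping the closed-form ground-truth metrics
(`true_metrics`) exact in both modes. Ground truth uses endpoint
definitions: DELTA = (INIT−END)/INIT, ACV = amplitude/constriction duration,
ADV = regained amplitude/recovery duration.

## Scene model (what the generator emulates)

A tangential transpalpebral view is reduced to its essentials: a bright
eyelid echo band at the top of the frame, a bright iris echo band deeper in
the image, and an anechoic gap in the iris band whose width is the pupil
diameter divided by the pixel spacing (rounded to whole pixels). Speckle is
multiplicative gamma noise with unit mean (shape 4 by default; SD = 1/2 per
pixel), followed by a Gaussian point-spread blur (σ = 1 px) and clipping to
[0, 1]. Defaults: 96×128 px at 0.1 mm/px, 30 Hz, 5 s, stimulus at 1.0 s,
intensities eyelid 0.85 / iris 0.75 / background 0.30 / pupil 0.05. The
background is kept below half the eyelid echo so the bright-band search
(below) separates bands reliably under speckle.

Deliberately **not** modelled: radio-frequency beamforming and depth
attenuation, eye motion and blinks, probe-pressure deformation, consensual
reflexes. Passing the synthetic suite therefore demonstrates correctness of
the measurement chain on images with realistic contrast, speckle statistics
and pixel/frame quantisation — not robustness to motion artefacts or
anatomical variability in clinical B-mode data.

## Segmentation

1. **Iris-band ROI.** Rows are scored by their 90th-percentile intensity
   (robust to a wide anechoic gap); contiguous runs above half the maximum
   are candidate bands, and the band containing the most sub-Otsu (dark)
   pixels wins. Frames without band structure fall back to the whole frame;
   frames with intensity range below 0.1 are rejected as invalid.
2. **Thresholding.** Otsu inside the band (default) or a fixed threshold;
   pixels below threshold are pupil candidates.
3. **Morphology.** Binary opening (radius 1) then closing (radius 2) with
   disk elements; components smaller than 30 px are discarded. Opening
   rounds right-angle corners by construction — the measured chord is
   unaffected.
4. **Tracking.** The component nearest the previous frame's centroid is
   selected (ties: larger area, then smaller row); without a prior, the
   largest component. If nothing lies within the 20 px search radius the
   largest component re-seeds the track.
5. **Chord.** The diameter is the contiguous pixel run through the centroid
   column on the row nearest the centroid, measured inclusively
   ((max − min + 1) px), times the pixel spacing. The maximum-over-all-rows
   alternative can be obtained by measuring masks directly; the
   centroid-row rule is the default because the chord is defined "through
   the pupil centroid".

Diameters are therefore quantised to whole pixels (0.1 mm at the default
spacing); every estimator downstream is designed with that staircase in
mind.

## Metric extraction

The valid-frame trace is smoothed with a 5-frame moving median (robust to
single-frame segmentation glitches; preserves values exactly on monotone
segments). INIT is the mean smoothed diameter over the 0.8 s before the
stimulus.

**Onset / LAT.** The crossing rule: the first post-stimulus sample below
`INIT − max(3·σ_baseline, 0.05 mm)` that keeps falling for 3 frames. The
raw crossing systematically lags true onset by the time needed to
accumulate the threshold drop (1–2 frames plus drop/ACV), so the onset is
refined: walk back along the monotone descent, then back-extrapolate a line
fitted to the early descent (5–60% of amplitude) to the baseline level,
clamped to [stimulus onset, crossing time]. On noise-free loops this
recovers latency to one frame; under default speckle the median error is
≤ 0.05 s and, importantly for method-comparison studies, the estimator is
nearly unbiased, so injected inter-modality latency offsets are recovered
to ±0.02 s.

**END / DELTA.** END is the earliest minimum of the smoothed trace after the
crossing. A median filter overshoots a sharp V-minimum by up to two frames
of descent slope; when both phase-line fits (below) exist, END is refined to
the descent/recovery line intersection, accepted only within
[min − 0.2 mm, min] (the smoothed minimum can only overestimate). DELTA is
(INIT − END)/INIT, an exact identity of the extracted record.

**Velocities.** Endpoint secants on a pixel-quantised staircase carry
errors of 20–30% for shallow reflexes, so ACV and ADV are estimated as the
slopes of lines fitted to the constriction and recovery phases — identical
to the secants for the linear reflex model. Each phase is first made
monotone by isotonic regression (pool-adjacent-violators, via
scikit-learn), which removes speckle flickers; each pooled block is then
collapsed to its (mean time, level) point — for a staircase these are the
plateau midpoints, unbiased samples of the underlying line. The first and
last blocks (baseline, minimum or converged-tail plateaus) are dropped, and
the recovery segment is truncated at the first sample reaching the window
top so the converged tail cannot enter the fit. Fit windows: 15–85% of the
amplitude for the descent, 10% up to the ADV recovery point + 5% for the
rise; the rise window top is additionally capped a quarter of the realized
recovery below the trace's converged level (median of the final 0.5 s), so
that a reflex which plateaus near the ADV point cannot leak its flat tail
into the fit. If fewer than two blocks survive, the endpoint secant is the
fallback. The ADV window ends at the configurable recovery point
(`recovery_fraction_for_adv`, default 0.5): devices do not publish their
dilation windows, and dynamic indices are known to be sensitive to such
calibration choices — a genuine inter-device difference that this package
surfaces as a parameter rather than hiding.

**Sessions.** Triplicate acquisitions are averaged field-wise over defined
values; a field is undefined in the average only when undefined in all
acquisitions. Quality control fails a trace that is shorter than 1 s past
the stimulus, has under 80% valid frames, under 3 valid baseline frames, or
a baseline coefficient of variation above 5%.

## Agreement and reliability statistics

Differences are ultrasound − infrared throughout; SDs use n−1; limits of
agreement use the fixed 1.96 multiplier (no small-sample t correction), and
no multiple-testing correction is applied. Regression is of ultrasound on
infrared. Pearson CIs use the Fisher z transform with the degenerate
interval [r, r] at |r| = 1. The proportional-bias slope (differences on
pair means) is tested with a two-sided t on n−2 df; an exactly zero slope
reports p = 1 even with vanishing residuals, and a perfect nonzero trend
reports p = 0. ICCs are computed from the two-way ANOVA mean squares of the
complete subjects × raters matrix; missing cells are an error (no
imputation). The Shapiro–Wilk statistic is delegated to
`scipy.stats.shapiro`; a zero-variance sample returns NaN.

## Study emulator

`run_study` draws per-eye waveforms from truncated-normal populations
(baseline 4.05 ± 0.57 mm, constriction ratio 0.25 ± 0.05, latency
0.28 ± 0.027 s, ACV 1.46 ± 0.30 mm/s, ADV 0.78 ± 0.17 mm/s — an adult ICU
cohort on the reference device's scale; constriction and recovery durations
are derived from the sampled amplitude and velocities, recovery fraction
0.85). Each eye receives three rendered acquisitions (independent speckle
seeds); the reference modality is emulated as analytic ground truth plus
configurable per-metric offsets and small device noise. The reliability arm
re-acquires each eye with a second emulated observer: independent speckle
and a ±2 px probe-placement shift of the scene template, giving ICC < 1
structure without modelling operator skill. Inter-observer ICC(2,1) uses
per-observer session means; intra-observer ICC(3,1) uses observer 1's three
repeats. All randomness derives from one `SeedSequence`, so identical
config + seed yields byte-identical CSV reports.

Problem sizes were chosen at the study's own scale: 20 patients × 2 eyes ×
3 acquisitions (plus the observer-2 arm) per study run, a 3×3×3 waveform
grid × 20 speckle seeds for parameter recovery, 100 random matrices for the
ICC oracle and 500 draws for Fisher coverage.

## Known limitations

- The scene is 2-D and static; segmentation robustness to motion, blinks
  and anatomical variation is untested by design.
- Latency estimation assumes a monotone early descent; heavily non-monotone
  traces fall back to the raw crossing time.
- The exponential waveform mode is rendered and measured, but the
  phase-line velocity estimators are calibrated for the linear mode (the
  slope of an exponential segment is not its secant); recovery bounds are
  validated on the linear model only.
- Eyes are treated as independent observations in the agreement statistics;
  no within-patient clustering adjustment is made.
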