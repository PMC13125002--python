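# Methods

This note documents the models, numerical choices and limitations behind
`crmon`: what each stage computes, why the defaults are what they are, and
what the synthetic cohort does and does not establish about real data.

## The monitoring pipeline

**Input contract.** The reserve predictor consumes PPG at 100 Hz in 5-s
windows of 500 samples, advanced by 1 s, each min–max normalized so the
window's extremes map exactly to 0 and 1. A flat window (zero range) produces
no prediction for that tick; missingness is an explicit NaN, never a repeated
or fabricated value, because 0 is a meaningful reserve reading on a safety
display.

**Causal rate conversion.** The portable oximeter dialect exports CSV at
31.25 Hz and the patient-monitor dialect at 1,000 Hz. The 1,000 Hz path is
decimated by keeping every 10th sample (inherently causal). The 31.25 Hz path
uses Fourier-method resampling; since an FFT over a growing record is neither
causal nor bounded in cost, the streaming implementation resamples the
trailing 7 s of raw samples at each 1-s tick and keeps the final 5 s. The
chunk's tail is extended by a 1-s even reflection (built only from past
samples) before the FFT so the periodic extension sees no jump at the window
end; without this, the edge artifact measurably distorts the final beat of
every window. Whole-record `resample_fourier` is also provided for
retrospective (offline) processing.

Windows are labelled by end time and cover the half-open interval
(t − 5 s, t]. Timestamp gaps longer than two sample periods invalidate the
windows overlapping them rather than being interpolated across.

**Smoothing.** Raw 1 Hz predictions pass through a causal trailing mean over
the 20 most recent *emitted* predictions, with no output until 20 have
accumulated. Missing ticks do not count toward the 20 — the filter averages
real predictions only, at the price of a slightly longer effective memory
when ticks are dropped.

**Predictor interface.** The convolutional network behind published reserve
estimates is prior, proprietary work; `crmon` treats the predictor as an
injection point. Two implementations ship:

* `SurrogatePredictor` — a deterministic morphology map. Systolic peaks are
  detected in the pre-normalization window (local maxima, 0.3-s refractory,
  prominence ≥ 0.45 of the window range — the prominence floor is what
  separates systolic peaks, ≈1.0 of range, from dicrotic waves, ≈0.2). The
  mean peak-to-trough amplitude and the beat rate are each mapped through an
  affine ramp between their calibrated baseline (amplitude 1.0 a.u., 65 bpm
  → 100%) and endpoint (amplitude 0.2 a.u., 100 bpm → 0%) values and
  combined with weight 0.7 on amplitude, clipped to [0, 100]. Windows with
  fewer than two detectable beats yield NaN.
* `OraclePredictor` — returns the protocol-derived reserve at the window's
  end time. It exists to separate concerns in testing: plumbing and the
  evaluation layer must recover it exactly.

## Triage zones and detectors

Zones follow the fuel-gauge convention: green above 70%, red below 40%,
yellow between. The published bands (">70" green, "<40" red) leave the two
boundary values unassigned; `crmon` assigns both to yellow — the conservative
middle — and makes the boundaries configurable.

The **threshold gates** count, at each tick, the predictions strictly below
the boundary (70 for the yellow gate, 40 for the red gate) among the most
recent min(60, available) predictions and flag once the count reaches 45.
Missing ticks occupy window slots as non-crossings. Strict comparison
reflects "passing below" the zone floor.

The **slope trend** fits an ordinary least-squares line to the trailing 5 min
of values (evaluated from the first fully covered window onward; NaNs are
dropped from the fit, and a window with fewer than two distinct time points
is skipped) and flags when the projected change over the window reaches 15
percent-units in the configured direction. OLS was chosen over an endpoint
difference for robustness to 1 Hz noise; on noise-free ramps both give the
same boundary, which is the only behavior the threshold pins down. The same
rule runs on MAP (falling) and HR (rising — heart rate climbs as hypovolemia
progresses), each first rescaled to percent of its baseline-period mean so
the 15-unit threshold is comparable across signals with different units.

Flags outside the chamber-active interval [baseline end, endpoint] are
discarded; the first surviving flag gives the early-warning margin
(endpoint − flag time)/60 in minutes, and a method that never validly flags
scores 0 min.

## Evaluation

The reference reserve is the pressure ratio on the protocol staircase,
CRM_GT(t) = 1 − LBNP_t / LBNP_HDD, clipped to [0, 1], where LBNP_HDD is the
chamber pressure at the decompensation endpoint. The literal staircase is the
default; a within-stage linear interpolation mode exists but is never used as
the reference.

Performance error PE = (pred − gt)/gt is computed on the fraction scale on
the inner join of prediction and reference ticks, dropping reference-zero
ticks and missing predictions; MDPE (median, signed bias) and MDAPE (median
absolute) are reported ×100 in percent. The 30-s rolling CV (sample SD over
mean, ×100) is computed on the smoothed stream — it measures the stability of
the displayed signal — excluding windows whose mean falls below a 1
percent-unit floor (division guard; not addressed by the published method,
configurable). Zone confusion counts (reference zone, predicted zone) pairs
per tick, normalizes rows to sum 1, and derives one-vs-rest accuracy,
precision, recall and specificity from the raw counts; a reference zone with
no ticks is reported as unavailable, not zero.

One deliberate choice: **PE and zone agreement are evaluated on the raw
predictions, not the smoothed stream** (CV is smoothed; detectors are
smoothed). The trailing mean lags the reference staircase by up to 19 s at
every stage transition, so evaluating the smoothed stream would charge the
predictor for filter delay — in particular, a perfect predictor would no
longer yield an identity confusion matrix. Both entry points accept
`use="smoothed"` to evaluate the displayed stream instead.

Inferential statistics (Shapiro–Wilk, Friedman, repeated-measures ANOVA) are
exposed as an optional report section that delegates to scipy/statsmodels;
they are standard routines and are not re-implemented. Dunn's post-hoc test
has no scipy/statsmodels implementation and is omitted rather than
hand-rolled.

## The LBNP simulator

The simulator emulates the stepped-LBNP study conditions: 5-min baseline,
−15/−30/−45/−60/−70/−80/−90/−100 mmHg stages of 5 min, immediate release at
the endpoint, 10-min recovery; 31.25 Hz PPG export (1,000 Hz for the monitor
dialect) and 1 Hz vitals. Per subject, a decompensation stage is drawn from a
categorical tolerance distribution — default (0, 0, 0, 0.25, 0.30, 0.25,
0.12, 0.08) over the eight stages, concentrating mass on the −60…−80 mmHg
stages so every subject reaches at least 60 mmHg — and the endpoint is placed
uniformly within the interior (10–95%) of that stage, reproducing
inter-subject tolerance spread without modelling syncope.

Two reserve trajectories coexist by design. The *latent* reserve is the
literal staircase ratio (what the evaluation reference uses, and what the
oracle predictor returns). The *physiological driver* is its within-stage
linear interpolation with exponential relaxation (τ = 120 s) back to baseline
after release — real physiology responds continuously, not in steps. Vitals
and waveform morphology follow the driver:

* HR = HR₀ · (1 + 0.55 · (1 − r)²), HR₀ ~ N(65, 3) bpm — a convex rise
  (≈ +55% at zero reserve) matching late-stage tachycardia;
* pulse amplitude falls linearly from 1.0 to 0.2 a.u. with reserve;
* MAP holds near its baseline (N(90, 4) mmHg) until reserve < 0.3, then
  declines linearly toward a 58 mmHg floor — the analog of the systolic <
  80 mmHg stop criterion, and the reason pressure is a *late* indicator;
* SpO₂ drifts from 98% by −3 · (1 − r)²;
* AR(1) noise (φ = 0.95) rides on each vital; white noise (SD 0.02 a.u.) on
  the waveform.

The PPG beat is a two-component template — a systolic Gaussian (center 0.30
of the beat, width 0.08) plus a 0.35-amplitude dicrotic Gaussian (center
0.65, width 0.10) — driven by a phase accumulator integrating the
instantaneous heart rate, so beat spacing tracks HR exactly. The widths keep
the fundamental dominant in the spectrum while preserving the two-bump
arterial shape. One `numpy` generator, seeded per subject, drives all draws
in a fixed documented order; identical (config, seed) reproduce a subject
byte-for-byte.

**What the simulator does not model** — and hence what passing tests do not
show about real data: no hemodynamic ODEs or baroreflex dynamics, no
respiratory modulation or motion artifact, no sensor dropouts, no
inter-subject morphology variation beyond amplitude/rate scaling, no syncope
physiology. The synthetic cohort validates the *pipeline* (constants,
causality, recovery, detector ordering), not the clinical accuracy of any
predictor.

## Expected behavior on the default cohort

With the surrogate predictor the cohort shows a positive MDPE (≈ +20%): the
physiological driver lags the reference staircase within each stage and the
rate term of the surrogate is concave in reserve, both inflating predictions
relative to the staircase reference. This is an honest property of the
surrogate-on-simulator pairing, not a calibration target — published
human-cohort error figures require the real recordings and trained network.
The qualitative detector ordering, however, is robust across seeds: reserve
trend ≳ yellow gate ≻ red gate ≻ MAP/HR trends, with the HR trend frequently
never flagging (its percent-of-baseline slope rarely reaches 15 units per
5 min until the final stages).

## Problem sizes

Default runs use 20 subjects at 31.25 Hz with full-length protocols
(~25–50 min of signal per subject); the test suite and the acceptance script
each complete in well under five minutes on one CPU at these sizes. Tests
that need many repetitions (normalization properties, smoothing oracles) use
short synthetic segments instead of full subjects.

## Known limitations

* The surrogate's calibration is tied to the simulator's default morphology
  bounds; applying it to real PPG would require re-calibration (or, better,
  the real model weights behind the predictor interface).
* Gate counting treats missing ticks as non-crossings; long dropouts
  therefore delay gate flags rather than invalidating them.
* The evaluation's inner-join alignment assumes both streams share the 1 Hz
  tick grid; sub-second offsets are rounded at 1 µs resolution.
* `WaveformRecord` assumes uniform sampling; records with timestamp gaps are
  handled by window invalidation, not by resampling onto a gapped axis.
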