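# Methods

This note documents the models, numerical choices and limitations behind
`eogkit`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Signal model and preprocessing

A recording is two synchronized channels in µV at a common sampling rate
(500 Hz DC throughout the tests): the bipolar horizontal derivation
(right − left outer canthus) and vertical derivation (above − below one
eye). Gaze rotation appears as step changes (≈ 10–20 µV/deg), saccades as
short velocity pulses, and blinks as large positive pulses on the vertical
channel (the eyelid sweep dominates the upper electrode).

**Baseline removal.** DC EOG drifts by hundreds of µV over tens of seconds
(electrode polarization, skin impedance). The drift is modeled by a single
degree-20 least-squares polynomial over the whole recording and subtracted.
Degree 20 is deliberately high — the drift is smooth but not low-order —
and is safe for events because a polynomial with ~20 degrees of freedom
over a minute-scale recording cannot follow second-scale gaze structure
(test: a 130 µV, 1.4 s excursion on drift is recovered to < 5% at its
edges). Time is normalized to t ∈ [−1, 1] before fitting; without this the
degree-20 Vandermonde system is numerically singular. Two consequences are
documented rather than hidden:

* *Edge unreliability.* Least-squares polynomials have maximal variance at
  the interval ends, and the fitted baseline oscillates there. The detector
  therefore discards candidate events whose bounds intersect the first/last
  `detect.edge_margin_s` (default 0.75 s) of the recording; set the margin
  to 0 to disable.
* *Level offsets.* The polynomial threads through the average of the gaze
  plateau structure, so detrended fixation levels sit tens of µV away from
  zero. Events riding on a large offset can fail the 10%-bound search (see
  blink limitations below).

The fit reports R² = 1 − SS_res/SS_tot (defined 0 for a constant input);
drifty minute-scale recordings land around 0.5–0.85.

**Wavelet truncation.** Content above a pseudo-frequency cutoff (default
100 Hz) is removed by zeroing Haar detail levels: level j (finest = 1)
covers approximately [fs/2^(j+1), fs/2^j] and is zeroed when its lower band
edge is at or above the cutoff, so at fs = 500 only level 1 (125–250 Hz) is
removed. Zeroing detail levels 1..J of an orthogonal periodized Haar
decomposition *is* the projection onto signals constant on aligned 2^J
blocks, and it is computed directly as that block average: the operator is
exactly linear, exactly idempotent in floating point, and agrees with a
PyWavelets decomposition to ~1e-15 (tested). The Haar projection is a
blunt spectral tool — a 150 Hz probe tone loses 88% (not all) of its
125–250 Hz band energy — but it does not smear event edges the way a
linear-phase lowpass does, which is why it is used here.

**Differentiation.** Velocity is computed by *central* differences
(`np.gradient`) scaled by fs. This choice is load-bearing: after level-1
Haar truncation the signal is pairwise-constant, so one-sided differences
alternate exact zeros with double-height spikes, and every velocity sample
becomes an isolated two-sample peak — destroying duration measurement. The
centered stencil straddles block boundaries and recovers a smooth velocity
signal with the correct scale (analytic check: the peak of a logistic
saccade's velocity pulse is recovered to ~1.5%, its 10%-bound width to
better than a sample).

Order of operations is baseline first, then truncation, then
differentiation. On drift-free input the two cleaning projections nearly
commute (order changes the result by < 10% of the noise scale; they are
different projections, so exact commutation is not expected).

## Auto-calibration

Each detection channel — |EOG_h′|, |EOG_v′| in µV/s, and the positive part
of the positional EOG_v in µV for blinks (blinks are upward deflections in
the up-minus-down derivation; config `calib.blink_use_abs` switches to the
absolute signal) — is calibrated independently:

1. every local maximum of the absolute signal is collected (plateau maxima
   count once, at their leftmost sample); at least `calib.min_peaks` (30)
   are required, otherwise the recording is declared too short;
2. amplitudes are sorted ascending and scaled so the maximum maps to 1;
3. isolated artifact peaks are trimmed from the top: scanning downward,
   peaks are discarded while the gap to the next lower peak is ≥ 0.03 (on
   the scaled curve); the scan stops at the first pair closer than that.
   After trimming the curve is re-scaled by default
   (`calib.rescale_after_trim`) so the 2% margin below stays interpretable;
4. for every split rank n ∈ [10, N−10] straight lines are fit to ranks
   1..n and n+1..N (x = rank; closed-form SSE via prefix sums, equivalent
   to per-split `np.polyfit` — tested for exact argmin agreement on
   hundreds of random curves) and the split n\* minimizing the summed SSE
   is the candidate pivot. Ties, including the perfectly-collinear
   degenerate case, break toward smaller n (the conservative threshold); a
   1e-12-relative tolerance keeps float noise from deciding genuine ties;
5. the threshold is 1.02 · d_{n\*} · scale.

Why it works: dense small noise peaks form a long shallow left segment,
sparse large event peaks a steep right tail; the two-line fit finds the
knee between the regimes. Noiseless two-segment curves with slope ratio
≥ 10 are recovered to ±3 ranks regardless of where the knee sits (30/50/70%
of the curve), and when event peaks are at least 5× the largest noise peak
the threshold lands strictly between noise maximum and event minimum in
≥ 95 of 100 seeded recordings (both properties recomputed by the
acceptance script).

Two genuine failure modes of the published trimming/knee rules, observed
during development and left intact because they are part of the method:

* *Sparse event clusters.* If a channel carries only a handful of event
  peaks whose adjacent gaps all exceed 0.03 of the scale (e.g. very few
  blinks with widely spread amplitudes), the trim scan walks through the
  entire event cluster and deletes it, collapsing the threshold into the
  noise. With ≥ ~10 events of natural amplitude spread this does not occur.
* *Event-free recordings.* With no events at all the knee lands inside the
  noise distribution and the pipeline reports hundreds of spurious
  low-amplitude "events". Auto-calibration presupposes that saccades and
  blinks are present; do not run it on empty traces.

The full calibration is homogeneous of degree 1: scaling the recording by
k scales all three thresholds by k exactly (asserted with k = 2, where
float arithmetic is exact), so detection output is invariant to amplifier
gain.

## Detection and classification

A *bounded peak* starts from a local extremum above threshold. The left
bound is the nearest earlier sample whose absolute value is at or below
`detect.bound_frac` (10%) of the peak amplitude; the right search
terminates at the bound level, promotes the peak when a taller
same-polarity sample appears (this absorbs double-peaked blinks into one
event; the bound level is recomputed from the promoted peak), or gives up
when the span would exceed `detect.max_peak_duration_s` (0.80 s), in which
case the peak is discarded. Bounds "found" exactly at the recording's
terminal samples do not count (the signal simply ran out). Overlapping
same-polarity peaks are merged to a fixpoint, keeping the larger peak;
opposite polarities may share boundary samples.

Blink extraction pairs each negative vertical-velocity peak with the
nearest preceding positive peak *with no other positive peak in between* —
the adjacent up-down pattern; a blink's own up-lobe is always the last
positive peak before its down-lobe, whereas a plain nearest-following rule
would let an earlier vertical saccade capture a blink's down-lobe and
destroy both events. The pair must lie within
`detect.max_blink_duration_s` (1.2 s) and contain a positional EOG_v
bounded peak above the blink threshold (searched with the blink duration
cap); then a blink is emitted with onset/offset at the positional peak's
bounds and the two velocity candidates are consumed.

Classification assigns each candidate exactly once: a horizontal candidate
overlapping a blink interval becomes saccade-with-blink (blink coexistence
is tested before obliqueness); otherwise a horizontal and a vertical
candidate whose intervals overlap by ≥ 1 sample (configurable
`detect.overlap_min_s`) merge into one oblique saccade spanning the union;
the rest keep their axis. The duration filter removes pure saccades outside
[30, 80] ms (inclusive); saccade-with-blink events are exempt because their
span is blink-dominated, and an optional `filters.blink_min_s` (off by
default) removes spuriously short blinks. The filter is idempotent. In the
library the filter defaults off; the command-line `detect` applies it by
default (the robust profile).

## Measures

Duration is (offset − onset)/fs. Saccade peak velocity is the maximum
absolute velocity on the event's axis inside the event (oblique: per-axis
maxima plus their Euclidean combination). Acceleration/deceleration are the
max/min of the differentiated velocity within the event (µV/s²) — the
formula is this package's interpretation, as no standard exists. Saccade
amplitude is the positional signal change offset-minus-onset (step
morphology); blink amplitude is peak-minus-onset (pulse morphology). Blink
closing/opening times are (peak − onset)/fs and (offset − peak)/fs, and the
blink's duration measure is restated as their sum so the identity
closing + opening = duration holds *exactly* in floating point (the sum
agrees with (offset − onset)/fs to 1 ulp). Gain calibration divides the
mean amplitude of caller-supplied reference saccades of known visual angle
(default 10°) by that angle; deg/s velocities are then gain-invariant by
construction. Note that an event's amplitude is measured between its
10%-velocity bounds, which cover ~95% of the underlying step, so a
recovered gain of ~0.95 × the true µV/deg is expected and harmless for
velocity ratios.

## The synthetic generator

The generator emulates the measurement conditions the detector targets: a
center-out saccade task recorded at 500 Hz DC.

* **Trials.** Each trial is an outward saccade (amplitude from
  {2.5, 5, 7.5, 10}°, direction from the 8 compass directions, projected
  h = cos θ, v = sin θ at 13 µV/deg), a fixation dwell of 1.25–1.35 s, and
  a return saccade. Blinks (300 ± 50 µV, 0.20–0.30 s, closing 40% of the
  duration) occur in 1.25–1.45 s inter-trial center-gaze gaps, as
  instructed blink pauses do in laboratory protocols. Structured placement
  is deliberate: independently scattered steps would random-walk the gaze
  position beyond any oculomotor range, which no real recording exhibits,
  and would place blinks on arbitrary voltage pedestals.
* **Saccade profile.** Logistic position step; the rate constant is set so
  the velocity pulse's width at 10% of its maximum equals the
  main-sequence duration map {2.5°: 37 ms, 5°: 45 ms, 7.5°: 51 ms,
  10°: 55 ms} (linear interpolation between, Gaussian jitter with the
  empirical spreads by default). Analytic peak velocity A·k/4 increases
  monotonically with amplitude. The window spans ±2 durations with
  endpoints renormalized to exactly 0 and A, so splicing introduces no
  velocity spike.
* **Nuisance terms.** Drift: 3–5 sinusoids below 0.05 Hz totalling
  ~200 µV; broadband noise: white, 0.5 µV SD (≈ 20 deg/s velocity-domain
  noise after denoising, a realistic floor); powerline: 0.5 µV at 50 Hz;
  artifacts: optional electrode-pop transients (abrupt 5–10× blink-scale
  jump, exponential return with 20–60 ms time constant, both channels).
  The pop shape matters: a symmetric rectangular spike is a degenerate
  artifact whose ± velocity lobes have identical magnitudes and therefore
  defeats the 0.03 trim rule by construction; real pops have a fast edge
  and a slow decay.
* **Vertical realism knob.** `v_gain_factor` (default 1.0) attenuates the
  vertical rotation signal relative to horizontal; real vertical EOG is
  weaker and noisier. At 0.6 the generator reproduces the qualitative
  classification pattern that small oblique saccades are mostly labeled
  horizontal while large ones are labeled oblique.

What the generator does **not** emulate: eyelid biomechanics (blinks are
stylized pulses), smooth pursuit, microsaccades, EMG bursts, electrode
pops with slow recovery drifts, or inter-subject electrode-placement
variability. Passing the benchmark therefore demonstrates that the
algorithm behaves as designed under its intended signal model, not that it
meets any particular performance number on human data.

## Benchmarks (what the acceptance script recomputes)

* *Pivot optimality*: exact argmin agreement with an exhaustive
  per-split `np.polyfit` oracle on 200 random curves (length ≤ 200).
* *Knee recovery*: ±3 ranks on 100 noiseless two-segment curves.
* *Threshold separation*: 100 recordings at 50 s with 20 horizontal
  saccades (7.5/10°), 12 blinks, 0.3 µV noise — every threshold strictly
  between the largest out-of-event peak and the smallest event peak
  (premise event/noise ≥ 5× asserted) in ≥ 95 runs.
* *Detection benchmark*: 50 recordings of 60 s with 40 saccades (5–10°,
  all 8 directions, out-and-return), 15 blinks, default drift/noise, no
  artifacts (scored segments in the reference work likewise excluded
  artifact epochs); with the 30–80 ms filter, mean saccade sensitivity
  ≥ 95%, blink sensitivity ≥ 93%, false-positive fraction ≤ 6%. Saccade
  sensitivity is computed over truth saccades whose true duration lies in
  the 30–80 ms window — the same two-sided windowing used when a
  duration-filtered detector is compared against a duration-filtered
  reference — and the false-positive fraction counts detections matching
  no truth event within 100 ms (fp/(tp+fp); no true-negative count exists
  for events in continuous time).
* *Kinematics*: 10° saccades with unjittered 55 ms durations recovered
  with mean absolute duration error ≤ 2 samples and peak velocity within
  10% of the analytic maximum.

Problem sizes (50–60 s recordings, 50–100 seeds) were chosen so each block
exercises the full pipeline while the whole script completes in seconds.

## Known limitations

* Blinks riding on detrended-level offsets larger than ~10% of their own
  amplitude fail the bound search and are missed; this is the dominant
  residual blink miss (~5% under benchmark conditions) and is inherent to
  the absolute 10%-bound rule combined with polynomial detrending.
* Thresholds are estimated once per recording; no adaptation over time.
* The false-positive floor is set by noise peaks just above the knee whose
  bound spans happen to fall inside the 30–80 ms window.
* One vertical-channel blink model: no separate treatment of partial lid
  closures or flurries; a double blink is one event by design.
* EDF support reads through `mne` and writes through a minimal 16-bit
  writer; channels with unequal sampling rates are not supported.
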