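# Methods

## The measurement model

Core body temperature (T<sub>b</sub>) is sampled hourly (two short-photoperiod
birds half-hourly) by an implanted logger with 0.0625 °C resolution and a
per-logger accuracy offset; activity is recorded as counts per minute by a
passive infrared sensor and normalized to each bird's maximum before
analysis. Time is kept as decimal hours since the start of recording with
lights-on anchored at clock 0, so Zeitgeber time (ZT 0 = lights-on)
coincides with the clock hour. Photoperiod transitions move dusk at
1 h/day while dawn stays fixed — this keeps ZT 0 stable, which the
anticipation analysis depends on; the alternative (moving dawn) would
confound breakpoint estimates with the schedule itself.

## The synthetic cohort

The generator emulates the statistical structure of such recordings, not
their physiology: there is no thermoregulatory model, no torpor, no
ambient-temperature dependence (birds are assumed thermoneutral).

**Entrained days** (0 < photoperiod < 24 h). T<sub>b</sub> follows a
mesor-centred template: trough in the dark, a linear anticipatory ramp
starting at `ramp_onset_zt`, a light-phase plateau, and a 2 h linear decay
after dusk. The ramp saturates 1 h *after* lights-on rather than at
lights-on; this makes the 7-point dawn window a single-hinge signal, so the
two-segment regression estimates the embedded onset without structural
bias (a ramp ending exactly at dawn puts two knees inside the window and
biases any single-breakpoint fit). Secondary features are additive
Gaussian bumps in ZT: a nocturnal peak (short photoperiod, ZT 11:05,
+0.6 °C) and an afternoon peak (long photoperiod, ZT 8:51, +0.5 °C), each
1 h wide.

**Constant conditions.** The 24 h template amplitude is zero — the model
deliberately contains *no* residual circadian component under LL/DD — and
the observed daily range arises from noise extremes plus husbandry
masking.

**Noise, masking, quantization.** Gaussian sensor/biological noise
(default SD 0.15 °C per hourly sample, consistent with breakpoint
dispersions of ±6–26 min across birds at these profile sizes); additive
stress-hyperthermia spikes at husbandry visits (+0.8 °C, exponential decay
with 30 min half-life — large enough to be detectably positive in the
paired test at default noise); values quantized to 1/16 °C after noise.

**Calibration.** The free scale — template amplitude under entrained
schedules, noise SD under constant conditions — is found by Brent
root-finding against a 400-day fixed-seed Monte-Carlo estimate of the mean
daily range, including bumps, spikes and noise (common random numbers make
the objective smooth and monotone). The calibration targets the
*pre-quantization* range; quantization changes the realized mean range by
well under 1 %. Targets for which no non-negative root exists (noise or
masking alone already exceed the requested range) raise an error. Measured
accuracy: mean observed daily range within 2 % of target over 1000
simulated days.

**Cohort structure.** Treatment mean daily ranges are 2.52 / 2.27 / 1.46 /
1.30 °C (SP/LP/LL/DD) with a between-bird SD of 0.33 °C — the value
implied by group standard errors of 0.12–0.19 °C at group sizes 5, 8, 8
and 3. Bird-level range offsets are drawn once per cohort and centred to
sum to zero within the birds entering the amplitude model (moment
matching): every simulated cohort then realises the stated group means
essentially exactly while keeping realistic between-bird spread, so the
mixed model sees the intended standard errors and contrast structure
rather than a cohort-level lottery. The LP→LL birds share one offset
across both treatments, giving the random intercept real repeated-measures
content. Dawn onsets carry 10 min SD between-bird jitter. Mesor 40.8 ±
0.15 °C puts the plateau near 42 °C and the trough near 40 °C.

**Activity.** Per-minute Poisson counts. Entrained days: zero in the dark,
a linear rate ramp from `activity_onset_zt` saturating 1 h after
lights-on, full drive (default 18 counts/min) through the light phase.
Constant conditions: a square-wave ultradian bout process (default 4 h
period, 50 % duty) modulating the rate — strongly under LL (95 % depth),
more weakly under DD. Husbandry defaults: one visit per day, fixed at ZT 3
under entrained schedules, uniformly random over the full day under
constant conditions — the regime appropriate for analysis windows, since a
visit schedule confined to working hours is itself genuinely 24 h
rhythmic and would mask the test.

## Analysis choices

* **Periodogram.** Candidate periods are every multiple of the sampling
  interval in [1 h, 30 h] (hourly T<sub>b</sub>: 2–30 h, since a one-bin
  fold is untestable; activity is mean-binned to 6 min for a finer grid).
  Incomplete final cycles are included — bins may hold unequal counts and
  K is the mean count per bin — because 10-day windows are not multiples
  of most periods and truncation would discard up to a full cycle.
  Pointwise α = 0.05 per period with no multiplicity correction (the
  conventional red-line display); a Bonferroni option exists but is off by
  default. Fundamental vs subharmonic periods are separated by the
  Q<sub>p</sub>/critical-value ratio, since a P-periodic signal carries
  similar Q<sub>p</sub> at 2P, 3P … but those folds have more degrees of
  freedom. A constant series returns Q<sub>p</sub> = 0 everywhere with a
  degenerate flag rather than an error.
* **Amplitude model.** Day boundaries at clock midnight; days with < 90 %
  of expected samples are dropped, transition days and half-hourly birds
  excluded. REML for variance components; the treatment test is a
  likelihood ratio between *ML* refits (REML likelihoods are not
  comparable across fixed-effect structures); contrasts use the
  studentized-range (Tukey) adjustment at residual degrees of freedom.
  A zero between-bird variance fit is flagged (`boundary_fit`), where the
  estimates coincide with ordinary group means.
* **Anticipation.** The dawn window is [lights-on − 5 h, + 1 h] inclusive,
  7 hourly T<sub>b</sub> points; activity enters as the mean of the 10
  one-minute counts immediately preceding each grid time. Because that
  10-min box average lags the instantaneous rate, activity breakpoints
  carry a ≈5 min late bias — an order of magnitude below the between-bird
  spread. The hinge breakpoint is optimized on a dense 1-min grid
  (earliest optimum on ties) with golden-section refinement, constrained
  to keep two points on each side. Replicate unit for the ±SD is the bird
  (each fitted on its 5-day mean profile); per-day fitting is available.
  Flat profiles are reported with a non-identifiability flag, and a
  declining post-slope is flagged as non-anticipatory, not forced.
* **Secondary peaks.** Peak = ZT of the highest *interior local maximum*
  of a centered 3 h moving average within the phase window (dark phase
  trimmed 2 h past dusk for the nocturnal peak; ZT 6–16 for the afternoon
  peak). A plain window argmax would sit on the dusk-decay or dawn-ramp
  shoulder, not the bump; monotone windows skip the day. The 3 h width is
  a smoothing choice, not a data-derived constant.
* **Husbandry.** A sample is "husbandry" if a visit fell in the hour
  ending at it, "1 h after" if in the hour before that (husbandry wins on
  overlap). The pipeline refuses to interpret a constant-condition
  T<sub>b</sub> periodogram when the visit log itself is 24 h significant
  in that window, unless overridden.

## What passing tests do and do not show

The generator reproduces first-order waveform shape, treatment effect
sizes and their uncertainty structure, anticipation onsets, ultradian
bouts, masking spikes and logger quantization. It does not reproduce
autocorrelated biological noise, missing-data patterns, gradual
re-entrainment after transitions, inter-day amplitude drift, or any
coupling between activity and T<sub>b</sub> beyond their shared template —
so green recovery tests validate the *estimators* under the stated
conditions, not the biology of any particular dataset.

## Problem sizes and determinism

Default runs use the full cohort (767 amplitude bird-days across 16
modelled birds), 10-day periodogram windows, 5-day dawn profiles from 3
birds per photoperiod, and 400-day calibration Monte-Carlo; the recovery
test suite re-simulates tens of cohorts in well under a minute on one CPU.
All randomness flows from one master seed through spawned child seeds
(one per bird/stream), so every series, fixture file and summary is
bit-reproducible given (parameters, seed); the calibration seed is fixed
independently of the cohort seed so calibrated scales are shared across
runs and cached.
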