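# ptarmigan-rhythms

Analysis pipeline for daily rhythms of core body temperature (T<sub>b</sub>)
and locomotor activity in birds held under polar-style light regimes: a
short photoperiod (SP, L:D 6:18), a long photoperiod (LP, L:D 16:8),
constant light (LL) and constant darkness (DD). The scientific questions it
addresses are the ones a chronobiologist asks of such recordings:

* Is the variable rhythmic, and at what period? — double-plotted actograms
  and the **χ²-periodogram**: fold the series at a candidate period *P*
  into *B = P/Δt* phase bins and compare bin-mean variance to total
  variance,
  *Q*<sub>P</sub> = *K* · Σ<sub>h</sub> (M<sub>h</sub> − M̄)² / σ̂²,
  with *K = N/B*; under the no-rhythm null *Q*<sub>P</sub> ~ χ²(*B* − 1).
* How large is the daily T<sub>b</sub> cycle? — **amplitude** = daily
  maximum − minimum per bird per day, compared across light regimes with a
  linear mixed model (treatment fixed effect, random intercept per bird,
  REML), estimated marginal means, Tukey-adjusted pairwise contrasts, and
  a likelihood-ratio test from ML refits.
* Does the bird *anticipate* dawn? — mean T<sub>b</sub> and pre-sample
  activity over the window from 5 h before lights-on to 1 h after, fitted
  with a continuous two-segment ("hinge") regression
  *y* = β₀ + β₁*t* + β₂·max(0, *t* − ψ); the breakpoint ψ is the onset of
  the anticipatory rise.
* Is apparent rhythmicity under LL/DD just husbandry stress? — T<sub>b</sub>
  samples categorized as husbandry / 1 h after / none, paired t-tests on
  per-bird category means, and a χ²-periodogram of the visit schedule that
  guards analysis windows against a rhythmic husbandry routine.

Because raw recordings of this kind are rarely redistributable, the package
ships a first-class **synthetic-data generator** (`ptarmigan_rhythms.simulate`,
`ptarmigan_rhythms.cohort`): an entrained daily T<sub>b</sub> template
(dark trough → pre-dawn linear ramp → light plateau → dusk decay, plus
secondary Gaussian peaks), Poisson activity with a pre-dawn ramp and ~4 h
ultradian bouts under constant light, stress-hyperthermia spikes at
husbandry visits, Gaussian sensor noise and 1/16 °C logger quantization.
A fixed-seed Monte-Carlo calibration root-finds the template amplitude
(or, under constant conditions, the noise SD) so the *expected* observed
daily range equals the target for each treatment. Every analysis stage is
therefore testable end-to-end against known ground truth.

## Worked example

```sh
python analysis/03_amplitude_model.py --seed 1
```

simulates the default cohort (7 SP birds × 48 d — one for 30 d, two logged
half-hourly and excluded from the model; 8 LP→LL birds × 23 + 14 d; 3 DD
birds × 83 d) and prints:

```
767 bird-days from 16 birds

Estimated marginal means (°C):
  DD: 1.30 (0.20)
  LL: 1.47 (0.12)
  LP: 2.25 (0.12)
  SP: 2.51 (0.16)

Treatment LR = 574.681 (df=3), p = 3.10e-124

Pairwise contrasts (Tukey-adjusted):
  DD vs LL: -0.17 (0.24), p = 0.885
  ...
  LP vs SP: -0.25 (0.20), p = 0.584
```

Read: the daily T<sub>b</sub> cycle is large and indistinguishable between
the two entrained photoperiods (≈2.5 and 2.3 °C, p = 0.58), collapses to
≈1.3–1.5 °C of noise-driven range under constant light or darkness
(cross-regime contrasts p < 0.001), and the two constant conditions do not
differ (p = 0.89). The other drivers follow the same pattern:

```sh
python analysis/01_simulate_cohort.py    # write CSV fixtures + manifest
python analysis/02_rhythm_detection.py   # actograms + χ²-periodograms
python analysis/04_dawn_anticipation.py  # hinge breakpoints + secondary peaks
python analysis/05_husbandry_masking.py  # stress-masking checks
```

`04` reports, e.g., an SP T<sub>b</sub> breakpoint near ZT 21:06 ± 29 min
against an activity breakpoint near ZT 22:20 — the core anticipation
result that T<sub>b</sub> rises hours before either lights-on or
locomotion. A `rhythms` console script (`rhythms simulate / analyze /
periodogram / amplitude`) exposes the same stages for shell use.

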