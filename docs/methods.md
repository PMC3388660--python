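# Methods

## Patient model

The simulated patient is a deterministic, beat-averaged lumped circulation
advanced with a fixed explicit step of 5 s (hemorrhage dynamics are
minutes-scale, and a fixed step makes trajectories bit-reproducible). No
arterial waveform is synthesized: PPV is computed analytically as a scalar
percentage, which is the form in which the controller consumes it.

**State and conservation.** The state carries the intravascular volume, the
interstitial excess of infused crystalloid, cumulative ledgers for
hemorrhage and infusions, and the derived outputs (HR, SV, CO, SBP/DBP/MAP,
true PPV). Volume is conserved exactly: baseline blood volume − cumulative
hemorrhage + cumulative infusions = intravascular volume + interstitial
excess at every step (the suite checks the residual stays below 0.1 ml).

**Volumes.** Blood volume is 70 ml/kg. Crystalloid enters the plasma
instantly and relaxes exponentially (half-life 25 min) toward a steady-state
intravascular retention of 0.45; colloid is fully retained on scenario
timescales. The retention fraction is the single most results-sensitive
constant: it sets how much infused fluid actually corrects the deficit and
therefore every managed-arm fluid total.

**Deficit-driven responses.** Let f = max(0, 1 − V/V₀) be the fractional
intravascular deficit. All physiological responses are static monotone
functions of f, normalized to be exact at f = 0 so the baseline state is a
fixed point of the dynamics:

* Stroke volume: SV = SV₀ · g(f), with g a falling logistic (midpoint 0.26,
  width 0.05). Above euvolemia a nearly-flat bonus (2% ceiling) models the
  Starling plateau: past euvolemia an extra 500 ml raises CO by well under
  2%, which is the substrate of the controller's inability to
  over-resuscitate.
* Heart rate: HR = HR₀ · (1 + 1.15 · d(f)), with d a normalized rising
  logistic (midpoint 0.27, width 0.04) representing baroreflex activation;
  HR is clamped to [30, 180] and SV to ≥ 5 ml.
* Vascular tone: SVR = SVR₀ · (1 + 0.3 · 1.15 · d(f)); MAP = CO × SVR, pulse
  pressure scales with SV, and SBP/DBP are reconstructed from MAP and pulse
  pressure so MAP = DBP + (SBP − DBP)/3 holds identically.
* PPV: a baseline-normalized logistic in f with ceiling 25%, returning 6% at
  euvolemia (safely below the 9–13% gray zone) and calibrated through two
  anchors — a 600-ml deficit maps to 10% and a 700-ml deficit to 15% for the
  reference 75-kg patient. The anchors account for the maintenance
  crystalloid already retained when bleeding starts, so that in the massive
  scenario (2,000 ml over 20 min, 100 ml/min) the cohort-mean crossing times
  land at ~7 min (PPV 10%) and ~8.5 min (PPV 15%) after onset.

The gain constants were fitted once, analytically, against the endpoint
anchors of the unmanaged mild/moderate/massive scenarios and the
detection-time anchors (CO −10% at ~14 min, MAP −10% at ~16 min, HR +10% at
~13 min after onset of the massive bleed). A single static deficit-response
curve cannot hit all nine anchors centrally — the moderate-hemorrhage
endpoints and the massive-hemorrhage crossing times pull in opposite
directions — so the curves sit within one printed SD of each anchor rather
than on top of each: this is a known limitation of the memoryless model.

**Drugs.** Ephedrine, phenylephrine, epinephrine and fentanyl add decaying
effect levels (single-exponential, half-lives 20/8/5/30 min) with soft
saturation (level/(level+k)), perturbing HR, vascular tone and
contractility. Magnitudes are set so one 100-µg phenylephrine dose raises
MAP by ~8–12 mm Hg in moderate shock. Doses are a manual-play convenience;
no closed-loop result depends on them.

## Population response model

The controller's prior is fitted on a synthetic stand-in for a pre/post
bolus database (n = 414 by default, regenerable at any n ≥ 50). Generative
truth: PPV is drawn from a two-mode mixture spanning 2–25%; the expected
%ΔCO after a reference 500-ml colloid bolus is clip(2.5·(PPV − 5.6), −5, 32)
plus Gaussian noise (SD 7 points); a responder is ΔCO ≥ 15%. This places the
responder probability near one half across the 9–13% PPV band — the gray
zone — rising steeply on either side.

Fitting is deterministic: a binomial GLM for the responder curve and a
two-stage least-squares fit (tail means for floor and cap, OLS on the
central band for slope and midpoint) for the expected-ΔCO curve. On 10,000
synthetic records the fitted responder curve recovers the generative one
within 0.05 absolute everywhere on [0, 25]%. Secondary inputs (CO, MAP, HR)
apply multiplicative modifiers bounded to ±20% so PPV remains the primary
driver. What passing these tests shows is internal consistency of the
pipeline, not fidelity to any real patient population: the stand-in does not
reproduce real covariance between PPV and CO, measurement-device strata, or
real gray-zone statistics.

## Controller

Thresholds are expressed in expected %ΔCO for the reference bolus: low = 5,
high = 15, initial test threshold = 8, which map through the default
population curve to PPV ≈ 7.6, 13 and 8.8 — bracketing the gray zone.
Boluses are 250 ml at 50 ml/min (test boluses 100 ml), evaluated 2 min after
completion against the CO at the start; "quicken" multiplies the active rate
by 1.5 (capped at 100 ml/min). The sensor is polled every 30 s.

Adaptation is multiplicative with step 0.10 and hard bounds (thresholds stay
within [0.5×, 2×] their defaults; the per-patient prediction rescale within
[0.5, 2]), which keeps the loop stable under sensor noise. Two choices the
design left open:

* The gray-zone "downward CO trend" gate is relative — a decline of at least
  0.5% of CO across the 5-min window — so slow numerical drift from
  crystalloid redistribution does not masquerade as deterioration.
* Consecutive failed test boluses escalate the threshold ratchet
  ((1 + step) raised to the streak length): repeated futile challenges add
  interstitial fluid without information, so the bar for re-probing rises.
* A failed test uses a volume-prorated responder cutoff (15% × volume/500),
  since expecting the full responder criterion from a 100-ml probe would
  label every test a failure.

An optional median filter over the last N PPV readings is available
(`ppv_filter_width`, default 1 = raw): commercial PPV displays already
average over respiratory cycles, and in the packaged noise experiments raw
readings give the most symmetric behavior because spurious triggers and
spurious halts statistically cancel.

## Scenarios and noise

Built-in timelines: mild 500 ml / moderate 1,500 ml over 90 min, massive
2,000 ml over 20 min (all starting at 30 min of a 150-min run); a 60-min
management-comparison case (2,000 ml over 20 min from t = 15); and a slow
120-min case (1,000 ml starting at t = 30). The slow-bleed duration is not
pinned by the source timelines; 30 min (33 ml/min — slower and longer than
the massive bleed) was chosen and also places the first closed-loop
intervention near 52 min from the start, matching the reference behavior.
Maintenance crystalloid (200 ml/h) runs in every scenario. Baseline traits
are drawn uniformly per trial from per-phase ranges; batches use
deterministic child seeds so trials are independent but exactly
reproducible.

Reported-PPV corruption touches only the sensor stream, never the simulator:
a constant per-trial bias drawn uniformly from ±5 points, a fresh uniform
±5-point fluctuation per reading, or both (worst case ±10 points), clamped
at zero.

**Fluid accounting.** "Fluid given" is totaled from hemorrhage onset to
onset + 90 min (clipped to scenario end), uniformly across scenarios; under
maintenance alone this is exactly 300 ml, which is the convention the
unmanaged-arm tables assume.

## Statistics

Group tables report mean ± sample SD across trials. Two-group comparisons
use the Mann-Whitney U test; multi-group comparisons use one-way ANOVA with
Tukey HSD post hoc at α = 0.05 (cross-trial endpoints are independent, so a
repeated-measures design would be inappropriate here). The CO coefficient of
variation uses the population SD of the within-trial samples over the full
scenario. Threshold-crossing times are linearly interpolated between 30-s
samples; "final" values are the last sample.

## Problem sizes and determinism

Default experiment sizes are those of the study conditions: 20 trials per
arm/condition, 40-patient baseline cohorts for the wide ranges and 80 for
the narrow ones. A full four-condition noise experiment (80 trials of 120
min at 5-s steps) runs in a couple of seconds. All randomness flows from a
single seed through `numpy.random.SeedSequence`; identical seeds give
bit-identical traces, decisions and reports.

## Known limitations

* The simulator is a re-derivation from printed calibration anchors, not a
  reconstruction of the original supplementary model; its CO response at
  gray-zone deficits is nearly flat (forced by the early-PPV/late-CO timing
  anchors), so managed fluid totals are several-fold smaller than the
  reference tables even though all timing, baseline and relative statistics
  reproduce. Relative fluid-difference metrics are correspondingly noisier
  per bolus quantum.
* No oxygen transport, hemodilution or anemia: a slow unmanaged bleed ends
  in low CO, never in an explicit death event, and the controller will keep
  volume-resuscitating indefinitely — supervision concerns are out of scope.
* No ventilator interaction, tidal-volume dependence of PPV, arrhythmia, or
  spontaneous breathing; PPV validity conditions are assumed to hold.
* Clinician behavior is not modeled; the "manual" management mode only
  applies pre-scripted drug schedules.
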