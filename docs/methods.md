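# Methods

## Overview

`pufftopo` implements the computational chain of a portable smoke-sampling
system: a flow meter records a smoker's draw at ~1 kHz, the recorded puffs
are reduced to a 100-ms setpoint profile, and a mass flow controller (MFC)
replays that profile through collection media. The package covers the
software side end to end — puff identification and characterization,
profile generation, a playback simulator with fidelity scoring, emission
yield normalization, and screening-level risk estimation — plus a synthetic
trace generator so every stage is testable without hardware.

Canonical units throughout: seconds, standard liters per minute (slpm) for
flow, milliliters for volume (1 slpm = 1000/60 ml/s). The flow meter is
assumed to report standardized (mass-equivalent) flow, as this sensor class
does; no temperature/pressure correction is applied.

## Synthetic puffs: the symmetric trapezoid

A puff regimen specifies three per-puff quantities — duration *D*, volume
*V*, and peak flow *Q* (ml/s) — plus a start-to-start inter-puff interval.
The generator renders each puff as a symmetric trapezoid (ramp *r*, plateau
*D* − 2*r*, ramp *r*): this is the minimal waveform consistent with all
three constraints, since the area condition fixes

    r = D − V / Q,    feasible iff  Q·D/2 ≤ V ≤ Q·D.

The limits are the triangle (*V* = *Q·D*/2, zero plateau) and the rectangle
(*V* = *Q·D*, zero ramp); infeasible triples raise immediately with the
violated bound named. All four built-in regimens are feasible trapezoids
(asserted in the test suite). Defaults mirror the sampling protocol the
system was used under: three puffs per sample, 30-s spacing, 1 kHz
sampling, one second of zero-flow padding at each end. Gaussian sensor
noise (sd in slpm) is added unclipped, so traces can dip below zero the way
a real differential sensor jitters; the detector must tolerate this.

What the generator does **not** emulate: physiological ramp asymmetry and
within-puff flutter, cigarette burn-rate drift across puffs, sensor drift
or quantization, and mouthpiece leaks. Passing round-trip tests therefore
demonstrate correctness of the detection/binning/playback chain under the
stated puff model, not detector performance on arbitrary human recordings.

## Puff detection

Pipeline (parameters in parentheses are the defaults):

1. **Median filter** the flow (5-ms window) to suppress impulse noise
   without smearing ramps.
2. **Hysteresis candidates**: a run of samples above the off-threshold
   (0.05 slpm) that reaches the on-threshold (0.1 slpm) somewhere. Two
   thresholds prevent noise around a single threshold from splitting one
   puff.
3. **Boundary extension** outward to the nearest sample at or below the
   boundary floor (0.01 slpm). Thresholds alone truncate the trapezoid
   ramps and bias duration and volume low; extension recovers the ramp
   feet. The floor sits well below the off-threshold but above typical
   filtered baseline noise, so extension stops within a few samples of the
   true foot.
4. **Merge** candidates whose gap is under 1.0 s (a mid-puff dip is not two
   puffs), then **drop** candidates shorter than 0.3 s (no human puff is
   that short; blips are artifacts).
5. **Metrics on the raw trace**: volume by trapezoidal integration over
   [start, end], maximum as the raw sample maximum (plateau ties need no
   tie-break — the value, not the location, is reported), average flow
   defined as volume/duration. Filtering therefore never biases the
   reported numbers.

With the defaults and noiseless 1-kHz trapezoids, detection recovers
duration to ±4 ms (the floor is crossed ~2 samples into each ramp), volume
to ≪0.5%, and peak flow exactly whenever the plateau spans ≥1 sample.
Interval estimates use successive start-to-start differences. Detected
boundaries are reported at sample times; no sub-sample refinement is
attempted at 1 kHz.

The average-flow definition (V/D) is deliberate: regimen tables sometimes
print an "average flow" row computed some other, unstated way that is
mutually inconsistent with (D, V); this package reports the volume-based
mean only.

## Control profiles

`bin_average` produces left-aligned contiguous 100-ms bins anchored at
trace time zero, each bin the mean of its samples, a trailing partial bin
averaged over the samples it has, and negative means clipped to zero (an
MFC cannot draw backwards). Zero-flow bins between puffs are retained so
playback preserves inter-puff timing. Anchoring at trace zero (not first
puff onset) keeps profile and trace on one clock, which simplifies fidelity
scoring. Bin means conserve volume relative to the trapezoidal integral up
to edge effects only; with zero-padded traces the two agree to ≪0.2%
(property-tested). 10-ms profiles are intentionally out of scope: the
hardware's serial command path cannot keep up, so the package does not
pretend to support them.

## MFC playback simulation

The machine is modeled as a first-order lag with a zero-order-hold command
stream:

    dQ/dt = (s(t) − Q)/τ,   s(t) = profile value, refreshed every
                            command interval, delayed by the latency

Defaults: τ = 0.05 s (fast-response MFC class), command interval 0.1 s
(the profile's own resolution), latency 0.02 s (USB-serial transport),
ceiling 5 slpm. Integration applies the exact exponential update
Q⁺ = s + (Q − s)·e^(−Δt/τ) per sample step, so the discretization is exact
between command switches at any sample rate; τ = 0 degenerates to
instantaneous tracking. The ceiling is applied to the setpoint (the
saturating-command interpretation), which keeps the response in [0, max]
without invalidating the exponential update. The profile's right edge
belongs to the last bin, so the τ→0, latency→0 limit reproduces the
zero-order-hold profile exactly.

Because a first-order lag has unit DC gain, volume lost on ramp-up is
returned on decay, and total delivered volume tracks programmed volume to
≪1% whenever the profile ends in a zero-flow tail longer than a few τ. The
5% volume agreement reported for the physical prototype is treated as an
upper bound the simulator must beat, not a value to reproduce: the real
device's per-bin deviations (~9% mean) are dominated by unmodeled hardware
(valve dynamics, pressure-drop coupling, flow measurement error) that this
minimal model does not claim to capture.

Fidelity scoring bins the achieved trace onto the profile grid and reports
per-bin relative deviations only for bins with programmed flow ≥ 0.1 slpm —
near-zero denominators would otherwise dominate the statistics — while all
bins count toward the volume comparison. The threshold choice is documented
rather than derived; how the physical system's printed deviations handled
near-zero bins is unknown.

## Emissions

Samples are a few puffs drawn through one media set, two replicates per
condition. `combine_replicates` sums masses, puffs, and volumes (two 3-puff
replicates → a 6-puff pool) and reports per-puff yields (µg/puff) and
airborne concentrations (µg/m³ = µg / ml drawn × 10⁶ — the inhaled-dose
denominator). Within-pair spread is the half-range of the two per-puff
yields; with n = 2 this equals the mean absolute deviation, and nothing
finer is identifiable from a pair. Between-product ratios
(`ratio_with_uncertainty`) divide matched per-puff yields pairwise and
report mean ± sample sd of the individual ratios rather than a
ratio-of-means; with two pairs this is the natural "m ± s" structure for a
replicated comparison, though with n = 2 the sd is itself a rough estimate.

## Risk

HQ = C/RfC per compound; CR = C · UR · (ED/AT) with defaults ED = 40 yr,
AT = 78 yr. No exposure-frequency or inhalation-rate term is applied:
concentrations are assumed already expressed as long-term exposure
concentrations, so the only amortization is duration over lifetime. Totals
are sums over compounds (for HQ this is the standard additive screening
index for a mixture). Toxicity parameters are user-supplied tables, never
bundled: RfC and unit-risk databases are version-dependent and should be
cited by the analysis, not frozen into a package.

## Numerical choices and degenerate inputs

- Trapezoidal integration with linearly interpolated endpoint values, so
  integrals of piecewise-linear signals between samples are exact;
  verified against dense midpoint-Riemann oracles to 0.1%.
- Uniform-sampling tolerance: max |Δt − 1/fs| < 0.1/fs; violations are hard
  errors naming the first offending row, as are non-monotone time stamps
  and non-numeric cells.
- Bin indexing uses floor(t/width + 1e-9) to keep exact bin-edge samples in
  the bin they open.
- Text round-trips are exact: flows are written with six decimals when that
  is lossless and full `repr` precision otherwise, and parsed with
  round-trip float conversion.
- An empty detection result is a valid output (silent trace), but an empty
  puff list cannot be summarized, an empty profile cannot be written, and a
  zero-volume profile cannot be fidelity-scored — each raises with a
  specific message.

## Problem sizes

The validation suite and the reproduction script run the same sizes the
system operates at: 1 kHz traces, three-puff trains (30-s spacing for
topography round trips; 5-s spacing for the playback fidelity sequence,
which shortens the silent stretches the simulator would spend at zero flow
without affecting the per-puff dynamics), 20 seeded noise replicates for
detection robustness. Everything completes in seconds on one core.

## Known limitations

- The trapezoid is a model of regimen tables, not of human inspiration
  waveforms; detector accuracy on real recordings is untested here.
- The first-order MFC model has no pressure-drop coupling to the cigarette
  or filter, no valve nonlinearity, and no measurement noise, so its
  per-bin deviation statistics are optimistic relative to hardware.
- Risk estimates are screening-level: three-compound sums, no dose-response
  modeling, no behavioral exposure factors (puffs/day, product use
  patterns).
- Streaming (real-time) detection and serial device control are out of
  scope; the package operates on recorded files.
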