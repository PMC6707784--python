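# Methods

This note documents the models, estimators, default parameters and design
choices behind `plmox`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Sensor calibration

**Model.** Phosphorescence quenching is modeled as linear Stern–Volmer in
inverse lifetime, 1/τ = 1/τ₀ + k_q·Po2, fitted per temperature by ordinary
least squares on 1/τ (the model is linear there, and the fit is matched by
an independent grid-search oracle in the tests). The functional form of
PtP-C343's response is not uniquely pinned down by any single reference;
linear Stern–Volmer is the standard first-order model for collisional
quenching and inverts in closed form. For sensors with visible curvature a
monotone-spline curve (`SplineCalibrationCurve`, PCHIP forward map with a
root-found exact inverse) can be swapped in.

**Temperature handling.** Curves are stored per calibration temperature
(default family: 32.4, 34.2, 35.7, 37.0 °C, bracketing the brain-surface
temperatures seen under dry, cooled and heated objectives). Between nodes,
τ₀ and k_q are interpolated linearly in temperature. Beyond the node range
the nearest curve is used up to ±0.5 °C; farther out the conversion raises.
Rationale: converting a lifetime with a curve for the wrong temperature
biases Po2 in a systematic direction (at fixed τ, a colder curve implies a
higher Po2 — the curves shift right as temperature falls), and a silent
extrapolation would hide precisely the mistake the temperature-indexed
family exists to prevent.

**Inversion tolerances.** A lifetime is only converted if it falls within
the fitted curve's lifetime range extended by a relative tolerance
(default 2 %, configurable); inside the tolerance band the result is
clamped to the fitted Po2 range. Fit preconditions: ≥ 4 points spanning
≥ 50 mmHg. Non-monotone sweeps are not rejected — the fit proceeds and a
warning naming the offending point pairs is recorded on the curve (flag
threshold: a lifetime *rise* exceeding 5 % of the sweep's dynamic range;
a scale-based floor so a gross outlier cannot inflate its own tolerance).

## Gated decay processing

**Clock geometry.** The nominal cycle is 250 µs (25 µs gate open, 225 µs
collection) at a 1.25 MHz digitizer — 312.5 samples. Internally a cycle
carries 312 whole 0.8 µs bins (31 on-phase, 281 off-phase; 249.6 µs of
samples) while cycle start times keep the nominal 250 µs period; the
residual 0.4 µs is dead time. This keeps all bin arithmetic integral at a
< 0.2 % deviation from the nominal clock. The first ⌈5.6/0.8⌉ = 7 off-phase
bins are discarded before any fit (gate transients and prompt
fluorescence); every `DecayCurve` therefore starts at ≥ 5.6 µs after the
gate end by construction.

**Lifetime estimator.** Accumulated decays are fitted by Poisson maximum
likelihood with model A·exp(−t/τ) + B (single exponential plus constant
background), optimized by L-BFGS-B in (log τ, log A, B) with an analytic
gradient, initialized from a count-weighted log-linear regression on
background-subtracted counts, and cross-checked against a coarse profile
grid so a bad basin raises rather than returning silently. The 95 %
confidence half-width on τ comes from the profile likelihood (χ²₁
threshold); an unidentifiable decay (e.g. flat background) yields an
interval clipped to the search bounds, never a confident τ. The estimator
is deterministic given its input. Known small-sample behavior: on pools
with few accumulated photons (≲ a few thousand) the free background can
absorb part of the tail and bias τ slightly; pool floors (below) keep the
reported quantities away from that regime.

**Po2 Mean contract.** The mean capillary Po2 is *fit-then-convert*: all
cycles are accumulated into one decay, fitted once, converted once. On
EAT-modulated traces this is not the time-average of instantaneous Po2 —
the accumulated decay is a photon-weighted lifetime mixture, and since
photons-per-cycle scale with τ while Po2 is convex in 1/τ, the fitted
value sits below the time-average of the planted Po2 waveform (the tests
assert the inequality explicitly). This mirrors what a real gated
acquisition measures.

## EAT analysis

**RBC detection.** An RBC in the focal volume displaces labeled plasma and
darkens the on-phase fluorescence. Detection: 3-cycle moving-average
smoothing; rolling-median baseline over 501 cycles (reflective padding so
a record that starts inside an RBC keeps a sane edge baseline); trough
floor at the 2nd percentile of the smoothed signal; event while the signal
sits below baseline − f·(baseline − floor) with f = 0.5; minimum duration
2 cycles; edges refined to the linear threshold crossing. A signal whose
dynamic range is under 4 shot-noise standard deviations yields no events
and a logged warning. All constants are configurable. The detector's
resolution is ~2 cycles (0.5 ms): planted passages separated by less merge
into one detection, which shows up as a ≲ 2 % flux undercount at awake
flux rates.

**Cycle classification.** With border window [b₁, b₂] = [1.0, 3.5] ms and
minimum inter-RBC window w = 5 ms: cycles inside [entry, exit] are
`inside_rbc`; cycles outside every event whose distance to the nearest
event edge falls in [b₁, b₂] are `border` (both flanks of both edges pool
together — which edge the original convention used is not documented, so
the symmetric reading was chosen and both bounds are configurable); gaps of
length ≥ 2·b₂ + w admit an `inter_rbc` window spanning the full mid-gap
region between the two flanking border zones (width gap − 2·b₂, centered);
everything else, including the record's leading and trailing partial gaps,
is `unclassified`. The labels partition the cycles by construction.

**Pooled conversions.** Po2 RBC and Po2 InterRBC accumulate their pools
and use the same fit-then-convert contract as Po2 Mean. Pools below a
floor (default 500 cycles) raise, naming the pool size — lifetime fits on
photon-starved pools are unstable. RBC flux is the event count over the
record duration; the EAT profile bins cycles by signed time from the
nearest edge (negative inside the cell) with a per-bin pool floor.

## Line-scan velocimetry

Rows are successive line scans (period default 0.5 ms), columns positions
along the capillary (pixel default 0.5 µm). Moving RBCs leave slanted dark
streaks with slope (columns/row) = v·T/Δx. The streak angle is found by a
Radon transform sweep: per-scan mean removal (detrends illumination while
preserving vertical, i.e. stationary, streaks), inscribed-circle masking,
square row-blocks (≤ 16, evenly spaced) whose per-angle projection
variances are max-normalized and pooled; a 1° coarse sweep is refined at
0.25° and interpolated parabolically. Velocity = (Δx/T)·tan θ, signed by
streak direction; angles within one fine step of vertical report exactly
0 mm/s with confidence 0 (unresolvably slow), and angles within 2° of the
scan axis raise (unresolvably fast at this line period). Confidence is the
normalized prominence of the objective peak. The implied velocity
resolution at 0.75 mm/s with the default scaling is ≈ 1 %.

## Hill saturation and comparisons

SO2 = Po2ⁿ/(Po2ⁿ + P50ⁿ) with defaults n = 2.59 and P50 = 40.2 mmHg
(C57BL/6 mouse blood); the capillary's saturation uses Po2 RBC, the pool
that reflects intracellular oxygen. The closed-form inverse round-trips to
1e-12. Condition comparisons are paired per capillary (delta and percent
change per capillary and metric, mean ± s.e.m. per condition); the
capillary is the statistical unit, mouse identity is carried as metadata
only, and unpaired capillaries are excluded from that pairing with a
logged note. Mixed-effects inference is deliberately out of scope — the
output tables are ready for any external statistics package.

## Synthetic data: what it emulates, and what it does not

**Sensor model.** τ₀ falls linearly from 45 µs at 32.4 °C to 40 µs at
37 °C; k_q rises from 0.90·10⁻³ to 1.00·10⁻³ /(µs·mmHg). These magnitudes
are invented; the property that matters — the right shift, i.e. a fixed
lifetime implying higher Po2 on a colder curve, at every lifetime in the
working range — is asserted in tests.

**Capillary traces.** RBC arrivals follow a gamma-renewal process
(shape 3) to mimic single-file regularity rather than Poisson clumping;
passages closer than the transit time merge. Transit time scales as a
3.5 µm effective single-file path over the velocity (≈ 4.7 ms at
0.75 mm/s). True Po2 holds the EAT peak inside a cell and relaxes
exponentially toward the inter-RBC baseline with a 2.0 ms constant —
matching the schematic monotone decay between cells; all parameters are
exposed. Off-phase counts are Poisson with the expectation
A·exp(−t/τ(Po2(t), T)) + B evaluated at bin centers (A = 0.05 counts/bin
at the gate end per cycle, B = 0.002 counts/bin — about one
phosphorescence photon per cycle, so tens of thousands of cycles per
stable fit, as in real gated acquisitions); on-phase counts switch between
plasma (600) and RBC (250) levels with Poisson noise. Detector gain is one
count per photon.

**Preset calibration.** Each resting-state preset fixes the physiological
quantities (tissue-proxy baseline, flux, velocity, temperature) and then
sets its EAT peak by bisection so the *measured* all-cycle fit-then-convert
Po2 of a noiseless trace equals the preset's target mean (42 mmHg awake
dry/heated, 34 mmHg awake cooled, 65 mmHg anesthetized with 30 % O₂). The
bisected peaks are frozen in the source with a regression test re-deriving
one. Because the single-exponential fit of a lifetime mixture saturates
(the free background absorbs part of the early-bin excess), these planted
peaks (84–95 mmHg) sit above physiological RBC Po2 — they are the
amplitudes *required* for the gated readout to reproduce the target means
under this waveform, not claims about real EAT amplitudes, which are not
numerically established. The anesthetized preset's baseline (55 mmHg),
flux (30 s⁻¹) and velocity (0.4 mm/s) are plausible values chosen here;
only its mean Po2 target is anchored externally.

**Known systematic.** The mid-gap window extends to 3.5 ms from each edge,
where the EAT tail is exp(−3.5/2.0) ≈ 17 % of its amplitude, so the
inter-RBC pool reads the planted baseline plus ≈ +5–8 % (noiseless).
Recovery tests budget for this; it is a property of the window definition
interacting with the waveform, not an estimator defect — the same
contamination exists in real recordings.

**Line scans.** Dark Gaussian cells (half-length 2 µm) over a bright
plasma background, Gaussian point-spread blur (σ = 1 px), Poisson shot
noise; zero velocity produces static vertical streaks.

**What passing does not show.** The generator draws from the same model
family the estimators assume (single-exponential decays, constant
background, ideal gating, rigid streaks). Real data add detector
afterpulsing and dead time, multi-exponential sensor decays, focal drift,
capillary stalls, and scanning artifacts — none of which are modeled, so
recovery here validates the pipeline's correctness and calibration logic,
not robustness to those effects.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; identical seeds give
bit-identical outputs (file checksums included), and no global random
state is used. The test suite and the acceptance script use 10 s records
(40,000 cycles) with 5 seeds per preset, 60,000-cycle accumulated decays
for estimator checks, and 20 seeds for noisy calibration fits — sizes at
which the statistical scatter of every asserted quantity is several times
smaller than its tolerance.
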