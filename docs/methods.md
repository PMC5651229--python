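# Methods

## Signal model and measurement definitions

The analysis operates on paired head/eye angular-velocity traces (deg/s)
sampled at a fixed rate (default 250 Hz, i.e. 4 ms per sample). All
classification happens in *samples*; milliseconds are derived at
presentation only, which avoids rounding drift between the two unit
systems.

**Local maxima.** An interior sample strictly above its neighbours. A
flat-topped run of equal values strictly above both neighbours counts once,
at the *first* sample of the run — ties are not otherwise addressed by the
method, and first-sample collapse is deterministic and order-stable.
Endpoints are never maxima.

**Prominence** of a maximum is its height above the basal velocity line:
extend left and right until a strictly higher sample (or the trace end),
take the minimum of each interval, and subtract the higher of the two
minima. This is invariant under adding a constant to the trace, which is
the point: the eye trace's baseline is not zero.

**Width** is the full width at `apex − prominence/2`. Walking outward from
the apex, the first sample at or below the reference brackets a crossing
whose position is linearly interpolated; interpolation makes the width a
continuous function of the data (sub-sample handling is otherwise
unspecified in the method's description). A side that never reaches the
reference before the trace end clamps to the end and sets a
`width_clamped` flag rather than failing; for peaks detected with a
consistent prominence this cannot occur (both interval minima lie at or
below the reference by construction), but `compute_width` is public and
accepts arbitrary reference prominences.

**Peak selection.** Candidates passing the prominence threshold are
returned first-in-time (up to `n_peaks`, default 1), matching the
documented behaviour of the MATLAB routine the method was built on; a
`max_prominence` selection mode is provided because the original tool's
behaviour with several passing peaks is not documented.

## Per-impulse analysis

Thresholds (defaults; all configurable in `AnalysisConfig`): head
prominence 100 deg/s, eye prominence 80 deg/s, one peak per trace, QC
minimum head velocity 120 deg/s (inclusive — the velocity must be
*reached*), low-velocity count threshold 130 deg/s (strict — *under*
130), ESTP head-width factor 1.5, onset fraction 0.10.

Direction is normalized by the sign of the extreme head velocity; the eye
trace keeps the device convention (slow phase aligned with head, saccade
lobe negative), which is what makes the first eye pass find the VOR peak
and the second pass — on the negated trace — find the saccade.

`ESTP = Hpt + 1.5·Hw + Sw` (samples). The saccade's "time of appearance"
is its apex `Sp` (the method measures latency at apexes as well); a config
switch can use the left half-prominence crossing instead. A tie
`Sp = ESTP` is **not** early (the definition is strictly "less than").

Latency defaults to `Sp − Hpt` (peak-referenced). An onset-referenced
mode is provided (latest sample before the head apex at or below 10% of
the head prominence) because the method's results are described both ways
and the onset variant is not otherwise operationalized; the peak reference
is the default since it is the one the measurement figure defines.
Non-positive latency is flagged `irregular` but still reported; QC is
flag-and-retain throughout — exclusion is the caller's decision.

## Summary statistics

"First saccade" per impulse is its single detected saccade, early or not.
All mean ± SD values use the sample SD (n−1); the convention is not stated
in the method's description, and sample SD is the field norm. Per-protocol
means are unweighted across tests (no per-participant weighting is
defined). Pairwise protocol differences are descriptive only. Note that
per-protocol mean latencies of 178.32, 152.04 and 112.8 ms imply pairwise
differences of 65.52, 39.24 and 26.28 ms by arithmetic.

## The simulator

Every event is a Gaussian velocity lobe: vHIT impulses and saccades are
bell-shaped, and the Gaussian FWHM `2σ√(2 ln 2)` gives a closed-form
prediction of the measured half-prominence width, so ground truth is exact.

```
head(t) = A_h G(t; t0, σ_h) − A_o K(t; t0 + 3σ_h + d, σ_o)
eye(t)  = g·head(t) − A_s G(t; t0 + L, σ_s) + ε(t)
```

`G` is a unit Gaussian; `K` is a *truncated* Gaussian with exact zero
outside ±3σ, used only for the overshoot lobe. Real overshoots have finite
duration, and exact compact support is what makes the overshoot-invariance
property provable and bit-exact: an overshoot whose support begins after
the head lobe's right half-prominence crossing (and after the saccade's
measurement region) leaves every sample those measurements depend on
untouched. ε is white Gaussian noise on the eye channel only (the device's
eye-velocity channel is the noisy one; head velocity comes from inertial
sensing).

Defaults: head apex 200 deg/s (comfortably above the 120 deg/s QC bound),
σ_h chosen for a 100 ms FWHM (25 samples at 250 Hz — typical vHIT
morphology), VOR gain 0.9, saccade 250 deg/s with 30 ms FWHM, overshoot
σ_o = σ_h/2. Trace length 250 samples (1 s), head apex at sample 50.
These waveform parameters are plausibility choices (no per-impulse waveform
parameters are published for this method) and are all exposed in
`SimulationSpec`.

Protocol presets draw per-impulse saccade latency from Normal
distributions with the first-saccade means/SDs measured under three
predictability levels: predictable 112.8 ± 56.96 ms, less predictable
152.04 ± 58.00 ms, unpredictable 178.32 ± 46.04 ms. The "±" values are
treated as SDs (whether they are SDs or SEMs is not stated; this is a
documented assumption, not an assertion about the source data). Draws are
clipped to [20 ms, trace end − 3σ_s]; the lower bound binds ~5% of
predictable draws and shifts that preset's realized mean up by ≈1.3 ms,
the upper bound never binds for these presets. `simulate_test` alternates
impulse sides and holds head morphology fixed across impulses — only the
saccade latency and the noise vary.

## What the simulator does and does not emulate

It emulates the morphology the measurements depend on: bell-shaped lobes,
baseline offsets (via the prominence definition), overshoot, gain scaling,
direction alternation, additive noise. It does **not** emulate blinks or
tracking artifacts, multi-saccade trains, head-velocity noise,
device-specific filtering, or per-impulse variability of head amplitude
and duration. Passing recovery tests therefore validates the measurement
chain under the stated signal model, not robustness to every artifact of
real recordings.

## Numerical behaviour at the classification boundary

The early/not-early decision is a strict threshold on a measured quantity,
so impulses whose true saccade apex lies within ~1 sample of the true ESTP
bound can legitimately classify either way under noise. Two effects
matter, both properties of the method applied to noisy data rather than
implementation artifacts: (1) measured saccade prominence is slightly
inflated because the basal line picks up negative noise excursions along
the post-saccade tail, widening the measured `Sw` and biasing measured
ESTP by about +0.35 samples at noise σ = 5 deg/s; (2) with the default
head width (100 ms FWHM) the ESTP bound sits 180 ms after the head apex —
almost exactly the unpredictable preset's mean latency, so that preset
concentrates probability mass on the knife edge. Away from the ±1-sample
boundary band, classification agrees with ground truth at ≥ 99%; inside
it, agreement is essentially a coin weighted by the +0.35-sample bias.
The acceptance script reports both the agreement with the hand-applied
ESTP rule on the measured widths (exact) and the agreement with simulator
truth (boundary ties included) so the distinction stays visible.

## File formats

The device vendor's XML export schema is proprietary and not public, so
the package defines open equivalents: a long-format CSV
(`impulse_id, side, sample_index, head_velocity_degps, eye_velocity_degps`
with `# key=value` metadata comments) and a minimal XML dialect
(`<shimp_test rate_hz=...><impulse id=... side=...><head>...</head>
<eye>...</eye></impulse></shimp_test>`). Both parse to identical in-memory
tests; trace floats are serialized at 10 significant digits so a
write/read round trip stays within 1e-6 deg/s everywhere, far below every
analysis threshold. Results are a versioned JSON document with sorted keys
and 2-decimal rounding of deg/s and ms values, so re-serialization is
byte-identical.

## Problem sizes

The validation suite uses 1000 random traces for the brute-force oracle
comparison, 500 noisy impulses for parameter recovery, 100 matched pairs
for overshoot invariance and 500-impulse tests per protocol for the
latency contrast — sizes at which the stochastic checks have comfortable
margins (the contrast's standard error is ≈3 ms) while the whole suite
runs in seconds.

## Known limitations

- One saccade per impulse by design; saccade trains are out of scope.
- No VOR gain computation (the gain algorithm is a device/vendor matter).
- No artifact rejection beyond the stated QC flags.
- The vendor XML is not parsed; an import adapter would slot into
  `shimpkit.io` without touching analysis code.
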