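# Methods

This note documents the models behind `pedalkin`, the defaults they use,
what the synthetic-data generator does and does not emulate, and the
design choices made where several options were defensible.

## Geometry and forward model

The world frame sits on the crank axle: x forward (direction of cycling),
z up.  The crank angle φ is measured from the world z-axis to the crank
arm, increasing in the forward-pedalling direction, so φ = 0° is top dead
center (TDC) and φ = 180° bottom dead center (BDC).  The pedal angle θ is
the angle between the pedal surface axis and the world horizontal; it is
mechanically independent of φ and, given normal ankle flexibility,
confined to a subrange of [−90°, 90°].  The pedal moves in the xz-plane;
the IMU's y-axis points along the pedal axle, so the gyroscope's
y-component reads the pedal angular rate ω = θ̇ directly.

Treating each crank revolution as swept at a constant rate (φ̈ ≈ 0 within
a revolution — cadence may still drift across revolutions), the
body-frame accelerometer reading (specific force including gravity) is

    ẍ_x = −r φ̇² (sin φ cos θ + cos φ sin θ) − g sin θ
    ẍ_y = 0
    ẍ_z = −r φ̇² (sin φ sin θ − cos φ cos θ) + g cos θ

with r the crank-arm length and g = 9.81 m/s².  Its squared magnitude is
frame-invariant and θ-free:

    a² = r² φ̇⁴ + 2 g r φ̇² cos φ + g² ,

maximal at TDC and minimal at BDC.  For a stationary crank (φ̇ = 0) the
reading reduces to the tilted-gravity pair (−g sin θ, g cos θ).

## Pre-processing

All analysis-relevant streams (accelerometer, gyroscope, resonance
frequencies) pass through a second-order Butterworth low-pass with cutoff
fc = 2.2 Hz at fs = 25 Hz, applied forward-backward (zero net phase,
effective gain = single-pass gain squared) with odd-reflection padding of
length 3·(order+1).  The filter operates on sample index under a
nominal-fs assumption; `validate_session` flags sessions whose mean
sampling interval deviates more than 10% from 1/fs rather than resampling
them.  One shared `FilterSpec` covers all streams; per-stream overrides
are possible through the config.

## Crank angle, cadence, left–right offset

TDC/BDC events are the alternating maxima/minima of the filtered a²(t).
Peak picking uses `scipy.signal.find_peaks` with

- minimum separation 60/(2·cadence_max) s, cadence_max = 150 rpm by
  default (no physiological pedalling should exceed it on an ergometer);
- a prominence floor of 0.5 × the median peak-to-trough amplitude,
  estimated adaptively from an unconstrained first pass.  Prominences are
  computed on an odd-reflection extension of the signal so that extrema
  near the record boundaries are not discarded merely because one of
  their bases is truncated;
- strict alternation enforced afterwards, keeping the more prominent of
  two adjacent same-kind events.

φ(t) is then linear in time between successive events (TDC ↦ 0° mod 360,
BDC ↦ 180°), valid only inside the first/last event; forward pedalling is
assumed since a² is direction-blind.  Cadence is 30/Δt rpm per interval
between adjacent events, piecewise constant.  At 25 Hz this quantizes
event times to ±20 ms, which bounds the per-interval cadence error by
roughly rpm²/30·(1/fs) (≈ 5 rpm at 60 rpm) while the time-weighted mean
remains unbiased; the crank-angle MAE from the same quantization is a few
degrees.

The left–right offset check interpolates the right side's unwrapped angle
onto each valid left timestamp (the sides log on independent clocks),
takes the circular difference, and reports the circular mean and circular
standard deviation in degrees.

## Pedal angle

The accelerometer-only estimate is θ̂a = atan2(−ẍ_x, ẍ_z) (the sign of
the x-argument is flipped so a stationary pedal at +θ reads +θ; the raw
gravity components alone would return −θ).  It is exact only for φ̇ = 0;
while pedalling, the centripetal term rφ̇² contributes a crank-phase-locked
bias ρ(t) that the 2.2 Hz filter cannot remove (it lives at the ~1 Hz
crank frequency).

The refinement is a scalar Kalman filter on θ (degrees):

    predict:  θ⁻ = θ + ω·Ts ,   P⁻ = P + Q
    update:   K = P⁻/(P⁻+R) ,   θ = θ⁻ + K·wrap(θ̂a − θ⁻) ,  P = (1−K)P⁻

with the innovation wrapped to (−180°, 180°].  The wrap is load-bearing:
whenever rφ̇² > g (above ≈ 88 rpm with r = 0.17 m) the accelerometer
vector is dominated by the rotating centripetal term and θ̂a sweeps
through full revolutions; an unwrapped measurement would accumulate a
secular ~360°-per-revolution ramp and drag the state away, whereas the
wrapped innovation stays bounded and averages out.  NaN measurements
(zero-magnitude accelerometer samples) skip the update, leaving pure
dead reckoning for that step.

Defaults: Ts = 1/fs; Q = (σ_gyro·Ts·180/π)² (gyro noise propagated
through one integration step, σ_gyro = 0.02 rad/s) with a tunable scale
factor; R = 100 deg², a deliberately pessimistic measurement variance
reflecting that ρ is dominated by pedalling bias rather than sensor
noise; θ₀ = first valid θ̂a; P₀ = R.  The Gaussian-ρ assumption is wrong
in detail — the bias is deterministic and phase-locked, hence correlated
— but with R large the filter leans on the gyro and uses θ̂a only as a
slow drift anchor, which is exactly the regime where the simplification
is benign.

## Load calibration

Each channel (Fx, Fz in N, Mx in Nm) maps the four LC-tank resonance
frequencies to a load through an affine model fitted by LASSO:
70/30 train/test split (seeded, shuffled), α selected by 10-fold CV over
25 log-spaced points in [1e−10, 1e2], ties in mean CV MSE broken toward
the larger (sparser) α.  Features are standardized (center + unit
variance) before the L1 fit — otherwise the α grid is meaningless against
~250 kHz features — and coefficients are transformed back to raw units.
Constant frequency columns (which arise when a channel's coil layout
makes a coil insensitive to the loaded axis) are retained with a warning.
The α-grid search is written out explicitly (per-α `sklearn` Lasso over
seeded `KFold` splits) so the tie-break rule and the back-transform are
visible; at the grid minimum the fit agrees with ordinary least squares
to ~1e−4 in the coefficients.

Error statistics use the population convention (divide by n):
μ = E[e], σ = population std, MAE = E|e|, RMSE = √E[e²], so
RMSE² = μ² + σ² holds identically and MAE ≤ RMSE always; R² is reported
as missing for a zero-variance reference.

## Synthetic data

The generator exists because no recordings of the physical pedal are
public; it produces sessions from the forward model above with exact
ground truth, and is itself under test.

- **Cadence**: constant or slowly varying rpm profile, sampled once per
  revolution and held, making φ exactly piecewise linear.  Default 60 rpm,
  60 s, fs = 25 Hz, r = 0.17 m.
- **Ankle model**: θ = θ₀ + A·sin(φ + phase), default θ₀ = −10°, A = 20°
  — a smooth, crank-locked sweep spanning a typical ankle range; the
  true ankle trajectory of any individual rider is not modelled, only the
  admissible-range behaviour.
- **Loads**: one half-cosine bump per revolution, peaking at φ = 90° (the
  downstroke) with 180° width; default peaks Fx = 50 N, Fz = 300 N,
  Mx = 1 Nm, all inside the bench calibration ranges
  (Fx ∈ [−189.72, 243.81] N, Fz ∈ [−244.12, 555.28] N,
  Mx ∈ [−2.618, 3.329] Nm).
- **LC-tank surrogate**: frequencies = baseline + S·(Fx,Fz,Mx), exactly
  affine.  Only the sign structure of S is contractual: Fx moves coil 0
  opposite to coils 1–2, Mx moves coils 1 and 2 oppositely with coil 0
  fixed, Fz moves coils 0–2 equally; the fourth readout channel
  duplicates coil 0's pattern (redundant channel).  Magnitudes
  (≈250 kHz baselines, Hz-per-N sensitivities) are order-of-magnitude
  placeholders — the true electromagnetic response is deliberately out of
  scope, so calibration tests demonstrate *recovery of an affine map
  under the correct sign structure*, not absolute bench accuracy.
- **Noise**: additive white Gaussian, defaults σ_accel = 0.5 m/s²,
  σ_gyro = 0.02 rad/s, σ_freq = 2 Hz — consumer-MEMS-scale figures; the
  hardware's true noise spectra are unpublished.  The gyro stream is the
  central finite difference of the θ truth before noise injection, so
  dead-reckoning tests are self-consistent.
- **Two sides**: right crank = left + 180° exactly; optional per-side
  uniform timestamp jitter (≤ 5 ms used in tests) emulates
  unsynchronized logging.  Everything is driven by one integer seed via
  spawned generators; identical seeds give identical sessions.

What passing tests therefore show: the estimators invert this forward
model correctly at the stated noise levels and sampling rate.  What they
do not show: robustness to real riders' non-sinusoidal ankle motion,
within-revolution cadence fluctuation (pathological pedalling), sensor
bias/drift and scale error, nonlinear or thermally drifting LC-tank
response, or dropped samples — all of which the file-format layer can
represent but the generator does not produce.

## Analytics

Force magnitude is the in-plane √(Fx² + Fz²); the lateral component Fy is
not sensed.  Time binning defaults to 1 s windows, crank-angle binning to
36 bins (10°); bin statistics are mean and population std, with empty
bins flagged (NaN, count 0) rather than dropped silently.  The yaw
mapping (L−R)/(L+R), clipped to [−1, 1] and 0 at zero total force, is the
package's choice of a bounded, antisymmetric balance signal satisfying
the direction contract "harder left press steers left"; the speed signal
is a configurable gain times cadence.

## File formats and numerics

Sessions are flat CSV (time_s, side, ax..az, gx..gz, f0..f3; side L/R;
metadata in `# key = value` header comments) with 9 significant digits —
beyond sensor resolution, so write→read→write is byte-stable.  Empty
frequency fields mark IMU-only sessions.  Angles cross every user-facing
boundary in degrees, angular rates in rad/s; internal trigonometry is in
radians.  Calibration CSV quantization at 9 significant digits of a
~250 kHz carrier limits file-round-tripped calibration recovery to
~1e−5 N; in-memory recovery on noiseless data is exact to <1e−6.

## Known limitations

- Crank direction is assumed forward; a² is direction-blind and no
  direction detection is attempted.
- The crank-angle validity window excludes data before the first and
  after the last detected dead center.
- The KF uses fixed Q and R; a dynamic measurement variance (inflating R
  near φ ∈ {90°, 270°}, where the centripetal bias peaks) would track
  pedal-angle extrema better and is the natural next step, along with
  nonlinear filters (EKF/UKF).
- Cadence is reported at half-revolution resolution; at 25 Hz its
  per-interval quantization error grows quadratically with cadence.
- The acceptance script and test suite run everything at desk scale
  (60 s sessions, 20 seeds, 120–150 calibration records per channel),
  sizes chosen to make the statistics stable while keeping a full run in
  tens of seconds.
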