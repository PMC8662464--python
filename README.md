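# pedalkin

Analytics for sensor-instrumented ergometer pedals used in rehabilitation
training.  Each pedal carries a 6-axis IMU (accelerometer + gyroscope,
sampled at 25 Hz) and an inductive load sensor: four LC resonant circuits
whose resonance frequencies shift as applied loads displace a sprung
target.  From those two raw streams, `pedalkin` estimates the quantities a
therapist or athlete actually cares about — crank angle, cadence, pedal
(ankle) angle, and the applied forces and torque — and turns them into
post-session summaries and game-control signals for interactive training.

## What it computes

**Crank angle φ and cadence.**  With the crank angle measured from the
vertical (top dead center, TDC, at φ = 0°) and each revolution pedalled at
an approximately constant rate, the squared accelerometer magnitude is
frame-invariant and collapses to

```
a²(φ) = r²φ̇⁴ + 2 g r φ̇² cos φ + g²
```

(`r` crank-arm length, `g` gravity) — maximal at TDC, minimal at bottom
dead center (BDC, φ = 180°).  After zero-phase second-order Butterworth
low-pass filtering (cutoff 2.2 Hz), TDC/BDC events are detected as the
alternating extrema of a²(t), φ(t) is linearly interpolated between them,
and cadence follows from the half-revolution intervals (30/Δt rpm).
Because the two pedals share one crank, the left–right offset — nominally
180° — is a built-in consistency check, computed by interpolating one
side's angle onto the other's (unsynchronized) timestamps.

**Pedal angle θ.**  The accelerometer-only estimate
θ̂a = atan2(−ẍₓ, ẍ_z) is exact for a stationary crank but biased by the
centripetal term rφ̇² while pedalling.  A scalar Kalman filter fuses the
gyro-driven process model θ[k+1] = θ[k] + ω·Ts + ν, ν∼N(0,Q) with the
measurement y = θ̂a = θ + ρ, ρ∼N(0,R), using a circular innovation so
±180° wrap-arounds in θ̂a never corrupt the state.

**Load calibration.**  Each load channel (forward shear Fx, normal force
Fz, torque Mx) gets an L1-regularized affine map F̂ = w·f + b from the four
resonance frequencies, fitted on a seeded 70/30 train/test split with the
regularization strength chosen by 10-fold cross-validation over 25
log-spaced values in [1e−10, 1e2].  Every accuracy report carries the
error statistics μ, σ, MAE, RMSE and R² (population convention, so
RMSE² = μ² + σ²).

**Session analytics and gamification.**  Force magnitude √(Fx²+Fz²)
binned over 1 s windows or over 10° crank-angle bins, per-side breakdowns
for arbitrary session intervals, and a (speed, yaw) control pair: speed
proportional to cadence, yaw = (L−R)/(L+R) toward the harder-pressing
foot.

Because no public recordings of the pedal hardware exist, the package
ships a first-class simulator (`pedalkin.simulate`) that generates
sessions from this same forward model with known ground truth, including
an affine LC-tank surrogate obeying the coil-layout sign pattern.  All
estimators are validated against it.

## Worked example

```python
import numpy as np
from pedalkin import SensorNoiseModel, estimate_session, lr_offset, make_session

session, truth = make_session(duration=60.0, cadence_profile=60.0,
                              noise=SensorNoiseModel(seed=1), seed=1)
est = estimate_session(session)

mean, std = lr_offset(est["left"].crank, est["right"].crank)
print(f"LR offset: {mean:.1f} deg (std {std:.1f})")
print(f"median cadence: {np.nanmedian(est['left'].cadence_rpm):.1f} rpm")

th = truth["left"].theta_deg
pedal = est["left"].pedal
m = np.isfinite(pedal.theta_rough_deg)
print(f"rough RMSE: {np.sqrt(np.mean((pedal.theta_rough_deg[m]-th[m])**2)):.2f} deg")
print(f"KF RMSE:    {np.sqrt(np.mean((pedal.theta_deg[m]-th[m])**2)):.2f} deg")
```

prints

```
LR offset: 178.2 deg (std 7.3)
median cadence: 62.5 rpm
rough RMSE: 28.72 deg
KF RMSE:    2.10 deg
```

The left–right offset sits at the nominal 180° (the spread reflects
sample-quantized dead-center timing), the cadence estimate brackets the
true 60 rpm at the half-revolution resolution, and the Kalman fusion cuts
the pedal-angle error by an order of magnitude relative to the
accelerometer-only estimate, whose error is dominated by the centripetal
bias.

The same pipeline is available from the shell:

```
pedalkin simulate --out session.csv --truth truth.csv --seed 1
pedalkin validate session.csv
pedalkin estimate --session session.csv --out estimates.csv
pedalkin calibrate --records cal.csv --out model.json --report report.json
```

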