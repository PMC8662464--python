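"""Synthetic pedalling sessions with known ground truth.

The forward model mirrors the instrumented-pedal geometry: a crank arm of
length ``r`` rotating about a horizontal axle, with the crank angle φ
measured from the world vertical (top dead center, TDC, at φ = 0°) and
increasing in the forward-pedalling direction, and a pedal whose surface
angle θ relative to the world horizontal stays within [−90°, 90°].

Each crank revolution is carried out at a constant rate (φ̈ ≈ 0 within a
revolution); cadence may change between revolutions.  Under that
approximation the body-frame accelerometer reading is

    ẍ_x = −r φ̇² (sin φ cos θ + cos φ sin θ) − g sin θ
    ẍ_y = 0
    ẍ_z = −r φ̇² (sin φ sin θ − cos φ cos θ) + g cos θ

whose squared magnitude collapses to the frame-invariant

    ‖ẍ‖² = r² φ̇⁴ + 2 g r φ̇² cos φ + g²,

maximal at TDC and minimal at bottom dead center (BDC, φ = 180°).  The
gyroscope measures the pedal's angular rate ω = θ̇ on its y-axis.

The inductive load sensor is emulated by an affine surrogate: four LC-tank
resonance frequencies shift linearly with the in-plane loads (Fx, Fz, Mx)
following the coil-layout sign pattern — a forward shear Fx moves coil 0
opposite to coils 1 and 2, a torque Mx moves coils 1 and 2 oppositely and
leaves coil 0 untouched, and a normal force Fz moves coils 0–2 equally.
The fourth readout channel duplicates coil 0's pattern (redundant channel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import PedalkinError
from .io_session import Session, SessionMeta, SideStream

#: reference-sensor calibration ranges per load channel (N, N, Nm)
CALIBRATION_RANGES: dict[str, tuple[float, float]] = {
    "Fx": (-189.72, 243.81),
    "Fz": (-244.12, 555.28),
    "Mx": (-2.618, 3.329),
}

CadenceProfile = float | Callable[[float], float]


@dataclass
class TrajectoryTruth:
    """Ground-truth kinematics and loads on a common time grid.

    ``phi_deg`` is wrapped to [0, 360); ``phi_unwrapped_deg`` keeps the
    cumulative angle for oracle comparisons.  ``loads`` columns are
    (Fx [N], Fz [N], Mx [Nm]).
    """

    t: np.ndarray
    phi_deg: np.ndarray
    phidot_rad_s: np.ndarray
    phi_unwrapped_deg: np.ndarray
    theta_deg: np.ndarray | None = None
    loads: np.ndarray | None = None  # (n, 3)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("phi_deg", "phidot_rad_s", "phi_unwrapped_deg"):
            if len(getattr(self, name)) != n:
                raise PedalkinError(f"{name} length does not match time grid")


@dataclass(frozen=True)
class SensorNoiseModel:
    """Additive white Gaussian sensor noise, one stream at a time."""

    sigma_accel: float = 0.5   # m/s²
    sigma_gyro: float = 0.02   # rad/s
    sigma_freq: float = 2.0    # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_accel", "sigma_gyro", "sigma_freq"):
            if getattr(self, name) < 0:
                raise PedalkinError(f"{name} must be >= 0")


NOISELESS = SensorNoiseModel(sigma_accel=0.0, sigma_gyro=0.0, sigma_freq=0.0, seed=0)


def _default_sensitivity() -> np.ndarray:
    # columns: (Fx, Fz, Mx); rows: coils 0..3, coil 3 duplicating coil 0
    return np.array(
        [
            [+2.0, -3.0, 0.0],
            [-1.0, -3.0, +25.0],
            [-1.0, -3.0, -25.0],
            [+2.0, -3.0, 0.0],
        ]
    )


@dataclass
class LoadSensorSurrogate:
    """Affine load→frequency map standing in for the LC-tank physics."""

    baseline: np.ndarray = field(
        default_factory=lambda: np.array([250_000.0, 251_500.0, 249_000.0, 250_750.0])
    )
    sensitivity: np.ndarray = field(default_factory=_default_sensitivity)  # (4, 3) Hz/N, Hz/Nm

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, float)
        self.sensitivity = np.asarray(self.sensitivity, float)
        if self.baseline.shape != (4,) or self.sensitivity.shape != (4, 3):
            raise PedalkinError("surrogate needs a (4,) baseline and (4,3) sensitivity")
        self.validate_signs()

    def validate_signs(self) -> None:
        s = self.sensitivity
        fx, fz, mx = s[:, 0], s[:, 1], s[:, 2]
        if not (fx[0] * fx[1] < 0 and fx[0] * fx[2] < 0):
            raise PedalkinError("Fx column must move coil 0 opposite to coils 1 and 2")
        if not (np.isclose(fz[0], fz[1]) and np.isclose(fz[0], fz[2]) and fz[0] != 0):
            raise PedalkinError("Fz column must move coils 0-2 equally")
        if not (mx[0] == 0 and mx[1] * mx[2] < 0):
            raise PedalkinError("Mx column must leave coil 0 fixed and oppose coils 1/2")


# ------------------------------------------------------------- kinematics


def _cadence_fn(profile: CadenceProfile) -> Callable[[float], float]:
    if callable(profile):
        return profile
    value = float(profile)
    return lambda _t: value


def simulate_crank_trajectory(
    duration: float,
    cadence_profile: CadenceProfile,
    fs: float = 25.0,
    *,
    t: np.ndarray | None = None,
    phi0_deg: float = 0.0,
) -> TrajectoryTruth:
    """Crank angle and rate for revolution-wise constant cadence.

    ``cadence_profile`` is an rpm constant or a function of time (s); it is
    sampled once at the start of each revolution and held, so φ is exactly
    piecewise linear and φ̈ = 0 within every revolution.  ``t`` overrides the
    uniform ``fs`` grid (used for jittered-timestamp sessions).
    """
    if duration <= 0:
        raise PedalkinError("duration must be positive")
    rpm = _cadence_fn(cadence_profile)
    # build revolution segments: (t_start, phi_start_unwrapped, rate deg/s)
    seg_t = [0.0]
    seg_phi = [phi0_deg]
    seg_rate = []
    t_cur, phi_cur = 0.0, phi0_deg
    while t_cur < duration:
        r = float(rpm(t_cur))
        if r <= 0:
            raise PedalkinError(f"cadence must stay positive (got {r} rpm at t={t_cur:.3g}s)")
        rate = 6.0 * r  # deg/s
        seg_rate.append(rate)
        t_cur += 360.0 / rate
        phi_cur += 360.0
        seg_t.append(t_cur)
        seg_phi.append(phi_cur)
    if t is None:
        n = int(round(duration * fs))
        t = np.arange(n) / fs
    t = np.asarray(t, float)
    idx = np.clip(np.searchsorted(seg_t, t, side="right") - 1, 0, len(seg_rate) - 1)
    starts = np.asarray(seg_t)[idx]
    phis = np.asarray(seg_phi)[idx]
    rates = np.asarray(seg_rate)[idx]
    phi_unwrapped = phis + rates * (t - starts)
    return TrajectoryTruth(
        t=t,
        phi_deg=np.mod(phi_unwrapped, 360.0),
        phidot_rad_s=np.deg2rad(rates),
        phi_unwrapped_deg=phi_unwrapped,
    )


def simulate_pedal_angle(
    truth: TrajectoryTruth,
    theta0_deg: float = -10.0,
    amplitude_deg: float = 20.0,
    phase_deg: float = 0.0,
) -> TrajectoryTruth:
    """Fill θ(t) with the sinusoidal ankle model θ = θ₀ + A sin(φ + phase).

    The model is phase-locked to the crank; |θ₀| + |A| must not exceed 90°
    so the pedal angle stays in its admissible range.
    """
    if abs(theta0_deg) + abs(amplitude_deg) > 90.0:
        raise PedalkinError(
            f"|theta0|+|amplitude| = {abs(theta0_deg) + abs(amplitude_deg):.3g}° exceeds 90°"
        )
    theta = theta0_deg + amplitude_deg * np.sin(
        np.deg2rad(truth.phi_unwrapped_deg + phase_deg)
    )
    return replace(truth, theta_deg=theta)


def simulate_imu(
    truth: TrajectoryTruth,
    r: float = 0.17,
    g: float = 9.81,
    noise: SensorNoiseModel = NOISELESS,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Body-frame accelerometer and gyroscope streams for a trajectory.

    Returns ``(accel, gyro)``, each (n, 3).  The noiseless accelerometer is
    the exact forward model; the gyro y-component is the central finite
    difference of θ (keeping gyro and θ consistent for dead-reckoning
    tests), with zeros on the out-of-plane components.
    """
    if truth.theta_deg is None:
        raise PedalkinError("trajectory has no pedal angle; run simulate_pedal_angle first")
    phi = np.deg2rad(truth.phi_unwrapped_deg)
    theta = np.deg2rad(truth.theta_deg)
    c = r * truth.phidot_rad_s**2
    ax = -c * (np.sin(phi) * np.cos(theta) + np.cos(phi) * np.sin(theta)) - g * np.sin(theta)
    az = -c * (np.sin(phi) * np.sin(theta) - np.cos(phi) * np.cos(theta)) + g * np.cos(theta)
    accel = np.column_stack([ax, np.zeros_like(ax), az])
    if len(truth.t) > 1:
        omega = np.gradient(theta, truth.t)
    else:
        omega = np.zeros_like(theta)
    gyro = np.column_stack([np.zeros_like(omega), omega, np.zeros_like(omega)])
    if noise.sigma_accel > 0 or noise.sigma_gyro > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        accel = accel + rng.normal(0.0, noise.sigma_accel, accel.shape)
        gyro = gyro + rng.normal(0.0, noise.sigma_gyro, gyro.shape)
    return accel, gyro


def simulate_loads(
    truth: TrajectoryTruth,
    peak_Fx: float = 50.0,
    peak_Fz: float = 300.0,
    peak_Mx: float = 1.0,
    center_deg: float = 90.0,
    width_deg: float = 180.0,
) -> TrajectoryTruth:
    """Crank-phase-locked load profiles: one half-cosine bump per revolution.

    Each channel rises from zero to its peak at crank phase ``center_deg``
    (default 90°, the downstroke) over a bump of angular ``width_deg``.
    Peaks must stay inside the reference calibration ranges.
    """
    for name, peak in (("Fx", peak_Fx), ("Fz", peak_Fz), ("Mx", peak_Mx)):
        lo, hi = CALIBRATION_RANGES[name]
        if not (lo <= peak <= hi):
            raise PedalkinError(f"peak {name}={peak} outside calibration range [{lo}, {hi}]")
    delta = np.mod(truth.phi_deg - center_deg + 180.0, 360.0) - 180.0
    bump = np.where(
        np.abs(delta) <= width_deg / 2.0,
        np.cos(np.pi * delta / width_deg),
        0.0,
    )
    loads = np.column_stack([peak_Fx * bump, peak_Fz * bump, peak_Mx * bump])
    return replace(truth, loads=loads)


def loads_to_frequencies(
    loads: np.ndarray,
    surrogate: LoadSensorSurrogate | None = None,
    noise: SensorNoiseModel = NOISELESS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map (n, 3) loads to (n, 4) resonance frequencies (exactly affine)."""
    if surrogate is None:
        surrogate = LoadSensorSurrogate()
    loads = np.atleast_2d(np.asarray(loads, float))
    freqs = surrogate.baseline + loads @ surrogate.sensitivity.T
    if noise.sigma_freq > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        freqs = freqs + rng.normal(0.0, noise.sigma_freq, freqs.shape)
    return freqs


# ---------------------------------------------------------------- sessions


def make_session(
    duration: float = 60.0,
    cadence_profile: CadenceProfile = 60.0,
    fs: float = 25.0,
    r: float = 0.17,
    g: float = 9.81,
    *,
    theta0_deg: float = -10.0,
    amplitude_deg: float = 20.0,
    phase_deg: float = 0.0,
    peak_Fx: float = 50.0,
    peak_Fz: float = 300.0,
    peak_Mx: float = 1.0,
    surrogate: LoadSensorSurrogate | None = None,
    noise: SensorNoiseModel | None = None,
    timestamp_jitter_s: float = 0.0,
    seed: int = 0,
    with_loads: bool = True,
) -> tuple[Session, dict[str, TrajectoryTruth]]:
    """A full two-sided session plus its per-side ground truth.

    The right crank leads the left by exactly 180° (the two pedals share
    one crank).  Per-side timestamps are optionally jittered uniformly in
    ``±timestamp_jitter_s`` to emulate unsynchronized logging; the same
    seed always yields the identical session.
    """
    if timestamp_jitter_s < 0 or timestamp_jitter_s >= 0.5 / fs:
        raise PedalkinError("timestamp jitter must lie in [0, 1/(2 fs))")
    if noise is None:
        noise = SensorNoiseModel(seed=seed)
    master = np.random.SeedSequence(seed)
    side_seqs = master.spawn(2)
    n = int(round(duration * fs))
    base_t = np.arange(n) / fs
    sides: dict[str, SideStream] = {}
    truths: dict[str, TrajectoryTruth] = {}
    for side, phi0, seq in (("left", 0.0, side_seqs[0]), ("right", 180.0, side_seqs[1])):
        rng = np.random.default_rng(seq)
        t = base_t
        if timestamp_jitter_s > 0:
            t = base_t + rng.uniform(-timestamp_jitter_s, timestamp_jitter_s, n)
        truth = simulate_crank_trajectory(duration, cadence_profile, fs, t=t, phi0_deg=phi0)
        truth = simulate_pedal_angle(truth, theta0_deg, amplitude_deg, phase_deg)
        if with_loads:
            truth = simulate_loads(truth, peak_Fx, peak_Fz, peak_Mx)
        accel, gyro = simulate_imu(truth, r=r, g=g, noise=noise, rng=rng)
        freqs = None
        if with_loads:
            freqs = loads_to_frequencies(truth.loads, surrogate, noise=noise, rng=rng)
        sides[side] = SideStream(t=t, accel=accel, gyro=gyro, freqs=freqs)
        truths[side] = truth
    session = Session(sides=sides, meta=SessionMeta(fs=fs, r=r, g=g))
    session.validate()
    return session, truths


def simulate_calibration_records(
    surrogate: LoadSensorSurrogate | None = None,
    n_per_channel: int = 200,
    cycles: int = 8,
    noise: SensorNoiseModel = NOISELESS,
    seed: int = 0,
):
    """Bench-style calibration data: cyclic load ramps per channel.

    Each channel is loaded ``cycles`` times across its calibration range
    (triangular ramps, emulating an operator loading/unloading the rig)
    while the other channels stay at zero; frequencies come from the
    surrogate with optional readout noise.  Returns a list of
    :class:`pedalkin.io_session.CalibrationRecord`.
    """
    from .io_session import CalibrationRecord

    if surrogate is None:
        surrogate = LoadSensorSurrogate()
    rng = np.random.default_rng(seed)
    records: list[CalibrationRecord] = []
    channels = ("Fx", "Fz", "Mx")
    for ci, channel in enumerate(channels):
        lo, hi = CALIBRATION_RANGES[channel]
        phase = np.linspace(0.0, cycles, n_per_channel, endpoint=False)
        tri = 2.0 * np.abs(phase - np.floor(phase + 0.5))  # triangle in [0, 1]
        load = lo + (hi - lo) * tri
        loads3 = np.zeros((n_per_channel, 3))
        loads3[:, ci] = load
        freqs = loads_to_frequencies(loads3, surrogate, noise=noise, rng=rng)
        for k in range(n_per_channel):
            records.append(CalibrationRecord(freqs=freqs[k], load=float(load[k]), channel=channel))
    return records
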