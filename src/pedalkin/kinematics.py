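"""Crank-angle, cadence and pedal-angle estimation from IMU streams.

Crank angle.  For revolutions at approximately constant rate the squared
acceleration magnitude a² = r²φ̇⁴ + 2grφ̇²cos φ + g² peaks at top dead
center (TDC, φ = 0°) and bottoms at bottom dead center (BDC, φ = 180°),
so TDC/BDC events are found as the alternating maxima/minima of the
filtered a²(t) signal and φ(t) is linearly interpolated between them.
Forward pedalling is assumed: φ runs 0→180° from a TDC to the next BDC
and 180→360° back (a² is blind to direction).

Cadence.  Each half-revolution between adjacent extrema spans 180°, so
the per-interval cadence is 30/Δt rpm, piecewise constant.

Left–right offset.  The two pedals share one crank, so their crank angles
should differ by 180°.  Because the sides log on unsynchronized clocks,
the other side's angle is linearly interpolated across the bracketing
timestamps before the circular difference is taken.

Pedal angle.  The accelerometer-only rough estimate θ̂a = atan2(−ẍ_x, ẍ_z)
is exact only for a stationary crank; while pedalling, the centripetal
term rφ̇² biases it (the measurement uncertainty ρ).  A scalar Kalman
filter fuses the gyro-driven process model θ[k+1] = θ[k] + ω·Ts + ν,
ν ~ N(0, Q), with the measurement y = θ̂a = θ + ρ, ρ ~ N(0, R), trading
gyro drift against accelerometer bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import PedalkinError
from .io_session import Session
from .preprocess import FilterSpec, lowpass_session

TDC = "TDC"
BDC = "BDC"


@dataclass
class CrankTrace:
    """Estimated crank angle with detected dead-center events.

    ``phi_deg`` is valid only between the first and last detected
    extremum (the ``valid`` mask); ``phi_unwrapped_deg`` accumulates
    half-revolutions for interpolation across the wrap.
    """

    t: np.ndarray
    phi_deg: np.ndarray
    valid: np.ndarray
    extrema: list[tuple[int, str]]
    phi_unwrapped_deg: np.ndarray

    @property
    def revolutions(self) -> int:
        n_tdc = sum(1 for _, kind in self.extrema if kind == TDC)
        return max(n_tdc - 1, 0)


@dataclass
class PedalAngleTrace:
    t: np.ndarray
    theta_rough_deg: np.ndarray  # accelerometer-only θ̂a
    theta_deg: np.ndarray        # KF-fused θ̂
    variance_deg2: np.ndarray    # posterior P


@dataclass(frozen=True)
class KFParams:
    """Scalar Kalman-filter tuning (all angle quantities in degrees)."""

    Q: float            # process-noise variance, deg²
    R: float = 100.0    # measurement-noise variance, deg²
    Ts: float = 0.04    # s
    theta0: float | None = None  # None -> first valid measurement
    P0: float | None = None      # None -> R

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.R <= 0 or self.Ts <= 0:
            raise PedalkinError("Q, R and Ts must be positive")
        if self.P0 is not None and self.P0 <= 0:
            raise PedalkinError("P0 must be positive")

    @classmethod
    def from_noise(
        cls,
        sigma_gyro: float = 0.02,
        fs: float = 25.0,
        q_scale: float = 1.0,
        R: float = 100.0,
    ) -> "KFParams":
        """Q from the gyro noise propagated through one integration step."""
        Ts = 1.0 / fs
        q = (np.rad2deg(sigma_gyro) * Ts) ** 2 * q_scale
        return cls(Q=q, R=R, Ts=Ts)


# ------------------------------------------------------------ crank angle


def accel_sq_magnitude(accel: np.ndarray) -> np.ndarray:
    """Per-sample squared Euclidean norm of the (n, 3) acceleration.

    Frame-invariant: rotations leave it unchanged, so body-frame readings
    can be compared against the world-frame closed form directly.
    """
    accel = np.asarray(accel, float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise PedalkinError("accel must be (n, 3)")
    return np.einsum("ij,ij->i", accel, accel)


def detect_extrema(
    a2: np.ndarray,
    fs: float,
    cadence_max_rpm: float = 150.0,
    prominence_factor: float = 0.5,
) -> list[tuple[int, str]]:
    """Alternating TDC (maxima) / BDC (minima) events in the filtered a².

    Minimum peak separation comes from the fastest plausible cadence
    (default 150 rpm → 0.2 s between dead centers); the prominence floor
    is ``prominence_factor`` times the median peak-to-trough amplitude,
    estimated from an unconstrained first pass.  When two same-kind
    extrema end up adjacent, the more prominent one is kept.  An empty
    list (with a warning) means no rotation was detected.
    """
    a2 = np.asarray(a2, float)
    n = len(a2)
    min_dist = max(1, int(round(fs * 60.0 / (2.0 * cadence_max_rpm))))
    # odd-reflection extension so boundary extrema get full-height prominences
    ext = n - 1
    if ext > 0:
        left = 2.0 * a2[0] - a2[1 : ext + 1][::-1]
        right = 2.0 * a2[-1] - a2[-ext - 1 : -1][::-1]
        padded = np.concatenate([left, a2, right])
    else:
        padded = a2

    def _peaks(x, prominence=None):
        idx, props = signal.find_peaks(x, distance=min_dist, prominence=prominence)
        keep = (idx >= ext) & (idx < ext + n)
        prom = props.get("prominences")
        return idx[keep] - ext, None if prom is None else prom[keep]

    peaks0, _ = _peaks(padded)
    troughs0, _ = _peaks(-padded)
    if len(peaks0) == 0 or len(troughs0) == 0:
        warnings.warn("no a² extrema found; stationary session?", stacklevel=2)
        return []
    amplitude = float(np.median(a2[peaks0]) - np.median(a2[troughs0]))
    if amplitude <= 0:
        warnings.warn("degenerate a² signal (zero peak-to-trough amplitude)", stacklevel=2)
        return []
    prom = prominence_factor * amplitude
    peaks, pproms = _peaks(padded, prominence=prom)
    troughs, tproms = _peaks(-padded, prominence=prom)
    events = [(int(i), TDC, p) for i, p in zip(peaks, pproms)]
    events += [(int(i), BDC, p) for i, p in zip(troughs, tproms)]
    events.sort(key=lambda e: e[0])
    # enforce strict alternation, keeping the more prominent of clashes
    kept: list[tuple[int, str, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    return [(i, kind) for i, kind, _ in kept]


def interpolate_crank_angle(extrema: list[tuple[int, str]], t: np.ndarray) -> CrankTrace:
    """φ(t) linear in time between successive dead centers.

    TDC samples map to 0° (mod 360), BDC to 180°; each successive
    extremum advances the unwrapped angle by 180°.  Samples outside the
    first/last extremum are marked invalid.
    """
    t = np.asarray(t, float)
    n = len(t)
    if len(extrema) < 2:
        raise PedalkinError("need at least two alternating extrema to interpolate φ")
    kinds = [kind for _, kind in extrema]
    for a, b in zip(kinds, kinds[1:]):
        if a == b:
            raise PedalkinError("extrema must strictly alternate TDC/BDC")
    idx = np.array([i for i, _ in extrema])
    phi_start = 0.0 if kinds[0] == TDC else 180.0
    phi_ext = phi_start + 180.0 * np.arange(len(extrema))
    phi_unwrapped = np.interp(t, t[idx], phi_ext)
    valid = (t >= t[idx[0]]) & (t <= t[idx[-1]])
    phi_unwrapped = np.where(valid, phi_unwrapped, np.nan)
    return CrankTrace(
        t=t,
        phi_deg=np.mod(phi_unwrapped, 360.0),
        valid=valid,
        extrema=list(extrema),
        phi_unwrapped_deg=phi_unwrapped,
    )


def cadence_from_crank(trace: CrankTrace) -> np.ndarray:
    """Piecewise-constant cadence (rpm) from half-revolution intervals.

    Adjacent extrema are 180° apart, so the interval cadence is 30/Δt
    rpm; NaN outside the valid region.
    """
    if len(trace.extrema) < 2:
        raise PedalkinError("need at least two extrema for cadence")
    idx = np.array([i for i, _ in trace.extrema])
    t_ext = trace.t[idx]
    rpm_int = 30.0 / np.diff(t_ext)  # half a revolution per interval
    out = np.full(len(trace.t), np.nan)
    seg = np.searchsorted(t_ext, trace.t, side="right") - 1
    inside = (seg >= 0) & (seg < len(rpm_int))
    out[inside] = rpm_int[np.clip(seg[inside], 0, len(rpm_int) - 1)]
    out[trace.t == t_ext[-1]] = rpm_int[-1]
    out[~trace.valid] = np.nan
    return out


def lr_offset(left: CrankTrace, right: CrankTrace) -> tuple[float, float]:
    """Circular mean and std (deg) of the left→right crank-angle offset.

    For every valid left sample inside the right side's valid range, the
    right crank angle is linearly interpolated across the bracketing
    right timestamps; the circular difference right − left is then
    averaged on the unit circle.
    """
    lv = left.valid
    rv = right.valid
    if not lv.any() or not rv.any():
        raise PedalkinError("both traces need a valid region")
    rt = right.t[rv]
    rphi = right.phi_unwrapped_deg[rv]
    mask = lv & (left.t >= rt[0]) & (left.t <= rt[-1])
    if not mask.any():
        raise PedalkinError("no temporal overlap between valid regions")
    r_interp = np.interp(left.t[mask], rt, rphi)
    diff = np.deg2rad(r_interp - left.phi_unwrapped_deg[mask])
    z = np.mean(np.exp(1j * diff))
    mean_deg = float(np.mod(np.rad2deg(np.angle(z)), 360.0))
    r_len = min(float(np.abs(z)), 1.0)
    std_deg = float(np.rad2deg(np.sqrt(max(-2.0 * np.log(r_len), 0.0)))) if r_len > 0 else float("inf")
    return mean_deg, std_deg


# ------------------------------------------------------------ pedal angle


def rough_pedal_angle(accel: np.ndarray) -> np.ndarray:
    """Accelerometer-only pedal angle θ̂a (deg, (−180, 180]).

    Sign convention: the x-argument of the two-argument arctangent is
    negated so that a stationary pedal at angle θ returns +θ (the raw
    gravity components give −θ otherwise).  Near-zero-magnitude samples
    return NaN (angle undefined).
    """
    accel = np.asarray(accel, float)
    ax, az = accel[:, 0], accel[:, 2]
    mag = np.hypot(ax, az)
    theta = np.degrees(np.arctan2(-ax, az))
    theta = np.where(mag > 1e-12, theta, np.nan)
    # atan2 returns (−180, 180] up to the -180 == 180 seam; normalize
    theta = np.where(theta <= -180.0, 180.0, theta)
    return theta


def _wrap_deg(x):
    return (x + 180.0) % 360.0 - 180.0


def kalman_pedal_angle(
    theta_rough_deg: np.ndarray,
    omega_rad_s: np.ndarray,
    params: KFParams,
    t: np.ndarray | None = None,
) -> PedalAngleTrace:
    """Fuse θ̂a with the gyro rate ω through the scalar predict–update KF.

    Predict: θ⁻ = θ + ω·Ts (deg), P⁻ = P + Q.  Update with y = θ̂a and
    variance R; NaN measurements skip the update (pure dead reckoning for
    that step).  The innovation y − θ⁻ is wrapped to (−180°, 180°] so the
    θ̂a seam never produces spurious full-turn corrections — in the
    fast-crank regime (rφ̇² > g) θ̂a sweeps through whole revolutions and
    an unwrapped measurement would drag the state along a secular ramp.
    The fused output is reported in (−180, 180].
    """
    theta_rough_deg = np.asarray(theta_rough_deg, float)
    omega_rad_s = np.asarray(omega_rad_s, float)
    if theta_rough_deg.shape != omega_rad_s.shape:
        raise PedalkinError("theta_rough and omega must have equal length")
    n = len(theta_rough_deg)
    if n == 0:
        raise PedalkinError("empty input series")
    y = theta_rough_deg
    finite = np.isfinite(y)
    if params.theta0 is not None:
        theta = float(params.theta0)
    elif finite.any():
        theta = float(y[np.argmax(finite)])
    else:
        theta = 0.0
    P = float(params.P0) if params.P0 is not None else float(params.R)
    omega_deg = np.rad2deg(omega_rad_s)
    thetas = np.empty(n)
    variances = np.empty(n)
    for k in range(n):
        theta = theta + omega_deg[k] * params.Ts
        P = P + params.Q
        if finite[k]:
            K = P / (P + params.R)
            theta = theta + K * _wrap_deg(y[k] - theta)
            P = (1.0 - K) * P
        thetas[k] = theta
        variances[k] = P
    wrapped = np.mod(thetas + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if t is None:
        t = np.arange(n) * params.Ts
    return PedalAngleTrace(
        t=np.asarray(t, float),
        theta_rough_deg=theta_rough_deg,
        theta_deg=wrapped,
        variance_deg2=variances,
    )


# --------------------------------------------------------------- pipeline


@dataclass
class SideEstimate:
    """All per-side estimator outputs for one session."""

    crank: CrankTrace
    cadence_rpm: np.ndarray
    pedal: PedalAngleTrace
    loads: np.ndarray | None = None  # (n, 3) filled in when a calibration model is applied


def estimate_session(
    session: Session,
    filter_spec: FilterSpec | None = None,
    kf_params: KFParams | None = None,
    cadence_max_rpm: float = 150.0,
    prominence_factor: float = 0.5,
) -> dict[str, SideEstimate]:
    """Run the full kinematics chain (filter → crank → cadence → KF) per side."""
    if filter_spec is None:
        filter_spec = FilterSpec(fs=session.meta.fs)
    if kf_params is None:
        kf_params = KFParams.from_noise(fs=session.meta.fs)
    filtered = lowpass_session(session, filter_spec)
    out: dict[str, SideEstimate] = {}
    for side, st in filtered.sides.items():
        a2 = accel_sq_magnitude(st.accel)
        extrema = detect_extrema(
            a2, session.meta.fs, cadence_max_rpm=cadence_max_rpm,
            prominence_factor=prominence_factor,
        )
        crank = interpolate_crank_angle(extrema, st.t)
        cadence = cadence_from_crank(crank)
        theta_a = rough_pedal_angle(st.accel)
        pedal = kalman_pedal_angle(theta_a, st.gyro[:, 1], kf_params, t=st.t)
        out[side] = SideEstimate(crank=crank, cadence_rpm=cadence, pedal=pedal)
    return out
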