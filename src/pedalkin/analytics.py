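"""Post-session summaries and game-control signals.

Force "magnitude" is the in-plane √(Fx² + Fz²) — the lateral shear Fy is
not sensed by the pedal.  Session views bin that magnitude over time
(1 s bins) or over crank angle (10° bins by default), and per-side
breakdowns summarize cadence, forces and pedal angle for arbitrary
sub-intervals of the session.

For gamified feedback, cadence maps monotonically to a speed signal and
the left/right force balance to a yaw in [−1, 1]; positive yaw steers
toward the side pressing harder (left, by the sign convention here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PedalkinError
from .kinematics import CrankTrace


@dataclass
class BinnedSeries:
    """Per-bin mean, population std and count; NaN stats for empty bins."""

    edges: np.ndarray   # (k+1,)
    mean: np.ndarray    # (k,)
    std: np.ndarray     # (k,)
    count: np.ndarray   # (k,) int


@dataclass(frozen=True)
class GameControl:
    speed: float  # unitless, >= 0, monotone in cadence
    yaw: float    # in [-1, 1]; positive = toward the left pedal


@dataclass
class SummaryStats:
    mean: float
    std: float
    min: float
    max: float
    count: int


def _bin_stats(values: np.ndarray, which: np.ndarray, k: int) -> BinnedSeries:
    mean = np.full(k, np.nan)
    std = np.full(k, np.nan)
    count = np.zeros(k, dtype=int)
    for b in range(k):
        v = values[which == b]
        count[b] = len(v)
        if len(v):
            mean[b] = np.mean(v)
            std[b] = np.std(v)
    return BinnedSeries(edges=np.empty(0), mean=mean, std=std, count=count)


def force_magnitude(Fx: np.ndarray, Fz: np.ndarray) -> np.ndarray:
    """In-plane force magnitude √(Fx² + Fz²)."""
    return np.hypot(np.asarray(Fx, float), np.asarray(Fz, float))


def binned_force_magnitude(
    Fx: np.ndarray, Fz: np.ndarray, t: np.ndarray, bin_width: float = 1.0
) -> BinnedSeries:
    """Mean ± std of the force magnitude over fixed-width time bins."""
    if bin_width <= 0:
        raise PedalkinError("bin width must be positive")
    t = np.asarray(t, float)
    mag = force_magnitude(Fx, Fz)
    if len(t) != len(mag):
        raise PedalkinError("loads and t must be aligned")
    t0 = np.floor(t.min() / bin_width) * bin_width
    k = int(np.ceil((t.max() - t0) / bin_width)) or 1
    edges = t0 + bin_width * np.arange(k + 1)
    which = np.clip(((t - t0) / bin_width).astype(int), 0, k - 1)
    out = _bin_stats(mag, which, k)
    out.edges = edges
    return out


def force_by_crank_angle(
    Fx: np.ndarray, Fz: np.ndarray, trace: CrankTrace, n_bins: int = 36
) -> BinnedSeries:
    """Mean ± std of the force magnitude per crank-angle bin over [0°, 360°).

    Samples where the crank angle is invalid (outside the detected
    dead-center span) are excluded.
    """
    if n_bins < 1:
        raise PedalkinError("n_bins must be >= 1")
    mag = force_magnitude(Fx, Fz)
    if len(mag) != len(trace.t):
        raise PedalkinError("loads must align with the crank trace")
    mask = trace.valid & np.isfinite(mag)
    if not mask.any():
        raise PedalkinError("no valid crank-angle overlap with the load series")
    width = 360.0 / n_bins
    which = np.clip((trace.phi_deg[mask] / width).astype(int), 0, n_bins - 1)
    out = _bin_stats(mag[mask], which, n_bins)
    out.edges = width * np.arange(n_bins + 1)
    return out


def per_side_breakdown(
    metrics: dict[str, dict[str, np.ndarray]],
    times: dict[str, np.ndarray],
    interval: tuple[float, float] | None = None,
) -> dict[str, dict[str, SummaryStats]]:
    """Per-side summaries of arbitrary metric series, whole session or a slice.

    ``metrics[side][name]`` are sample-aligned series (cadence, normal
    force, shear force, pedal angle, ...); ``times[side]`` their common
    timestamps.  ``interval=(t0, t1)`` restricts to t0 ≤ t ≤ t1; an empty
    interval yields count-0 summaries with NaN stats rather than an error.
    """
    out: dict[str, dict[str, SummaryStats]] = {}
    for side, series in metrics.items():
        t = np.asarray(times[side], float)
        sel = np.ones(len(t), dtype=bool)
        if interval is not None:
            t0, t1 = interval
            sel = (t >= t0) & (t <= t1)
        out[side] = {}
        for name, values in series.items():
            v = np.asarray(values, float)[sel]
            v = v[np.isfinite(v)]
            if len(v) == 0:
                out[side][name] = SummaryStats(np.nan, np.nan, np.nan, np.nan, 0)
            else:
                out[side][name] = SummaryStats(
                    mean=float(np.mean(v)),
                    std=float(np.std(v)),
                    min=float(np.min(v)),
                    max=float(np.max(v)),
                    count=int(len(v)),
                )
    return out


def game_controls(
    cadence_rpm: float,
    left_force: float,
    right_force: float,
    speed_gain: float = 1.0,
) -> GameControl:
    """Map cadence and the left/right force balance to game signals.

    speed = gain·cadence; yaw = (L − R)/(L + R) clipped to [−1, 1] and 0
    when no force is applied.  Forces are magnitudes, hence must be ≥ 0.
    """
    if cadence_rpm < 0:
        raise PedalkinError("cadence must be >= 0")
    if left_force < 0 or right_force < 0:
        raise PedalkinError("pedal force magnitudes must be >= 0")
    total = left_force + right_force
    yaw = 0.0 if total == 0 else float(np.clip((left_force - right_force) / total, -1.0, 1.0))
    return GameControl(speed=float(speed_gain * cadence_rpm), yaw=yaw)
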