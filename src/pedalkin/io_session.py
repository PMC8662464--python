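"""Session and calibration file I/O.

A *session* is the universal input of the package: per-pedal (left/right)
time series of 3-axis acceleration, 3-axis angular rate and, when the
inductive load sensor is active, the four LC-tank resonance frequencies.
Sessions are stored as a single flat CSV table

    time_s, side, ax, ay, az, gx, gy, gz, f0, f1, f2, f3

with ``side`` in {L, R}, frequencies left empty for IMU-only recordings,
and session metadata (sampling rate ``fs``, crank-arm length ``r``,
gravitational acceleration ``g``) carried in ``# key = value`` header
comments.  Numeric fields are written with 9 significant digits, which
exceeds the sensors' resolution and makes write→read→write byte-stable.

Angular rates are stored in rad/s; angles everywhere at user-facing
boundaries are degrees.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .errors import SessionFormatError, SessionValidationError

SIDE_LABELS = ("left", "right")
_SIDE_TO_CSV = {"left": "L", "right": "R"}
_CSV_TO_SIDE = {"L": "left", "R": "right"}

IMU_COLUMNS = ["time_s", "side", "ax", "ay", "az", "gx", "gy", "gz"]
FREQ_COLUMNS = ["f0", "f1", "f2", "f3"]
SESSION_COLUMNS = IMU_COLUMNS + FREQ_COLUMNS

#: significant digits used for every numeric field on disk
FILE_PRECISION = 9


@dataclass(frozen=True)
class SensorSample:
    """One timestamped reading from one pedal.

    ``freqs`` is ``None`` for IMU-only sessions.  The gyroscope measures the
    pedal's angular rate, so the y-component of ``gyro`` is the pedal-angle
    rate θ̇ in rad/s.
    """

    t: float
    side: str
    accel: np.ndarray  # (3,) m/s², pedal body frame
    gyro: np.ndarray   # (3,) rad/s, pedal body frame
    freqs: np.ndarray | None = None  # (4,) Hz


@dataclass
class SessionMeta:
    """Session-level constants: sampling rate, crank-arm length, gravity."""

    fs: float = 25.0   # Hz
    r: float = 0.17    # m, crank-axle to pedal-axle distance
    g: float = 9.81    # m/s²

    def validate(self) -> None:
        if not (self.fs > 0):
            raise SessionValidationError(f"fs must be positive, got {self.fs}")
        if not (self.r > 0):
            raise SessionValidationError(f"r must be positive, got {self.r}")
        if not (self.g > 0):
            raise SessionValidationError(f"g must be positive, got {self.g}")


@dataclass
class SideStream:
    """All samples of one side as contiguous arrays (t sorted, ascending)."""

    t: np.ndarray                 # (n,) s
    accel: np.ndarray             # (n, 3) m/s²
    gyro: np.ndarray              # (n, 3) rad/s
    freqs: np.ndarray | None = None  # (n, 4) Hz or None

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Session:
    """A full recording: one :class:`SideStream` per side plus metadata.

    The two sides are *not* assumed time-synchronized; cross-side
    comparisons interpolate over timestamps.
    """

    sides: dict[str, SideStream] = field(default_factory=dict)
    meta: SessionMeta = field(default_factory=SessionMeta)

    def samples(self, side: str) -> Iterator[SensorSample]:
        st = self.sides[side]
        for i in range(len(st)):
            yield SensorSample(
                t=float(st.t[i]),
                side=side,
                accel=st.accel[i],
                gyro=st.gyro[i],
                freqs=None if st.freqs is None else st.freqs[i],
            )

    def validate(self) -> None:
        self.meta.validate()
        for side, st in self.sides.items():
            if side not in SIDE_LABELS:
                raise SessionValidationError(f"unknown side label {side!r}")
            dt = np.diff(st.t)
            if np.any(dt < 0):
                i = int(np.argmax(dt < 0)) + 1
                raise SessionValidationError(
                    f"{side}: timestamps not sorted, first offending row {i} "
                    f"(t={st.t[i]:.6g} after t={st.t[i - 1]:.6g})"
                )
            if not np.all(np.isfinite(st.t)):
                raise SessionValidationError(f"{side}: non-finite timestamp")
            if st.freqs is not None:
                finite = np.isfinite(st.freqs)
                if np.any(st.freqs[finite] <= 0):
                    raise SessionValidationError(
                        f"{side}: resonance frequencies must be strictly positive"
                    )


@dataclass(frozen=True)
class CalibrationRecord:
    """One calibration pair: a frequency quadruple and its reference load."""

    freqs: np.ndarray  # (4,) Hz
    load: float        # N for Fx/Fz, Nm for Mx
    channel: str       # 'Fx' | 'Fz' | 'Mx'


# ------------------------------------------------------------------ formats


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return f"{x:.{FILE_PRECISION}g}"


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to the flat-CSV dialect (re-readable, byte-stable)."""
    session.validate()
    lines = [
        "# pedalkin session v1",
        f"# fs = {_fmt(session.meta.fs)}",
        f"# r = {_fmt(session.meta.r)}",
        f"# g = {_fmt(session.meta.g)}",
        ",".join(SESSION_COLUMNS),
    ]
    for side in SIDE_LABELS:
        if side not in session.sides:
            continue
        st = session.sides[side]
        tag = _SIDE_TO_CSV[side]
        freqs = st.freqs
        for i in range(len(st)):
            row = [_fmt(float(st.t[i])), tag]
            row += [_fmt(float(v)) for v in st.accel[i]]
            row += [_fmt(float(v)) for v in st.gyro[i]]
            if freqs is None:
                row += ["", "", "", ""]
            else:
                row += [_fmt(float(v)) for v in freqs[i]]
            lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_session(path: str | Path) -> Session:
    """Read a session CSV written by :func:`write_session`.

    Raises :class:`SessionFormatError` when a required column is missing and
    :class:`SessionValidationError` when per-side timestamps are unsorted.
    """
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"no such session file: {path}")
    meta = SessionMeta()
    header_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            header_lines.append(line)
        else:
            break
    for line in header_lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            key = key.strip()
            if key in ("fs", "r", "g"):
                setattr(meta, key, float(val))
    df = pd.read_csv(path, comment="#")
    for col in IMU_COLUMNS:
        if col not in df.columns:
            raise SessionFormatError(f"session file missing required column {col!r}")
    have_freqs = all(c in df.columns for c in FREQ_COLUMNS)
    sides: dict[str, SideStream] = {}
    for tag, sub in df.groupby("side", sort=True):
        if tag not in _CSV_TO_SIDE:
            raise SessionFormatError(f"unknown side label {tag!r} (expected L or R)")
        side = _CSV_TO_SIDE[tag]
        t = sub["time_s"].to_numpy(float)
        accel = sub[["ax", "ay", "az"]].to_numpy(float)
        gyro = sub[["gx", "gy", "gz"]].to_numpy(float)
        freqs = None
        if have_freqs:
            f = sub[FREQ_COLUMNS].to_numpy(float)
            if np.any(np.isfinite(f)):
                freqs = f
        sides[side] = SideStream(t=t, accel=accel, gyro=gyro, freqs=freqs)
    session = Session(sides=sides, meta=meta)
    session.validate()
    return session


def write_calibration_records(records: list[CalibrationRecord], path: str | Path) -> None:
    lines = [",".join(FREQ_COLUMNS + ["load", "channel"])]
    for r in records:
        lines.append(
            ",".join([_fmt(float(v)) for v in r.freqs] + [_fmt(float(r.load)), r.channel])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration_records(path: str | Path) -> list[CalibrationRecord]:
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"no such calibration file: {path}")
    df = pd.read_csv(path)
    for col in FREQ_COLUMNS + ["load", "channel"]:
        if col not in df.columns:
            raise SessionFormatError(f"calibration file missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CalibrationRecord(
                freqs=row[FREQ_COLUMNS].to_numpy(float),
                load=float(row["load"]),
                channel=str(row["channel"]),
            )
        )
    return out


# --------------------------------------------------------------- validation


@dataclass
class ValidationReport:
    """Report-only session diagnostics; never mutates the session."""

    per_side: dict[str, dict[str, float]]
    flags: list[str]

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_session(session: Session, interval_tol: float = 0.10) -> ValidationReport:
    """Sampling-interval statistics, NaN counts and per-side durations.

    A flag is raised when a side's mean sampling interval deviates more than
    ``interval_tol`` (fractionally) from the nominal ``1/fs``, when the
    maximum gap exceeds twice the nominal interval, or when NaNs are present.
    """
    nominal = 1.0 / session.meta.fs
    per_side: dict[str, dict[str, float]] = {}
    flags: list[str] = []
    for side, st in session.sides.items():
        dt = np.diff(st.t)
        mean_dt = float(np.mean(dt)) if len(dt) else float("nan")
        max_gap = float(np.max(dt)) if len(dt) else float("nan")
        # freq NaNs are legitimate "channel absent" markers, so only IMU
        # streams count toward the NaN diagnostic
        nan_count = int(np.sum(~np.isfinite(st.accel)) + np.sum(~np.isfinite(st.gyro)))
        stats = {
            "n_samples": float(len(st)),
            "duration_s": float(st.t[-1] - st.t[0]) if len(st) else 0.0,
            "mean_interval_s": mean_dt,
            "max_gap_s": max_gap,
            "nan_count": float(nan_count),
        }
        per_side[side] = stats
        if len(dt) and abs(mean_dt - nominal) > interval_tol * nominal:
            flags.append(
                f"{side}: mean interval {mean_dt:.4g}s deviates >"
                f"{interval_tol:.0%} from nominal {nominal:.4g}s"
            )
        if len(dt) and max_gap > 2.0 * nominal:
            flags.append(f"{side}: max gap {max_gap:.4g}s exceeds 2/fs")
        if nan_count:
            flags.append(f"{side}: {nan_count} non-finite IMU values")
    return ValidationReport(per_side=per_side, flags=flags)


# ------------------------------------------------------------------- config

DEFAULT_CONFIG: dict = {
    "fs": 25.0,
    "r": 0.17,
    "g": 9.81,
    "filter": {"order": 2, "fc_hz": 2.2},
    "kf": {"q_scale": 1.0, "r_var_deg2": 100.0},
    "peaks": {"cadence_max_rpm": 150.0, "prominence_factor": 0.5},
    "seed": 0,
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML run configuration, merged over package defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise SessionFormatError(f"config file {path} must contain a mapping")
    return _deep_update(cfg, loaded)
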