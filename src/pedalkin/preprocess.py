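"""Zero-phase low-pass filtering of analysis-relevant signals.

All streams entering the kinematics and analytics stages are passed through
a second-order Butterworth low-pass (cutoff 2.2 Hz at fs = 25 Hz by
default), applied forward-backward so the net phase shift is zero and the
effective magnitude response is the Butterworth response squared.  Edges
are handled with odd-reflection padding of length 3·(order + 1).

The filter operates on sample index and assumes nominally uniform
sampling; sessions where that assumption is poor are flagged by
``validate_session`` rather than resampled here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import PedalkinError
from .io_session import Session, SideStream


@dataclass(frozen=True)
class FilterSpec:
    order: int = 2
    fc: float = 2.2   # Hz
    fs: float = 25.0  # Hz

    def __post_init__(self) -> None:
        if self.order < 1:
            raise PedalkinError("filter order must be >= 1")
        if not (0 < self.fc < self.fs / 2):
            raise PedalkinError(
                f"cutoff must satisfy 0 < fc < fs/2, got fc={self.fc}, fs={self.fs}"
            )

    @property
    def padlen(self) -> int:
        return 3 * (self.order + 1)

    def butter_response(self, f_hz: np.ndarray | float) -> np.ndarray:
        """Analytic squared-magnitude (forward-backward) gain at ``f_hz``."""
        ratio = np.asarray(f_hz, float) / self.fc
        single = 1.0 / np.sqrt(1.0 + ratio ** (2 * self.order))
        return single**2


def lowpass_zero_phase(x: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Forward-backward Butterworth low-pass, along axis 0, length-preserving."""
    if spec is None:
        spec = FilterSpec()
    x = np.asarray(x, float)
    if x.shape[0] <= spec.padlen:
        raise PedalkinError(
            f"signal too short for zero-phase filtering: need > {spec.padlen} samples, "
            f"got {x.shape[0]}"
        )
    b, a = signal.butter(spec.order, spec.fc, btype="low", fs=spec.fs)
    return signal.filtfilt(b, a, x, axis=0, padtype="odd", padlen=spec.padlen)


def lowpass_session(session: Session, spec: FilterSpec | None = None) -> Session:
    """Return a copy of the session with accel, gyro and frequency streams filtered."""
    if spec is None:
        spec = FilterSpec(fs=session.meta.fs)
    sides = {}
    for side, st in session.sides.items():
        freqs = None if st.freqs is None else lowpass_zero_phase(st.freqs, spec)
        sides[side] = SideStream(
            t=st.t.copy(),
            accel=lowpass_zero_phase(st.accel, spec),
            gyro=lowpass_zero_phase(st.gyro, spec),
            freqs=freqs,
        )
    return Session(sides=sides, meta=replace(session.meta))
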