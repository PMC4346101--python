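"""Per-sample feature extraction from raw triaxial accelerometer traces.

Three primitives feed the detector: the sum (vector-magnitude) acceleration
|a| = √(ax²+ay²+az²), a causal low-pass gravity estimate, and the capture of
a gravity vector from the earliest stillness window (all samples with |a|
inside a band around 1 g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .quaternion import GravityVector

__all__ = [
    "AccelTrace",
    "GravityEstimate",
    "sum_acceleration",
    "lowpass_gravity",
    "capture_still_gravity",
]

#: tolerance on sample-interval uniformity, seconds
_DT_TOL = 1e-6


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled triaxial acceleration series in g-units.

    ``t`` is in seconds, strictly increasing with spacing 1/sample_rate
    (within 1e-6 s); the three axis arrays have equal length ≥ 1.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self):
        for name in ("t", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if n < 1:
            raise ValueError("trace must contain at least one sample")
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("t, ax, ay, az must have equal lengths")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > _DT_TOL):
                raise ValueError(
                    "timestamps must be uniform at 1/sample_rate "
                    f"(max deviation {np.max(np.abs(dt - 1.0 / self.sample_rate)):.3g} s)"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def as_matrix(self) -> np.ndarray:
        """(n, 3) array of axis samples."""
        return np.column_stack([self.ax, self.ay, self.az])

    def slice(self, start: int, stop: int) -> "AccelTrace":
        return AccelTrace(
            self.t[start:stop],
            self.ax[start:stop],
            self.ay[start:stop],
            self.az[start:stop],
            self.sample_rate,
        )

    def rotated(self, rotation_matrix: np.ndarray) -> "AccelTrace":
        """Trace re-expressed in a device frame rotated by the given 3×3 matrix."""
        m = self.as_matrix() @ np.asarray(rotation_matrix, dtype=float).T
        return AccelTrace(self.t, m[:, 0], m[:, 1], m[:, 2], self.sample_rate)

    @classmethod
    def from_samples(cls, samples: np.ndarray, sample_rate: float = 100.0,
                     t0: float = 0.0) -> "AccelTrace":
        samples = np.asarray(samples, dtype=float)
        t = t0 + np.arange(len(samples)) / sample_rate
        return cls(t, samples[:, 0], samples[:, 1], samples[:, 2], sample_rate)


def sum_acceleration(trace: AccelTrace) -> np.ndarray:
    """Elementwise vector magnitude |a| = √(ax²+ay²+az²), in g-units."""
    return np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)


@dataclass(frozen=True)
class GravityEstimate:
    """Per-sample low-pass gravity series.

    ``g`` is (n, 3) in g-units.  The first ``warmup_samples`` samples carry
    the filter's startup transient and are excluded from gravity capture.
    """

    t: np.ndarray
    g: np.ndarray
    warmup_samples: int
    cutoff_hz: float

    @property
    def valid(self) -> np.ndarray:
        mask = np.zeros(len(self.t), dtype=bool)
        mask[self.warmup_samples:] = True
        return mask


def lowpass_gravity(trace: AccelTrace, cutoff_hz: float = 1.0,
                    order: int = 2) -> GravityEstimate:
    """Causal Butterworth low-pass estimate of the per-axis gravity component.

    Body posture is quasi-static while voluntary-movement dynamics sit at
    roughly 2 Hz and above, so a 1 Hz second-order Butterworth separates the
    gravity component.  The filter is applied forward-only (causal), as it
    would run on-device; its state is initialised from the first sample so a
    constant input passes through unchanged.  The first three time constants
    (3 / (2π·cutoff)) are flagged as warm-up.
    """
    fs = trace.sample_rate
    if not 0.0 < cutoff_hz < fs / 2.0:
        raise ValueError(
            f"cutoff_hz must lie in (0, sample_rate/2) = (0, {fs / 2}), got {cutoff_hz}"
        )
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=fs)
    zi = sps.lfilter_zi(b, a)
    m = trace.as_matrix()
    out = np.empty_like(m)
    for k in range(3):
        out[:, k], _ = sps.lfilter(b, a, m[:, k], zi=zi * m[0, k])
    warmup = int(math.ceil(3.0 / (2.0 * math.pi * cutoff_hz) * fs))
    return GravityEstimate(trace.t, out, min(warmup, len(trace)), cutoff_hz)


def capture_still_gravity(
    trace: AccelTrace,
    window_s: float = 0.5,
    band_g: tuple[float, float] = (0.7, 1.3),
) -> GravityVector | None:
    """Mean gravity vector over the earliest stillness window, or None.

    A stillness window is a contiguous run of ``window_s`` seconds in which
    every sample's |a| lies inside ``band_g``.  Absence of such a window is
    a value (None), not an error.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = max(1, int(round(window_s * trace.sample_rate)))
    if win > len(trace):
        return None
    sa = sum_acceleration(trace)
    in_band = (sa >= band_g[0]) & (sa <= band_g[1])
    # earliest index where `win` consecutive samples are all in band
    run = np.convolve(in_band.astype(int), np.ones(win, dtype=int), mode="valid")
    hits = np.nonzero(run == win)[0]
    if len(hits) == 0:
        return None
    i0 = int(hits[0])
    m = trace.as_matrix()[i0 : i0 + win]
    mean = m.mean(axis=0)
    return GravityVector(
        float(mean[0]),
        float(mean[1]),
        float(mean[2]),
        source_window=(float(trace.t[i0]), float(trace.t[i0 + win - 1])),
    )
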