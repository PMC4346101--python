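"""Online fall-detection state machine.

The detector runs CALIBRATE → MONITOR → IMPACT → SETTLE → (ALARM | MONITOR)
over a trace:

* CALIBRATE — average the gravity vector g_before over the stillness window
  at the start of the trace (the wearer standing still after putting the
  device on).
* MONITOR — watch the sum acceleration |a| for an impact, |a| ≥ a_threshold
  (default 2 g).
* IMPACT/SETTLE — record the running peak and search the next t_threshold
  seconds (default 2 s) for a stillness window; its mean vector is g_after.
* Decision — θ from the quaternion decomposition of g_before→g_after; alarm
  iff |θ| lies inside the angle band (default 60°–120°, i.e. 90° ± 30° to
  tolerate ground tilt and lying posture).

``FallDetector`` is a scikit-learn-style estimator (``get_params`` /
``set_params`` / ``fit`` / ``predict``); ``fit`` validates parameters and is
otherwise a no-op because the thresholds are fixed design constants, not
learned.  ``AccelThresholdDetector`` is the acceleration-only comparison
baseline that alarms on the impact threshold alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .quaternion import GravityVector, decompose, rotation_angle
from .signal import AccelTrace, capture_still_gravity, sum_acceleration

__all__ = [
    "DetectorConfig",
    "FallEvent",
    "FallDetector",
    "AccelThresholdDetector",
    "CalibrationError",
    "detect",
    "detect_acceleration_only",
    "format_alarm_message",
]

REJECT_NONE = "none"
REJECT_NO_SETTLE = "no_settle"
REJECT_ANGLE = "angle_out_of_band"
REJECT_NO_AFTER_GRAVITY = "no_after_gravity"


class CalibrationError(ValueError):
    """The trace does not begin with a stillness period to calibrate g_before."""


@dataclass(frozen=True)
class DetectorConfig:
    """All detector thresholds and filter parameters.

    Units: thresholds in g, times in seconds, angles in degrees, rates in Hz.
    """

    a_threshold: float = 2.0
    t_threshold: float = 2.0
    gravity_band: tuple[float, float] = (0.7, 1.3)
    angle_band: tuple[float, float] = (60.0, 120.0)
    still_window_s: float = 0.5
    lowpass_cutoff_hz: float = 1.0
    sample_rate: float = 100.0

    def __post_init__(self):
        if self.a_threshold <= self.gravity_band[1]:
            raise ValueError("a_threshold must exceed the gravity band's upper edge")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if not 0 < self.angle_band[0] < self.angle_band[1] <= 180:
            raise ValueError("angle_band must satisfy 0 < low < high <= 180")
        if not 0 < self.gravity_band[0] < self.gravity_band[1]:
            raise ValueError("gravity_band must satisfy 0 < low < high")
        if self.still_window_s <= 0:
            raise ValueError("still_window_s must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gravity_band"] = list(self.gravity_band)
        d["angle_band"] = list(self.angle_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        for key in ("gravity_band", "angle_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class FallEvent:
    """One detected impact and its alarm decision.

    ``theta`` is the signed decomposition angle in degrees; it is None when
    no post-impact gravity was captured or for the acceleration-only
    baseline, which never computes it.
    """

    impact_time: float
    peak_a: float
    g_before: GravityVector
    g_after: Optional[GravityVector]
    theta: Optional[float]
    is_alarm: bool
    reject_reason: str = REJECT_NONE

    def to_dict(self) -> dict:
        def _gv(g):
            if g is None:
                return None
            return {
                "gx": g.gx,
                "gy": g.gy,
                "gz": g.gz,
                "source_window": list(g.source_window) if g.source_window else None,
            }

        return {
            "impact_time": self.impact_time,
            "peak_a": self.peak_a,
            "g_before": _gv(self.g_before),
            "g_after": _gv(self.g_after),
            "theta": self.theta,
            "is_alarm": self.is_alarm,
            "reject_reason": self.reject_reason,
        }


def _earliest_still_window(in_band: np.ndarray, start: int, stop: int, win: int):
    """Index of the earliest run of `win` in-band samples inside [start, stop)."""
    seg = in_band[start:stop]
    if len(seg) < win:
        return None
    run = np.convolve(seg.astype(int), np.ones(win, dtype=int), mode="valid")
    hits = np.nonzero(run == win)[0]
    if len(hits) == 0:
        return None
    return start + int(hits[0])


class FallDetector(BaseEstimator):
    """Two-feature fall detector: impact threshold + quaternion rotation angle.

    Parameters mirror :class:`DetectorConfig` field-for-field.  ``detect``
    returns the full event list for one trace; ``predict`` maps traces to
    boolean alarm labels (True iff at least one alarmed event) so the
    detector composes with scikit-learn model-selection utilities.
    """

    def __init__(
        self,
        a_threshold: float = 2.0,
        t_threshold: float = 2.0,
        gravity_band: tuple[float, float] = (0.7, 1.3),
        angle_band: tuple[float, float] = (60.0, 120.0),
        still_window_s: float = 0.5,
        lowpass_cutoff_hz: float = 1.0,
        sample_rate: float = 100.0,
    ):
        self.a_threshold = a_threshold
        self.t_threshold = t_threshold
        self.gravity_band = gravity_band
        self.angle_band = angle_band
        self.still_window_s = still_window_s
        self.lowpass_cutoff_hz = lowpass_cutoff_hz
        self.sample_rate = sample_rate

    # -- configuration plumbing -------------------------------------------

    @property
    def config(self) -> DetectorConfig:
        return DetectorConfig(**{k: getattr(self, k) for k in DetectorConfig.__dataclass_fields__})

    @classmethod
    def from_config(cls, config: DetectorConfig) -> "FallDetector":
        return cls(**{k: getattr(config, k) for k in DetectorConfig.__dataclass_fields__})

    # -- estimator surface -------------------------------------------------

    def fit(self, X=None, y=None) -> "FallDetector":
        """Validate parameters; thresholds are design constants, nothing is learned."""
        _ = self.config  # raises on invalid parameter combinations
        self.is_fitted_ = True
        return self

    def predict(self, X: AccelTrace | Iterable[AccelTrace]) -> np.ndarray:
        """Boolean alarm label per trace (True iff any event alarms)."""
        traces = [X] if isinstance(X, AccelTrace) else list(X)
        return np.array(
            [any(e.is_alarm for e in self.detect(tr)) for tr in traces], dtype=bool
        )

    # -- detection ---------------------------------------------------------

    def _decide(self, g_before: GravityVector, g_after: Optional[GravityVector]):
        """(theta, is_alarm, reject_reason) once settling has been resolved."""
        if g_after is None:
            return None, False, REJECT_NO_SETTLE
        theta = decompose(g_before, g_after).theta
        lo, hi = self.angle_band
        if lo < abs(theta) < hi:
            return theta, True, REJECT_NONE
        return theta, False, REJECT_ANGLE

    def detect(self, trace: AccelTrace) -> List[FallEvent]:
        """Run the state machine over one trace and return time-ordered events."""
        cfg = self.config  # validates
        if trace.sample_rate != self.sample_rate:
            raise ValueError(
                f"trace sample rate {trace.sample_rate} Hz does not match "
                f"detector sample rate {self.sample_rate} Hz"
            )
        sa = sum_acceleration(trace)
        lo_g, hi_g = cfg.gravity_band
        in_band = (sa >= lo_g) & (sa <= hi_g)
        win = max(1, int(round(cfg.still_window_s * cfg.sample_rate)))
        settle_span = int(round(cfg.t_threshold * cfg.sample_rate))
        m = trace.as_matrix()

        # CALIBRATE: earliest stillness window, which must precede any impact
        first_impact = np.argmax(sa >= cfg.a_threshold) if np.any(sa >= cfg.a_threshold) else len(sa)
        cal_start = _earliest_still_window(in_band, 0, len(sa), win)
        if cal_start is None or cal_start + win > first_impact:
            raise CalibrationError(
                "trace must begin with a stillness period of at least "
                f"{cfg.still_window_s} s with |a| in [{lo_g}, {hi_g}] g "
                "before any sample reaches a_threshold"
            )
        gb_mean = m[cal_start : cal_start + win].mean(axis=0)
        g_before = GravityVector(
            *map(float, gb_mean),
            source_window=(float(trace.t[cal_start]), float(trace.t[cal_start + win - 1])),
        )

        events: List[FallEvent] = []
        i = cal_start + win  # MONITOR from the end of the calibration window
        n = len(sa)
        while i < n:
            over = np.nonzero(sa[i:] >= cfg.a_threshold)[0]
            if len(over) == 0:
                break
            i0 = i + int(over[0])  # IMPACT
            search_stop = min(n, i0 + settle_span + 1)
            s0 = _earliest_still_window(in_band, i0, search_stop, win)
            if s0 is None:
                peak = float(sa[i0:search_stop].max())
                theta, is_alarm, reason = self._decide(g_before, None)
                g_after = None
                resume = search_stop
            else:
                peak = float(sa[i0 : max(s0, i0 + 1)].max())
                seg = m[s0 : s0 + win].mean(axis=0)
                g_after = GravityVector(
                    *map(float, seg),
                    source_window=(float(trace.t[s0]), float(trace.t[s0 + win - 1])),
                )
                theta, is_alarm, reason = self._decide(g_before, g_after)
                resume = s0 + win  # refractory: resume after the settle window
            events.append(
                FallEvent(
                    impact_time=float(trace.t[i0]),
                    peak_a=peak,
                    g_before=g_before,
                    g_after=g_after,
                    theta=theta,
                    is_alarm=is_alarm,
                    reject_reason=reason,
                )
            )
            i = resume
        return events


class AccelThresholdDetector(FallDetector):
    """Comparison baseline: alarm on the impact threshold |a| ≥ a_threshold alone.

    Impact segmentation and settling are identical to :class:`FallDetector`
    so event counts are comparable; the rotation angle is never computed.
    """

    def _decide(self, g_before, g_after):
        return None, True, REJECT_NONE


def detect(trace: AccelTrace, config: DetectorConfig | None = None) -> List[FallEvent]:
    """Run the two-feature detector with the given (or default) configuration."""
    return FallDetector.from_config(config or DetectorConfig()).detect(trace)


def detect_acceleration_only(
    trace: AccelTrace, config: DetectorConfig | None = None
) -> List[FallEvent]:
    """Run the acceleration-threshold baseline with the given configuration."""
    return AccelThresholdDetector.from_config(config or DetectorConfig()).detect(trace)


def format_alarm_message(
    event: FallEvent,
    lat: float,
    lon: float,
    map_url_template: str = "https://maps.example/?q={lat},{lon}",
) -> str:
    """Single-line alarm message with timestamp, rotation angle and map URL."""
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude out of range [-90, 90]: {lat}")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude out of range [-180, 180]: {lon}")
    url = map_url_template.format(lat=lat, lon=lon)
    theta = "n/a" if event.theta is None else f"{event.theta:.1f}deg"
    return (
        f"FALL ALARM t={event.impact_time:.2f}s peak={event.peak_a:.2f}g "
        f"theta={theta} location={url}"
    )
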