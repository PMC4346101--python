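"""Trace, config and report serialization.

On-disk trace dialect: CSV with header ``t,ax,ay,az``; ``t`` in seconds,
accelerations in g-units (every threshold in the detector is stated in g).
Detector configuration round-trips through YAML field-for-field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import DetectorConfig, FallEvent
from .signal import AccelTrace

__all__ = [
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_config",
    "write_config",
    "write_events",
    "G_TO_MS2",
    "g_to_ms2",
    "ms2_to_g",
]

#: standard gravity, m/s² per g-unit
G_TO_MS2 = 9.80665

REQUIRED_COLUMNS = ("t", "ax", "ay", "az")


class TraceParseError(ValueError):
    """A trace file violates the CSV dialect (named line where possible)."""


def g_to_ms2(x):
    return np.asarray(x, dtype=float) * G_TO_MS2


def ms2_to_g(x):
    return np.asarray(x, dtype=float) / G_TO_MS2


def read_trace(path, sample_rate: float | None = None) -> AccelTrace:
    """Read a ``t,ax,ay,az`` CSV; validates monotone uniform timestamps.

    If ``sample_rate`` is omitted it is inferred from the median timestamp
    spacing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing} (header line 1)")
    if len(df) == 0:
        raise TraceParseError(f"{path}: no samples (header-only file)")
    for col in REQUIRED_COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise TraceParseError(f"{path}: non-numeric {col!r} at line {bad[0] + 2}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.nonzero(dt <= 0)[0][0]) + 3
            raise TraceParseError(f"{path}: non-increasing t at line {line}")
        if sample_rate is None:
            sample_rate = 1.0 / float(np.median(dt))
        if np.any(np.abs(dt - 1.0 / sample_rate) > 1e-6):
            line = int(np.nonzero(np.abs(dt - 1.0 / sample_rate) > 1e-6)[0][0]) + 3
            raise TraceParseError(
                f"{path}: inconsistent sampling interval at line {line} "
                f"(expected {1.0 / sample_rate:.6g} s)"
            )
    elif sample_rate is None:
        sample_rate = 100.0
    try:
        return AccelTrace(t, df["ax"].to_numpy(float), df["ay"].to_numpy(float),
                          df["az"].to_numpy(float), sample_rate)
    except ValueError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def write_trace(trace: AccelTrace, path) -> None:
    """Write the same CSV dialect; write∘read is identity to ~1e-9."""
    df = pd.DataFrame(
        {"t": trace.t, "ax": trace.ax, "ay": trace.ay, "az": trace.az}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_config(path) -> DetectorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DetectorConfig.from_dict(data)


def write_config(config: DetectorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_events(events: list[FallEvent], path, **metadata) -> None:
    payload = {
        "schema_version": 1,
        **metadata,
        "events": [e.to_dict() for e in events],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
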