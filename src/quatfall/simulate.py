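"""Seeded parametric accelerometer-waveform generator for nine motion classes.

The generator emulates the qualitative waveform structure of waist-worn
accelerometer recordings for four fall directions and five activities of
daily living (walking, jumping, squatting, sitting, resting), so the
detector and evaluation harness can be exercised end-to-end without
hardware:

* falls — stillness, a free-fall dip (|a| → ~0.3 g), a half-sine impact
  spike (3–6 g, 30–80 ms), an exponentially damped ~15 Hz ring-down, then
  lying still with gravity rotated 90° ± 15° from the standing direction;
* jumping — landing spikes of 2.5–3.5 g with the upright orientation
  restored;
* walking — |a| oscillating 1 ± ~0.5 g at ~2 Hz, never reaching 2 g;
* squatting / sitting — sub-threshold peaks with small (< 15° / < 30°)
  orientation changes;
* resting — a lying-down transition rotating gravity by ~95–115° but with a
  peak of only 1.4–1.8 g, the fall look-alike that an acceleration-only
  detector confuses.

Every trace is deterministic given its seed.  Orientation changes are
time-interpolated rotations of the gravity direction (a slerp along a fixed
axis), so intermediate samples are physically coherent.  The simulated
mounting places standing gravity within ~10° of the device +x axis and fall
rotation axes within ~55° of the device z-axis; see docs/methods.md for why
this geometry matters to the decomposition angle.

All class constants live in :data:`CLASS_PARAMS` for transparent tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

from .quaternion import Quaternion
from .signal import AccelTrace

__all__ = [
    "MotionSpec",
    "GroundTruth",
    "LabeledTrace",
    "FALL_CLASSES",
    "ADL_CLASSES",
    "MOTION_CLASSES",
    "CLASS_PARAMS",
    "generate",
    "generate_cohort",
]

FALL_CLASSES = ("fall_forward", "fall_backward", "fall_leftward", "fall_rightward")
ADL_CLASSES = ("walking", "jumping", "squatting", "sitting", "resting")
MOTION_CLASSES = FALL_CLASSES + ADL_CLASSES

#: All waveform constants per motion class.  Ranges (lo, hi) are drawn
#: uniformly per trace; scalars are fixed.  Angles in degrees, times in
#: seconds, accelerations in g.
CLASS_PARAMS: dict[str, dict] = {
    **{
        cls: {
            "pre_still_s": 2.0,
            "freefall_s": (0.2, 0.4),
            "freefall_level_g": 0.3,
            "impact_peak_g": (3.0, 6.0),
            "impact_dur_s": (0.03, 0.08),
            "ring_s": 0.5,
            "ring_amp_g": 0.8,
            "ring_freq_hz": 15.0,
            "ring_tau_s": 0.1,
            "post_still_s": 3.0,
            "rotation_deg": (75.0, 105.0),
            # azimuth of the fall rotation axis from the device z-axis, and
            # the sign of the rotation; forward/backward share the simulated
            # body-lateral axis (+45°), leftward/rightward the body-anterior
            # axis (−45°)
            "axis_azimuth_deg": {"fall_forward": 45.0, "fall_backward": 45.0,
                                 "fall_leftward": -45.0, "fall_rightward": -45.0}[cls],
            "rotation_sign": {"fall_forward": 1.0, "fall_backward": -1.0,
                              "fall_leftward": 1.0, "fall_rightward": -1.0}[cls],
            "axis_wobble_deg": 10.0,
            "mount_tilt_deg": 10.0,
        }
        for cls in FALL_CLASSES
    },
    "walking": {
        "pre_still_s": 1.5,
        "walk_s": 6.0,
        "step_freq_hz": 2.0,
        "step_amp_g": 0.45,
        "harmonic_amp_g": 0.08,
        "sway_deg": 5.0,
        "sway_freq_hz": 1.0,
        "mount_tilt_deg": 10.0,
    },
    "jumping": {
        "pre_still_s": 2.0,
        "n_jumps": 2,
        "crouch_s": 0.3,
        "crouch_dip_g": 0.3,
        "flight_s": 0.25,
        "flight_level_g": 0.3,
        "land_peak_g": (2.5, 3.5),
        "land_dur_s": 0.05,
        "ring_s": 0.35,
        "ring_amp_g": 0.6,
        "ring_freq_hz": 15.0,
        "ring_tau_s": 0.08,
        "between_still_s": 1.2,
        "wobble_deg": 5.0,
        "mount_tilt_deg": 10.0,
    },
    "squatting": {
        "pre_still_s": 1.5,
        "n_cycles": 2,
        "cycle_s": 2.5,
        "dip_amp_g": 0.28,
        "tilt_deg": 10.0,
        "post_still_s": 1.0,
        "mount_tilt_deg": 10.0,
    },
    "sitting": {
        "pre_still_s": 2.0,
        "transition_s": 1.0,
        "dip_g": 0.15,
        "seat_peak_g": (1.5, 1.9),
        "seat_dur_s": 0.06,
        "ring_s": 0.3,
        "ring_amp_g": 0.25,
        "ring_freq_hz": 12.0,
        "ring_tau_s": 0.08,
        "post_still_s": 2.5,
        "tilt_deg": (15.0, 25.0),
        "axis_azimuth_deg": 0.0,
        "axis_wobble_deg": 20.0,
        "mount_tilt_deg": 10.0,
    },
    "resting": {
        "pre_still_s": 2.0,
        "transition_s": 1.2,
        "dip_g": 0.2,
        "land_peak_g": (1.4, 1.8),
        "land_dur_s": 0.06,
        "ring_s": 0.4,
        "ring_amp_g": 0.35,
        "ring_freq_hz": 12.0,
        "ring_tau_s": 0.1,
        "post_still_s": 3.0,
        "rotation_deg": (95.0, 115.0),
        "axis_azimuth_deg": 0.0,
        "axis_wobble_deg": 15.0,
        "mount_tilt_deg": 10.0,
    },
}


@dataclass(frozen=True)
class MotionSpec:
    """Specification of one synthetic trace."""

    motion_class: str
    seed: int = 0
    duration_s: Optional[float] = None
    noise_sigma_g: float = 0.02
    sample_rate: float = 100.0
    device_orientation: Optional[Quaternion] = None
    class_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(
                f"unknown motion class {self.motion_class!r}; "
                f"expected one of {MOTION_CLASSES}"
            )


@dataclass(frozen=True)
class GroundTruth:
    """True labels for one generated trace.

    ``rotation_angle_deg`` is the geometric (geodesic) angle between the
    true before/after gravity directions — invariant under any device
    orientation.  ``peak_a`` is the noise-free peak of |a|.
    """

    motion_class: str
    g_before_dir: np.ndarray
    g_after_dir: np.ndarray
    peak_a: float
    rotation_angle_deg: float

    @property
    def is_fall(self) -> bool:
        return self.motion_class in FALL_CLASSES


class LabeledTrace(NamedTuple):
    trace: AccelTrace
    truth: GroundTruth


# --------------------------------------------------------------------------
# building blocks

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _rand_dir_near(rng: np.random.Generator, center: np.ndarray, max_tilt_deg: float) -> np.ndarray:
    """Random unit vector within a cone of max_tilt_deg around `center`."""
    tilt = math.radians(rng.uniform(0.0, max_tilt_deg))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    # orthonormal basis around center
    c = center / np.linalg.norm(center)
    helper = np.array([0.0, 0.0, 1.0]) if abs(c[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(c, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)
    return c * math.cos(tilt) + (e1 * math.cos(phi) + e2 * math.sin(phi)) * math.sin(tilt)


def _perp_axis(rng: np.random.Generator, gb: np.ndarray, azimuth_deg: float,
               wobble_deg: float) -> np.ndarray:
    """Rotation axis near the given y–z-plane azimuth, projected ⊥ gb."""
    psi = math.radians(azimuth_deg + rng.uniform(-wobble_deg, wobble_deg))
    ax = np.array([0.0, math.sin(psi), math.cos(psi)])
    ax = ax - ax.dot(gb) * gb
    n = np.linalg.norm(ax)
    if n < 1e-12:  # pathological mounting; fall back to any perpendicular
        ax = np.cross(gb, np.array([0.0, 1.0, 0.0]))
        n = np.linalg.norm(ax)
    return ax / n


def _rodrigues_path(gb: np.ndarray, axis: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """(n, 3) unit gravity direction rotated about `axis` by per-sample angles."""
    k = axis / np.linalg.norm(axis)
    c = np.cos(angles_rad)[:, None]
    s = np.sin(angles_rad)[:, None]
    kxg = np.cross(k, gb)
    kdg = k.dot(gb)
    return gb * c + kxg * s + k * (kdg * (1.0 - c))


def _ring(t: np.ndarray, amp: float, freq: float, tau: float) -> np.ndarray:
    return amp * np.exp(-t / tau) * np.sin(2.0 * math.pi * freq * t)


class _Profile:
    """Accumulates magnitude m(t) and rotation-fraction s(t) segment by segment."""

    def __init__(self, fs: float):
        self.fs = fs
        self._m: list[np.ndarray] = []
        self._s: list[np.ndarray] = []

    def add(self, duration_s: float, m_fn: Callable[[np.ndarray], np.ndarray],
            s_fn: Callable[[np.ndarray], np.ndarray]):
        n = max(1, int(round(duration_s * self.fs)))
        t = np.arange(n) / self.fs
        self._m.append(np.broadcast_to(np.asarray(m_fn(t), dtype=float), (n,)).copy())
        self._s.append(np.broadcast_to(np.asarray(s_fn(t), dtype=float), (n,)).copy())

    def const(self, duration_s: float, m: float, s: float):
        self.add(duration_s, lambda t: np.full_like(t, m), lambda t: np.full_like(t, s))

    def arrays(self):
        return np.concatenate(self._m), np.concatenate(self._s)


# --------------------------------------------------------------------------
# per-class profiles: each returns (profile, total_rotation_deg)

def _profile_fall(rng, p, fs):
    gamma = rng.uniform(*p["rotation_deg"]) * p["rotation_sign"]
    ff = rng.uniform(*p["freefall_s"])
    peak = rng.uniform(*p["impact_peak_g"])
    imp = rng.uniform(*p["impact_dur_s"])
    lvl = p["freefall_level_g"]
    span = ff + imp
    pr = _Profile(fs)
    pr.const(p["pre_still_s"], 1.0, 0.0)
    pr.add(ff, lambda t: 1.0 + (lvl - 1.0) * _smoothstep(t / (0.4 * ff)),
           lambda t: _smoothstep(t / span))
    pr.add(imp, lambda t: lvl + (peak - lvl) * np.sin(math.pi * t / imp),
           lambda t: _smoothstep((ff + t) / span))
    pr.add(p["ring_s"],
           lambda t: 1.0 + _ring(t, p["ring_amp_g"], p["ring_freq_hz"], p["ring_tau_s"]),
           lambda t: np.ones_like(t))
    pr.const(p["post_still_s"], 1.0, 1.0)
    return pr, gamma


def _profile_walking(rng, p, fs):
    f, amp, h = p["step_freq_hz"], p["step_amp_g"], p["harmonic_amp_g"]
    phase = rng.uniform(0.0, 2.0 * math.pi)
    pr = _Profile(fs)
    pr.const(p["pre_still_s"], 1.0, 0.0)
    pr.add(p["walk_s"],
           lambda t: 1.0 + amp * np.sin(2 * math.pi * f * t)
           + h * np.sin(4 * math.pi * f * t + phase),
           lambda t: np.sin(2 * math.pi * p["sway_freq_hz"] * t))
    return pr, p["sway_deg"]


def _profile_jumping(rng, p, fs):
    pr = _Profile(fs)
    pr.const(p["pre_still_s"], 1.0, 0.0)
    for _ in range(p["n_jumps"]):
        peak = rng.uniform(*p["land_peak_g"])
        pr.add(p["crouch_s"],
               lambda t: 1.0 - p["crouch_dip_g"] * np.sin(math.pi * t / p["crouch_s"]),
               lambda t: np.zeros_like(t))
        pr.add(p["flight_s"],
               lambda t: np.full_like(t, p["flight_level_g"]),
               lambda t: np.sin(math.pi * t / p["flight_s"]))  # transient wobble
        pr.add(p["land_dur_s"],
               lambda t, pk=peak: p["flight_level_g"]
               + (pk - p["flight_level_g"]) * np.sin(math.pi * t / p["land_dur_s"]),
               lambda t: np.zeros_like(t))
        pr.add(p["ring_s"],
               lambda t: 1.0 + _ring(t, p["ring_amp_g"], p["ring_freq_hz"], p["ring_tau_s"]),
               lambda t: np.zeros_like(t))
        pr.const(p["between_still_s"], 1.0, 0.0)
    return pr, p["wobble_deg"]


def _profile_squatting(rng, p, fs):
    pr = _Profile(fs)
    pr.const(p["pre_still_s"], 1.0, 0.0)
    for _ in range(p["n_cycles"]):
        pr.add(p["cycle_s"],
               lambda t: 1.0 - p["dip_amp_g"] * np.sin(2 * math.pi * t / p["cycle_s"]),
               lambda t: np.sin(math.pi * t / p["cycle_s"]) ** 2)  # tilt out and back
    pr.const(p["post_still_s"], 1.0, 0.0)
    return pr, p["tilt_deg"]


def _profile_sitting(rng, p, fs):
    tilt = rng.uniform(*p["tilt_deg"])
    peak = rng.uniform(*p["seat_peak_g"])
    tr = p["transition_s"]
    pr = _Profile(fs)
    pr.const(p["pre_still_s"], 1.0, 0.0)
    pr.add(tr, lambda t: 1.0 - p["dip_g"] * np.sin(math.pi * t / tr),
           lambda t: _smoothstep(t / tr))
    pr.add(p["seat_dur_s"],
           lambda t: 1.0 + (peak - 1.0) * np.sin(math.pi * t / p["seat_dur_s"]),
           lambda t: np.ones_like(t))
    pr.add(p["ring_s"],
           lambda t: 1.0 + _ring(t, p["ring_amp_g"], p["ring_freq_hz"], p["ring_tau_s"]),
           lambda t: np.ones_like(t))
    pr.const(p["post_still_s"], 1.0, 1.0)
    return pr, tilt


def _profile_resting(rng, p, fs):
    gamma = rng.uniform(*p["rotation_deg"])
    peak = rng.uniform(*p["land_peak_g"])
    tr = p["transition_s"]
    pr = _Profile(fs)
    pr.const(p["pre_still_s"], 1.0, 0.0)
    pr.add(tr, lambda t: 1.0 - p["dip_g"] * np.sin(math.pi * t / tr),
           lambda t: _smoothstep(t / tr))
    pr.add(p["land_dur_s"],
           lambda t: 1.0 + (peak - 1.0) * np.sin(math.pi * t / p["land_dur_s"]),
           lambda t: np.ones_like(t))
    pr.add(p["ring_s"],
           lambda t: 1.0 + _ring(t, p["ring_amp_g"], p["ring_freq_hz"], p["ring_tau_s"]),
           lambda t: np.ones_like(t))
    pr.const(p["post_still_s"], 1.0, 1.0)
    return pr, gamma


_BUILDERS = {
    **{cls: _profile_fall for cls in FALL_CLASSES},
    "walking": _profile_walking,
    "jumping": _profile_jumping,
    "squatting": _profile_squatting,
    "sitting": _profile_sitting,
    "resting": _profile_resting,
}


# --------------------------------------------------------------------------

def generate(spec: MotionSpec) -> LabeledTrace:
    """Generate one trace with its ground truth, deterministically per seed."""
    p = dict(CLASS_PARAMS[spec.motion_class])
    p.update(spec.class_params)
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate

    gb = _rand_dir_near(rng, np.array([1.0, 0.0, 0.0]), p["mount_tilt_deg"])
    axis = _perp_axis(rng, gb, p.get("axis_azimuth_deg", 0.0),
                      p.get("axis_wobble_deg", 45.0))
    pr, total_deg = _BUILDERS[spec.motion_class](rng, p, fs)
    m, s = pr.arrays()

    if spec.duration_s is not None:
        want = int(round(spec.duration_s * fs))
        if want < len(m):
            raise ValueError(
                f"duration_s={spec.duration_s} shorter than the "
                f"{spec.motion_class} waveform ({len(m) / fs:.2f} s)"
            )
        pad = want - len(m)
        m = np.concatenate([m, np.full(pad, m[-1])])
        s = np.concatenate([s, np.full(pad, s[-1])])

    u = _rodrigues_path(gb, axis, np.radians(total_deg) * s)
    samples = m[:, None] * u
    peak_a = float(np.max(np.abs(m)))
    ga = u[-1]

    if spec.noise_sigma_g > 0:
        samples = samples + rng.normal(0.0, spec.noise_sigma_g, samples.shape)

    if spec.device_orientation is not None:
        q = spec.device_orientation.normalized()
        r = _quat_to_matrix(q)
        samples = samples @ r.T
        gb = r @ gb
        ga = r @ ga

    trace = AccelTrace.from_samples(samples, sample_rate=fs)
    geodesic = math.degrees(math.acos(float(np.clip(np.dot(gb, ga), -1.0, 1.0))))
    truth = GroundTruth(
        motion_class=spec.motion_class,
        g_before_dir=gb,
        g_after_dir=ga,
        peak_a=peak_a,
        rotation_angle_deg=geodesic,
    )
    _check_class_guarantees(spec, trace, truth)
    return LabeledTrace(trace, truth)


def _quat_to_matrix(q: Quaternion) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _check_class_guarantees(spec: MotionSpec, trace: AccelTrace, truth: GroundTruth):
    """Class-parameter guarantees asserted on every generated trace."""
    sa = np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)
    if truth.is_fall:
        if sa.max() < 2.0:
            raise AssertionError("fall trace failed to exceed the 2 g impact threshold")
    elif spec.motion_class in ("walking", "squatting"):
        if sa.max() >= 2.0:
            raise AssertionError(f"{spec.motion_class} trace reached 2 g")


def generate_cohort(n_per_class: int, seed: int = 0,
                    classes: Sequence[str] = MOTION_CLASSES,
                    **spec_kwargs) -> list[LabeledTrace]:
    """n_per_class traces per motion class with per-trace derived seeds.

    The label sequence and every trace are stable across runs for a fixed
    seed.  Extra keyword arguments are forwarded to every MotionSpec.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_per_class * len(classes))
    out = []
    k = 0
    for cls in classes:
        for _ in range(n_per_class):
            out.append(generate(MotionSpec(cls, seed=int(child_seeds[k]), **spec_kwargs)))
            k += 1
    return out
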