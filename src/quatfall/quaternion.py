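"""Quaternion algebra and the gravity-to-gravity rotation decomposition.

A fall rotates the wearer's body — and with it the gravity vector measured
in the device frame — by roughly 90°.  This module implements the quaternion
machinery that turns a *before* and an *after* gravity vector into a single
rotation angle θ: the relative rotation is factored into three elementary
unit quaternions,

    Q1  tilt of g_before down into the device's horizontal (x–y) plane,
    Q2  azimuthal rotation about the device k-axis,
    Q3  tilt back up to g_after,

composed as ``Q = Q3 ⊗ Q2 ⊗ Q1`` and summarised by the total angle
``θ = 2·arctan(|q_vec| / q0)``.

θ is reported signed, in degrees, in (−180°, 180°].  Note that θ is the
angle of this particular three-stage factorisation, not the geodesic angle
between the two gravity directions; the two coincide for the canonical
waist mounting (standing gravity near a horizontal device axis) but the
factorised angle is inflated in tilted frames.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "Quaternion",
    "GravityVector",
    "Decomposition",
    "multiply",
    "conjugate",
    "rotation_angle",
    "rotate_vector",
    "decompose",
]

#: horizontal-norm threshold below which the tilt axis is undefined
EPSILON_H = 1e-8

_UNIT_TOL = 1e-9


class Quaternion(NamedTuple):
    """Scalar-first quaternion ``q0 + q1·i + q2·j + q3·k``."""

    q0: float
    q1: float = 0.0
    q2: float = 0.0
    q3: float = 0.0

    @property
    def norm(self) -> float:
        return math.sqrt(self.q0**2 + self.q1**2 + self.q2**2 + self.q3**2)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3])

    def is_unit(self, tol: float = _UNIT_TOL) -> bool:
        return abs(self.norm - 1.0) < tol

    def normalized(self) -> "Quaternion":
        n = self.norm
        if n == 0.0:
            raise ValueError("cannot normalize the zero quaternion")
        return Quaternion(self.q0 / n, self.q1 / n, self.q2 / n, self.q3 / n)

    def conjugate(self) -> "Quaternion":
        return Quaternion(self.q0, -self.q1, -self.q2, -self.q3)

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

    def left_matrix(self) -> np.ndarray:
        """4×4 matrix M(Q) such that ``M(Q) @ b == Q ⊗ b``.

        This is the matrix form through which quaternion multiplication is
        conventionally carried out on fixed-point microcontrollers.
        """
        q0, q1, q2, q3 = self
        return np.array(
            [
                [q0, -q1, -q2, -q3],
                [q1, q0, -q3, q2],
                [q2, q3, q0, -q1],
                [q3, -q2, q1, q0],
            ]
        )

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float) -> "Quaternion":
        """Unit quaternion rotating by ``angle_deg`` about ``axis`` (right-hand rule)."""
        ax = np.asarray(axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0.0:
            raise ValueError("rotation axis must be non-zero")
        ax = ax / n
        half = math.radians(angle_deg) / 2.0
        s = math.sin(half)
        return cls(math.cos(half), s * ax[0], s * ax[1], s * ax[2])

    def __matmul__(self, other: "Quaternion") -> "Quaternion":
        return multiply(self, other)


def multiply(a: Quaternion, b: Quaternion) -> Quaternion:
    """Hamilton product a ⊗ b (equals ``a.left_matrix() @ b``)."""
    a0, a1, a2, a3 = a
    b0, b1, b2, b3 = b
    return Quaternion(
        a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
        a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
        a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
        a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
    )


def conjugate(a: Quaternion) -> Quaternion:
    """Q* = q0 − q1·i − q2·j − q3·k."""
    return a.conjugate()


def rotation_angle(q: Quaternion) -> float:
    """Total rotation angle θ of a unit quaternion, signed, in degrees.

    ``θ = 2·arctan(√(q1²+q2²+q3²) / q0)`` with the sign of q0 carried
    through the arctan, so θ ∈ (−180°, 180°] and is negative when q0 < 0.
    The quaternion sign is deliberately not canonicalised.  q0 = 0 returns
    exactly 180° (the arctan limit).
    """
    v = math.sqrt(q.q1**2 + q.q2**2 + q.q3**2)
    if q.q0 == 0.0:
        return 180.0
    return math.degrees(2.0 * math.atan(v / q.q0))


@dataclass(frozen=True)
class GravityVector:
    """Gravity estimate in device coordinates, in g-units.

    ``source_window`` records the [start, end] time span (seconds) of the
    stillness window the vector was averaged over; it is None for directly
    constructed vectors.
    """

    gx: float
    gy: float
    gz: float
    source_window: tuple[float, float] | None = None

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.gx**2 + self.gy**2 + self.gz**2)

    def as_array(self) -> np.ndarray:
        return np.array([self.gx, self.gy, self.gz])

    def direction(self) -> np.ndarray:
        m = self.magnitude
        if m == 0.0:
            raise ValueError("zero gravity vector has no direction")
        return self.as_array() / m

    @classmethod
    def from_array(cls, v, source_window=None) -> "GravityVector":
        v = np.asarray(v, dtype=float)
        return cls(float(v[0]), float(v[1]), float(v[2]), source_window)


def rotate_vector(q: Quaternion, v: GravityVector | np.ndarray) -> GravityVector:
    """Sandwich product Q ⊗ v ⊗ Q* applied to a pure (vector) quaternion."""
    arr = v.as_array() if isinstance(v, GravityVector) else np.asarray(v, dtype=float)
    pure = Quaternion(0.0, arr[0], arr[1], arr[2])
    out = multiply(multiply(q, pure), conjugate(q))
    return GravityVector(out.q1, out.q2, out.q3)


@dataclass(frozen=True)
class Decomposition:
    """Three-stage factorisation of the before→after gravity rotation."""

    Q1: Quaternion
    Q2: Quaternion
    Q3: Quaternion
    theta1: float  # degrees, elevation of g_before
    theta2: float  # degrees, azimuth change, wrapped to (-180, 180]
    theta3: float  # degrees, minus elevation of g_after
    alpha_sin: float
    alpha_cos: float
    beta_sin: float
    beta_cos: float
    Q: Quaternion = field(default=Quaternion(1.0))
    theta: float = 0.0  # degrees, signed total rotation angle
    degenerate_before: bool = False
    degenerate_after: bool = False


def _wrap_pi(angle: float) -> float:
    """Wrap radians into (−π, π]."""
    wrapped = math.fmod(angle + math.pi, 2.0 * math.pi)
    if wrapped <= 0.0:
        wrapped += 2.0 * math.pi
    return wrapped - math.pi


def _tilt_terms(g: np.ndarray, epsilon_h: float):
    """Elevation angle, tilt-axis direction cosines and azimuth of a unit vector.

    When the horizontal norm vanishes (gravity along ±k) the tilt axis is
    undefined; the j-axis is used (sin = 0, cos = 1), the azimuth is taken
    as 0 and the degeneracy is flagged.
    """
    h = math.hypot(g[0], g[1])
    elevation = math.atan2(g[2], h)
    if h < epsilon_h:
        return elevation, 0.0, 1.0, 0.0, True
    return elevation, -g[1] / h, g[0] / h, math.atan2(g[1], g[0]), False


def decompose(
    g_before: GravityVector | np.ndarray,
    g_after: GravityVector | np.ndarray,
    epsilon_h: float = EPSILON_H,
) -> Decomposition:
    """Factor the gravity rotation into Q1 (tilt down), Q2 (azimuth), Q3 (tilt up).

    Both inputs are normalised to unit length first — the factorisation
    depends only on direction, which removes sensitivity to the ±0.3 g
    capture tolerance.  The composed ``Q = Q3 ⊗ Q2 ⊗ Q1`` maps the unit
    g_before direction onto the unit g_after direction.

    Raises ValueError if either vector has zero magnitude.
    """
    gb = g_before.as_array() if isinstance(g_before, GravityVector) else np.asarray(g_before, float)
    ga = g_after.as_array() if isinstance(g_after, GravityVector) else np.asarray(g_after, float)
    nb, na = np.linalg.norm(gb), np.linalg.norm(ga)
    if nb == 0.0 or na == 0.0:
        raise ValueError("gravity vectors must have non-zero magnitude")
    gb, ga = gb / nb, ga / na

    elev_b, alpha_sin, alpha_cos, azim_b, degen_b = _tilt_terms(gb, epsilon_h)
    elev_a, beta_sin, beta_cos, azim_a, degen_a = _tilt_terms(ga, epsilon_h)

    th1 = elev_b
    th2 = _wrap_pi(azim_a - azim_b)
    th3 = -elev_a

    h1, h3 = th1 / 2.0, th3 / 2.0
    q1 = Quaternion(
        math.cos(h1), math.sin(h1) * alpha_sin, math.sin(h1) * alpha_cos, 0.0
    )
    q2 = Quaternion(math.cos(th2 / 2.0), 0.0, 0.0, math.sin(th2 / 2.0))
    q3 = Quaternion(
        math.cos(h3), math.sin(h3) * beta_sin, math.sin(h3) * beta_cos, 0.0
    )
    q = multiply(q3, multiply(q2, q1))

    return Decomposition(
        Q1=q1,
        Q2=q2,
        Q3=q3,
        theta1=math.degrees(th1),
        theta2=math.degrees(th2),
        theta3=math.degrees(th3),
        alpha_sin=alpha_sin,
        alpha_cos=alpha_cos,
        beta_sin=beta_sin,
        beta_cos=beta_cos,
        Q=q,
        theta=rotation_angle(q),
        degenerate_before=degen_b,
        degenerate_after=degen_a,
    )
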