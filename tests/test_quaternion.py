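"""Quaternion algebra and the three-stage gravity-rotation decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from quatfall import (
    GravityVector,
    Quaternion,
    conjugate,
    decompose,
    multiply,
    rotate_vector,
    rotation_angle,
)

finite = st.floats(-10, 10, allow_nan=False)


def left_matrix_oracle(a):
    """4×4 left-multiplication matrix, written out element by element."""
    q0, q1, q2, q3 = a
    return np.array(
        [
            [q0, -q1, -q2, -q3],
            [q1, q0, -q3, q2],
            [q2, q3, q0, -q1],
            [q3, -q2, q1, q0],
        ]
    )


def rotmat_oracle(q):
    """Unit quaternion → 3×3 rotation matrix (independent of the package)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestMultiply:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0, 0, 0), (0.3, -1.2, 4.0, 0.5), (0.3, -1.2, 4.0, 0.5)),
            ((0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)),  # i⊗j = k
            ((0, 0, 1, 0), (0, 0, 0, 1), (0, 1, 0, 0)),  # j⊗k = i
            ((0, 1, 0, 0), (0, 1, 0, 0), (-1, 0, 0, 0)),  # i² = −1
        ],
    )
    def test_hamilton_rules(self, a, b, expected):
        assert multiply(Quaternion(*a), Quaternion(*b)) == pytest.approx(expected)

    def test_matches_matrix_form(self, rng):
        for _ in range(1000):
            a, b = (Quaternion(*rng.normal(size=4)) for _ in range(2))
            via_matrix = left_matrix_oracle(a) @ np.array(b)
            assert multiply(a, b).as_array() == pytest.approx(via_matrix, abs=1e-12)

    def test_associativity(self, rng):
        for _ in range(300):
            a, b, c = (Quaternion(*rng.normal(size=4)) for _ in range(3))
            lhs = multiply(multiply(a, b), c).as_array()
            rhs = multiply(a, multiply(b, c)).as_array()
            assert lhs == pytest.approx(rhs, abs=1e-12)

    @given(st.tuples(finite, finite, finite, finite),
           st.tuples(finite, finite, finite, finite))
    def test_left_matrix_agrees(self, a, b):
        qa, qb = Quaternion(*a), Quaternion(*b)
        assert multiply(qa, qb).as_array() == pytest.approx(
            qa.left_matrix() @ qb.as_array(), abs=1e-9
        )


class TestConjugate:
    @pytest.mark.parametrize(
        "q, expected",
        [((1, 0, 0, 0), (1, 0, 0, 0)), ((0, 1, 0, 0), (0, -1, 0, 0))],
    )
    def test_examples(self, q, expected):
        assert conjugate(Quaternion(*q)) == pytest.approx(expected)

    def test_q_times_conjugate_is_norm_squared(self, rng):
        for _ in range(200):
            a = Quaternion(*rng.normal(size=4))
            prod = multiply(a, conjugate(a)).as_array()
            assert prod == pytest.approx([a.norm**2, 0, 0, 0], abs=1e-12)


class TestRotationAngle:
    def test_identity_is_zero(self):
        assert rotation_angle(Quaternion(1, 0, 0, 0)) == 0.0

    def test_half_angle_90(self):
        c = math.cos(math.radians(45))
        assert rotation_angle(Quaternion(c, c, 0, 0)) == pytest.approx(90.0)

    def test_zero_scalar_is_180(self):
        assert rotation_angle(Quaternion(0, 1, 0, 0)) == 180.0

    def test_negative_scalar_gives_negative_angle(self):
        c = math.cos(math.radians(45))
        assert rotation_angle(Quaternion(-c, c, 0, 0)) == pytest.approx(-90.0)


class TestRotateVector:
    def test_identity(self):
        v = GravityVector(0.2, -0.4, 0.9)
        out = rotate_vector(Quaternion(1, 0, 0, 0), v)
        assert out.as_array() == pytest.approx(v.as_array())

    def test_90_about_k(self):
        q = Quaternion.from_axis_angle([0, 0, 1], 90.0)
        out = rotate_vector(q, GravityVector(1, 0, 0))
        assert out.as_array() == pytest.approx([0, 1, 0], abs=1e-12)

    def test_matches_rotation_matrix_and_preserves_norm(self, rng):
        for _ in range(300):
            q = Quaternion(*rng.normal(size=4)).normalized()
            v = rng.normal(size=3)
            out = rotate_vector(q, GravityVector(*v)).as_array()
            assert out == pytest.approx(rotmat_oracle(q) @ v, abs=1e-12)
            assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(v), abs=1e-12)


class TestDecompose:
    def test_no_rotation(self):
        d = decompose(GravityVector(1, 0, 0), GravityVector(1, 0, 0))
        assert (d.theta1, d.theta2, d.theta3) == (0, 0, 0)
        assert d.Q == pytest.approx((1, 0, 0, 0))
        assert d.theta == 0.0

    def test_quarter_turn_in_horizontal_plane(self):
        d = decompose(GravityVector(1, 0, 0), GravityVector(0, 1, 0))
        assert d.theta1 == pytest.approx(0.0)
        assert d.theta2 == pytest.approx(90.0)
        assert d.theta3 == pytest.approx(0.0)
        assert abs(d.theta) == pytest.approx(90.0)
        # cross-check against an axis-angle rotation-matrix oracle
        assert rotmat_oracle(d.Q) @ [1, 0, 0] == pytest.approx([0, 1, 0], abs=1e-12)

    def test_unit_invariants_and_axis_cosines(self, rng):
        for gb, ga in zip(random_unit_vectors(rng, 100), random_unit_vectors(rng, 100)):
            d = decompose(GravityVector(*gb), GravityVector(*ga))
            for q in (d.Q1, d.Q2, d.Q3, d.Q):
                assert abs(q.norm - 1.0) < 1e-9
            if not (d.degenerate_before or d.degenerate_after):
                assert d.alpha_sin**2 + d.alpha_cos**2 == pytest.approx(1.0, abs=1e-9)
                assert d.beta_sin**2 + d.beta_cos**2 == pytest.approx(1.0, abs=1e-9)

    def test_composed_rotation_maps_before_to_after(self, rng):
        """Q3⊗Q2⊗Q1 carries ĝ_before onto ĝ_after; verified both by the
        sandwich product and by composing the three stages as rotation
        matrices."""
        for gb, ga in zip(random_unit_vectors(rng, 1000), random_unit_vectors(rng, 1000)):
            d = decompose(GravityVector(*gb), GravityVector(*ga))
            sandwich = rotate_vector(d.Q, GravityVector(*gb)).as_array()
            assert np.linalg.norm(sandwich - ga) < 1e-9
            staged = rotmat_oracle(d.Q3) @ rotmat_oracle(d.Q2) @ rotmat_oracle(d.Q1) @ gb
            assert np.linalg.norm(staged - ga) < 1e-9

    def test_angle_invariant_under_common_azimuthal_rotation(self, rng):
        """A shared rotation about the device k-axis leaves |θ| unchanged."""
        for gb, ga in zip(random_unit_vectors(rng, 200), random_unit_vectors(rng, 200)):
            if min(np.hypot(*gb[:2]), np.hypot(*ga[:2])) < 1e-3:
                continue
            base = abs(decompose(GravityVector(*gb), GravityVector(*ga)).theta)
            phi = rng.uniform(0, 360)
            r = rotmat_oracle(Quaternion.from_axis_angle([0, 0, 1], phi))
            turned = abs(decompose(GravityVector(*(r @ gb)), GravityVector(*(r @ ga))).theta)
            assert turned == pytest.approx(base, abs=1e-9)

    def test_same_vector_gives_zero_angle(self, rng):
        for g in random_unit_vectors(rng, 100):
            d = decompose(GravityVector(*g), GravityVector(*g))
            assert rotation_angle(d.Q) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_vertical_gravity_flagged_but_valid(self):
        d = decompose(GravityVector(0, 0, 1), GravityVector(0, 1, 0))
        assert d.degenerate_before and not d.degenerate_after
        out = rotate_vector(d.Q, GravityVector(0, 0, 1)).as_array()
        assert out == pytest.approx([0, 1, 0], abs=1e-9)
        # staged angle: 90° tilt about j then 90° azimuth about k compose to
        # 2·arccos(cos45°·cos45°) = 120°, larger than the 90° geodesic
        assert abs(d.theta) == pytest.approx(120.0)

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValueError):
            decompose(GravityVector(0, 0, 0), GravityVector(1, 0, 0))

    def test_magnitude_insensitive(self):
        """Only direction matters: scaled inputs give the same angle."""
        a = decompose(GravityVector(0.8, 0.1, 0.3), GravityVector(0.1, 1.2, 0.2))
        b = decompose(GravityVector(1.6, 0.2, 0.6), GravityVector(0.05, 0.6, 0.1))
        assert a.theta == pytest.approx(b.theta, abs=1e-12)
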