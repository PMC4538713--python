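"""Rigid-transform algebra and the point-displacement motion metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navmc.geometry import (
    CFOV,
    FRONTAL_CORTEX,
    ReferencePoint,
    apply_to_point,
    compose,
    from_matrix,
    identity,
    invert,
    make_rigid,
    motion_magnitude,
)

params_strategy = st.tuples(
    *([st.floats(-180, 180, allow_nan=False)] * 3),
    *([st.floats(-50, 50, allow_nan=False)] * 3),
).map(np.array)


def chord(radius: float, theta_deg: float) -> float:
    return 2.0 * radius * np.sin(np.radians(theta_deg) / 2.0)


class TestMakeRigid:
    def test_zero_params_is_identity(self):
        assert np.allclose(make_rigid(np.zeros(6)).matrix, np.eye(4))

    def test_pure_translation_matrix(self):
        t = make_rigid([0, 0, 0, 3, 0, 0])
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, [3, 0, 0])

    def test_quarter_turn_about_z(self):
        t = make_rigid([0, 0, 90, 0, 0, 0])
        assert np.allclose(apply_to_point(t, [1, 0, 0]), [0, 1, 0], atol=1e-12)

    @pytest.mark.parametrize("bad", [[np.nan, 0, 0, 0, 0, 0], [0, 0, 0, np.inf, 0, 0]])
    def test_non_finite_params_rejected(self, bad):
        with pytest.raises(ValueError, match="finite"):
            make_rigid(bad)

    def test_unsupported_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            make_rigid(np.zeros(6), convention="ZYX")


class TestComposeInvert:
    def test_compose_with_inverse_is_identity(self):
        t = make_rigid([10, -20, 30, 5, -7, 2])
        assert np.allclose(compose(t, invert(t)).matrix, np.eye(4), atol=1e-9)

    def test_translations_add(self):
        a = make_rigid([0, 0, 0, 1, 2, 3])
        b = make_rigid([0, 0, 0, 4, 5, 6])
        assert np.allclose(compose(a, b).translation, [5, 7, 9])

    def test_z_rotations_add(self):
        a = make_rigid([0, 0, 30, 0, 0, 0])
        b = make_rigid([0, 0, 60, 0, 0, 0])
        expected = make_rigid([0, 0, 90, 0, 0, 0])
        assert np.allclose(compose(a, b).matrix, expected.matrix, atol=1e-12)

    def test_compose_order_is_b_then_a(self):
        rot = make_rigid([0, 0, 90, 0, 0, 0])
        shift = make_rigid([0, 0, 0, 1, 0, 0])
        # shift then rotate: (1,0,0) -> (2,0,0) -> (0,2,0)
        assert np.allclose(apply_to_point(compose(rot, shift), [1, 0, 0]), [0, 2, 0])

    def test_invert_pure_translation(self):
        t = invert(make_rigid([0, 0, 0, 3, 0, 0]))
        assert np.allclose(t.translation, [-3, 0, 0])

    def test_double_inverse_round_trips(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = np.concatenate([rng.uniform(-180, 180, 3), rng.uniform(-50, 50, 3)])
            t = make_rigid(p)
            assert np.allclose(invert(invert(t)).matrix, t.matrix, atol=1e-9)


class TestApplyAndMagnitude:
    def test_identity_fixes_points(self):
        assert np.allclose(apply_to_point(identity(), [0, 60, 0]), [0, 60, 0])
        assert motion_magnitude(identity(), FRONTAL_CORTEX) == 0.0

    def test_translation_shifts_point(self):
        t = make_rigid([0, 0, 0, 0, 0, -5])
        assert np.allclose(apply_to_point(t, [0, 60, 0]), [0, 60, -5])

    def test_345_translation_magnitude(self):
        t = make_rigid([0, 0, 0, 3, 4, 0])
        assert motion_magnitude(t, FRONTAL_CORTEX) == pytest.approx(5.0)
        # translations displace every point equally
        assert motion_magnitude(t, CFOV) == pytest.approx(5.0)

    def test_one_degree_rotation_chord_at_cortex(self):
        t = make_rigid([0, 0, 1, 0, 0, 0])
        expected = chord(60.0, 1.0)  # 2*60*sin(0.5 deg) = 1.0471843 mm
        assert motion_magnitude(t, FRONTAL_CORTEX) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.0471843, abs=1e-6)
        # rotation about the origin fixes the centre of FOV
        assert motion_magnitude(t, CFOV) == 0.0

    def test_nod_displaces_cortex_but_not_cfov(self):
        nod = make_rigid([5, 0, 0, 0, 0, 0])
        assert motion_magnitude(nod, FRONTAL_CORTEX) > 0
        assert motion_magnitude(nod, CFOV) == 0.0


class TestFromMatrix:
    def test_rejects_reflection(self):
        m = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="determinant"):
            from_matrix(m)

    def test_rejects_bad_bottom_row(self):
        m = np.eye(4)
        m[3, 0] = 1e-3
        with pytest.raises(ValueError, match="bottom row"):
            from_matrix(m)

    def test_gimbal_lock_round_trips(self):
        t = make_rigid([25, 90, -40, 1, 2, 3])
        back = from_matrix(t.matrix)
        assert np.allclose(back.matrix, t.matrix, atol=1e-8)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(params_strategy)
def test_rigid_invariants_hold_for_random_params(params):
    """Orthonormal rotation, exact bottom row, params regenerate the matrix."""
    t = make_rigid(params)
    r = t.rotation
    assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)
    assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
    assert np.array_equal(t.matrix[3], [0, 0, 0, 1])
    regen = make_rigid(t.params)
    assert np.allclose(regen.matrix, t.matrix, atol=1e-9)
    # operations preserve the invariants
    for derived in (invert(t), compose(t, t)):
        rr = derived.rotation
        assert np.allclose(rr @ rr.T, np.eye(3), atol=1e-9)
        assert np.array_equal(derived.matrix[3], [0, 0, 0, 1])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(params_strategy, params_strategy)
def test_params_extraction_round_trips_through_matrix(p, q):
    """from_matrix(compose) reproduces the matrix product exactly enough."""
    prod = compose(make_rigid(p), make_rigid(q))
    assert np.allclose(prod.matrix, make_rigid(p).matrix @ make_rigid(q).matrix, atol=1e-9)


def test_displacement_triangle_inequality_over_random_pairs():
    """|T_a T_b x - x| <= |T_a y - y| + |T_b x - x| with y = T_b x."""
    rng = np.random.default_rng(42)
    ref = FRONTAL_CORTEX
    for _ in range(1000):
        a = make_rigid(np.concatenate([rng.uniform(-30, 30, 3), rng.uniform(-20, 20, 3)]))
        b = make_rigid(np.concatenate([rng.uniform(-30, 30, 3), rng.uniform(-20, 20, 3)]))
        displaced = ReferencePoint("displaced", apply_to_point(b, ref.coords))
        lhs = motion_magnitude(compose(a, b), ref)
        rhs = motion_magnitude(a, displaced) + motion_magnitude(b, ref)
        assert lhs <= rhs + 1e-9
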