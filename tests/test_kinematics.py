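"""Deformation-gradient construction, invariants, and the active split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myomech import (active_decomposition, basic_invariants, build_fiber_frame,
                     deformation_state, fiber_frame_e3, generalized_invariants,
                     loadcase_deformation)
from myomech.kinematics import (LOAD_CASES, LoadCaseSpec,
                                active_stretch_tensor, structural_mix)

from .conftest import random_isochoric_F

stretches = st.floats(0.6, 1.6)


class TestFiberFrame:
    def test_axis_aligned_structural_tensor(self):
        f = build_fiber_frame((0.0, 0.0, 1.0))
        expected = np.zeros((3, 3))
        expected[2, 2] = 1.0
        np.testing.assert_allclose(f.M, expected)

    def test_scaling_invariance(self):
        np.testing.assert_allclose(build_fiber_frame((0, 0, 2.0)).M,
                                   build_fiber_frame((0, 0, 1.0)).M)

    def test_oblique_direction_idempotent_unit_trace(self):
        f = build_fiber_frame(np.array([1.0, 1.0, 0.0]) / np.sqrt(2))
        assert np.isclose(np.trace(f.M), 1.0)
        np.testing.assert_allclose(f.M @ f.M, f.M, atol=1e-15)
        np.testing.assert_allclose(f.M, f.M.T)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            build_fiber_frame((0.0, 0.0, 0.0))


class TestLoadCases:
    def test_reference_state(self):
        d = loadcase_deformation(mode="UTCAF", magnitude=1.0)
        np.testing.assert_allclose(d.F, np.eye(3))

    @pytest.mark.parametrize("mode", LOAD_CASES)
    @pytest.mark.parametrize("mag", [0.7, 0.95, 1.2, 1.45])
    def test_unit_determinant(self, mode, mag):
        mag = 0.3 if mode == "SAF" else mag
        d = loadcase_deformation(mode=mode, magnitude=mag)
        assert np.isclose(d.J, 1.0, atol=1e-14)

    def test_isometric_fiber_modes(self):
        # PSTIF holds the fiber; SAF shears without fiber stretch
        assert np.isclose(loadcase_deformation(mode="PSTIF", magnitude=1.2).lam, 1.0)
        d = loadcase_deformation(mode="SAF", magnitude=0.3)
        assert np.isclose(d.lam, 1.0)  # shear along the fiber leaves it unstretched
        assert np.isclose(d.J, 1.0)
        assert np.isclose(d.C[2, 1], 0.3)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            LoadCaseSpec("UTCAF", -0.5)
        with pytest.raises(ValueError):
            LoadCaseSpec("NOPE", 1.1)


class TestBasicInvariants:
    def test_reference_values(self, frame):
        inv = basic_invariants(deformation_state(np.eye(3), frame), frame)
        assert (inv.I1bar, inv.I4bar, inv.I5bar) == (3.0, 1.0, 1.0)
        assert inv.B1 == inv.B2 == 0.0

    def test_pure_fiber_stretch_has_no_shear(self, frame):
        d = loadcase_deformation(mode="UTCAF", magnitude=1.2)
        inv = basic_invariants(d, frame)
        assert np.isclose(inv.I4bar, 1.44)
        assert np.isclose(inv.B1, 0.0, atol=1e-12)
        assert np.isclose(inv.B2, 0.0, atol=1e-7)
        assert np.isclose(inv.theta, 1.0)

    def test_along_fiber_shear_activates_B1(self, frame):
        d = loadcase_deformation(mode="SAF", magnitude=0.2)
        inv = basic_invariants(d, frame)
        # oracle: direct tensor evaluation of the invariant definitions
        Cb = d.Cbar
        M = frame.M
        I4 = np.tensordot(Cb, M)
        I5 = np.tensordot(Cb @ Cb, M)
        assert inv.B1 > 0.0
        assert np.isclose(inv.B1, np.sqrt(I5 / I4**2 - 1.0))

    def test_transversely_symmetric_diagonal_stretches_shear_free(self, frame):
        # diag(mu, mu, lam) with det 1: theta == 1 exactly, B1 = B2 = 0
        for lam in (0.8, 1.1, 1.4):
            F = np.diag([lam**-0.5, lam**-0.5, lam])
            inv = basic_invariants(deformation_state(F, frame), frame)
            assert abs(inv.B1) < 1e-12 and abs(inv.B2) < 1e-7

    def test_transverse_asymmetry_activates_B2(self, frame):
        d = loadcase_deformation(mode="UTCTF", magnitude=1.2)
        inv = basic_invariants(d, frame)
        assert inv.B2 > 0.1

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_frame_invariance_under_rotation(self, seed):
        rng = np.random.default_rng(seed)
        frame = fiber_frame_e3()
        F = random_isochoric_F(rng)
        # random rotation via QR
        Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        a = basic_invariants(deformation_state(F, frame), frame)
        b = basic_invariants(deformation_state(Q @ F, frame), frame)
        for name in ("I1bar", "I4bar", "I5bar", "B1", "B2"):
            assert np.isclose(getattr(a, name), getattr(b, name),
                              rtol=1e-9, atol=1e-9)


class TestGeneralizedInvariants:
    def test_reference_passive(self, frame):
        gi = generalized_invariants(np.eye(3), 0.6388, 0.0, frame)
        assert np.isclose(gi.Itilde, 1.0)
        assert np.isclose(gi.Jtilde, 1.0)
        assert np.isclose(np.trace(gi.Ltilde), 1.0)

    def test_passive_limit_no_active_part(self, frame):
        rng = np.random.default_rng(0)
        F = random_isochoric_F(rng)
        gi = generalized_invariants(F.T @ F, 0.5, 0.0, frame)
        assert gi.Itilde_a == 0.0

    def test_uniaxial_closed_form(self, frame):
        lam, w0 = 1.2, 0.6388
        C = loadcase_deformation(mode="UTCAF", magnitude=lam).C
        gi = generalized_invariants(C, w0, 0.0, frame)
        expected = (w0 / 3.0) * (2.0 / lam + lam**2) + (1.0 - w0) * lam**2
        assert np.isclose(gi.Itilde_p, expected, rtol=1e-14)

    def test_activation_augments_fiber_contribution(self, frame):
        rng = np.random.default_rng(1)
        F = random_isochoric_F(rng)
        C = F.T @ F
        g0 = generalized_invariants(C, 0.6, 0.0, frame)
        g3 = generalized_invariants(C, 0.6, 0.3, frame)
        assert np.isclose(g3.Itilde - g0.Itilde, 0.3 * np.tensordot(C, frame.M))
        assert np.isclose(g3.Jtilde, g0.Jtilde)


class TestActiveDecomposition:
    def test_zero_activation_is_identity(self, frame):
        rng = np.random.default_rng(2)
        d = deformation_state(random_isochoric_F(rng), frame)
        ad = active_decomposition(d, 0.0, frame)
        np.testing.assert_allclose(ad.Fa, np.eye(3))
        np.testing.assert_allclose(ad.Ce, d.C)

    @pytest.mark.parametrize("wa", [0.1, 0.3, 0.7, 0.95])
    def test_active_part_volume_preserving(self, frame, wa):
        Fa = active_stretch_tensor(wa, frame)
        assert np.isclose(np.linalg.det(Fa), 1.0, rtol=1e-13)

    def test_round_trip(self, frame):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = deformation_state(random_isochoric_F(rng), frame)
            ad = active_decomposition(d, 0.4, frame)
            np.testing.assert_allclose(ad.Fe @ ad.Fa, d.F, rtol=1e-12)

    def test_reference_fiber_component(self, frame):
        d = deformation_state(np.eye(3), frame)
        ad = active_decomposition(d, 0.3, frame)
        assert np.isclose(ad.Ce[2, 2], (1.0 - 0.3) ** -2)

    def test_singular_activation_rejected(self, frame):
        with pytest.raises(ValueError):
            active_stretch_tensor(1.0, frame)


def test_structural_mix_unit_trace():
    L = structural_mix(0.37, fiber_frame_e3())
    assert np.isclose(np.trace(L), 1.0)
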