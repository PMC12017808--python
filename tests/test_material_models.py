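"""Constitutive stress evaluations: consistency, identities, objectivity."""

import dataclasses

import numpy as np
import pytest

from myomech import (Activation, elasticity_tensor, fiber_frame_e3,
                     fitted_params, get_model, pk2_stress, psi, push_forward)

from .conftest import FAMILY, MODELS, random_isochoric_F, sqrtm_spd


def fd_pk2(psifn, C, h=1e-6):
    """Oracle: S = 2 dpsi/dC by central differences on symmetric C."""
    S = np.zeros((3, 3))
    for k in range(3):
        for l in range(k, 3):
            dC = np.zeros((3, 3))
            dC[k, l] = dC[l, k] = h
            g = (psifn(C + dC) - psifn(C - dC)) / (2.0 * h)
            if k == l:
                S[k, k] = 2.0 * g
            else:
                S[k, l] = S[l, k] = g
    return S


class TestReferenceState:
    @pytest.mark.parametrize("name", MODELS)
    def test_zero_energy_and_stress_passive(self, name, frame, passive):
        res = pk2_stress(name, np.eye(3), frame, passive)
        assert res.psi == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.S, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.sigma, 0.0, atol=1e-10)

    @pytest.mark.parametrize("name", MODELS)
    def test_stress_result_push_forward_relations(self, name, frame, tetanic):
        F = np.diag([1.1**-0.5, 1.1**-0.5, 1.1])
        res = pk2_stress(name, F, frame, tetanic)
        np.testing.assert_allclose(res.S, res.S.T, atol=1e-10)
        np.testing.assert_allclose(res.P, F @ res.S, rtol=1e-12)
        np.testing.assert_allclose(
            res.sigma, res.P @ F.T / np.linalg.det(F), rtol=1e-12)


class TestPassiveFamilyIdentity:
    def test_energy_and_stress_coincide_without_activation(self, frame, passive):
        F = random_isochoric_F(np.random.default_rng(5))
        ref = pk2_stress("GASA", F, frame, passive)
        for name in ("ASA", "GASAM"):
            res = pk2_stress(name, F, frame, passive)
            assert res.psi == pytest.approx(ref.psi, rel=1e-12)
            np.testing.assert_allclose(res.S, ref.S, rtol=1e-10, atol=1e-12)

    def test_uniaxial_passive_energy_example(self, frame, passive):
        F = np.diag([1.2**-0.5, 1.2**-0.5, 1.2])
        vals = [psi(n, F, frame, passive) for n in FAMILY]
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[0] == pytest.approx(vals[2], rel=1e-12)


class TestEnergyConsistency:
    """S must be the derivative of the strain energy (tolerance 1e-6)."""

    def test_gasa_frozen_level(self, frame, tetanic):
        model = get_model("GASA")
        rng = np.random.default_rng(10)
        for _ in range(8):
            F = random_isochoric_F(rng)
            C = F.T @ F
            lam = float(np.sqrt(np.tensordot(C, frame.M)))
            wa = model.omega_a(lam, 1.0)

            def frozen_psi(C2):
                _, It, Jt, detC = model._stress_frozen(C2, frame, wa, False)
                return model._energy(It, Jt, detC, False)

            S = model.pk2(sqrtm_spd(C), frame, tetanic).S
            Sfd = fd_pk2(frozen_psi, C)
            assert np.max(np.abs(S - Sfd)) / np.max(np.abs(S)) < 1e-6

    @pytest.mark.parametrize("name", ["GASAM", "ASA"])
    def test_full_derivative_including_activation(self, name, frame, tetanic):
        model = get_model(name)
        rng = np.random.default_rng(11)
        for _ in range(5):
            F = random_isochoric_F(rng)
            C = F.T @ F
            S = model.pk2(sqrtm_spd(C), frame, tetanic).S
            Sfd = fd_pk2(lambda C2: model.psi(sqrtm_spd(C2), frame, tetanic), C)
            assert np.max(np.abs(S - Sfd)) / np.max(np.abs(S)) < 2e-6

    def test_ase_fiber_stress_matches_energy_quadrature(self, tetanic):
        model = get_model("ASE")
        h = 1e-6
        for lb in (0.85, 1.05, 1.25, 1.45):
            fd = (model.psi_fiber(lb + h, 1.0)
                  - model.psi_fiber(lb - h, 1.0)) / (2 * h)
            assert fd == pytest.approx(model.sigma_fiber_total(lb, 1.0) / lb,
                                       rel=1e-6)

    def test_ase_full_stress_at_shear_state(self, frame, tetanic):
        model = get_model("ASE")
        F = np.eye(3)
        F[2, 1], F[0, 1] = 0.25, 0.1
        C = F.T @ F
        S = model.pk2(sqrtm_spd(C), frame, tetanic).S
        Sfd = fd_pk2(lambda C2: model.psi(sqrtm_spd(C2), frame, tetanic), C)
        assert np.max(np.abs(S - Sfd)) / np.max(np.abs(S)) < 1e-6


class TestASERemarks:
    def test_pure_fiber_compression_stress_free_without_companion(self, frame, passive):
        """With vanishing shear and no matrix companion, passive compression
        along the fiber produces no stress."""
        params = dataclasses.replace(fitted_params("ASE"), mu=0.0)
        model = get_model("ASE", params)
        F = np.diag([0.9**-0.5, 0.9**-0.5, 0.9])
        res = model.pk2(F, frame, passive, incompressible=True)
        from myomech.response import nominal_response

        assert nominal_response(model, "UTCAF", 0.9, passive) == pytest.approx(0.0, abs=1e-10)

    def test_singular_shear_invariant_is_regular_on_stretch_path(self, frame, tetanic):
        # theta == 1 exactly along axisymmetric stretches: must not blow up
        for lam in (0.7, 1.0, 1.3):
            F = np.diag([lam**-0.5, lam**-0.5, lam])
            res = pk2_stress("ASE", F, frame, tetanic)
            assert np.all(np.isfinite(res.S))


class TestObjectivity:
    @pytest.mark.parametrize("name", MODELS)
    def test_rotation_invariance_of_pk2(self, name, frame, tetanic):
        rng = np.random.default_rng(12)
        F = random_isochoric_F(rng)
        Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        a = pk2_stress(name, F, frame, tetanic).S
        b = pk2_stress(name, Q @ F, frame, tetanic).S
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)

    def test_pure_rotation_pushes_forward(self, frame, tetanic):
        rng = np.random.default_rng(13)
        Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        S = pk2_stress("GASAM", np.eye(3), frame, tetanic).S
        P, sigma = push_forward(S, Q)
        np.testing.assert_allclose(sigma, Q @ S @ Q.T, rtol=1e-12)


class TestElasticityTensor:
    def test_directional_derivative(self, frame, passive):
        # moderate penalty keeps the finite-difference curvature benign
        params = dataclasses.replace(fitted_params("GASA"), kappa=10.0)
        model = get_model("GASA", params)
        rng = np.random.default_rng(14)
        F = random_isochoric_F(rng)
        C = F.T @ F
        CC, resid = elasticity_tensor(model, sqrtm_spd(C), frame, passive)
        dC = 1e-6 * rng.standard_normal((3, 3))
        dC = 0.5 * (dC + dC.T)
        S0 = model.pk2(sqrtm_spd(C), frame, passive).S
        S1 = model.pk2(sqrtm_spd(C + dC), frame, passive).S
        pred = 0.5 * np.einsum("ijkl,kl->ij", CC, dC)
        err = np.max(np.abs(S1 - S0 - pred)) / np.max(np.abs(S1 - S0))
        assert err < 1e-3
        assert resid < 1e-6

    @pytest.mark.parametrize("name", FAMILY)
    def test_major_symmetry_passive(self, name, frame, passive):
        model = get_model(name)
        F = np.diag([1.1, 1.1**-0.5, 1.1**-0.5])
        _, resid = elasticity_tensor(model, F, frame, passive)
        assert resid < 1e-6

    def test_isotropic_small_strain_constant_tangent(self, frame, passive):
        # omega0 = 1 removes the fiber preference: tangent nearly constant
        params = dataclasses.replace(fitted_params("GASA"), omega0=0.99,
                                     kappa=10.0)
        model = get_model("GASA", params)
        CC1, _ = elasticity_tensor(model, np.eye(3), frame, passive)
        F = np.eye(3) * 1.001
        F /= np.linalg.det(F) ** (1 / 3)
        CC2, _ = elasticity_tensor(model, F, frame, passive)
        assert np.max(np.abs(CC1 - CC2)) / np.max(np.abs(CC1)) < 0.05


class TestModelRegistry:
    def test_unknown_model(self):
        with pytest.raises(ValueError):
            get_model("NOPE")

    def test_omega_a_reported(self, frame, tetanic):
        res = pk2_stress("GASAM", np.eye(3), frame, tetanic)
        assert 0.0 < res.omega_a_used < 1.0
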