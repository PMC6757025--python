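"""Pointwise kinematics and stress-response checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrophyfem import mechanics
from atrophyfem.mechanics import (DomainError, InvertedElementError,
                                  LocalKinematics, MaterialParams,
                                  atrophy_stretch, cauchy_stress,
                                  elastic_decompose, material_tangent,
                                  second_pk_stress, von_mises)

MU, KAPPA = 2.07, 207.0


@pytest.mark.parametrize("upsilon, expected", [
    (1.0, 1.0),
    (0.5, 0.5 ** (1 / 3)),
    (0.8, 0.8 ** (1 / 3)),
])
def test_atrophy_stretch_is_cube_root(upsilon, expected):
    assert atrophy_stretch(upsilon) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
def test_atrophy_stretch_domain(bad):
    with pytest.raises(DomainError):
        atrophy_stretch(bad)


class TestElasticDecompose:
    def test_exact_cancellation(self):
        lam = 0.5 ** (1 / 3)
        kin = elastic_decompose(lam * np.eye(2), 0.5)
        assert np.allclose(kin.Fe, np.eye(2), atol=1e-14)
        assert kin.Je == pytest.approx(1.0, abs=1e-14)

    def test_identity_atrophy(self):
        F = np.array([[1.1, 0.02], [0.0, 0.95]])
        kin = elastic_decompose(F, 1.0)
        assert np.allclose(kin.Fe, F)
        assert kin.Je == pytest.approx(np.linalg.det(F))

    def test_undeformed_with_atrophy(self):
        kin = elastic_decompose(np.eye(2), 0.5)
        assert np.allclose(kin.Fe, 0.5 ** (-1 / 3) * np.eye(2))
        assert kin.Je == pytest.approx(0.5 ** (-2 / 3))

    def test_reconstruction_invariant(self, rng):
        F = np.eye(2) + 0.1 * rng.normal(size=(2, 2))
        kin = elastic_decompose(F, 0.73)
        assert np.allclose(kin.Fe * kin.lambda_a, F, atol=1e-12)

    def test_inverted_gradient_rejected(self):
        with pytest.raises(InvertedElementError):
            elastic_decompose(np.diag([1.0, -1.0]), 0.9)


class TestCauchyStress:
    def test_stress_free_reference(self):
        kin = elastic_decompose(np.eye(2), 1.0)
        s = cauchy_stress(kin, MU, KAPPA)
        assert np.allclose(s.sigma, 0.0, atol=1e-15)
        assert s.von_mises == 0.0

    def test_stress_free_atrophy(self):
        # pure atrophy deformation F = λa·I generates no stress
        for ups in (0.9, 0.5, 0.2):
            kin = elastic_decompose(ups ** (1 / 3) * np.eye(2), ups)
            s = cauchy_stress(kin, MU, KAPPA)
            assert np.allclose(s.sigma, 0.0, atol=1e-13)

    def test_small_shear_linear_limit(self):
        gamma = 1e-4
        Fe = np.array([[1.0, gamma], [0.0, 1.0]])
        kin = LocalKinematics(F=Fe, J=1.0, lambda_a=1.0, Fe=Fe, Je=1.0)
        s = cauchy_stress(kin, MU, KAPPA)
        assert s.sigma[0, 1] == pytest.approx(MU * gamma, abs=1e-8)

    def test_small_biaxial_linear_limit(self):
        eps = 1e-5
        Fe = (1 + eps) * np.eye(2)
        kin = LocalKinematics(F=Fe, J=(1 + eps) ** 2, lambda_a=1.0, Fe=Fe,
                              Je=(1 + eps) ** 2)
        s = cauchy_stress(kin, MU, KAPPA)
        expected = 2 * MU * eps + 2 * KAPPA * eps
        assert s.sigma[0, 0] == pytest.approx(expected, rel=1e-3)

    @settings(deadline=None, max_examples=40)
    @given(theta=st.floats(-np.pi, np.pi),
           seed=st.integers(0, 2**16))
    def test_objectivity(self, theta, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(2) + 0.2 * rng.normal(size=(2, 2))
        if np.linalg.det(F) <= 0.05:
            return
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        s1 = cauchy_stress(elastic_decompose(F, 0.8), MU, KAPPA)
        s2 = cauchy_stress(elastic_decompose(R @ F, 0.8), MU, KAPPA)
        assert np.allclose(s2.sigma, R @ s1.sigma @ R.T, atol=1e-10)
        assert s2.von_mises == pytest.approx(s1.von_mises, abs=1e-10)


class TestVonMises:
    def test_zero(self):
        assert von_mises(np.zeros((2, 2))) == 0.0

    def test_pure_shear(self):
        tau = 0.37
        assert von_mises(np.array([[0, tau], [tau, 0]])) == \
            pytest.approx(np.sqrt(3) * tau, rel=1e-12)

    def test_uniaxial(self):
        s = 1.234
        assert von_mises(np.diag([s, 0.0])) == pytest.approx(s, rel=1e-12)

    def test_in_plane_hydrostatic_convention(self):
        # with the zero-out-of-plane 3×3 embedding, an in-plane hydrostatic
        # state is NOT deviator-free: von Mises equals |p|
        p = 0.5
        assert von_mises(p * np.eye(2)) == pytest.approx(p, rel=1e-12)


class TestMaterialTangent:
    def test_linear_elastic_limit(self):
        kin = elastic_decompose(np.eye(2), 1.0)
        D = material_tangent(kin, MU, KAPPA)
        expected = np.array([[2 * MU + KAPPA, KAPPA, 0],
                             [KAPPA, 2 * MU + KAPPA, 0],
                             [0, 0, MU]])
        assert np.allclose(D, expected, atol=1e-10)

    def test_finite_difference_agreement(self, rng):
        F = np.eye(2) + 0.15 * rng.normal(size=(2, 2))
        assert np.linalg.det(F) > 0
        kin = elastic_decompose(F, 0.8)
        D = material_tangent(kin, MU, KAPPA)
        # FD of S with respect to E = (C − I)/2 through C perturbations
        C = kin.Fe.T @ kin.Fe
        h = 1e-6
        voigt = [(0, 0), (1, 1), (0, 1)]
        Dfd = np.zeros((3, 3))
        for b, (k, l) in enumerate(voigt):
            dC = np.zeros((2, 2))
            dC[k, l] = dC[l, k] = h  # dE with engineering shear = h on col 2
            Sp = _S_of_C(C + dC, MU, KAPPA)
            Sm = _S_of_C(C - dC, MU, KAPPA)
            # dE11 = dC11/2 but the engineering shear γ = C01 directly
            col = (Sp - Sm) / (2 * h) * (2.0 if k == l else 1.0)
            Dfd[:, b] = [col[0, 0], col[1, 1], col[0, 1]]
        assert np.allclose(D, Dfd, rtol=1e-5, atol=1e-8)

    def test_major_symmetry(self, rng):
        F = np.eye(2) + 0.3 * rng.normal(size=(2, 2))
        if np.linalg.det(F) <= 0.05:
            F = np.eye(2)
        D = material_tangent(elastic_decompose(F, 0.6), MU, KAPPA)
        assert np.allclose(D, D.T, atol=1e-10)


def _S_of_C(C, mu, kappa):
    Ci = np.linalg.inv(C)
    lnJe = 0.5 * np.log(np.linalg.det(C))
    return mu * (np.eye(2) - Ci) + kappa * lnJe * Ci


def test_second_pk_consistent_with_cauchy(rng):
    # sigma = (1/Je) Fe S Feᵀ must match the direct Cauchy formula
    F = np.eye(2) + 0.2 * rng.normal(size=(2, 2))
    kin = elastic_decompose(F, 0.85)
    S = second_pk_stress(kin, MU, KAPPA)
    sigma = kin.Fe @ S @ kin.Fe.T / kin.Je
    assert np.allclose(sigma, cauchy_stress(kin, MU, KAPPA).sigma, atol=1e-12)


def test_material_params_validation():
    with pytest.raises(DomainError):
        MaterialParams(mu_gray=-1.0)
    with pytest.raises(DomainError):
        MaterialParams(kappa_ratio=2.0)
    p = MaterialParams()
    assert p.mu_of("gray") == 2.07
    assert p.mu_of("white") == 1.15
    assert p.kappa_of("gray") == pytest.approx(207.0)


def test_batch_kernels_match_pointwise(rng):
    n = 16
    F = np.eye(2)[None] + 0.15 * rng.normal(size=(n, 2, 2))
    F = np.where(np.linalg.det(F)[:, None, None] > 0.1, F, np.eye(2)[None])
    ups = rng.uniform(0.5, 1.0, size=n)
    lam = ups ** (1 / 3)
    mu = np.full(n, MU)
    kappa = np.full(n, KAPPA)
    sig, vm = mechanics.batch_cauchy(F, lam, mu, kappa)
    for i in range(n):
        ref = cauchy_stress(elastic_decompose(F[i], ups[i]), MU, KAPPA)
        assert np.allclose(sig[i], ref.sigma, atol=1e-12)
        assert vm[i] == pytest.approx(ref.von_mises, abs=1e-12)
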