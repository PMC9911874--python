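"""Free energies, stresses, relaxation potentials and dissipation."""

import numpy as np
import pytest

from leafmech.constitutive import (
    MaterialParameters,
    MaterialState,
    dissipation_rate,
    driving_forces,
    evaluate,
    fiber_flow_direction,
    load_parameters,
    mandel_stresses,
    potential_gradients,
    psi_eq_ani,
    psi_eq_iso,
    psi_neq_ani,
    psi_neq_iso,
    relaxation_potentials,
    second_pk_stress,
    total_energy,
)
from leafmech.kinematics import (
    elastic_cg,
    pushforward_structure,
    random_rotation,
    random_spd,
    spd_inv,
    structure_tensor,
)

I3 = np.eye(3)


def neo_hooke_oracle(C, mu, lam):
    """Independent term-by-term evaluation of the matrix energy."""
    w = np.linalg.eigvalsh(C)
    J = w[0] * w[1] * w[2]
    return mu / 2 * (w.sum() - 3 - np.log(J)) + lam / 4 * (J - 1 - np.log(J))


def fiber_oracle(C, N, k1, k2):
    """Independent evaluation of the exponential fiber energy."""
    I4 = float(N @ C @ N) / float(N @ N)
    return k1 / (2 * k2) * (np.exp(k2 * (I4 - 1) ** 2) - 1)


def random_state(rng, spread=0.02):
    return MaterialState(random_spd(rng, spread), random_spd(rng, spread))


class TestEnergies:
    def test_zero_at_reference(self, petiole):
        assert psi_eq_iso(I3, petiole) == 0.0
        assert psi_neq_iso(I3, petiole) == 0.0
        M = petiole.structure
        assert psi_eq_ani(I3, M, petiole) == 0.0
        assert psi_neq_ani(I3, M, petiole) == 0.0

    def test_matrix_energy_against_oracle(self, petiole, rng):
        C = np.diag([1.0404, 0.9801, 0.9801])
        expected = neo_hooke_oracle(C, petiole.mu_eq_iso, petiole.lambda_eq_iso)
        assert np.isclose(psi_eq_iso(C, petiole), expected, rtol=1e-12)
        for _ in range(20):
            C = random_spd(rng, 0.1)
            assert np.isclose(
                psi_neq_iso(C, petiole),
                neo_hooke_oracle(C, petiole.mu_neq_iso, petiole.lambda_neq_iso),
                rtol=1e-12,
            )

    def test_matrix_energy_positive_away_from_reference(self, petiole, rng):
        for _ in range(100):
            C = random_spd(rng, 0.2)
            if not np.allclose(C, I3):
                assert psi_eq_iso(C, petiole) > 0.0

    def test_shared_kernel_between_eq_and_neq(self, petiole, rng):
        swapped = petiole.replace(
            mu_neq_iso=petiole.mu_eq_iso, lambda_neq_iso=petiole.lambda_eq_iso
        )
        C = random_spd(rng, 0.1)
        assert np.isclose(psi_neq_iso(C, swapped), psi_eq_iso(C, petiole), rtol=1e-14)

    def test_fiber_energy_against_oracle(self, petiole):
        C = np.diag([1.0404, 1.0, 1.0])
        N = np.array([1.0, 0.0, 0.0])
        expected = fiber_oracle(C, N, petiole.k1_eq_ani, petiole.k2_eq_ani)
        assert np.isclose(psi_eq_ani(C, structure_tensor(N), petiole), expected, rtol=1e-12)

    def test_fiber_energy_insensitive_to_cross_stretch(self, petiole):
        M = structure_tensor([1.0, 0.0, 0.0])
        assert psi_eq_ani(np.diag([1.0, 4.0, 1.0]), M, petiole) == 0.0

    def test_fiber_k2_zero_limit(self):
        # quadratic limit k1/2 (I4 - 1)^2, continuous as k2 -> 0
        p0 = dict(
            mu_eq_iso=1.0, lambda_eq_iso=1.0, mu_neq_iso=1.0, lambda_neq_iso=1.0,
            k1_neq_ani=1.0, k2_neq_ani=1.0, tau_iso=1.0, tau_ani=1.0,
        )
        M = structure_tensor([1.0, 0.0, 0.0])
        C = np.diag([1.1, 1.0, 1.0])
        exact = MaterialParameters(k1_eq_ani=2.0, k2_eq_ani=0.0, **p0)
        tiny = MaterialParameters(k1_eq_ani=2.0, k2_eq_ani=1e-9, **p0)
        assert np.isclose(psi_eq_ani(C, M, exact), 1.0 * 0.1**2)
        assert np.isclose(psi_eq_ani(C, M, exact), psi_eq_ani(C, M, tiny), rtol=1e-6)

    def test_nonpositive_det_rejected(self, petiole):
        with pytest.raises(ValueError):
            psi_eq_iso(np.diag([1.0, 1.0, -1.0]), petiole)


class TestSecondPKStress:
    def test_stress_free_reference(self, all_params):
        for p in all_params.values():
            S = second_pk_stress(I3, MaterialState.identity(), p)
            assert np.abs(S).max() == 0.0

    def test_matches_finite_difference_of_energy(self, petiole, rng):
        """S = 2 dPsi/dC with the internal state frozen (six components)."""
        h = 1e-6
        for _ in range(5):
            C = random_spd(rng, 0.05)
            st = random_state(rng)
            S = second_pk_stress(C, st, petiole)
            for i in range(3):
                for j in range(i, 3):
                    dC = np.zeros((3, 3))
                    dC[i, j] += h / 2
                    dC[j, i] += h / 2
                    fd = (total_energy(C + dC, st, petiole) - total_energy(C - dC, st, petiole)) / (2 * h)
                    assert np.isclose(2 * fd, S[i, j], rtol=1e-6, atol=1e-8 * np.abs(S).max())

    def test_pure_neo_hookean_closed_form(self, rng):
        p = MaterialParameters(
            mu_eq_iso=2.0, lambda_eq_iso=5.0, mu_neq_iso=0.0, lambda_neq_iso=0.0,
            k1_eq_ani=0.0, k2_eq_ani=0.1, k1_neq_ani=0.0, k2_neq_ani=0.1,
            tau_iso=1.0, tau_ani=1.0,
        )
        C = random_spd(rng, 0.1)
        expected = 2.0 * (I3 - spd_inv(C)) + 2.5 * (np.linalg.det(C) - 1.0) * spd_inv(C)
        assert np.allclose(second_pk_stress(C, MaterialState.identity(), p), expected, atol=1e-12)

    def test_objectivity(self, petiole, rng):
        """S lives in the reference configuration: invariant under QF."""
        F = I3 + 0.05 * rng.standard_normal((3, 3))
        st = random_state(rng)
        C = F.T @ F
        for _ in range(20):
            Q = random_rotation(rng)
            QF = Q @ F
            assert np.abs(
                second_pk_stress(QF.T @ QF, st, petiole) - second_pk_stress(C, st, petiole)
            ).max() < 1e-12

    def test_isotropic_limit_fiber_direction_irrelevant(self, petiole, rng):
        p0 = petiole.replace(k1_eq_ani=0.0, k1_neq_ani=0.0)
        C = random_spd(rng, 0.1)
        st = random_state(rng)
        ref = second_pk_stress(C, st, p0)
        worst = 0.0
        for _ in range(100):
            N = rng.standard_normal(3)
            p1 = p0.replace(fiber_direction=N)
            worst = max(worst, np.abs(second_pk_stress(C, st, p1) - ref).max())
        assert worst < 1e-12


class TestMandelStresses:
    def test_zero_when_fully_relaxed(self, petiole, rng):
        C = random_spd(rng, 0.05)
        Sigma, Gamma = mandel_stresses(C, MaterialState(C.copy(), C.copy()), petiole)
        assert np.abs(Sigma).max() < 1e-12
        assert np.abs(Gamma).max() < 1e-10

    def test_diagonal_coaxial_oracle(self, petiole):
        """Sigma from 2 C_e dPsi/dC_e evaluated per eigenvalue on diagonal data."""
        C = np.diag([1.05, 0.98, 1.01])
        Ci = np.diag([1.02, 0.99, 1.0])
        Sigma, _ = mandel_stresses(C, MaterialState(Ci, I3.copy()), petiole)
        ce = np.diagonal(C) / np.diagonal(Ci)
        J = np.prod(ce)
        mu, lam = petiole.mu_neq_iso, petiole.lambda_neq_iso
        expected = mu * (ce - 1.0) + lam / 2 * (J - 1.0)
        assert np.allclose(np.diagonal(Sigma), expected, rtol=1e-12)

    def test_symmetry_of_gamma(self, petiole, rng):
        worst = 0.0
        for _ in range(1000):
            C = random_spd(rng, 0.05)
            st = random_state(rng)
            _, Gamma = mandel_stresses(C, st, petiole)
            n = np.linalg.norm(Gamma)
            if n > 0:
                worst = max(worst, np.linalg.norm(Gamma - Gamma.T) / n)
        assert worst < 1e-10


class TestRelaxationPotentials:
    def test_zero_at_equilibrium(self, petiole):
        g_iso, g_ani = relaxation_potentials(np.zeros((3, 3)), np.zeros((3, 3)), I3, I3, petiole)
        assert g_iso == 0.0 and g_ani == 0.0

    def test_hand_computed_isochoric_volumetric_split(self):
        # Sigma = diag(3,0,0), mu_neq = 1, kappa_neq = 1:
        # dev = diag(2,-1,-1), tr(dev^2) = 6 -> 3; tr(Sigma)^2/9 = 1 -> total 4
        p = MaterialParameters(
            mu_eq_iso=1.0, lambda_eq_iso=0.0, mu_neq_iso=1.0, lambda_neq_iso=1.0 / 3.0,
            k1_eq_ani=0.0, k2_eq_ani=0.0, k1_neq_ani=1.0, k2_neq_ani=0.0,
            tau_iso=1.0, tau_ani=1.0,
        )
        assert np.isclose(p.kappa_neq_iso, 1.0)
        g_iso, _ = relaxation_potentials(np.diag([3.0, 0.0, 0.0]), np.zeros((3, 3)), I3, I3, p)
        assert np.isclose(g_iso, 4.0)

    def test_quadratic_homogeneity(self, petiole, rng):
        C = random_spd(rng, 0.05)
        st = random_state(rng)
        Sigma, Gamma = mandel_stresses(C, st, petiole)
        Ce = elastic_cg(C, st.Ci_ani)
        Mt = pushforward_structure(st.Ci_ani, petiole.structure)
        g1 = relaxation_potentials(Sigma, Gamma, Ce, Mt, petiole)
        g2 = relaxation_potentials(2 * Sigma, 2 * Gamma, Ce, Mt, petiole)
        assert np.allclose(np.array(g2), 4 * np.array(g1), rtol=1e-12)

    def test_gradients_match_finite_differences(self, petiole, rng):
        """Closed-form dg/dSigma and dg/dGamma vs central differences."""
        C = random_spd(rng, 0.05)
        st = random_state(rng)
        Sigma, Gamma = mandel_stresses(C, st, petiole)
        Ce = elastic_cg(C, st.Ci_ani)
        Mt = pushforward_structure(st.Ci_ani, petiole.structure)
        dg_iso, dg_ani = potential_gradients(Sigma, Gamma, Ce, Mt, petiole)
        h = 1e-6
        for i in range(3):
            for j in range(i, 3):
                dX = np.zeros((3, 3))
                dX[i, j] += h / 2
                dX[j, i] += h / 2
                fd_iso = (
                    relaxation_potentials(Sigma + dX, Gamma, Ce, Mt, petiole)[0]
                    - relaxation_potentials(Sigma - dX, Gamma, Ce, Mt, petiole)[0]
                ) / (2 * h)
                fd_ani = (
                    relaxation_potentials(Sigma, Gamma + dX, Ce, Mt, petiole)[1]
                    - relaxation_potentials(Sigma, Gamma - dX, Ce, Mt, petiole)[1]
                ) / (2 * h)
                # symmetric perturbation probes dg_ij + dg_ji
                factor = 1.0 if i == j else 1.0
                assert np.isclose(fd_iso * factor, dg_iso[i, j], rtol=1e-6, atol=1e-9)
                assert np.isclose(fd_ani * factor, dg_ani[i, j], rtol=1e-6, atol=1e-9)


class TestDrivingForcesAndDissipation:
    def test_equilibrium_is_stationary(self, petiole):
        f_iso, f_ani = driving_forces(I3, MaterialState.identity(), petiole)
        assert np.abs(f_iso).max() < 1e-14
        assert np.abs(f_ani).max() < 1e-14

    def test_identity_state_forces_equal_twice_gradient(self, petiole, rng):
        C = random_spd(rng, 0.05)
        st = MaterialState.identity()
        Sigma, Gamma = mandel_stresses(C, st, petiole)
        Mt = petiole.structure
        dg_iso, dg_ani = potential_gradients(Sigma, Gamma, C, Mt, petiole)
        f_iso, f_ani = driving_forces(C, st, petiole)
        assert np.allclose(f_iso, 2 * dg_iso, rtol=1e-12)
        assert np.allclose(f_ani, 2 * dg_ani, rtol=1e-12)

    def test_dissipation_two_routes_agree(self, petiole, rng):
        """Sigma : d_i + Gamma : d_i equals (2/tau) g by quadratic homogeneity."""
        for _ in range(100):
            C = random_spd(rng, 0.05)
            st = random_state(rng)
            Sigma, Gamma = mandel_stresses(C, st, petiole)
            Ce = elastic_cg(C, st.Ci_ani)
            Mt = pushforward_structure(st.Ci_ani, petiole.structure)
            g_iso, g_ani = relaxation_potentials(Sigma, Gamma, Ce, Mt, petiole)
            dg_iso, dg_ani = potential_gradients(Sigma, Gamma, Ce, Mt, petiole)
            direct = (
                float(np.tensordot(Sigma, dg_iso)) / petiole.tau_iso
                + float(np.tensordot(Gamma, dg_ani)) / petiole.tau_ani
            )
            via_g = dissipation_rate(Sigma, Gamma, g_iso, g_ani, petiole)
            assert np.isclose(direct, via_g, rtol=1e-12, atol=1e-18)

    def test_dissipation_nonnegative_randomized(self, all_params, rng):
        """Second-law check over randomized states and all parameter sets."""
        for p in all_params.values():
            for _ in range(500):
                C = random_spd(rng, 0.1)
                st = random_state(rng, 0.05)
                assert evaluate(C, st, p).dissipation_rate >= -1e-10


class TestParameterHandling:
    def test_shipped_sets_load_and_validate(self, all_params):
        for p in all_params.values():
            assert p.tau_iso > 0 and p.tau_ani > 0
            assert np.isclose(np.linalg.norm(p.fiber_direction), 1.0)

    def test_inverse_rate_keys_convert(self):
        p = load_parameters("venation_tension")
        assert np.isclose(p.tau_iso, 1.0 / 0.0004)
        assert np.isclose(p.tau_ani, 1.0 / 0.0566)

    def test_negative_modulus_rejected(self, petiole):
        with pytest.raises(ValueError):
            petiole.replace(mu_eq_iso=-1.0)

    def test_roundtrip_dict(self, petiole):
        q = MaterialParameters.from_dict(petiole.to_dict())
        assert q.to_dict() == petiole.to_dict()
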