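import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from excitoncd import constants as const
from excitoncd.chromo_params import MonopoleSet, ParameterError
from excitoncd.matrix_engine import (
    ContractViolation,
    ExcitonSystem,
    Hamiltonian,
    OverlapError,
    build_hamiltonian,
    compute_states,
    coulomb_coupling,
    diagonalize,
    rotational_strengths,
)
from excitoncd.synthetic_data import (
    DimerSpec,
    make_helical_array,
    make_twisted_dimer,
    mirror_system,
    synthetic_chromophore,
    transform_system,
)


def _point_pair(center, direction, mu_D, spacing=0.1):
    center = np.asarray(center, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    q = mu_D * const.DEBYE_TO_E_ANGSTROM / spacing
    return MonopoleSet(
        charges=np.array([q, -q]),
        positions=np.array([center + 0.5 * spacing * d, center - 0.5 * spacing * d]),
    )


def dipole_dipole_cm1(mu1_D, mu2_D, r12_A, eps=1.0):
    """Independent closed form: V = C (μ₁·μ₂ − 3(μ₁·R̂)(μ₂·R̂))/R³."""
    m1 = np.asarray(mu1_D) * const.DEBYE_TO_E_ANGSTROM
    m2 = np.asarray(mu2_D) * const.DEBYE_TO_E_ANGSTROM
    r = np.asarray(r12_A, float)
    R = np.linalg.norm(r)
    rh = r / R
    return (
        const.COULOMB_CM1_PER_E2_ANGSTROM
        / eps
        * (m1 @ m2 - 3 * (m1 @ rh) * (m2 @ rh))
        / R**3
    )


class TestCoulombCoupling:
    def test_decays_to_zero_at_huge_distance(self):
        a = _point_pair([0, 0, 0], [1, 0, 0], 4.0)
        b = _point_pair([0, 0, 1e6], [1, 0, 0], 4.0)
        assert abs(coulomb_coupling(a, b)) < 1e-6

    @pytest.mark.parametrize("geometry", ["parallel_perp", "collinear", "oblique"])
    def test_matches_point_dipole_formula_at_20A(self, geometry):
        if geometry == "parallel_perp":
            d1 = d2 = [1, 0, 0]
            sep = [0, 0, 20.0]
        elif geometry == "collinear":
            d1 = d2 = [0, 0, 1]
            sep = [0, 0, 20.0]
        else:
            d1, d2, sep = [1, 0, 0], [0.3, 0.8, 0.52], [3.0, 4.0, 19.0]
        a = _point_pair([0, 0, 0], d1, 4.0)
        b = _point_pair(sep, d2, 2.5)
        expected = dipole_dipole_cm1(
            4.0 * np.asarray(d1) / np.linalg.norm(d1),
            2.5 * np.asarray(d2) / np.linalg.norm(d2),
            sep,
        )
        got = coulomb_coupling(a, b)
        assert got == pytest.approx(expected, rel=0.01)

    def test_symmetry_and_dielectric_scaling(self):
        a = _point_pair([0, 0, 0], [1, 0, 0], 4.0)
        b = _point_pair([2, 3, 11.0], [0, 1, 0], 2.0)
        v = coulomb_coupling(a, b, 1.0)
        # symmetric up to summation order (the coupling is a small difference
        # of large q/r terms, so ~1e-10 relative is the fp floor here)
        assert coulomb_coupling(b, a, 1.0) == pytest.approx(v, rel=1e-9)
        assert coulomb_coupling(a, b, 2.0) == pytest.approx(v / 2, rel=1e-12)

    def test_overlapping_sets_rejected(self):
        a = _point_pair([0, 0, 0], [1, 0, 0], 4.0)
        b = _point_pair([0.3, 0, 0], [1, 0, 0], 4.0)
        with pytest.raises(OverlapError):
            coulomb_coupling(a, b)


class TestBuildHamiltonian:
    def test_single_group_is_diagonal(self):
        g = synthetic_chromophore([0, 0, 0], [4.0, 0, 0], 35000.0)
        H = build_hamiltonian(ExcitonSystem([g]), static_field=True)
        assert H.matrix.shape == (1, 1)
        assert H.matrix[0, 0] == pytest.approx(35000.0)

    def test_dimer_matrix_assembled_from_coupling(self):
        system, _ = make_twisted_dimer(DimerSpec(twist_deg=60.0))
        g1, g2 = system.placed
        v = coulomb_coupling(
            g1.transitions[0].monopoles, g2.transitions[0].monopoles
        )
        H = build_hamiltonian(system)
        expected = np.array([[35000.0, v], [v, 35000.0]])
        assert np.allclose(H.matrix, expected, atol=1e-9)

    def test_brute_force_oracle_small_systems(self):
        """H must equal an independent triple-loop over all monopole pairs."""
        system = make_helical_array(n_groups=4, rise_A=6.0, twist_deg=50.0,
                                    monopole_spacing_A=0.1)
        H = build_hamiltonian(system).matrix
        basis = system.basis
        n = len(basis)
        ref = np.zeros((n, n))
        C = const.COULOMB_CM1_PER_E2_ANGSTROM
        for x in range(n):
            i, a = basis[x]
            ref[x, x] = system.placed[i].transition(a).wavenumber_cm1
            for y in range(n):
                if x == y:
                    continue
                j, b = basis[y]
                if i == j:
                    continue  # no cross densities in this synthetic system
                ma = system.placed[i].transition(a).monopoles
                mb = system.placed[j].transition(b).monopoles
                s = 0.0
                for qa, pa in zip(ma.charges, ma.positions):
                    for qb, pb in zip(mb.charges, mb.positions):
                        s += qa * qb / np.linalg.norm(pa - pb)
                ref[x, y] = C * s
        assert np.allclose(H, ref, rtol=0.0, atol=1e-9)

    def test_symmetry_invariant(self):
        system = make_helical_array(n_groups=5)
        H = build_hamiltonian(system).matrix
        assert np.allclose(H, H.T, atol=1e-9)

    def test_static_field_requires_cross_monopoles(self):
        import dataclasses

        g1 = synthetic_chromophore([0, 0, 0], [4.0, 0, 0], 35000.0)
        second = dataclasses.replace(g1.transitions[0], label="t2",
                                     wavenumber_cm1=36000.0)
        g1 = dataclasses.replace(g1, transitions=(g1.transitions[0], second))
        g2 = synthetic_chromophore([0, 0, 12.0], [0, 4.0, 0], 35000.0)
        # give the partner a permanent density so the static field is nonzero
        g2 = dataclasses.replace(
            g2,
            permanent_ground=MonopoleSet(
                np.array([0.3, -0.3]),
                np.array([[0.0, 0.0, 11.5], [0.0, 0.0, 12.5]]),
                "PERMANENT",
            ),
        )
        with pytest.raises(ParameterError, match="cross"):
            build_hamiltonian(ExcitonSystem([g1, g2]), static_field=True)
        H = build_hamiltonian(ExcitonSystem([g1, g2]), static_field=False)
        assert H.matrix[0, 1] == 0.0  # same-group element vanishes


class TestDiagonalize:
    def test_diagonal_matrix(self):
        H = Hamiltonian(np.diag([1.0, 3.0, 2.0]), basis=[(0, "a"), (1, "a"), (2, "a")])
        states = diagonalize(H)
        assert [s.wavenumber_cm1 for s in states] == [1.0, 2.0, 3.0]
        C = np.array([s.coefficients for s in states]).T
        assert np.allclose(np.abs(C), np.eye(3)[:, [0, 2, 1]])

    def test_dimer_closed_form(self):
        nu0, v = 35000.0, 120.0
        H = Hamiltonian(np.array([[nu0, v], [v, nu0]]), basis=[(0, "a"), (1, "a")])
        states = diagonalize(H)
        assert states[0].wavenumber_cm1 == pytest.approx(nu0 - v)
        assert states[1].wavenumber_cm1 == pytest.approx(nu0 + v)
        assert np.allclose(
            np.abs(states[0].coefficients), [1 / math.sqrt(2)] * 2
        )
        # sign gauge: first nonzero coefficient positive
        for s in states:
            nz = s.coefficients[np.abs(s.coefficients) > 1e-12]
            assert nz[0] > 0

    def test_random_20x20_reconstruction_and_trace(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(20, 20))
        H = Hamiltonian((A + A.T) / 2 + np.diag(np.full(20, 100.0)),
                        basis=[(i, "a") for i in range(20)])
        states = diagonalize(H)
        C = np.array([s.coefficients for s in states]).T
        lam = np.array([s.wavenumber_cm1 for s in states])
        assert np.linalg.norm(C @ np.diag(lam) @ C.T - H.matrix) <= 1e-8 * np.linalg.norm(H.matrix)
        assert np.allclose(C.T @ C, np.eye(20), atol=1e-8)
        assert np.sum(lam) == pytest.approx(np.trace(H.matrix), rel=1e-6)

    def test_rejects_non_symmetric(self):
        with pytest.raises(ContractViolation):
            Hamiltonian(np.array([[1.0, 2.0], [0.0, 1.0]]), basis=[(0, "a"), (1, "a")])


class TestRotationalStrengths:
    def test_achiral_single_chromophore_has_zero_R(self):
        g = synthetic_chromophore([3.0, -2.0, 7.0], [4.0, 0, 0], 35000.0)
        _, states = compute_states(ExcitonSystem([g]))
        assert states[0].rotational_strength_1e40cgs == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("twist", [30.0, 60.0, 120.0, 150.0])
    def test_dimer_couplet_matches_closed_form(self, twist):
        system, ana = make_twisted_dimer(DimerSpec(twist_deg=twist))
        _, states = compute_states(system)
        assert states[0].wavenumber_cm1 == pytest.approx(ana["nu_low"], rel=1e-6)
        assert states[1].wavenumber_cm1 == pytest.approx(ana["nu_high"], rel=1e-6)
        assert states[0].rotational_strength_1e40cgs == pytest.approx(
            ana["R_low"], rel=1e-6
        )
        assert states[1].rotational_strength_1e40cgs == pytest.approx(
            ana["R_high"], rel=1e-6
        )
        # equal magnitude, opposite sign
        assert states[0].rotational_strength_1e40cgs == pytest.approx(
            -states[1].rotational_strength_1e40cgs, rel=1e-9
        )

    def test_sum_rule_achiral_groups(self):
        system = make_helical_array(n_groups=6, rise_A=5.0, twist_deg=40.0)
        _, states = compute_states(system)
        rs = np.array([s.rotational_strength_1e40cgs for s in states])
        assert abs(rs.sum()) <= 1e-8 * np.max(np.abs(rs))

    def test_sum_rule_with_intrinsic_magnetic_moments(self):
        g1 = synthetic_chromophore(
            [0, 0, 0], [4.0, 0, 0], 35000.0, magnetic_dipole_muB=[0.3, 0.1, 0.0]
        )
        g2 = synthetic_chromophore(
            [0, 4.0, 9.0], [0, 3.0, 1.0], 36000.0, magnetic_dipole_muB=[0, 0, 0.5]
        )
        system = ExcitonSystem([g1, g2])
        intrinsic = sum(
            const.DEBYE_BOHR_MAGNETON_TO_1E40_CGS
            * float(t.electric_dipole_D @ t.magnetic_dipole_muB)
            for g in system.placed
            for t in g.transitions
        )
        _, states = compute_states(system)
        total = sum(s.rotational_strength_1e40cgs for s in states)
        assert total == pytest.approx(intrinsic, abs=1e-8 * max(1.0, abs(intrinsic)))

    @pytest.mark.parametrize("variant", ["local_mean", "eigenstate"])
    def test_origin_independence(self, variant):
        system, _ = make_twisted_dimer(DimerSpec(twist_deg=60.0))
        H, states = compute_states(system, positional_frequency=variant)
        r0 = np.array([s.rotational_strength_1e40cgs for s in states])
        for shift in ([1.0, -2.0, 0.5], [1e6, 0, 0], [0, 1e6, 1e6]):
            moved = transform_system(system, np.eye(3), np.asarray(shift, float))
            _, st2 = compute_states(moved, positional_frequency=variant)
            r1 = np.array([s.rotational_strength_1e40cgs for s in st2])
            assert np.allclose(r1, r0, rtol=1e-8, atol=1e-8 * np.max(np.abs(r0)))

    def test_rotation_invariance(self):
        system, _ = make_twisted_dimer(DimerSpec(twist_deg=60.0))
        _, states = compute_states(system)
        r0 = np.array([s.rotational_strength_1e40cgs for s in states])
        nu0 = np.array([s.wavenumber_cm1 for s in states])
        R = Rotation.from_euler("zxz", [33.0, 71.0, -14.0], degrees=True).as_matrix()
        rotated = transform_system(system, R, np.zeros(3))
        _, st2 = compute_states(rotated)
        assert np.allclose([s.wavenumber_cm1 for s in st2], nu0, rtol=1e-8)
        assert np.allclose(
            [s.rotational_strength_1e40cgs for s in st2], r0,
            rtol=1e-8, atol=1e-8 * np.max(np.abs(r0)),
        )

    @pytest.mark.parametrize(
        "normal", [(0, 0, 1.0), (1.0, 0, 0), (0.3, -0.7, 0.648)]
    )
    def test_mirror_antisymmetry(self, normal):
        system, _ = make_twisted_dimer(DimerSpec(twist_deg=60.0))
        _, states = compute_states(system)
        mirrored = mirror_system(system, plane_normal=normal,
                                 plane_point=(1.0, 2.0, 3.0))
        _, st2 = compute_states(mirrored)
        for a, b in zip(states, st2):
            assert b.wavenumber_cm1 == pytest.approx(a.wavenumber_cm1, rel=1e-10)
            assert b.rotational_strength_1e40cgs == pytest.approx(
                -a.rotational_strength_1e40cgs,
                abs=1e-8 * abs(a.rotational_strength_1e40cgs) + 1e-12,
            )

    def test_dipole_strength_sum_conserved(self):
        system = make_helical_array(n_groups=5, rise_A=5.5, twist_deg=70.0)
        _, states = compute_states(system)
        total_d = sum(s.dipole_strength_D2 for s in states)
        local = sum(
            float(t.electric_dipole_D @ t.electric_dipole_D)
            for g in system.placed
            for t in g.transitions
        )
        assert total_d == pytest.approx(local, rel=1e-6)
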