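import numpy as np
import pytest

import excitoncd as e
from excitoncd.matrix_engine import ExcitonSystem, compute_states
from excitoncd.synthetic_data import (
    DimerSpec,
    EnsembleSpec,
    jitter_structure,
    make_ensemble,
    make_helical_array,
    make_twisted_dimer,
    mirror_system,
    synthetic_chromophore,
    synthetic_hcaii_like_structure,
)


class TestTwistedDimer:
    @pytest.mark.parametrize("twist", [0.0, 180.0])
    def test_parallel_and_antiparallel_are_cd_silent(self, twist):
        system, ana = make_twisted_dimer(DimerSpec(twist_deg=twist))
        assert ana["R_plus"] == pytest.approx(0.0, abs=1e-12)
        _, states = compute_states(system)
        for s in states:
            assert s.rotational_strength_1e40cgs == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_twist_is_degenerate(self):
        _, ana = make_twisted_dimer(DimerSpec(twist_deg=90.0))
        assert ana["degenerate"]
        assert ana["V_cm1"] == pytest.approx(0.0, abs=1e-9)
        # the couplet is conservative in every geometry
        assert ana["R_plus"] + ana["R_minus"] == pytest.approx(0.0, abs=1e-12)

    def test_couplet_is_conservative(self):
        _, ana = make_twisted_dimer(DimerSpec(twist_deg=60.0))
        assert ana["R_plus"] == pytest.approx(-ana["R_minus"], rel=1e-12)
        assert ana["V_cm1"] != 0.0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DimerSpec(separation_A=0.01, monopole_spacing_A=0.02)
        with pytest.raises(ValueError):
            DimerSpec(dipole_D=0.0)


class TestEnsembles:
    def test_zero_jitter_reproduces_base(self):
        base, _ = make_twisted_dimer(DimerSpec())
        frames = make_ensemble(
            base, EnsembleSpec(sigma_translation_A=0.0, sigma_rotation_deg=0.0,
                               n_frames=3, seed=1)
        )
        for frame in frames:
            for p_f, p_b in zip(frame.placed, base.placed):
                assert np.allclose(p_f.group_origin, p_b.group_origin, atol=1e-12)
                assert np.allclose(
                    p_f.transitions[0].electric_dipole_D,
                    p_b.transitions[0].electric_dipole_D, atol=1e-12,
                )

    def test_seed_determinism(self):
        base, _ = make_twisted_dimer(DimerSpec())
        spec = EnsembleSpec(sigma_translation_A=0.4, sigma_rotation_deg=8.0,
                            n_frames=5, seed=42)
        f1 = make_ensemble(base, spec)
        f2 = make_ensemble(base, spec)
        for a, b in zip(f1, f2):
            for pa, pb in zip(a.placed, b.placed):
                assert np.allclose(pa.group_origin, pb.group_origin, atol=0)
        f3 = make_ensemble(base, EnsembleSpec(0.4, 8.0, 5, seed=43))
        assert not np.allclose(f1[0].placed[0].group_origin,
                               f3[0].placed[0].group_origin)

    def test_jitter_distance_statistics(self):
        """Mean pair distance over frames stays within 3 standard errors."""
        base, _ = make_twisted_dimer(DimerSpec(separation_A=10.0))
        sigma, n = 0.5, 200
        frames = make_ensemble(
            base, EnsembleSpec(sigma_translation_A=sigma, sigma_rotation_deg=0.0,
                               n_frames=n, seed=9)
        )
        dists = np.array(
            [
                np.linalg.norm(f.placed[0].group_origin - f.placed[1].group_origin)
                for f in frames
            ]
        )
        # difference of two iid N(0, σ²I) displacements → per-axis var 2σ²;
        # for R≫σ the distance is ≈ N(R, 2σ²) plus O(σ²/R) bias
        se = np.sqrt(2) * sigma / np.sqrt(n)
        assert abs(dists.mean() - 10.0) < 3 * se + 2 * sigma**2 / 10.0

    def test_structure_level_jitter_topology_and_determinism(self, hcaii_like):
        ens = jitter_structure(hcaii_like, 0.3, 5.0, 3, seed=5)
        assert ens.n_models == 3
        assert ens.models[0].topology() == ens.models[2].topology()
        ens2 = jitter_structure(hcaii_like, 0.3, 5.0, 3, seed=5)
        a = next(ens.models[1].residues()).atoms[0].xyz
        b = next(ens2.models[1].residues()).atoms[0].xyz
        assert np.allclose(a, b, atol=0)


class TestMirror:
    def test_double_reflection_is_identity(self):
        system, _ = make_twisted_dimer(DimerSpec(twist_deg=60.0))
        twice = mirror_system(mirror_system(system, (0, 1, 0), (0, 2.0, 0)),
                              (0, 1, 0), (0, 2.0, 0))
        for p0, p1 in zip(system.placed, twice.placed):
            assert np.allclose(p0.group_origin, p1.group_origin, atol=1e-12)
            assert np.allclose(
                p0.transitions[0].electric_dipole_D,
                p1.transitions[0].electric_dipole_D, atol=1e-12,
            )
            assert np.allclose(
                p0.transitions[0].magnetic_dipole_muB,
                p1.transitions[0].magnetic_dipole_muB, atol=1e-12,
            )

    def test_reflected_dimer_negates_rotational_strengths(self):
        system, _ = make_twisted_dimer(DimerSpec(twist_deg=60.0))
        _, st = compute_states(system)
        _, st_m = compute_states(mirror_system(system))
        for a, b in zip(st, st_m):
            assert b.rotational_strength_1e40cgs == pytest.approx(
                -a.rotational_strength_1e40cgs, rel=1e-9
            )

    def test_coplanar_system_is_cd_silent(self):
        """A system lying entirely in one plane equals its own mirror image,
        so every rotational strength must vanish."""
        g1 = synthetic_chromophore(
            [0, 0, 0], 4.0 * np.array([np.cos(0.5), 0.0, np.sin(0.5)]), 35000.0
        )
        g2 = synthetic_chromophore(
            [0, 0, 10.0], 4.0 * np.array([np.cos(1.2), 0.0, np.sin(1.2)]), 35000.0
        )
        _, states = compute_states(ExcitonSystem([g1, g2]))
        for s in states:
            assert s.rotational_strength_1e40cgs == pytest.approx(0.0, abs=1e-9)


class TestHelicalArray:
    def test_shape_and_sum_rule(self):
        system = make_helical_array(n_groups=6)
        assert system.n_basis == 6
        _, states = compute_states(system)
        rs = np.array([s.rotational_strength_1e40cgs for s in states])
        assert abs(rs.sum()) <= 1e-8 * np.abs(rs).max()


class TestSyntheticHcaiiLike:
    def test_census_and_composition(self):
        st = synthetic_hcaii_like_structure()
        comp = e.residue_composition(st)
        assert comp["TRP"] == 2.7
        assert comp["TYR"] == 3.1
        sites = e.detect_chromophores(st)
        trp = [s for s in sites if s.chromophore_type.value == "TRP_INDOLE"]
        tyr = [s for s in sites if s.chromophore_type.value == "TYR_PHENOL"]
        assert (len(trp), len(tyr)) == (7, 8)

    def test_tabulated_pair_distances(self):
        st = synthetic_hcaii_like_structure()
        by_num = {s.seqnum: s for s in e.detect_chromophores(st)}
        expected = {
            (5, 16): 5.4, (97, 245): 8.0, (192, 209): 10.4, (123, 128): 10.1,
            (191, 192): 8.6, (194, 209): 3.9, (88, 128): 7.8,
        }
        # template centroids are exact to the 1e-6 Å rounding of the shipped
        # parameter file
        for (a, b), d in expected.items():
            assert e.centroid_distance(by_num[a], by_num[b]) == pytest.approx(
                d, abs=1e-5
            )

    def test_seed_changes_orientations_not_distances(self):
        a = synthetic_hcaii_like_structure(seed=7)
        b = synthetic_hcaii_like_structure(seed=8)
        sa = {s.seqnum: s for s in e.detect_chromophores(a)}
        sb = {s.seqnum: s for s in e.detect_chromophores(b)}
        assert np.allclose(sa[5].centroid, sb[5].centroid, atol=1e-5)
        assert not np.allclose(
            sa[5].ring_atoms["CG"], sb[5].ring_atoms["CG"], atol=1e-6
        )
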