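"""Numerical core: superposition, TM-score, shape, SASA, interfaces."""

import math

import numpy as np
import pytest

import dockmap as dm
from dockmap import synth
from dockmap.errors import DegenerateInputError
from dockmap.geometry import SASA_POINTS, tm_d0, tm_from_distances
from dockmap.structio import AtomRecord, Chain, Residue, StructureModel


def _rand_rigid(seed):
    return synth.random_rigid_motion(np.random.default_rng(seed))


class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(size=(20, 3))
        tr, rmsd = dm.kabsch(P, P)
        assert rmsd < 1e-12
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_recovers_random_rotation(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(15, 3)) * 10
        R, t = synth.random_rigid_motion(rng)
        tr, rmsd = dm.kabsch(P, P @ R.T + t)
        assert rmsd < 1e-8
        assert np.abs(tr.rotation - R).max() < 1e-8
        assert np.abs(tr.translation - t).max() < 1e-8

    def test_mirror_gives_proper_rotation(self, rng):
        P = rng.normal(size=(25, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # reflection
        tr, rmsd = dm.kabsch(P, Q)
        assert np.isclose(np.linalg.det(tr.rotation), 1.0, atol=1e-8)
        assert rmsd > 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            dm.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateInputError):
            dm.kabsch(line, line)

    def test_orthonormality(self, rng):
        P = rng.normal(size=(30, 3))
        Q = rng.normal(size=(30, 3))
        tr, _ = dm.kabsch(P, Q)
        assert np.allclose(tr.rotation.T @ tr.rotation, np.eye(3), atol=1e-8)
        assert np.isclose(np.linalg.det(tr.rotation), 1.0, atol=1e-8)


class TestTMScore:
    def test_identical_full_pairing_is_one(self, rng):
        X = rng.normal(size=(100, 3)) * 8
        pairs = np.column_stack([np.arange(100), np.arange(100)])
        score, _ = dm.tm_score(pairs, X, X, 100)
        assert score == 1.0

    def test_half_coverage_at_zero_distance(self):
        # 50 of 100 residues paired at d = 0: score = 0.5
        assert tm_from_distances(np.zeros(50), 100) == 0.5

    def test_all_distances_at_d0(self):
        # every paired distance exactly d0 halves each term
        L = 100
        d0 = tm_d0(L)
        for k in (100, 60, 30):
            assert tm_from_distances(np.full(k, d0), L) == pytest.approx(0.5 * k / L)

    def test_d0_floor_and_domain(self):
        assert tm_d0(16) == 0.5  # formula would go negative; floored
        with pytest.raises(DegenerateInputError):
            tm_d0(15)

    def test_rigid_motion_invariance(self, rng):
        X = rng.normal(size=(80, 3)) * 10
        Y = X + rng.normal(size=X.shape)
        pairs = np.column_stack([np.arange(80), np.arange(80)])
        base, _ = dm.tm_score(pairs, X, Y, 80)
        for seed in range(5):
            R, t = _rand_rigid(seed)
            moved, _ = dm.tm_score(pairs, X @ R.T + t, Y, 80)
            assert abs(moved - base) < 1e-6


class TestShapeStats:
    def test_octahedron_isotropic(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        s = dm.shape_stats(pts)
        assert s.anisotropy == 1.0

    def test_uniform_ball_rg_ratio(self):
        rng = np.random.default_rng(42)
        n = 100_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = u * (rng.random(n) ** (1 / 3))[:, None]
        s = dm.shape_stats(pts)
        assert abs(s.rg_ratio - math.sqrt(3 / 5)) < 0.005
        assert s.rg_ratio < 0.8  # sits below the compactness filter

    def test_prolate_spheroid_anisotropic(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5000, 3)) * np.array([4.0, 1.0, 1.0])
        assert dm.shape_stats(pts).anisotropy > 1.5

    def test_anisotropy_at_least_one(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(rng.integers(4, 50), 3))
            assert dm.shape_stats(pts).anisotropy >= 1.0

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(60, 3)) * np.array([3.0, 1.5, 1.0])
        base = dm.shape_stats(pts)
        for seed in range(5):
            R, t = _rand_rigid(seed)
            s = dm.shape_stats(pts @ R.T + t)
            assert abs(s.rg_ratio - base.rg_ratio) < 1e-6
            assert abs(s.anisotropy - base.anisotropy) < 1e-6

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            dm.shape_stats(np.zeros((10, 3)))


class TestStructuralAlign:
    def test_self_alignment_exact(self, compact_chain):
        res = dm.structural_align(compact_chain, compact_chain)
        assert res.tm_score == 1.0
        assert res.rmsd < 1e-9
        assert res.pairs == [(i, i) for i in range(len(compact_chain))]
        assert res.seq_identity == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_perturbed_copy_high_score(self, compact_chain, seed):
        rng = np.random.default_rng(seed)
        ca = synth.perturb(compact_chain.ca_coords(), 0.5, rng)
        R, t = synth.random_rigid_motion(rng)
        moved = synth.chain_from_ca(ca @ R.T + t,
                                    synth.random_sequence(len(ca), rng), "Z")
        res = dm.structural_align(moved, compact_chain)
        assert res.tm_score > 0.9

    @pytest.mark.parametrize("seed", range(20))
    def test_random_coil_below_gate(self, compact_chain, seed):
        rng = np.random.default_rng(1000 + seed)
        coil = synth.chain_from_ca(synth.random_coil_ca(64, rng),
                                   synth.random_sequence(64, rng), "Z")
        res = dm.structural_align(coil, compact_chain)
        assert res.tm_score < 0.4

    def test_pairs_strictly_increasing(self, compact_chain, rng):
        ca = synth.perturb(compact_chain.ca_coords(), 1.0, rng)
        moved = synth.chain_from_ca(ca, synth.random_sequence(len(ca), rng), "Z")
        res = dm.structural_align(moved, compact_chain)
        a = np.array(res.pairs)
        assert np.all(np.diff(a[:, 0]) > 0) and np.all(np.diff(a[:, 1]) > 0)

    def test_too_short_rejected(self, compact_chain, rng):
        tiny = synth.chain_from_ca(synth.serpentine_ca(5),
                                   synth.random_sequence(5, rng), "Z")
        with pytest.raises(DegenerateInputError):
            dm.structural_align(tiny, compact_chain)


def _single_atom_model(element="C", n=1):
    atoms = [AtomRecord(1, "CA", "ALA", "A", 1, " ", 0, 0, 0, 1.0, element)]
    return StructureModel(chains=[Chain("A", [Residue("ALA", 1, atoms)])])


class TestSasa:
    def test_isolated_atom_sphere_area(self):
        areas = dm.sasa(_single_atom_model())
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert areas[("A", 1)] == pytest.approx(expected, rel=2.0 / SASA_POINTS + 1e-3)

    def test_buried_atom_in_cage(self):
        # central atom enclosed by a dense shell of neighbors
        rng = np.random.default_rng(0)
        u = rng.normal(size=(300, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        atoms = [AtomRecord(1, "CA", "ALA", "A", 1, " ", 0, 0, 0, 1.0, "C")]
        cage = [AtomRecord(i + 2, "CA", "ALA", "A", i + 2, " ",
                           *(u[i] * 3.0), 1.0, "C") for i in range(300)]
        model = StructureModel(chains=[Chain("A", [
            Residue("ALA", 1, atoms)] + [Residue("ALA", i + 2, [a])
                                         for i, a in enumerate(cage)])])
        areas = dm.sasa(model)
        assert areas[("A", 1)] < 1.0

    def test_probe_monotonicity_convex(self):
        areas1 = sum(dm.sasa(_single_atom_model(), probe=1.4).values())
        areas2 = sum(dm.sasa(_single_atom_model(), probe=2.8).values())
        assert areas2 > areas1

    def test_unknown_element_warns(self):
        with pytest.warns(UserWarning, match="unknown element"):
            dm.sasa(_single_atom_model(element="XX"))


class TestInterface:
    def test_separated_chains(self, complex_fixture):
        a, b = complex_fixture.model.chains
        far = b.transformed(np.eye(3), np.array([500.0, 0.0, 0.0]))
        rep = dm.interface_report(a, far)
        assert rep.interface_area == 0.0
        assert not rep.interface_residues_a and not rep.interface_residues_b
        assert rep.clash_count == 0

    def test_close_pair_is_clash(self, rng):
        a = synth.chain_from_ca(synth.serpentine_ca(8),
                                synth.random_sequence(8, rng), "A")
        b = a.transformed(np.eye(3), np.array([2.0, 0.0, 0.0]))
        b.label = "B"
        rep = dm.interface_report(a, b)
        assert rep.clash_count >= 1

    def test_matches_brute_force_scan(self, complex_fixture):
        a, b = complex_fixture.model.chains
        rep = dm.interface_report(a, b, contact_cutoff=5.0)
        res_a, res_b = set(), set()
        for ra in a.residues:
            for rb in b.residues:
                for aa in ra.atoms:
                    for ab in rb.atoms:
                        if np.linalg.norm(aa.coord - ab.coord) <= 5.0:
                            res_a.add(ra.number)
                            res_b.add(rb.number)
        assert rep.interface_residues_a == res_a
        assert rep.interface_residues_b == res_b

    def test_area_symmetric(self, complex_fixture):
        a, b = complex_fixture.model.chains
        r1 = dm.interface_report(a, b)
        r2 = dm.interface_report(b, a)
        assert r1.interface_area == pytest.approx(r2.interface_area, abs=1e-6)
        assert r1.interface_residues_a == r2.interface_residues_b

    def test_buried_area_positive_for_contact(self, complex_fixture):
        a, b = complex_fixture.model.chains
        rep = dm.interface_report(a, b)
        assert rep.interface_area > 50.0
        assert rep.clash_count == 0


class TestLargestInterface:
    def test_two_chain_input(self, complex_fixture):
        pair, rep = dm.largest_interface_pair(complex_fixture.model)
        assert pair == ("A", "B")
        assert rep.interface_area > 0

    def test_tetramer_engineered_interface(self):
        tet = synth.make_tetramer(seed=2)
        pair, rep = dm.largest_interface_pair(tet)
        # exhaustive oracle
        areas = {}
        for i in range(len(tet.chains)):
            for j in range(i + 1, len(tet.chains)):
                key = tuple(sorted((tet.chains[i].label, tet.chains[j].label)))
                areas[key] = dm.interface_report(tet.chains[i], tet.chains[j]).interface_area
        assert pair == max(sorted(areas), key=lambda k: areas[k])
        assert rep.interface_area == pytest.approx(max(areas.values()))

    def test_dispersed_chains_tie_rule(self, rng):
        base = synth.serpentine_ca(10)
        seq = synth.random_sequence(10, rng)
        chains = [synth.chain_from_ca(base + np.array([200.0 * k, 0, 0]), seq, lab)
                  for k, lab in enumerate("ABC")]
        pair, rep = dm.largest_interface_pair(StructureModel(chains=chains))
        assert pair == ("A", "B")
        assert rep.interface_area == 0.0

    def test_single_chain_rejected(self, compact_chain):
        with pytest.raises(ValueError):
            dm.largest_interface_pair(StructureModel(chains=[compact_chain]))
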