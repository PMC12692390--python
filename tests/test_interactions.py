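import numpy as np
import pytest

from switchscan.core import MissingAtomsError, Structure, Trajectory, SwitchscanError
from switchscan.interactions import (
    DistanceSeries,
    InteractionCriterion,
    detect_hbonds,
    detect_hydrophobic,
    detect_saltbridges,
    ligand_contact_fraction,
    lock_state_series,
    occupancy_from_distances,
    occupancy_matrix,
    pair_distance_series,
    scan_contacts,
)

from conftest import make_atom, random_rotation, random_toy_system
from oracles import (
    brute_hbonds,
    brute_hydrophobic,
    brute_min_distance,
    brute_saltbridges,
)


def _traj_of(structure, n_frames=1, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    coords = np.repeat(structure.coords[None], n_frames, axis=0)
    if jitter:
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    return Trajectory(structure, coords, np.arange(float(n_frames)) * 100.0)


class TestPairDistanceSeries:
    def test_saltbridge_metric_constructed_geometry(self, toy_saltbridge_structure):
        traj = _traj_of(toy_saltbridge_structure, n_frames=3)
        series = pair_distance_series(traj, ("A", 1), ("A", 3), "saltbridge")
        assert np.allclose(series.values, 3.5)

    def test_constant_series_from_repeated_frames(self, toy_saltbridge_structure):
        traj = _traj_of(toy_saltbridge_structure, n_frames=5)
        series = pair_distance_series(traj, ("A", 1), ("A", 3), "saltbridge")
        assert np.ptp(series.values) == 0.0

    def test_matches_bruteforce_min_over_selection(self):
        structure, traj = random_toy_system(seed=11, n_res=8, n_frames=10)
        # pick a basic/acidic pair present in the toy
        basic = acidic = None
        for res in structure.iter_residues():
            if res.res_name == "ARG" and basic is None:
                basic = res
            if res.res_name in ("ASP", "GLU") and acidic is None:
                acidic = res
        if basic is None or acidic is None:
            pytest.skip("random toy lacks a chargeable pair at this seed")
        series = pair_distance_series(traj, basic.key, acidic.key, "saltbridge")
        from switchscan.core import saltbridge_atoms
        _, aA = saltbridge_atoms(basic.res_name)
        _, aB = saltbridge_atoms(acidic.res_name)
        idxA = structure.residue_atom_indices(basic, aA)
        idxB = structure.residue_atom_indices(acidic, aB)
        expected = [brute_min_distance(traj.coords[f], idxA, idxB)
                    for f in range(traj.n_frames)]
        assert np.allclose(series.values, expected, atol=1e-12)

    def test_missing_sidechain_atoms_named(self, toy_saltbridge_structure):
        atoms = [a for a in toy_saltbridge_structure.atoms if a.name != "OD1"]
        atoms = [a for a in atoms if a.name != "OD2"]
        s = Structure(atoms)
        with pytest.raises(MissingAtomsError, match="ASP"):
            pair_distance_series(_traj_of(s), ("A", 1), ("A", 3), "saltbridge")


class TestOccupancy:
    def test_fraction_is_exact_count(self):
        series = DistanceSeries((("A", 1), ("A", 2), "saltbridge"),
                                [3.0, 3.0, 5.0, 6.0], [0., 1., 2., 3.])
        assert occupancy_from_distances(series, 4.0) == 0.5
        assert occupancy_from_distances(series, 10.0) == 1.0
        assert occupancy_from_distances(series, 1.0) == 0.0

    def test_empty_series_rejected(self):
        series = DistanceSeries((("A", 1), ("A", 2), "ca"), [], [])
        with pytest.raises(SwitchscanError):
            occupancy_from_distances(series, 4.0)

    def test_binomial_recovery_of_planted_probability(self):
        """900 frames of independent formation at p=0.82 estimate p within
        3 binomial SD."""
        rng = np.random.default_rng(42)
        p, n = 0.82, 900
        formed = rng.random(n) < p
        values = np.where(formed, 3.2, 9.0)
        series = DistanceSeries((("A", 1), ("A", 2), "saltbridge"),
                                values, np.arange(float(n)))
        est = occupancy_from_distances(series, 4.0)
        assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_lock_state_hysteresis_suppresses_chatter(self):
        # chattering around the cutoff should not flip the state
        values = np.array([3.0] * 20 + [5.0, 3.0] * 5 + [6.0] * 20)
        series = DistanceSeries((("A", 1), ("A", 2), "saltbridge"),
                                values, np.arange(float(values.size)))
        states = lock_state_series(series, cutoff=4.5, hysteresis=10)
        assert states[:30].all()          # stays formed through the chatter
        assert not states[-5:].any()      # eventually flips to broken


class TestDetectorOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_saltbridge_set_equality(self, seed):
        structure, traj = random_toy_system(seed=seed, n_res=12, n_frames=6)
        for f in range(traj.n_frames):
            ours = detect_saltbridges(traj.coords[f], structure)
            assert ours == brute_saltbridges(traj.coords[f], structure)

    @pytest.mark.parametrize("seed,with_h", [(0, False), (1, False), (2, True), (3, True)])
    def test_hbond_set_equality(self, seed, with_h):
        structure, traj = random_toy_system(seed=seed, n_res=10, n_frames=5,
                                            with_h=with_h)
        for f in range(traj.n_frames):
            ours = detect_hbonds(traj.coords[f], structure)
            assert ours == brute_hbonds(traj.coords[f], structure)

    @pytest.mark.parametrize("seed", range(5))
    def test_hydrophobic_set_equality(self, seed):
        structure, traj = random_toy_system(seed=seed, n_res=12, n_frames=6)
        for f in range(traj.n_frames):
            ours = detect_hydrophobic(traj.coords[f], structure)
            assert ours == brute_hydrophobic(traj.coords[f], structure)

    def test_hbond_distance_and_angle_examples(self):
        # Ser OG donor with H pointing at Asp OD1: detected at 2.9 Å
        def build(d):
            atoms = [
                make_atom(1, "N", 1, "SER", (0, 5, 0)),
                make_atom(2, "CA", 1, "SER", (1, 5, 0)),
                make_atom(3, "C", 1, "SER", (2, 5, 0)),
                make_atom(4, "O", 1, "SER", (2, 6, 5)),
                make_atom(5, "OG", 1, "SER", (0, 0, 0)),
                make_atom(6, "HG", 1, "SER", (1.0, 0, 0), element="H"),
                make_atom(7, "N", 3, "ASP", (d, 5, 0)),
                make_atom(8, "CA", 3, "ASP", (d + 1, 5, 0)),
                make_atom(9, "C", 3, "ASP", (d + 2, 5, 0)),
                make_atom(10, "O", 3, "ASP", (d + 2, 6, 5)),
                make_atom(11, "OD1", 3, "ASP", (d, 0, 0)),
                make_atom(12, "OD2", 3, "ASP", (d, -1.5, 0)),
            ]
            return Structure(atoms)

        near = build(2.9)
        bonds = detect_hbonds(near.coords, near)
        assert ((("A", 1), "OG"), (("A", 3), "OD1")) in bonds
        far = build(3.8)
        assert ((("A", 1), "OG"), (("A", 3), "OD1")) not in detect_hbonds(far.coords, far)

    def test_hydrophobic_cutoff_boundary(self):
        def build(d):
            atoms = [
                make_atom(1, "N", 1, "LEU", (0, 5, 0)),
                make_atom(2, "CA", 1, "LEU", (1, 5, 0)),
                make_atom(3, "C", 1, "LEU", (2, 5, 0)),
                make_atom(4, "O", 1, "LEU", (2, 6, 0)),
                make_atom(5, "CB", 1, "LEU", (0, 2, 0)),
                make_atom(6, "CD1", 1, "LEU", (0, 0, 0)),
                make_atom(7, "N", 3, "LEU", (d, 5, 0)),
                make_atom(8, "CA", 3, "LEU", (d + 1, 5, 0)),
                make_atom(9, "C", 3, "LEU", (d + 2, 5, 0)),
                make_atom(10, "O", 3, "LEU", (d + 2, 6, 0)),
                make_atom(11, "CB", 3, "LEU", (d, 2, 0)),
                make_atom(12, "CD1", 3, "LEU", (d, 0, 0)),
            ]
            return Structure(atoms)

        close = build(4.9)
        assert ((("A", 1)), (("A", 3))) in {
            tuple(p) for p in detect_hydrophobic(close.coords, close)
        } or ((("A", 1), ("A", 3))) in detect_hydrophobic(close.coords, close)
        apart = build(5.1)
        assert detect_hydrophobic(apart.coords, apart) == set()


class TestInvariances:
    def test_occupancy_invariant_under_frame_reordering(self):
        structure, traj = random_toy_system(seed=6, n_res=10, n_frames=8)
        crit = InteractionCriterion.default("hydrophobic")
        pairs = [(("A", 1), ("A", 4)), (("A", 1), ("A", 7))]
        pairs = [p for p in pairs
                 if all(structure.residue(*k).res_name in crit.nonpolar_set
                        for k in p)]
        if not pairs:
            pytest.skip("toy lacks nonpolar pairs at this seed")
        occ = occupancy_matrix(traj, pairs, crit, burn_in=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(traj.n_frames)
        shuffled = Trajectory(structure, traj.coords[perm], traj.times)
        occ2 = occupancy_matrix(shuffled, pairs, crit, burn_in=0)
        assert np.allclose(occ.occupancy, occ2.occupancy)

    def test_occupancy_invariant_under_rigid_motion(self):
        structure, traj = random_toy_system(seed=6, n_res=10, n_frames=6)
        rng = np.random.default_rng(1)
        R = random_rotation(rng)
        t = rng.normal(scale=20.0, size=3)
        moved = Trajectory(structure, traj.coords @ R.T + t, traj.times)
        for f in range(traj.n_frames):
            assert detect_saltbridges(traj.coords[f], structure) == \
                detect_saltbridges(moved.coords[f], structure)
            assert detect_hydrophobic(traj.coords[f], structure) == \
                detect_hydrophobic(moved.coords[f], structure)

    def test_pair_order_permutation_permutes_occupancies(self, toy_saltbridge_structure):
        traj = _traj_of(toy_saltbridge_structure, n_frames=4)
        crit = InteractionCriterion.default("saltbridge")
        pairs = [(("A", 1), ("A", 3))]
        occ = occupancy_matrix(traj, pairs + pairs[::-1], crit, burn_in=0)
        assert occ.occupancy[0] == occ.occupancy[1]


class TestScanContacts:
    @pytest.mark.parametrize("kind", ["hbond", "hydrophobic"])
    def test_scan_matches_frame_detectors(self, kind):
        """Whole-network occupancy equals counting per-frame detector hits."""
        structure, traj = random_toy_system(seed=13, n_res=10, n_frames=8)
        crit = InteractionCriterion.default(kind)
        occ = scan_contacts(traj, crit, burn_in=0)
        detector = detect_hbonds if kind == "hbond" else detect_hydrophobic
        counts = {}
        for f in range(traj.n_frames):
            found = detector(traj.coords[f], structure, crit)
            if kind == "hbond":
                found = {tuple(sorted((d[0], a[0]))) for d, a in found}
            for pair in found:
                counts[pair] = counts.get(pair, 0) + 1
        expected = {p: c / traj.n_frames for p, c in counts.items()}
        ours = {tuple(p): o for p, o in zip(occ.pairs, occ.occupancy) if o > 0}
        assert ours == pytest.approx(expected)


class TestLigandContacts:
    @pytest.fixture
    def ligand_system(self):
        atoms = [
            make_atom(1, "N", 1, "PHE", (0, 0, 0)),
            make_atom(2, "CA", 1, "PHE", (1.5, 0, 0)),
            make_atom(3, "C", 1, "PHE", (2.5, 1, 0)),
            make_atom(4, "O", 1, "PHE", (2.5, 2, 0)),
            make_atom(5, "CB", 1, "PHE", (1.5, -1.5, 0)),
            make_atom(6, "C1", 99, "LIG", (1.5, -4.5, 0)),  # 3.0 Å from CB
            make_atom(7, "C2", 99, "LIG", (2.5, -5.5, 0)),
        ]
        return Structure(atoms)

    def test_always_and_never_in_contact(self, ligand_system):
        traj = _traj_of(ligand_system, n_frames=6)
        assert ligand_contact_fraction(traj, ("A", 99), ("A", 1), 4.0) == 1.0
        far = ligand_system.coords.copy()
        far[5:] += [0, -10, 0]
        traj_far = Trajectory(ligand_system, np.repeat(far[None], 6, axis=0),
                              np.arange(6.0))
        assert ligand_contact_fraction(traj_far, ("A", 99), ("A", 1), 4.0) == 0.0

    def test_missing_ligand_is_an_error(self, ligand_system):
        traj = _traj_of(ligand_system)
        with pytest.raises(SwitchscanError, match="ligand"):
            ligand_contact_fraction(traj, ("A", 42), ("A", 1), 4.0)

    def test_planted_contact_probability_recovered(self, ligand_system):
        """Two-state ligand position with P(contact)=0.6 recovered within
        3 binomial SD."""
        rng = np.random.default_rng(3)
        n, p = 600, 0.6
        coords = np.repeat(ligand_system.coords[None], n, axis=0)
        away = rng.random(n) >= p
        coords[away, 5:, 1] -= 10.0
        traj = Trajectory(ligand_system, coords, np.arange(float(n)))
        est = ligand_contact_fraction(traj, ("A", 99), ("A", 1), 4.0)
        assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n)
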