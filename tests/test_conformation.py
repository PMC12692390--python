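import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchscan.core import Structure, SwitchscanError, Trajectory
from switchscan.conformation import (
    assign_ss,
    ca_pca,
    circular_mean_deg,
    circular_variance,
    dihedral,
    ev_displacements,
    phi_psi,
    radius_of_gyration,
    rmsd_series,
    ss_fractions,
    superpose,
)
from switchscan.synth import ALPHA_PHI_PSI, PI_PHI_PSI, build_backbone

from conftest import helix_structure, make_atom, random_rotation


def _traj(structure, coords, dt=100.0):
    return Trajectory(structure, coords,
                      np.arange(float(len(coords))) * dt)


class TestSuperposition:
    def test_self_superposition_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        sp = superpose(X, X)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(sp.translation, 0, atol=1e-10)
        assert sp.rmsd <= 1e-10

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1]])
        Y = X @ R.T + np.array([1.0, 2.0, 3.0])
        sp = superpose(Y, X)
        assert sp.rmsd <= 1e-8
        assert np.allclose(sp.apply(Y), X, atol=1e-8)
        assert np.isclose(np.linalg.det(sp.rotation), 1.0)

    def test_collinear_selection_rejected(self):
        X = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(SwitchscanError, match="collinear|degenerate"):
            superpose(X, X + 1.0)

    def test_displaced_atom_rmsd_matches_direct_optimizer(self):
        """One atom displaced among N fixed: our analytic Kabsch RMSD must
        match a numerical minimisation over rotations+translations."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        X = rng.normal(scale=5.0, size=(10, 3))
        Y = X.copy()
        Y[3] += np.array([2.0, -1.0, 0.5])

        def cost(params):
            R = Rotation.from_rotvec(params[:3]).as_matrix()
            t = params[3:]
            return np.sqrt((((Y @ R.T + t) - X) ** 2).sum() / len(X))

        best = min(
            (minimize(cost, np.concatenate([rng.normal(scale=0.1, size=3),
                                            rng.normal(scale=0.1, size=3)]),
                      method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
             for _ in range(3)),
            key=lambda r: r.fun,
        )
        ours = superpose(Y, X).rmsd
        assert ours == pytest.approx(best.fun, abs=1e-6)
        assert ours <= best.fun + 1e-9  # ours is the true minimum


class TestRmsdAndRg:
    def test_rigid_copies_have_zero_rmsd(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        s = Structure([make_atom(i + 1, "CA", i + 1, "GLY", X[i])
                       for i in range(12)])
        frames = []
        for _ in range(5):
            R = random_rotation(rng)
            frames.append(X @ R.T + rng.normal(scale=10, size=3))
        traj = _traj(s, np.stack(frames))
        assert np.all(rmsd_series(traj, X) <= 1e-8)

    def test_gaussian_noise_rmsd_scaling(self):
        """Per-atom isotropic noise sigma gives mean RMSD ≈ sigma·sqrt(3)
        for large N (superposition correction is O(1/N))."""
        rng = np.random.default_rng(4)
        N, sigma = 400, 0.5
        X = rng.normal(scale=10.0, size=(N, 3))
        s = Structure([make_atom(i + 1, "CA", i + 1, "GLY", X[i])
                       for i in range(N)])
        frames = X[None] + rng.normal(scale=sigma, size=(20, N, 3))
        vals = rmsd_series(_traj(s, frames), X)
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_two_atoms_two_angstroms_apart(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(frame) == pytest.approx(1.0)

    def test_coincident_atoms_have_zero_rg(self):
        frame = np.zeros((5, 3))
        assert radius_of_gyration(frame) == 0.0

    def test_rg_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        X = rng.normal(scale=4.0, size=(50, 3))
        direct = np.sqrt(((X - X.mean(axis=0)) ** 2).sum(axis=1).mean())
        assert radius_of_gyration(X) == pytest.approx(direct, abs=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(SwitchscanError):
            radius_of_gyration(np.zeros((5, 3)), selection=[])


class TestPCA:
    def _ca_structure(self, X):
        return Structure([make_atom(i + 1, "CA", i + 1, "GLY", X[i])
                          for i in range(len(X))])

    def test_identical_frames_give_zero_eigenvalues(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        s = self._ca_structure(X)
        traj = _traj(s, np.repeat(X[None], 5, axis=0))
        pca = ca_pca([("only", traj)], list(range(10)))
        assert np.all(pca.eigenvalues <= 1e-12)

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(scale=8.0, size=(12, 3))
        s = self._ca_structure(X)
        frames = X[None] + rng.normal(scale=0.7, size=(40, 12, 3))
        pca = ca_pca([("only", _traj(s, frames))], list(range(12)))
        # trace identity on the aligned ensemble the PCA itself analysed:
        # reconstruct displacements from the (orthonormal) projections
        total_var = (pca.projections ** 2).sum() / len(pca.projections)
        assert pca.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(8)
        X = rng.normal(scale=8.0, size=(8, 3))
        s = self._ca_structure(X)
        frames = X[None] + rng.normal(scale=0.5, size=(30, 8, 3))
        pca = ca_pca([("only", _traj(s, frames))], list(range(8)))
        G = pca.eigenvectors.T @ pca.eigenvectors
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_condition_labels_follow_frames(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 3)) * 5
        s = self._ca_structure(X)
        tA = _traj(s, X[None] + rng.normal(scale=0.1, size=(4, 6, 3)))
        tB = _traj(s, X[None] + rng.normal(scale=0.1, size=(3, 6, 3)))
        pca = ca_pca([("A", tA), ("B", tB)], list(range(6)))
        assert pca.frame_labels == ["A"] * 4 + ["B"] * 3

    def test_single_atom_mode_displacement_mapping(self):
        """A mode moving only one atom concentrates its EV magnitude there."""
        rng = np.random.default_rng(10)
        X = rng.normal(scale=6.0, size=(9, 3))
        s = self._ca_structure(X)
        frames = np.repeat(X[None], 60, axis=0)
        frames[:, 4, 0] += rng.normal(scale=2.0, size=60)  # only atom 4 moves
        pca = ca_pca([("only", _traj(s, frames))], list(range(9)))
        # superposition absorbs a ~1/N share of the motion into the fit,
        # so the other atoms carry a small residual
        mags = ev_displacements(pca, 0)
        assert mags.argmax() == 4
        assert mags[4] > 3 * np.delete(mags, 4).max()

    def test_component_out_of_range(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(5, 3)) * 4
        s = self._ca_structure(X)
        pca = ca_pca([("only", _traj(s, X[None] + rng.normal(
            scale=0.2, size=(6, 5, 3))))], list(range(5)))
        with pytest.raises(SwitchscanError):
            ev_displacements(pca, 99)

    def test_fewer_than_two_frames_rejected(self):
        X = np.random.default_rng(12).normal(size=(5, 3)) * 4
        s = self._ca_structure(X)
        with pytest.raises(SwitchscanError):
            ca_pca([("only", _traj(s, X[None]))], list(range(5)))


class TestDihedrals:
    def _backbone_traj(self, phis, psis, n_frames=1):
        n = len(phis)
        bb = build_backbone(phis, psis)
        atoms, serial = [], 1
        for i in range(n):
            for name in ("N", "CA", "C", "O"):
                atoms.append(make_atom(serial, name, i + 1, "ALA", bb[name][i]))
                serial += 1
        s = Structure(atoms)
        return s, _traj(s, np.repeat(s.coords[None], n_frames, axis=0))

    def test_build_and_recompute_roundtrip(self):
        phis = [-57.0, -60.0, -85.0, -57.0, -120.0, -57.0]
        psis = [-47.0, -40.0, -10.0, -47.0, 130.0, -47.0]
        s, traj = self._backbone_traj(phis, psis)
        stats = phi_psi(traj, [("A", i) for i in range(2, 6)])
        for st_ in stats:
            i = st_.residue[1] - 1
            expected = phis[i] if st_.kind == "phi" else psis[i]
            assert st_.values[0] == pytest.approx(expected, abs=1e-6)

    def test_terminal_residue_rejected_by_name(self):
        s, traj = self._backbone_traj([-57.0] * 4, [-47.0] * 4)
        with pytest.raises(SwitchscanError, match="A/ALA1"):
            phi_psi(traj, [("A", 1)])

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(13)
        s, traj = self._backbone_traj([-57.0] * 6, [-47.0] * 6, n_frames=3)
        R = random_rotation(rng)
        moved = Trajectory(s, traj.coords @ R.T + rng.normal(scale=30, size=3),
                           traj.times)
        a = phi_psi(traj, [("A", 3)])
        b = phi_psi(moved, [("A", 3)])
        for x, y in zip(a, b):
            assert np.allclose(x.values, y.values, atol=1e-8)

    def test_agrees_with_mdanalysis(self, tmp_path):
        """Independent oracle: MDAnalysis dihedral calculation."""
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.lib.distances import calc_dihedrals
        from switchscan.io import write_structure

        phis = [-57.0, -70.0, -100.0, -57.0, -45.0]
        psis = [-47.0, -30.0, 120.0, -47.0, -60.0]
        s, traj = self._backbone_traj(phis, psis)
        path = tmp_path / "bb.pdb"
        write_structure(s, path)
        u = mda.Universe(str(path))
        for i in (2, 3, 4):  # 1-based interior residues
            res = u.residues[i - 1]
            prev = u.residues[i - 2]
            phi_ref = np.degrees(calc_dihedrals(
                prev.atoms.select_atoms("name C").positions[0],
                res.atoms.select_atoms("name N").positions[0],
                res.atoms.select_atoms("name CA").positions[0],
                res.atoms.select_atoms("name C").positions[0]))
            ours = [x for x in phi_psi(traj, [("A", i)]) if x.kind == "phi"][0]
            # PDB coordinates carry 1e-3 Å precision → ~0.1° dihedral slack
            assert ours.values[0] == pytest.approx(float(phi_ref), abs=0.1)

    def test_circular_mean_handles_wraparound(self):
        m = circular_mean_deg(np.array([179.0, -179.0]))
        assert min(abs(m - 180.0), abs(m + 180.0)) <= 1e-9
        assert circular_mean_deg(np.array([10.0, -10.0])) == pytest.approx(0.0)

    @given(st.lists(st.floats(min_value=-180, max_value=179.9), min_size=2,
                    max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_circular_variance_bounds(self, angles):
        v = circular_variance(np.array(angles))
        assert -1e-12 <= v <= 1.0 + 1e-12

    def test_dihedral_range_convention(self):
        # trans arrangement yields the -180 edge, not +180
        p = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]
        assert dihedral(*p) == -180.0


class TestSecondaryStructure:
    def test_alpha_helix_interior_is_H(self):
        s = helix_structure(*ALPHA_PHI_PSI, n=12)
        labels = assign_ss(s.coords, s).labels
        assert all(l == "H" for l in labels[2:-2])

    def test_pi_helix_interior_is_I(self):
        s = helix_structure(*PI_PHI_PSI, n=12)
        labels = assign_ss(s.coords, s).labels
        assert all(l == "I" for l in labels[2:-2])

    def test_310_helix_interior_is_G(self):
        s = helix_structure(-49.0, -26.0, n=12)
        labels = assign_ss(s.coords, s).labels
        assert all(l == "G" for l in labels[2:-2])

    def test_extended_chain_is_coil(self):
        s = helix_structure(-179.0, 179.0, n=12)
        assert assign_ss(s.coords, s).labels == ["C"] * 12

    def test_pi_priority_no_H_inside_pi_run(self):
        """Mixed helix with a π middle segment: residues inside the π run
        must not be labelled H under π priority."""
        n = 20
        phis = [ALPHA_PHI_PSI[0]] * n
        psis = [ALPHA_PHI_PSI[1]] * n
        for j in range(7, 14):
            phis[j], psis[j] = PI_PHI_PSI
        bb = build_backbone(phis, psis)
        atoms, serial = [], 1
        for i in range(n):
            for name in ("N", "CA", "C", "O"):
                atoms.append(make_atom(serial, name, i + 1, "ALA", bb[name][i]))
                serial += 1
        s = Structure(atoms)
        labels = assign_ss(s.coords, s).labels
        pi_positions = [i for i, l in enumerate(labels) if l == "I"]
        assert pi_positions, "π segment must be detected"
        assert all(labels[i] != "H" for i in pi_positions)

    def test_agrees_with_mdtraj_dssp(self, tmp_path):
        """Independent oracle: mdtraj's DSSP on ideal fixtures."""
        md = pytest.importorskip("mdtraj")
        from switchscan.io import write_structure

        for phi_psi in (ALPHA_PHI_PSI, PI_PHI_PSI):
            s = helix_structure(*phi_psi, n=14)
            path = tmp_path / "helix.pdb"
            write_structure(s, path)
            theirs = md.compute_dssp(md.load(str(path)), simplified=False)[0]
            ours = assign_ss(s.coords, s).labels
            # compare interiors; DSSP implementations differ at termini
            assert list(theirs[2:-2]) == ours[2:-2]

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(14)
        s = helix_structure(*ALPHA_PHI_PSI, n=10)
        R = random_rotation(rng)
        moved = s.coords @ R.T + rng.normal(scale=25, size=3)
        assert assign_ss(s.coords, s).labels == assign_ss(moved, s).labels

    def test_fractions_sum_to_one(self):
        s = helix_structure(*ALPHA_PHI_PSI, n=10)
        rng = np.random.default_rng(15)
        coords = s.coords[None] + rng.normal(scale=0.05, size=(4, s.n_atoms, 3))
        fr = ss_fractions(_traj(s, coords))
        for frac in fr.values():
            assert sum(frac.values()) == pytest.approx(1.0)

    def test_missing_backbone_atoms_named(self):
        s = helix_structure(*ALPHA_PHI_PSI, n=6)
        atoms = [a for a in s.atoms if not (a.res_seq == 3 and a.name == "O")]
        broken = Structure(atoms)
        with pytest.raises(SwitchscanError, match="ALA3"):
            assign_ss(broken.coords, broken)
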