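"""Tests for superposition, RMSD/RMSF, H-bond occupancy, secondary
structure and segment distances, including independent oracles."""

import numpy as np
import pandas as pd
import pytest

from bir2sim import traj_metrics as tm

from conftest import ideal_helix, ideal_strand


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabsch:
    def test_identity_on_identical_coordinates(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = tm.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        rot90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        moved = pts @ rot90.T + np.array([5.0, -2.0, 7.0])
        _, _, rmsd = tm.kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_grid_oracle_on_four_point_toy(self):
        """Brute-force oracle: scan rotations on a 5-degree global Euler
        grid, then refine on a 1-degree local grid around the best cell;
        the analytic solution must match the grid minimum to 1e-3 A and
        never exceed it."""
        rng = np.random.default_rng(7)
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 3]])
        mob = ref @ random_rotation(rng).T + rng.normal(0, 0.3, (4, 3))

        def grid_min(alphas, betas, gammas):
            best = np.inf
            mc = mob - mob.mean(0)
            qc = ref - ref.mean(0)
            for a in alphas:
                ca, sa = np.cos(a), np.sin(a)
                rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
                for b in betas:
                    cb, sb = np.cos(b), np.sin(b)
                    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
                    for g in gammas:
                        cc, sc = np.cos(g), np.sin(g)
                        rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
                        rot = rz1 @ ry @ rz2
                        rmsd = np.sqrt(((mc @ rot.T - qc) ** 2)
                                       .sum(1).mean())
                        if rmsd < best:
                            best, args = rmsd, (a, b, g)
            return best, args

        step5 = np.radians(5.0)
        coarse, (a0, b0, g0) = grid_min(
            np.arange(0, 2 * np.pi, step5), np.arange(0, np.pi, step5),
            np.arange(0, 2 * np.pi, step5))
        step1 = np.radians(1.0)
        fine, _ = grid_min(np.arange(a0 - step5, a0 + step5, step1),
                           np.arange(b0 - step5, b0 + step5, step1),
                           np.arange(g0 - step5, g0 + step5, step1))
        _, _, kabsch_rmsd = tm.kabsch_superpose(mob, ref)
        assert kabsch_rmsd <= fine + 1e-12
        assert abs(kabsch_rmsd - fine) < 1e-3

    def test_collinear_selection_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="degenerate"):
            tm.kabsch_superpose(line, line + 1.0)


class TestSubsetRmsd:
    def make_traj(self, frames, ids=None):
        frames = np.asarray(frames)
        ids = ids if ids is not None else np.arange(1, frames.shape[1] + 1)
        return tm.Trajectory(frames, ids)

    def test_copies_of_reference_give_zeros(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(10, 3))
        traj = self.make_traj(np.repeat(ref[None], 5, axis=0))
        sel = tm.ResidueSelection("all", tuple(range(1, 11)))
        out = tm.subset_rmsd(traj, ref, sel, sel)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_single_displaced_bead_closed_form(self):
        # fit on a disjoint rigid frame; one of k measured beads moves 1 A
        rng = np.random.default_rng(2)
        ref = rng.normal(0, 4, size=(12, 3))
        frame = ref.copy()
        frame[8] += np.array([1.0, 0, 0])  # measured bead displaced 1 A
        traj = self.make_traj(frame[None])
        fit = tm.ResidueSelection("anchor", tuple(range(1, 7)))
        meas = tm.ResidueSelection("meas", (7, 8, 9, 10))  # k = 4
        out = tm.subset_rmsd(traj, ref, fit, meas)
        assert out[0] == pytest.approx(1.0 / np.sqrt(4), abs=1e-12)

    def test_matches_direct_definition_oracle(self):
        # independent implementation: explicit Kabsch + explicit RMSD loop
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 5, size=(9, 3))
        frames = ref[None] + rng.normal(0, 0.7, size=(6, 9, 3))
        traj = self.make_traj(frames)
        fit = tm.ResidueSelection("fit", tuple(range(1, 10)))
        meas = tm.ResidueSelection("meas", (2, 4, 8))
        out = tm.subset_rmsd(traj, ref, fit, meas)
        midx = [1, 3, 7]
        for f in range(6):
            rot, trans, _ = tm.kabsch_superpose(frames[f], ref)
            moved = frames[f] @ rot.T + trans
            direct = np.sqrt(np.mean([np.sum((moved[i] - ref[i]) ** 2)
                                      for i in midx]))
            assert out[f] == pytest.approx(direct, abs=1e-9)

    def test_measure_equals_fit_matches_kabsch_rmsd(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(0, 5, size=(8, 3))
        frames = ref[None] + rng.normal(0, 0.5, size=(4, 8, 3))
        traj = self.make_traj(frames)
        sel = tm.ResidueSelection("all", tuple(range(1, 9)))
        out = tm.subset_rmsd(traj, ref, sel, sel)
        for f in range(4):
            _, _, rmsd = tm.kabsch_superpose(frames[f], ref)
            assert abs(out[f] - rmsd) < 1e-12

    def test_missing_residues_named_in_error(self):
        traj = self.make_traj(np.zeros((1, 4, 3)) + np.arange(4)[None, :, None])
        with pytest.raises(tm.SelectionError, match=r"\[9\]"):
            tm.subset_rmsd(traj, traj.coords[0],
                           tm.ResidueSelection("fit", (1, 2, 3)),
                           tm.ResidueSelection("bad", (2, 9)))


class TestRmsf:
    def test_static_trajectory_gives_zeros(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(8, 3))
        traj = tm.Trajectory(np.repeat(ref[None], 4, 0), np.arange(1, 9))
        out = tm.rmsf(traj, tm.ResidueSelection("all", tuple(range(1, 9))))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_isotropic_jitter_analytic_value(self):
        # rigid anchors + one bead jittered with per-axis sigma = 0.2 A:
        # RMSF = 0.2 * sqrt(3)
        rng = np.random.default_rng(1)
        anchors = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0],
                            [0, 0, 10], [10, 10, 0]])
        n_frames = 100000
        frames = np.repeat(
            np.vstack([anchors, [[5.0, 5, 5]]])[None], n_frames, 0)
        frames[:, 5] += rng.normal(0, 0.2, size=(n_frames, 3))
        traj = tm.Trajectory(frames, np.arange(1, 7))
        out = tm.rmsf(traj, tm.ResidueSelection("probe", (6,)),
                      fit_selection=tm.ResidueSelection("anchors",
                                                        (1, 2, 3, 4, 5)))
        assert out.loc[6] == pytest.approx(0.2 * np.sqrt(3), rel=0.02)

    def test_single_frame_rejected(self):
        traj = tm.Trajectory(np.zeros((1, 4, 3)), np.arange(1, 5))
        with pytest.raises(ValueError):
            tm.rmsf(traj, tm.ResidueSelection("all", (1, 2, 3, 4)))


class TestHbondOccupancy:
    def geometric_traj(self, ha_dist, angle_deg, n_frames=4):
        """Donor N-H ... acceptor O with controlled geometry."""
        theta = np.radians(180.0 - angle_deg)
        acceptor = np.array([1.0 + ha_dist * np.cos(theta),
                             ha_dist * np.sin(theta), 0.0])
        coords = np.array([[0.0, 0, 0],    # N (donor heavy)
                           [1.0, 0, 0],    # H
                           acceptor])      # O
        frames = np.repeat(coords[None], n_frames, 0)
        return tm.Trajectory(frames, [1, 1, 2],
                             residue_names=["ARG", "ARG", "ALA"],
                             atom_names=["N", "H", "O"],
                             elements=["N", "H", "O"])

    def test_satisfying_geometry_every_frame_gives_100(self):
        traj = self.geometric_traj(ha_dist=2.0, angle_deg=165.0)
        occ, present = tm.hbond_occupancy(traj, (1, "N", "H"), (2, "O"))
        assert occ == 100.0
        assert present.all()

    def test_distance_beyond_cutoff_gives_zero(self):
        traj = self.geometric_traj(ha_dist=3.7, angle_deg=165.0)
        occ, _ = tm.hbond_occupancy(traj, (1, "N", "H"), (2, "O"))
        assert occ == 0.0

    def test_angle_below_cutoff_gives_zero(self):
        traj = self.geometric_traj(ha_dist=2.0, angle_deg=120.0)
        occ, _ = tm.hbond_occupancy(traj, (1, "N", "H"), (2, "O"))
        assert occ == 0.0

    def test_heavy_atom_mode_measures_from_donor(self):
        # H...O = 3.0 but N...O = 4.0: hydrogen convention accepts,
        # heavy-atom convention rejects
        traj = self.geometric_traj(ha_dist=3.0, angle_deg=180.0)
        occ_h, _ = tm.hbond_occupancy(traj, (1, "N", "H"), (2, "O"))
        occ_d, _ = tm.hbond_occupancy(
            traj, (1, "N", "H"), (2, "O"),
            criterion=tm.HBondCriterion(mode="heavy"))
        assert occ_h == 100.0
        assert occ_d == 0.0

    def test_disallowed_acceptor_element_rejected(self):
        traj = self.geometric_traj(2.0, 170.0)
        traj.elements[2] = "P"
        with pytest.raises(ValueError, match="acceptor element"):
            tm.hbond_occupancy(traj, (1, "N", "H"), (2, "O"))

    def test_planted_surrogate_occupancy_exact(self):
        # bead pair within cutoff in exactly 250 of 1000 frames
        n = 1000
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = 8.0
        present_idx = np.arange(0, n, 4)  # 250 frames
        coords[present_idx, 1, 0] = 5.0
        traj = tm.Trajectory(coords, [166, 185])
        occ, present = tm.hbond_occupancy(traj, 166, 185,
                                          surrogate_cutoff=6.2)
        assert occ == 25.0
        assert present.sum() == 250

    def test_surrogate_requires_cutoff(self):
        traj = tm.Trajectory(np.zeros((2, 2, 3)), [166, 185])
        with pytest.raises(ValueError, match="surrogate_cutoff"):
            tm.hbond_occupancy(traj, 166, 185)


class TestSecondaryStructure:
    def test_ideal_helix_interior_fully_helical(self):
        traj = ideal_helix(12)
        ss = tm.secondary_structure_fraction(traj)
        assert np.allclose(ss.loc[2:10, "helix"], 1.0)
        assert np.allclose(ss.sum(axis=1), 1.0)

    def test_ideal_strand_interior_fully_sheet(self):
        traj = ideal_strand(12)
        ss = tm.secondary_structure_fraction(traj)
        assert np.allclose(ss.loc[2:10, "sheet"], 1.0)

    def test_termini_are_coil(self):
        ss = tm.secondary_structure_fraction(ideal_helix(12))
        assert ss.loc[1, "coil"] == 1.0
        assert ss.loc[12, "coil"] == 1.0

    def test_planted_mixture_recovers_fractions(self):
        helix = ideal_helix(12).coords[0]
        strand = ideal_strand(12).coords[0]
        frames = np.array([helix if k % 2 == 0 else strand
                           for k in range(10)])
        traj = tm.Trajectory(frames, np.arange(1, 13))
        ss = tm.secondary_structure_fraction(traj)
        interior = ss.loc[3:9]
        assert np.allclose(interior["helix"], 0.5, atol=0.1 + 1e-12)
        assert np.allclose(interior["sheet"], 0.5, atol=0.1 + 1e-12)

    def test_chain_break_classified_coil_with_warning(self):
        coords = ideal_helix(12).coords[0].copy()
        coords[6:] += 30.0  # break between residues 6 and 7
        traj = tm.Trajectory(coords[None], np.arange(1, 13))
        with pytest.warns(UserWarning, match="chain break"):
            ss = tm.secondary_structure_fraction(traj)
        assert ss.loc[6, "coil"] == 1.0
        assert ss.loc[7, "coil"] == 1.0

    def test_too_short_chain_rejected(self):
        traj = tm.Trajectory(np.zeros((1, 3, 3)), [1, 2, 3])
        with pytest.raises(ValueError):
            tm.secondary_structure_fraction(traj)


class TestDistances:
    def test_identical_selections_give_zero(self):
        rng = np.random.default_rng(0)
        traj = tm.Trajectory(rng.normal(size=(3, 6, 3)), np.arange(1, 7))
        sel = tm.ResidueSelection("a", (1, 2, 3))
        assert np.allclose(tm.segment_distance(traj, sel, sel), 0.0)

    def test_three_four_five_triangle(self):
        coords = np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        traj = tm.Trajectory(coords, [1, 2])
        d = tm.segment_distance(traj, tm.ResidueSelection("a", (1,)),
                                tm.ResidueSelection("b", (2,)))
        assert d[0] == pytest.approx(5.0)

    def test_radius_of_gyration_closed_form(self):
        # 2 beads 2r apart: Rg = r
        coords = np.array([[[0.0, 0, 0], [6.0, 0, 0]]])
        traj = tm.Trajectory(coords, [1, 2])
        rg = tm.radius_of_gyration(traj, tm.ResidueSelection("ab", (1, 2)))
        assert rg[0] == pytest.approx(3.0)


class TestRigidInvariance:
    def test_metrics_invariant_under_global_rigid_transform(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(0, 5, size=(10, 3))
        frames = ref[None] + rng.normal(0, 0.5, size=(5, 10, 3))
        ids = np.arange(1, 11)
        traj = tm.Trajectory(frames, ids)
        rot = random_rotation(rng)
        shift = np.array([3.0, -8.0, 2.0])
        moved = tm.Trajectory(frames @ rot.T + shift, ids)

        sel = tm.ResidueSelection("all", tuple(ids))
        sub = tm.ResidueSelection("sub", (2, 5, 7))
        a_sel = tm.ResidueSelection("a", (1, 2, 3))
        b_sel = tm.ResidueSelection("b", (8, 9, 10))

        assert np.allclose(tm.subset_rmsd(traj, ref, sel, sub),
                           tm.subset_rmsd(moved, ref @ rot.T + shift,
                                          sel, sub), atol=1e-9)
        assert np.allclose(tm.rmsf(traj, sel).values,
                           tm.rmsf(moved, sel).values, atol=1e-9)
        assert np.allclose(tm.segment_distance(traj, a_sel, b_sel),
                           tm.segment_distance(moved, a_sel, b_sel),
                           atol=1e-9)


class TestTrajectoryIO:
    def small_traj(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 8, size=(3, 6, 3)).round(3)
        return tm.Trajectory(coords, np.arange(163, 169),
                             residue_names=["ALA", "ARG", "GLY", "CYS",
                                            "HIS", "TRP"])

    def test_pdb_round_trip(self, tmp_path):
        traj = self.small_traj()
        path = tmp_path / "traj.pdb"
        tm.write_pdb_trajectory(traj, path)
        back = tm.read_pdb_trajectory(path)
        assert back.n_frames == traj.n_frames
        assert np.array_equal(back.residue_ids, traj.residue_ids)
        assert back.residue_names == traj.residue_names
        assert np.allclose(back.coords, traj.coords, atol=1e-3)

    def test_xyz_round_trip_with_template(self, tmp_path):
        traj = self.small_traj()
        path = tmp_path / "traj.xyz"
        tm.write_xyz_trajectory(traj, path)
        back = tm.read_xyz_trajectory(path, template=traj)
        assert np.array_equal(back.coords, traj.coords)
        assert np.array_equal(back.residue_ids, traj.residue_ids)

    def test_mdtraj_reads_written_pdb_and_agrees_on_rmsd(self, tmp_path):
        """Cross-check against mdtraj as an independent oracle: the
        written multi-model PDB must load with identical coordinates and
        give the same all-atom RMSD after superposition."""
        mdtraj = pytest.importorskip("mdtraj")
        traj = self.small_traj()
        path = tmp_path / "traj.pdb"
        tm.write_pdb_trajectory(traj, path)
        mt = mdtraj.load_pdb(str(path), standard_names=False)
        assert mt.n_frames == traj.n_frames
        assert np.allclose(mt.xyz * 10.0, traj.coords, atol=1e-2)
        sel = tm.ResidueSelection("all", tuple(traj.residue_ids))
        ours = tm.subset_rmsd(traj, traj.coords[0], sel, sel)
        theirs = mdtraj.rmsd(mt, mt, 0) * 10.0
        assert np.allclose(ours, theirs, atol=1e-3)

    def test_inconsistent_model_atom_counts_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        good = ("MODEL        0\n"
                "ATOM      1  CA  ALA A 163       0.000   0.000   0.000"
                "  1.00  0.00           C\n"
                "ATOM      2  CA  ALA A 164       3.800   0.000   0.000"
                "  1.00  0.00           C\n"
                "ENDMDL\nMODEL        1\n"
                "ATOM      1  CA  ALA A 163       0.000   0.000   0.000"
                "  1.00  0.00           C\n"
                "ENDMDL\nEND\n")
        path.write_text(good)
        with pytest.raises(ValueError):
            tm.read_pdb_trajectory(path)
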