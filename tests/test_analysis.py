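"""Trajectory observables: closed-form checks and additivity identities."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from stunbh.analysis import (
    com_distance_trace,
    count_within,
    interaction_map,
    radius_of_gyration,
    rmsd,
    rmsf,
)
from stunbh.dynamics import Trajectory
from stunbh.forcefield import group_interaction_energy
from stunbh.topology import BeadTopology, Conformation, InputError

from helpers import random_solvated_toy


def simple_topo(n, groups=None, residues=None, masses=None):
    return BeadTopology(
        bead_type=["W"] * n,
        mass=np.full(n, 1.0) if masses is None else np.asarray(masses, float),
        charge=np.zeros(n),
        bonds=np.empty((0, 4)),
        angles=np.empty((0, 5)),
        group=groups if groups is not None else ["solvent"] * n,
        residue_id=residues if residues is not None else list(range(n)),
        backbone=[False] * n,
    )


def static_trajectory(coords, n_frames=3, box=None):
    X = np.repeat(coords[None], n_frames, axis=0)
    z = np.zeros(n_frames)
    return Trajectory(X, np.arange(n_frames, dtype=float) + 1.0, z, z, z, box)


class TestRmsd:
    def test_identical_structures_zero(self):
        c = Conformation(np.random.default_rng(0).normal(size=(5, 3)))
        assert rmsd(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_translated_copy_with_fit_zero(self):
        rng = np.random.default_rng(1)
        a = Conformation(rng.normal(size=(6, 3)))
        b = Conformation(a.coords + [3.0, -2.0, 7.0])
        assert rmsd(b, a, fit=True) == pytest.approx(0.0, abs=1e-10)

    def test_rotated_copy_with_fit_zero(self):
        rng = np.random.default_rng(2)
        a = Conformation(rng.normal(size=(6, 3)))
        rot = Rotation.random(rng=rng)
        b = Conformation(rot.apply(a.coords) + 1.5)
        assert rmsd(b, a, fit=True) == pytest.approx(0.0, abs=1e-10)

    def test_no_fit_closed_form(self):
        a = Conformation([[0, 0, 0], [0, 0, 0]])
        b = Conformation([[3, 4, 0], [0, 0, 0]])
        assert rmsd(b, a, fit=False) == pytest.approx(np.sqrt(25 / 2), abs=1e-12)

    def test_size_mismatch_raises(self):
        a = Conformation(np.zeros((3, 3)))
        b = Conformation(np.zeros((4, 3)))
        with pytest.raises(InputError):
            rmsd(a, b, fit=False)
        with pytest.raises(InputError):
            rmsd(a, b, selection=[0, 1, 3], fit=False)


class TestRadiusOfGyration:
    def test_single_bead_zero(self):
        topo = simple_topo(1)
        assert radius_of_gyration(Conformation([[1, 2, 3]]), topo) == 0.0

    def test_two_unit_masses_half_distance(self):
        topo = simple_topo(2)
        conf = Conformation([[0, 0, 0], [6.0, 0, 0]])
        assert radius_of_gyration(conf, topo) == pytest.approx(3.0, abs=1e-12)

    def test_square_corners(self):
        a = 4.0
        topo = simple_topo(4)
        conf = Conformation([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]])
        assert radius_of_gyration(conf, topo) == pytest.approx(a / np.sqrt(2), abs=1e-12)

    def test_rigid_motion_invariant(self):
        rng = np.random.default_rng(3)
        topo = simple_topo(7, masses=rng.uniform(1, 80, 7))
        coords = rng.normal(size=(7, 3)) * 5
        rot = Rotation.random(rng=rng)
        rg0 = radius_of_gyration(Conformation(coords), topo)
        rg1 = radius_of_gyration(Conformation(rot.apply(coords) + 9.0), topo)
        assert rg1 == pytest.approx(rg0, abs=1e-10)

    def test_empty_selection_raises(self):
        topo = simple_topo(2)
        with pytest.raises(InputError):
            radius_of_gyration(Conformation(np.zeros((2, 3))), topo, selection=[])


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(8, 3)) * 10
        groups = ["receptor"] * 4 + ["ligand"] * 4
        topo = simple_topo(8, groups=groups, residues=[0, 1, 2, 3, 0, 0, 1, 1])
        traj = static_trajectory(coords, n_frames=5)
        vals = rmsf(traj, topo)
        assert np.allclose(vals.values, 0.0)

    def test_two_point_alternation_half_distance(self):
        # one ligand bead flips between two points d apart; receptor static
        d = 3.0
        base = np.zeros((5, 3))
        base[:4] = [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]]
        frames = []
        for k in range(6):
            f = base.copy()
            f[4] = [20.0, 0, 0] if k % 2 == 0 else [20.0 + d, 0, 0]
            frames.append(f)
        z = np.zeros(6)
        traj = Trajectory(np.array(frames), np.arange(6.0) + 1, z, z, z)
        topo = simple_topo(5, groups=["receptor"] * 4 + ["ligand"],
                           residues=[0, 1, 2, 3, 0])
        vals = rmsf(traj, topo, fit=False)
        assert vals[0] == pytest.approx(d / 2, abs=1e-12)

    def test_nucleobase_value_is_mean_of_member_beads(self):
        rng = np.random.default_rng(5)
        n = 10
        groups = ["receptor"] * 4 + ["ligand"] * 6
        residues = [0, 1, 2, 3] + [0, 0, 1, 1, 2, 2]
        topo = simple_topo(n, groups=groups, residues=residues)
        X = rng.normal(size=(7, n, 3))
        X[:, :4] = X[0, :4]  # static receptor so the fit is exact
        z = np.zeros(7)
        traj = Trajectory(X, np.arange(7.0) + 1, z, z, z)
        per_bead = rmsf(traj, topo, group_by="bead", fit=False)
        per_base = rmsf(traj, topo, fit=False)
        lig = topo.select("ligand")
        for res in (0, 1, 2):
            members = lig[topo.residue_id[lig] == res]
            assert per_base[res] == pytest.approx(
                per_bead.values[members].mean(), abs=1e-12)

    def test_short_window_raises(self):
        topo = simple_topo(4, groups=["receptor"] * 4)
        traj = static_trajectory(np.zeros((4, 3)), n_frames=3)
        with pytest.raises(InputError):
            rmsf(traj, topo, window=(0, 1))


class TestComDistance:
    def test_coincident_groups_zero(self):
        topo = simple_topo(2, groups=["ligand", "receptor"])
        traj = static_trajectory(np.zeros((2, 3)))
        assert np.allclose(com_distance_trace(traj, topo), 0.0)

    def test_rigid_translation_invariant(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(6, 3)) * 4
        topo = simple_topo(6, groups=["ligand"] * 3 + ["receptor"] * 3)
        t0 = static_trajectory(coords)
        t1 = static_trajectory(coords + [11.0, -3.0, 5.0])
        assert com_distance_trace(t0, topo) == pytest.approx(
            com_distance_trace(t1, topo))

    def test_minimum_image(self):
        topo = simple_topo(2, groups=["ligand", "receptor"])
        coords = np.array([[2.5, 50.0, 50.0], [97.5, 50.0, 50.0]])
        traj = static_trajectory(coords, box=(100.0, 100.0, 100.0))
        assert com_distance_trace(traj, topo)[0] == pytest.approx(5.0, abs=1e-12)


class TestInteractionMap:
    def test_distant_groups_zero_map(self, pocket_ff):
        topo = simple_topo(2, groups=["ligand", "receptor"])
        topo.bead_type[:] = ["LNB", "PKT"]
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        traj = static_trajectory(coords)
        imap = interaction_map(traj, topo, pocket_ff)
        assert np.allclose(imap.matrix.values, 0.0)

    def test_matrix_total_equals_group_interaction(self, pocket_ff):
        topo, conf = random_solvated_toy(seed=11)
        traj = static_trajectory(conf.coords, n_frames=4, box=conf.box)
        imap = interaction_map(traj, topo, pocket_ff)
        total = group_interaction_energy(conf, topo, pocket_ff)
        assert imap.matrix.values.sum() == pytest.approx(total, abs=1e-8)

    def test_column_sums_equal_histogram(self, pocket_ff):
        topo, conf = random_solvated_toy(seed=12)
        traj = static_trajectory(conf.coords, n_frames=2, box=conf.box)
        imap = interaction_map(traj, topo, pocket_ff)
        assert np.allclose(imap.matrix.sum(axis=0).values,
                           imap.histogram.values, atol=1e-12)

    def test_single_frame_window_is_instantaneous(self, pocket_ff):
        topo, conf = random_solvated_toy(seed=13)
        rng = np.random.default_rng(0)
        X = np.stack([conf.coords, conf.coords + rng.normal(size=conf.coords.shape)])
        z = np.zeros(2)
        traj = Trajectory(X, np.array([1.0, 2.0]), z, z, z, conf.box)
        one = interaction_map(traj, topo, pocket_ff, window=(0, 1))
        total0 = group_interaction_energy(conf, topo, pocket_ff)
        assert one.matrix.values.sum() == pytest.approx(total0, abs=1e-8)

    def test_threshold_mask(self, pocket_ff):
        topo, conf = random_solvated_toy(seed=14)
        traj = static_trajectory(conf.coords, n_frames=2, box=conf.box)
        imap = interaction_map(traj, topo, pocket_ff, threshold=-0.5)
        assert imap.mask.values.sum() == (imap.matrix.values <= -0.5).sum()


class TestCountWithin:
    def test_empty_target_zero(self):
        topo = simple_topo(2, groups=["ligand", "receptor"])
        n, ids = count_within(Conformation(np.zeros((2, 3))), topo,
                              "ligand", "solvent", cutoff=7.0)
        assert n == 0 and ids.size == 0

    @pytest.mark.parametrize("r, expected", [(6.9, 1), (7.1, 0)])
    def test_strict_threshold(self, r, expected):
        topo = simple_topo(2, groups=["ligand", "solvent"])
        conf = Conformation([[0, 0, 0], [r, 0, 0]])
        n, _ = count_within(conf, topo, "ligand", "solvent", cutoff=7.0)
        assert n == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_periodic(self, seed):
        rng = np.random.default_rng(seed)
        box = 40.0
        n = 500
        coords = rng.uniform(0, box, size=(n, 3))
        groups = ["ligand"] * 20 + ["solvent"] * 480
        topo = simple_topo(n, groups=groups, residues=[0] * n)
        conf = Conformation(coords, (box, box, box))
        cutoff = 7.0
        count, ids = count_within(conf, topo, "ligand", "solvent", cutoff)
        # O(N^2) oracle with explicit minimum image
        lig, sol = coords[:20], coords[20:]
        d = lig[:, None, :] - sol[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        brute = np.flatnonzero((r < cutoff).any(axis=0)) + 20
        assert count == len(brute)
        assert np.array_equal(ids, brute)
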