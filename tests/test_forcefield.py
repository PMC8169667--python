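"""Force-field unit and property tests: closed forms, gradients, identities."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stunbh.forcefield import (
    binding_energy,
    dmd_scaled_params,
    energy_and_forces,
    forces,
    group_interaction_energy,
    total_energy,
)
from stunbh.synthetic import make_lj_cluster
from stunbh.topology import (
    BeadTopology,
    Conformation,
    ForceFieldParams,
    InputError,
    TopologyError,
)

from helpers import R_MIN, SIGMA, make_two_group_pair, random_solvated_toy


class TestTotalEnergy:
    def test_pair_beyond_cutoff_is_exactly_zero(self, lj_ff_cut):
        topo, conf = make_lj_cluster(2, seed=0)
        conf.coords[:] = [[0, 0, 0], [lj_ff_cut.r_cut + 1.0, 0, 0]]
        assert total_energy(conf, topo, lj_ff_cut) == 0.0

    def test_lj_minimum_closed_form(self, dimer, lj_ff):
        topo, conf = dimer
        assert total_energy(conf, topo, lj_ff) == pytest.approx(-1.0, abs=1e-12)

    def test_bond_at_rest_length_zero(self):
        topo = BeadTopology(
            bead_type=["LJ", "LJ"], mass=[72, 72], charge=[0, 0],
            bonds=[[0, 1, 5.0, 300.0]], angles=np.empty((0, 5)),
            group=["ligand", "ligand"], residue_id=[0, 0],
            backbone=[False, False],
        )
        ff = ForceFieldParams(lj_sigma={"LJ": SIGMA}, lj_epsilon={"LJ": 1.0})
        conf = Conformation([[0, 0, 0], [5.0, 0, 0]])
        # the bonded pair is excluded from nonbonded terms
        assert total_energy(conf, topo, ff) == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_lengths_raise(self, lj_ff):
        topo, _ = make_lj_cluster(3, seed=0)
        conf = Conformation(np.zeros((2, 3)) + [[0, 0, 0], [6, 0, 0]])
        with pytest.raises(TopologyError):
            total_energy(conf, topo, lj_ff)

    def test_rigid_motion_invariance(self, lj_ff_cut):
        topo, conf = make_lj_cluster(8, seed=3)
        e0 = total_energy(conf, topo, lj_ff_cut)
        rng = np.random.default_rng(5)
        for _ in range(5):
            rot = Rotation.random(rng=rng)
            t = rng.uniform(-20, 20, 3)
            moved = Conformation(rot.apply(conf.coords) + t)
            assert total_energy(moved, topo, lj_ff_cut) == pytest.approx(e0, abs=1e-8)

    def test_nonbonded_energy_linear_in_scale(self, solvated_toy, pocket_ff):
        topo, conf = solvated_toy
        e_full = total_energy(conf, topo, pocket_ff)
        e_half = total_energy(conf, topo, pocket_ff.with_scale(0.5))
        e_tenth = total_energy(conf, topo, pocket_ff.with_scale(0.1))
        # E(s) = E_bond + s * E_nb  =>  collinearity of three points
        slope1 = (e_full - e_half) / 0.5
        slope2 = (e_half - e_tenth) / 0.4
        assert slope1 == pytest.approx(slope2, rel=1e-10)


class TestForces:
    def test_isolated_bead_zero_force(self, lj_ff_cut):
        topo, conf = make_lj_cluster(2, seed=0)
        conf.coords[:] = [[0, 0, 0], [50.0, 0, 0]]
        assert np.allclose(forces(conf, topo, lj_ff_cut), 0.0)

    def test_dimer_at_minimum_zero_force(self, dimer, lj_ff):
        topo, conf = dimer
        F = forces(conf, topo, lj_ff)
        assert np.abs(F).max() < 1e-10

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_central_differences(self, seed):
        topo, conf = random_solvated_toy(seed, n_lig=5, n_rec=5, n_sol=8, n_ion=2)
        from stunbh.synthetic import pocket_forcefield

        ff = pocket_forcefield()
        _, F = energy_and_forces(conf, topo, ff)
        h = 1e-5
        for i in range(0, topo.n_beads, 4):
            for k in range(3):
                cp, cm = conf.copy(), conf.copy()
                cp.coords[i, k] += h
                cm.coords[i, k] -= h
                fd = -(total_energy(cp, topo, ff) - total_energy(cm, topo, ff)) / (2 * h)
                assert F[i, k] == pytest.approx(fd, abs=1e-4)

    def test_force_continuous_at_switch_onset(self, lj_ff_cut):
        topo, _ = make_lj_cluster(2, seed=0)
        eps = 1e-7
        f_in = forces(Conformation([[0, 0, 0], [9.0 - eps, 0, 0]]), topo, lj_ff_cut)
        f_out = forces(Conformation([[0, 0, 0], [9.0 + eps, 0, 0]]), topo, lj_ff_cut)
        assert np.abs(f_in - f_out).max() < 1e-4

    def test_force_zero_at_cutoff(self, lj_ff_cut):
        topo, _ = make_lj_cluster(2, seed=0)
        conf = Conformation([[0, 0, 0], [11.9999, 0, 0]])
        assert np.abs(forces(conf, topo, lj_ff_cut)).max() < 1e-6


class TestGroupInteraction:
    def test_separated_groups_zero(self, lj_ff_cut):
        topo, conf = make_two_group_pair(r=lj_ff_cut.r_cut + 5.0)
        assert group_interaction_energy(conf, topo, lj_ff_cut) == 0.0

    def test_single_cross_pair_at_minimum(self, lj_ff):
        topo, conf = make_two_group_pair(r=R_MIN)
        assert group_interaction_energy(conf, topo, lj_ff) == pytest.approx(-1.0, abs=1e-12)

    def test_overlapping_selections_raise(self, lj_ff, dimer):
        topo, conf = dimer
        with pytest.raises(InputError):
            group_interaction_energy(conf, topo, lj_ff, [0, 1], [1])

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_binding_energy_decomposition(self, seed, pocket_ff):
        topo, conf = random_solvated_toy(seed)
        g = group_interaction_energy(conf, topo, pocket_ff)
        b = binding_energy(conf, topo, pocket_ff)
        assert abs(g - b) < 1e-8


class TestBindingEnergy:
    def test_noninteracting_groups_zero(self, lj_ff_cut):
        topo, conf = make_two_group_pair(r=30.0)
        assert binding_energy(conf, topo, lj_ff_cut) == 0.0

    def test_cross_pair_at_minimum(self, lj_ff):
        topo, conf = make_two_group_pair(r=R_MIN)
        assert binding_energy(conf, topo, lj_ff) == pytest.approx(-1.0, abs=1e-12)

    def test_missing_group_raises(self, lj_ff, dimer):
        topo, conf = dimer  # both beads are 'ligand'
        with pytest.raises(InputError):
            binding_energy(conf, topo, lj_ff)


class TestDmdScaling:
    def test_nonbonded_ratio_exactly_one_hundredth(self, solvated_toy, pocket_ff):
        topo, conf = solvated_toy
        dmd = dmd_scaled_params(pocket_ff)
        e_md = group_interaction_energy(conf, topo, pocket_ff)
        e_dmd = group_interaction_energy(conf, topo, dmd)
        assert e_dmd == pytest.approx(0.01 * e_md, rel=1e-12)

    def test_bonded_energy_unchanged(self, pocket_ff):
        topo = BeadTopology(
            bead_type=["LNB", "LNB"], mass=[72, 72], charge=[0, 0],
            bonds=[[0, 1, 5.0, 300.0]], angles=np.empty((0, 5)),
            group=["ligand", "ligand"], residue_id=[0, 0],
            backbone=[False, False],
        )
        conf = Conformation([[0, 0, 0], [5.7, 0, 0]])
        e_md = total_energy(conf, topo, pocket_ff)
        e_dmd = total_energy(conf, topo, dmd_scaled_params(pocket_ff))
        # the only term here is the (unscaled) bond
        assert e_dmd == pytest.approx(e_md, rel=1e-12)

    def test_idempotent_with_warning(self, pocket_ff):
        once = dmd_scaled_params(pocket_ff)
        with pytest.warns(UserWarning):
            twice = dmd_scaled_params(once)
        assert twice.nonbonded_scale == once.nonbonded_scale == 0.01
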