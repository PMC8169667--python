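"""STUN transform, Metropolis cases, kT controller, and search bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stunbh.forcefield import total_energy
from stunbh.stun_search import (
    MoveSettings,
    SearchState,
    adapt_kT,
    boltzmann_accept,
    init_search_state,
    make_objective,
    random_orientation,
    run_search,
    stun_bh_dmd_step,
    stun_transform,
)
from stunbh.synthetic import (
    cluster_move_settings,
    lj_forcefield,
    make_lj_cluster,
    make_pocket_system,
    pocket_forcefield,
)
from stunbh.topology import Conformation, InputError


class TestStunTransform:
    def test_zero_at_reference(self):
        assert stun_transform(5.0, 5.0) == 0.0

    @pytest.mark.parametrize("delta, expected", [
        (1.0, np.log(1 + np.sqrt(2))),       # ~0.881374
        (-1.0, np.log(-1 + np.sqrt(2))),
        (3.0, np.log(3 + np.sqrt(10))),
        (-3.0, np.log(-3 + np.sqrt(10))),    # ~-1.818446
    ])
    def test_closed_form(self, delta, expected):
        assert stun_transform(delta, 0.0) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(1e-3, 1e6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_and_sign(self, f, f0, gap):
        lo = stun_transform(f, f0)
        hi = stun_transform(f + gap, f0)
        assert hi > lo
        assert (stun_transform(f, f0) < 0) == (f < f0)


class TestBoltzmannAccept:
    def test_equal_always_accepted(self):
        assert boltzmann_accept(1.3, 1.3, kT=0.5, u=0.999999)

    def test_downhill_always_accepted(self):
        assert boltzmann_accept(0.2, 1.0, kT=1e-6, u=0.999999)

    def test_uphill_factor_half_accepts_below(self):
        kT = 0.7
        gap = kT * np.log(2.0)  # Boltzmann factor exactly 0.5
        assert boltzmann_accept(1.0 + gap, 1.0, kT, u=0.4)

    def test_uphill_factor_half_rejects_above(self):
        kT = 0.7
        gap = kT * np.log(2.0)
        assert not boltzmann_accept(1.0 + gap, 1.0, kT, u=0.6)


def state_with_history(history, kT=1.0):
    s = SearchState(f0=0.0, stun_last=0.0, x_last=Conformation(np.zeros((1, 3))),
                    kT=kT, rng=np.random.default_rng(0))
    s.accept_history = list(history)
    s.iteration = len(history)
    return s


class TestAdaptKT:
    def test_exactly_half_unchanged(self):
        s = state_with_history([True, False] * 10, kT=2.0)
        assert adapt_kT(s) == 2.0

    def test_high_acceptance_cools(self):
        s = state_with_history([True] * 16 + [False] * 4, kT=1.2)
        assert adapt_kT(s) == pytest.approx(1.0)

    def test_low_acceptance_heats(self):
        s = state_with_history([False] * 16 + [True] * 4, kT=1.0)
        assert adapt_kT(s) == pytest.approx(1.2)

    def test_clamped(self):
        s = state_with_history([True] * 20, kT=1.1e-6)
        assert adapt_kT(s) == 1e-6


class TestRandomOrientation:
    def test_rigid_rotation_preserves_geometry(self):
        topo, conf = make_pocket_system(seed=0)
        out = random_orientation(conf, topo, seed=1)
        rec = topo.select("receptor")
        lig = topo.select("ligand")
        d0 = np.linalg.norm(conf.coords[rec][:, None] - conf.coords[rec][None], axis=-1)
        d1 = np.linalg.norm(out.coords[rec][:, None] - out.coords[rec][None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-10
        m = topo.mass[rec][:, None]
        com0 = (m * conf.coords[rec]).sum(0) / m.sum()
        com1 = (m * out.coords[rec]).sum(0) / m.sum()
        assert np.abs(com0 - com1).max() < 1e-10
        assert np.array_equal(out.coords[lig], conf.coords[lig])

    def test_uniform_on_sphere(self):
        # rotate a receptor dimer many times; the bond direction must
        # average to zero within Monte-Carlo error
        topo, conf = make_pocket_system(seed=0)
        rec = topo.select("receptor")
        rng = np.random.default_rng(0)
        n = 3000
        dirs = np.empty((n, 3))
        for k in range(n):
            out = random_orientation(conf, topo, rng)
            v = out.coords[rec[1]] - out.coords[rec[0]]
            dirs[k] = v / np.linalg.norm(v)
        # per-component std of the mean is 1/sqrt(3n)
        assert np.abs(dirs.mean(axis=0)).max() < 3.0 / np.sqrt(3 * n)

    def test_requires_receptor(self, lj_ff_cut):
        topo, conf = make_lj_cluster(4, seed=0)
        with pytest.raises(InputError):
            random_orientation(conf, topo, seed=0)


class TestStepAndSearch:
    def test_f0_trace_nonincreasing_and_stun_zero_at_best(self, lj_ff_cut):
        topo, conf = make_lj_cluster(7, seed=0)
        move = cluster_move_settings(7)
        obj = make_objective(topo, lj_ff_cut, "total")
        state, live = init_search_state(conf, topo, lj_ff_cut, obj, move,
                                        rng=np.random.default_rng(1))
        f0s = [state.f0]
        for _ in range(30):
            live, rec = stun_bh_dmd_step(state, live, topo, lj_ff_cut, move, obj)
            f0s.append(state.f0)
            if rec["f"] < f0s[-2]:  # a new best recentres the transform
                assert stun_transform(state.f0, state.f0) == 0.0
        assert all(b <= a for a, b in zip(f0s, f0s[1:]))

    def test_mode_alternates(self, lj_ff_cut):
        topo, conf = make_lj_cluster(4, seed=3)
        move = cluster_move_settings(4)
        obj = make_objective(topo, lj_ff_cut, "total")
        state, live = init_search_state(conf, topo, lj_ff_cut, obj, move,
                                        rng=np.random.default_rng(0))
        modes = []
        for _ in range(4):
            live, rec = stun_bh_dmd_step(state, live, topo, lj_ff_cut, move, obj)
            modes.append(rec["mode"])
        assert modes == ["MD", "DMD", "MD", "DMD"]

    def test_rejection_restores_last_accepted(self, lj_ff_cut):
        topo, conf = make_lj_cluster(6, seed=5)
        move = cluster_move_settings(6)
        obj = make_objective(topo, lj_ff_cut, "total")
        state, live = init_search_state(conf, topo, lj_ff_cut, obj, move,
                                        rng=np.random.default_rng(2))
        state.kT = 1e-6  # freeze: every uphill proposal must be rejected
        for _ in range(10):
            before = state.x_last.coords.copy()
            live, rec = stun_bh_dmd_step(state, live, topo, lj_ff_cut, move, obj)
            if not rec["accepted"]:
                assert np.array_equal(live.coords, before)

    def test_zero_iters_returns_minimized_input(self, lj_ff_cut):
        topo, conf = make_lj_cluster(4, seed=1)
        move = cluster_move_settings(4)
        res = run_search(conf, topo, lj_ff_cut, n_starts=1, iters_per_start=0,
                         seed=0, move=move, objective="total")
        assert res.best_f == pytest.approx(
            total_energy(res.best_conf, topo, lj_ff_cut))
        assert res.n_starts_completed == 1
        assert len(res.log) == 1  # just the init record

    def test_search_reproducible(self, lj_ff_cut):
        topo, conf = make_lj_cluster(4, seed=6)
        move = cluster_move_settings(4)
        r1 = run_search(conf, topo, lj_ff_cut, n_starts=2, iters_per_start=5,
                        seed=9, move=move, objective="total",
                        start_perturbation=1.0)
        r2 = run_search(conf, topo, lj_ff_cut, n_starts=2, iters_per_start=5,
                        seed=9, move=move, objective="total",
                        start_perturbation=1.0)
        assert r1.best_f == r2.best_f
        assert np.array_equal(r1.best_conf.coords, r2.best_conf.coords)

    def test_lj4_search_finds_tetrahedron(self, lj_ff_cut):
        topo, conf = make_lj_cluster(4, seed=2)
        move = cluster_move_settings(4)
        res = run_search(conf, topo, lj_ff_cut, n_starts=2, iters_per_start=15,
                         seed=0, move=move, objective="total",
                         start_perturbation=2.0)
        assert res.best_f == pytest.approx(-6.0, abs=1e-4)
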