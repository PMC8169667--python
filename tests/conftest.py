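"""Shared fixtures: force fields, clusters, a tiny solvated complex."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import R_MIN, SIGMA, random_solvated_toy  # noqa: E402
from stunbh.synthetic import lj_forcefield, make_lj_cluster, pocket_forcefield  # noqa: E402


@pytest.fixture
def lj_ff():
    """Single LJ type, cutoff far beyond any test geometry (no switching)."""
    return lj_forcefield(sigma=SIGMA, epsilon=1.0, r_cut=100.0, lj_shift_start=99.0)


@pytest.fixture
def lj_ff_cut():
    """Single LJ type with the standard 9-12 A switched cutoff."""
    return lj_forcefield(sigma=SIGMA, epsilon=1.0)


@pytest.fixture
def pocket_ff():
    return pocket_forcefield()


@pytest.fixture
def dimer(lj_ff):
    topo, conf = make_lj_cluster(2, sigma=SIGMA, seed=0)
    conf.coords[:] = [[0.0, 0.0, 0.0], [R_MIN, 0.0, 0.0]]
    return topo, conf


@pytest.fixture
def solvated_toy():
    return random_solvated_toy(seed=7)
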