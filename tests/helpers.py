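"""Test helpers: tiny constructed systems and independent oracles."""

import numpy as np

from stunbh.topology import BeadTopology, Conformation

SIGMA = 4.7
R_MIN = 2.0 ** (1.0 / 6.0) * SIGMA  # LJ pair-minimum distance, ~5.2756 A

#: Untruncated global-minimum energies of small LJ clusters, units of epsilon.
LJ_GLOBAL_MINIMA = {2: -1.0, 3: -3.0, 4: -6.0, 7: -16.505384}


def make_two_group_pair(r, charge_a=0.0, charge_b=0.0):
    """Two beads in different groups at separation r (for cross-group tests)."""
    topo = BeadTopology(
        bead_type=["LJ", "LJ"],
        mass=[72.0, 72.0],
        charge=[charge_a, charge_b],
        bonds=np.empty((0, 4)),
        angles=np.empty((0, 5)),
        group=["ligand", "receptor"],
        residue_id=[0, 0],
        backbone=[False, False],
    )
    conf = Conformation([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    return topo, conf


def random_solvated_toy(seed, n_lig=4, n_rec=8, n_sol=16, n_ion=2, box=28.0):
    """A random 30-bead periodic system with all four groups and charges.

    Coordinates are drawn with a 2.5 A minimum separation so energies stay
    finite; charges are random but exactly neutral overall.
    """
    rng = np.random.default_rng(seed)
    n = n_lig + n_rec + n_sol + n_ion
    coords = []
    while len(coords) < n:
        p = rng.uniform(0, box, size=3)
        if coords:
            d = np.array(coords) - p
            d -= box * np.round(d / box)
            if np.min(np.einsum("ij,ij->i", d, d)) < 2.5**2:
                continue
        coords.append(p)
    charge = np.round(rng.uniform(-1, 1, size=n), 2)
    charge -= charge.sum() / n
    types = ["LNB"] * n_lig + ["PKT"] * n_rec + ["W"] * n_sol + ["ION"] * n_ion
    groups = (["ligand"] * n_lig + ["receptor"] * n_rec
              + ["solvent"] * n_sol + ["ion"] * n_ion)
    topo = BeadTopology(
        bead_type=types,
        mass=np.full(n, 72.0),
        charge=charge,
        bonds=np.array([[0, 1, 5.0, 200.0], [n_lig, n_lig + 1, 5.0, 200.0]]),
        angles=np.empty((0, 5)),
        group=groups,
        residue_id=list(range(n_lig)) + list(range(n_rec)) + list(range(n_sol + n_ion)),
        backbone=[False] * n,
    )
    return topo, Conformation(np.array(coords), (box, box, box))


def multistart_cluster_minimum(n, ff, n_starts=200, seed=0, radius_factor=1.2):
    """Independent multi-start oracle for the LJ_n global minimum.

    Draws compact random configurations (uniform in a sphere of radius
    ``radius_factor * n^(1/3) * sigma``, 0.8 sigma minimum separation),
    relaxes each with the local minimizer, and returns the lowest energy.
    """
    from stunbh.minimize import local_minimize
    from stunbh.topology import BeadTopology, Conformation

    sigma = ff.lj_sigma["LJ"]
    rng = np.random.default_rng(seed)
    topo = BeadTopology(
        bead_type=["LJ"] * n, mass=[72.0] * n, charge=[0.0] * n,
        bonds=np.empty((0, 4)), angles=np.empty((0, 5)),
        group=["ligand"] * n, residue_id=list(range(n)), backbone=[False] * n,
    )
    radius = radius_factor * n ** (1.0 / 3.0) * sigma
    best = np.inf
    for _ in range(n_starts):
        coords = []
        while len(coords) < n:
            p = rng.uniform(-radius, radius, 3)
            if np.dot(p, p) > radius**2:
                continue
            if coords and np.min(np.linalg.norm(np.array(coords) - p, axis=1)) < 0.8 * sigma:
                continue
            coords.append(p)
        _, e, _ = local_minimize(Conformation(np.array(coords)), topo, ff,
                                 force_tol=1e-4, max_iter=10000)
        best = min(best, e)
    return best


def pose_grid_oracle(topo, conf, ff, trans_step=2.0, rot_step_deg=60.0, top_k=24):
    """Brute-force rigid-pose oracle for the pocket system's best binding energy.

    Scans a structured orientation grid (Euler zyz angles at *rot_step_deg*
    increments) crossed with a *trans_step* translation lattice of the
    rigid (pre-minimized) ligand over the receptor, keeps the
    lowest-interaction poses, relaxes each fully, and returns the best
    binding energy found.  Entirely independent of the stochastic search.
    """
    import itertools

    from scipy.spatial.transform import Rotation

    from stunbh.forcefield import (
        cross_pair_table,
        group_interaction_energy,
        switched_pair_energy,
    )
    from stunbh.minimize import local_minimize

    lig = topo.select("ligand")
    rec = topo.select("receptor")
    mc, _, _ = local_minimize(conf, topo, ff, force_tol=1e-2, method="lbfgs")
    lcoords = mc.coords[lig] - mc.coords[lig].mean(axis=0)
    rcoords = conf.coords[rec]
    gi, gj, sig, eps, qq = cross_pair_table(topo, ff, lig, rec)
    gil = np.array([{g: k for k, g in enumerate(lig)}[g] for g in gi])
    gjl = np.array([{g: k for k, g in enumerate(rec)}[g] for g in gj])
    lo = rcoords.min(axis=0) - 8.0
    hi = rcoords.max(axis=0) + 8.0
    axes = [np.arange(lo[d], hi[d] + 1e-9, trans_step) for d in range(3)]
    T = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    angles = list(itertools.product(
        np.arange(0.0, 360.0, rot_step_deg),
        np.arange(0.0, 180.0 + 1e-9, rot_step_deg),
        np.arange(0.0, 360.0, rot_step_deg),
    ))
    rots = Rotation.from_euler("zyz", angles, degrees=True)
    candidates = []
    for rot in rots:
        lc = rot.apply(lcoords)
        base = lc[gil] - rcoords[gjl]
        d = base[None, :, :] + T[:, None, :]
        r = np.sqrt(np.einsum("mpk,mpk->mp", d, d))
        e = switched_pair_energy(r, sig, eps, qq, ff).sum(axis=1)
        for idx in np.argsort(e)[:2]:
            candidates.append((float(e[idx]), rot, T[idx]))
    candidates.sort(key=lambda c: c[0])
    best = np.inf
    for _, rot, t in candidates[:top_k]:
        cc = conf.copy()
        cc.coords[lig] = rot.apply(lcoords) + t
        mcc, _, _ = local_minimize(cc, topo, ff, force_tol=1e-2, method="lbfgs")
        best = min(best, group_interaction_energy(mcc, topo, ff))
    return best
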