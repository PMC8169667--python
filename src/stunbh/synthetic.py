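"""Synthetic bead systems with known structure.

Three families of fixtures stand in for a real coarse-grained
aptamer/protein complex:

* Lennard-Jones clusters, whose global minima are known analytically for
  small n (dimer -eps, triangle -3 eps, tetrahedron -6 eps) — the
  canonical benchmark surface for basin-hopping searches;
* a pocket-bearing receptor (a U-shaped groove of stiffly bonded beads,
  its floor lined with an attractive bead type) plus a flexible
  ligand chain carrying pendant "nucleobase" beads, so the groove-bound
  pose is the designed optimum of the ligand-receptor interaction energy;
* explicit solvent: water beads (one bead = four waters, 72 amu) inserted
  at random to a target mass density, and counterions replacing water
  beads until the system is neutral.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .stun_search import MoveSettings
from .topology import BeadTopology, Conformation, ForceFieldParams, InputError
from .units import KB

WATER_MASS = 72.0          # amu; one MARTINI-style bead = 4 waters
WATER_SIGMA = 4.7          # A
WATER_EPSILON = 5.0        # kJ/mol


def lj_forcefield(
    sigma: float = 4.7,
    epsilon: float = 1.0,
    r_cut: float = 12.0,
    lj_shift_start: float = 9.0,
) -> ForceFieldParams:
    """Parameters for a single neutral LJ bead type ``"LJ"``."""
    return ForceFieldParams(
        lj_sigma={"LJ": sigma},
        lj_epsilon={"LJ": epsilon},
        r_cut=r_cut,
        lj_shift_start=lj_shift_start,
    )


def make_lj_cluster(
    n: int,
    sigma: float = 4.7,
    epsilon: float = 1.0,
    seed: Optional[int] = None,
) -> tuple[BeadTopology, Conformation]:
    """n identical neutral LJ beads at random non-overlapping positions.

    Positions are drawn uniformly in a sphere of radius ``2 n^(1/3) sigma``
    with a minimum pair separation of ``0.9 sigma``; there are no bonds.
    Pair with :func:`lj_forcefield` and :func:`cluster_move_settings`.
    """
    if n < 2:
        raise InputError("a cluster needs at least 2 beads")
    rng = np.random.default_rng(seed)
    radius = 2.0 * n ** (1.0 / 3.0) * sigma
    min_sep = 0.9 * sigma
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place non-overlapping cluster beads")
        p = rng.uniform(-radius, radius, size=3)
        if np.dot(p, p) > radius**2:
            continue
        if coords and np.min(np.linalg.norm(np.array(coords) - p, axis=1)) < min_sep:
            continue
        coords.append(p)
    topo = BeadTopology(
        bead_type=["LJ"] * n,
        mass=[72.0] * n,
        charge=[0.0] * n,
        bonds=np.empty((0, 4)),
        angles=np.empty((0, 5)),
        group=["ligand"] * n,
        residue_id=list(range(n)),
        backbone=[False] * n,
    )
    return topo, Conformation(np.array(coords))


def cluster_move_settings(
    n: int, sigma: float = 4.7, epsilon: float = 1.0
) -> MoveSettings:
    """Proposal-move settings matched to a cluster's energy scale.

    The move temperature is set so kB*T ~ 0.7 eps (hot enough to hop
    between basins of order-eps depth, cool enough not to atomise the
    cluster outright), and a flat-bottom spherical restraint keeps beads
    from drifting beyond interaction range in the open boundary.
    """
    return MoveSettings(
        temperature=0.7 * epsilon / KB,
        dt=10.0,
        n_steps=100,
        containment_k=2.0,
        containment_radius=sigma * (0.5 + 0.45 * n ** (1.0 / 3.0)),
    )


# --------------------------------------------------------------------------
# pocket receptor + ligand chain

LATTICE = 5.0  # A, receptor bead spacing and ligand rest bond length


def pocket_forcefield() -> ForceFieldParams:
    """Typed parameters for the pocket fixture.

    Groove-floor beads (``PKT``) attract ligand nucleobase beads (``LNB``)
    through an explicit pair-table entry much stronger than the
    Lorentz-Berthelot background, making the groove-bound pose the
    designed optimum; wall beads (``WAL``) are weakly interacting.
    """
    return ForceFieldParams(
        lj_sigma={"LBB": 4.7, "LNB": 4.7, "PKT": 4.7, "WAL": 4.7,
                  "W": WATER_SIGMA, "ION": WATER_SIGMA},
        lj_epsilon={"LBB": 0.5, "LNB": 2.0, "PKT": 2.0, "WAL": 0.05,
                    "W": WATER_EPSILON, "ION": WATER_EPSILON},
        pair_table={("LNB", "PKT"): (4.7, 3.0), ("LBB", "PKT"): (4.7, 0.3)},
    )


def make_pocket_system(
    n_ligand: int = 6,
    pocket_depth: float = 10.0,
    seed: Optional[int] = None,
    charge_pattern: Optional[str] = None,
    pose: str = "above",
    nx: int = 10,
    nz: int = 5,
    box: Optional[tuple[float, float, float]] = None,
    ligand_bond_k: float = 300.0,
    ligand_angle_k: float = 200.0,
    receptor_bond_k: float = 400.0,
) -> tuple[BeadTopology, Conformation]:
    """Pocket-bearing receptor plus a flexible pendant-bead ligand chain.

    The receptor is a U-shaped groove on a 5 A lattice: an ``nx * nz``
    floor with two walls of ``pocket_depth / 5`` rows along its long
    edges, held near-rigid by stiff harmonic bonds between lattice
    neighbours.  The ligand is a chain of *n_ligand* backbone beads, each
    carrying one pendant nucleobase bead (harmonic bonds and angles).

    ``pose``: ``"above"`` (ligand hovering over the groove, out of
    contact — the usual search start), ``"groove"`` (bound in the groove,
    bases toward the attractive floor) or ``"wall"`` (laid against the
    outer wall face; same internal ligand conformation as ``"groove"``).

    ``charge_pattern=None`` leaves everything neutral; ``"paired"`` puts
    -1 e on every other nucleobase bead and +1 e on an equal number of
    groove-floor beads, so the designed total charge is always zero.

    ``ligand_bond_k`` / ``ligand_angle_k`` set the ligand's internal
    stiffness; raise them to make the chain effectively rigid (useful when
    comparing against rigid-pose oracles).  ``receptor_bond_k`` sets the
    receptor lattice stiffness; raise it to make the groove surface
    effectively impenetrable.
    """
    if n_ligand < 3:
        raise InputError("ligand chain needs at least 3 backbone beads")
    a = LATTICE
    wall_rows = max(int(round(pocket_depth / a)), 1)

    r_coords: list[list[float]] = []
    r_types: list[str] = []
    # floor (y = 0) on a half-spacing sub-lattice: bead spacing well below
    # sigma makes the surface smooth (no site-registration wells a ligand
    # bead could nestle into, and no hollows to penetrate); the interior
    # strip is the attractive pocket lining
    half = a / 2.0
    for i in range(2 * nx - 1):
        for j in range(2 * nz - 1):
            x, z = i * half, j * half
            r_coords.append([x, 0.0, z])
            r_types.append("PKT" if a - 1e-9 <= z <= (nz - 2) * a + 1e-9 else "WAL")
    # two walls along the x edges of the floor
    for i in range(nx):
        for h in range(1, wall_rows + 1):
            for zj in (0, nz - 1):
                r_coords.append([i * a, h * a, zj * a])
                r_types.append("WAL")
    n_rec = len(r_coords)
    r_coords_arr = np.array(r_coords)

    # stiff bonds between lattice neighbours keep the receptor near-rigid
    bonds: list[tuple[int, int, float, float]] = []
    for p in range(n_rec):
        for q in range(p + 1, n_rec):
            d = float(np.linalg.norm(r_coords_arr[p] - r_coords_arr[q]))
            if d < 1.03 * a:  # floor 1st-3rd shells, wall-wall, wall-floor
                bonds.append((p, q, d, receptor_bond_k))

    # ligand: backbone along x, one pendant nucleobase bead per backbone bead
    z_c = (nz - 1) * a / 2.0
    r_contact = 2.0 ** (1.0 / 6.0) * 4.7  # LJ minimum distance, ~5.27 A
    x0 = (nx - n_ligand) * a / 2.0
    if pose == "groove":
        y_base, y_bb, z_lig = r_contact, r_contact + a, z_c
    elif pose == "wall":
        y_base = y_bb = max(wall_rows * a / 2.0, a)
        z_lig = None  # handled below: bases toward the z=0 wall face
    elif pose == "above":
        y_base, y_bb, z_lig = wall_rows * a + 10.0, wall_rows * a + 15.0, z_c
    else:
        raise InputError(f"unknown pose {pose!r}")

    l_coords: list[list[float]] = []
    l_types: list[str] = []
    l_backbone: list[bool] = []
    for k in range(n_ligand):
        x = x0 + k * a
        if pose == "wall":
            l_coords.append([x, y_bb, -r_contact - a])      # backbone, outside
            l_coords.append([x, y_base, -r_contact])        # base, facing wall
        else:
            l_coords.append([x, y_bb, z_lig])
            l_coords.append([x, y_base, z_lig])
        l_types += ["LBB", "LNB"]
        l_backbone += [True, False]

    n_lig = len(l_coords)
    for k in range(n_ligand - 1):  # backbone chain
        bonds.append((n_rec + 2 * k, n_rec + 2 * (k + 1), a, ligand_bond_k))
    for k in range(n_ligand):      # pendant bases
        bonds.append((n_rec + 2 * k, n_rec + 2 * k + 1, a, ligand_bond_k))

    angles: list[tuple[int, int, int, float, float]] = []
    for k in range(n_ligand - 2):  # straight backbone
        angles.append(
            (n_rec + 2 * k, n_rec + 2 * (k + 1), n_rec + 2 * (k + 2), 180.0, ligand_angle_k)
        )
    for k in range(n_ligand - 1):  # base perpendicular to the chain
        angles.append(
            (n_rec + 2 * k + 1, n_rec + 2 * k, n_rec + 2 * (k + 1), 90.0, ligand_angle_k)
        )

    charge = np.zeros(n_rec + n_lig)
    if charge_pattern == "paired":
        base_idx = [n_rec + 2 * k + 1 for k in range(0, n_ligand, 2)]
        pkt_idx = [p for p, t in enumerate(r_types) if t == "PKT"]
        if len(pkt_idx) < len(base_idx):
            raise InputError("not enough pocket beads to pair charges")
        rng = np.random.default_rng(seed)
        chosen = rng.choice(pkt_idx, size=len(base_idx), replace=False)
        charge[base_idx] = -1.0
        charge[chosen] = 1.0
    elif charge_pattern is not None:
        raise InputError(f"unknown charge_pattern {charge_pattern!r}")

    coords = np.vstack([r_coords_arr, np.array(l_coords)])
    if box is not None:
        coords = coords - coords.mean(axis=0) + 0.5 * np.asarray(box)

    residue = np.concatenate([
        np.arange(n_rec),                       # one residue per receptor bead
        np.repeat(np.arange(n_ligand), 2),      # bb + base share a nucleobase id
    ])
    topo = BeadTopology(
        bead_type=r_types + l_types,
        mass=[72.0] * (n_rec + n_lig),
        charge=charge,
        bonds=np.array(bonds, dtype=float),
        angles=np.array(angles, dtype=float) if angles else np.empty((0, 5)),
        group=["receptor"] * n_rec + ["ligand"] * n_lig,
        residue_id=residue,
        backbone=[False] * n_rec + l_backbone,
    )
    return topo, Conformation(coords, box)


# --------------------------------------------------------------------------
# solvation

def solvate(
    conf: Conformation,
    topo: BeadTopology,
    density: float = 1.0,
    min_dist: float = 5.0,
    seed: Optional[int] = None,
    water_min_dist: float = 4.0,
    max_attempts: int = 1_000_000,
) -> tuple[BeadTopology, Conformation]:
    """Insert water beads at random until the mass density reaches *density*.

    Candidates are drawn uniformly in the periodic box and rejected if
    closer (minimum image) than *min_dist* to any pre-existing solute bead
    or *water_min_dist* to an already-inserted water.  Each water bead is
    type ``"W"``, 72 amu, neutral, its own residue.
    """
    if conf.box is None:
        raise InputError("solvation requires a periodic box")
    rng = np.random.default_rng(seed)
    L = np.asarray(conf.box)
    volume = float(np.prod(L))
    current_mass = float(topo.mass.sum())
    # density [g/cm^3] * V [A^3] -> amu:  1 g/cm^3 = 0.60221408 amu/A^3
    amu_per_a3 = density / 1.66053906660 * 1.0
    n_water = int(round((amu_per_a3 * volume - current_mass) / WATER_MASS))
    if n_water <= 0:
        raise InputError("system already at or above the requested density")

    from scipy.spatial import cKDTree

    solute_tree = cKDTree(np.mod(conf.coords, L), boxsize=L) if conf.n_beads else None
    placed: list[np.ndarray] = []
    attempts = 0
    batch = 256
    while len(placed) < n_water:
        if attempts > max_attempts:
            raise RuntimeError(
                f"placed only {len(placed)}/{n_water} water beads after "
                f"{max_attempts} attempts; lower the density or min_dist"
            )
        cand = rng.uniform(0.0, L, size=(batch, 3))
        attempts += batch
        ok = np.ones(batch, dtype=bool)
        if solute_tree is not None:
            d, _ = solute_tree.query(cand)
            ok &= d >= min_dist
        if placed:
            wtree = cKDTree(np.array(placed), boxsize=L)
            d, _ = wtree.query(cand)
            ok &= d >= water_min_dist
        fresh: list[np.ndarray] = []
        for p in cand[ok]:
            if fresh:
                dw = np.array(fresh) - p
                dw -= L * np.round(dw / L)
                if np.min(np.einsum("ij,ij->i", dw, dw)) < water_min_dist**2:
                    continue
            fresh.append(p)
            placed.append(p)
            if len(placed) == n_water:
                break

    n0 = topo.n_beads
    res0 = int(topo.residue_id.max()) + 1 if n0 else 0
    new_topo = BeadTopology(
        bead_type=np.concatenate([topo.bead_type, np.array(["W"] * n_water, dtype=object)]),
        mass=np.concatenate([topo.mass, np.full(n_water, WATER_MASS)]),
        charge=np.concatenate([topo.charge, np.zeros(n_water)]),
        bonds=topo.bonds,
        angles=topo.angles,
        group=np.concatenate([topo.group, np.array(["solvent"] * n_water, dtype=object)]),
        residue_id=np.concatenate([topo.residue_id, res0 + np.arange(n_water)]),
        backbone=np.concatenate([topo.backbone, np.zeros(n_water, dtype=bool)]),
    )
    new_conf = Conformation(np.vstack([conf.coords, np.array(placed)]), conf.box)
    return new_topo, new_conf


def add_counterions(
    topo: BeadTopology,
    conf: Conformation,
    ion_charge: float = 1.0,
    seed: Optional[int] = None,
) -> tuple[BeadTopology, Conformation]:
    """Neutralise the system by turning random water beads into ions.

    The total charge must be an integer multiple of ``-ion_charge``; the
    bead count is conserved (waters are converted in place).
    An already-neutral system is returned unchanged.
    """
    net = topo.total_charge()
    if abs(net) < 1e-9:
        return topo, conf
    n_ions_f = -net / ion_charge
    n_ions = int(round(n_ions_f))
    if n_ions <= 0 or abs(n_ions_f - n_ions) > 1e-6:
        raise InputError(
            f"net charge {net:+.3f} e cannot be neutralised with "
            f"ions of charge {ion_charge:+.3f} e"
        )
    waters = np.flatnonzero(topo.group == "solvent")
    if len(waters) < n_ions:
        raise InputError(f"need {n_ions} water beads to convert, have {len(waters)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(waters, size=n_ions, replace=False)
    bead_type = topo.bead_type.copy()
    charge = topo.charge.copy()
    group = topo.group.copy()
    bead_type[chosen] = "ION"
    charge[chosen] = ion_charge
    group[chosen] = "ion"
    new_topo = BeadTopology(
        bead_type=bead_type, mass=topo.mass.copy(), charge=charge,
        bonds=topo.bonds, angles=topo.angles, group=group,
        residue_id=topo.residue_id.copy(), backbone=topo.backbone.copy(),
    )
    return new_topo, conf.copy()
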