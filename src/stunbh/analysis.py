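"""Trajectory observables: RMSD, Rg, RMSF, COM distances, interaction maps,
and solvent-shell counts.

All functions are pure: repeated calls on the same (trajectory, topology,
parameters) return identical results.  Superpositions use the Kabsch
algorithm (unweighted least-squares rigid fit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dynamics import Trajectory
from .forcefield import cross_pair_energies
from .topology import (
    BeadTopology,
    Conformation,
    ForceFieldParams,
    InputError,
    displacement,
)

Selection = Union[str, Sequence[int], np.ndarray]


def _indices(topo: Optional[BeadTopology], sel: Optional[Selection], n: int) -> np.ndarray:
    if sel is None:
        return np.arange(n)
    if isinstance(sel, str):
        if topo is None:
            raise InputError("group-name selections need a topology")
        return topo.select(sel)
    return np.asarray(sel, dtype=int)


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of *mobile* onto *reference*.

    Returns (rotation matrix R, translation t, transformed mobile), with
    ``transformed = (mobile - mobile_centroid) @ R.T + ref_centroid``.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (mobile - mc) @ R.T + rc
    return R, rc - mc, moved


def rmsd(
    conf: Conformation,
    ref: Conformation,
    selection: Optional[Selection] = None,
    fit: bool = True,
    topo: Optional[BeadTopology] = None,
) -> float:
    """Root-mean-square deviation between two structures, A (mass-unweighted).

    With ``fit=True`` the selected beads are first superposed onto the
    reference (Kabsch); otherwise coordinates are compared as given.
    """
    if selection is None and conf.n_beads != ref.n_beads:
        raise InputError("structure and reference have different bead counts")
    idx = _indices(topo, selection, conf.n_beads)
    if idx.size and (idx.max() >= conf.n_beads or idx.max() >= ref.n_beads):
        raise InputError("selection sizes differ between structure and reference")
    a = conf.coords[idx]
    b = ref.coords[idx]
    if fit:
        _, _, a = kabsch_superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def radius_of_gyration(
    conf: Conformation,
    topo: BeadTopology,
    selection: Optional[Selection] = None,
    literal_unnormalized: bool = False,
) -> float:
    """Mass-weighted radius of gyration of a selection, A.

    Rg = sqrt( sum_i m_i |r_i - r_COM|^2 / sum_i m_i ) about the
    selection's mass centre.  ``literal_unnormalized=True`` skips the
    division by total mass (a compatibility variant, dimensionally
    amu^1/2 * A, useful only as a relative stability monitor).
    """
    idx = _indices(topo, selection, conf.n_beads)
    if idx.size == 0:
        raise InputError("empty selection")
    m = topo.mass[idx]
    r = conf.coords[idx]
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    s = float(np.sum(m * np.sum((r - com) ** 2, axis=1)))
    if literal_unnormalized:
        return float(np.sqrt(s))
    return float(np.sqrt(s / m.sum()))


def rmsf(
    traj: Trajectory,
    topo: BeadTopology,
    group_by: str = "nucleobase",
    window: Optional[tuple[int, int]] = None,
    fit: bool = True,
    fit_selection: Selection = "receptor",
) -> pd.Series:
    """Per-bead root-mean-square fluctuation, aggregated per ligand nucleobase.

    Frames in the window are superposed (Kabsch on *fit_selection*) onto
    the window-mean structure; per-bead RMSF is the RMS displacement from
    the superposed mean.  ``group_by="nucleobase"`` averages member-bead
    values within each ligand residue; ``group_by="bead"`` returns the
    per-bead values for every bead.
    """
    lo, hi = window if window is not None else (0, len(traj))
    X = traj.coords[lo:hi].copy()
    if len(X) < 2:
        raise InputError("RMSF window must contain at least 2 frames")
    if fit:
        fidx = _indices(topo, fit_selection, X.shape[1])
        if fidx.size < 3:
            raise InputError("fit selection needs at least 3 beads")
        ref = X[0][fidx]
        for _ in range(2):  # fit to running mean, twice for self-consistency
            for k in range(len(X)):
                R, _, _ = kabsch_superpose(X[k][fidx], ref)
                mc = X[k][fidx].mean(axis=0)
                rc = ref.mean(axis=0)
                X[k] = (X[k] - mc) @ R.T + rc
            ref = X[:, fidx].mean(axis=0)
    mean = X.mean(axis=0)
    per_bead = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    if group_by == "bead":
        return pd.Series(per_bead, name="rmsf")
    if group_by != "nucleobase":
        raise InputError(f"unknown group_by {group_by!r}")
    lig = topo.select("ligand")
    out = {}
    for res in np.unique(topo.residue_id[lig]):
        members = lig[topo.residue_id[lig] == res]
        out[int(res)] = float(per_bead[members].mean())
    return pd.Series(out, name="rmsf").sort_index()


def com_distance_trace(
    traj: Trajectory,
    topo: BeadTopology,
    group_a: Selection = "ligand",
    group_b: Selection = "receptor",
    per_nucleobase: bool = False,
) -> Union[np.ndarray, pd.DataFrame]:
    """Per-frame mass-centre distance between two selections, A.

    Minimum-image when the trajectory is periodic.  With
    ``per_nucleobase=True`` group_a is split by ligand residue id and a
    DataFrame (frames x nucleobases) is returned.
    """
    ib = _indices(topo, group_b, traj.coords.shape[1])
    mb = topo.mass[ib][:, None]

    def trace(ia: np.ndarray) -> np.ndarray:
        ma = topo.mass[ia][:, None]
        ca = (traj.coords[:, ia] * ma).sum(axis=1) / ma.sum()
        cb = (traj.coords[:, ib] * mb).sum(axis=1) / mb.sum()
        d = displacement(ca, cb, traj.box)
        return np.linalg.norm(d, axis=1)

    if not per_nucleobase:
        ia = _indices(topo, group_a, traj.coords.shape[1])
        if ia.size == 0 or ib.size == 0:
            raise InputError("empty selection")
        return trace(ia)
    lig = _indices(topo, group_a, traj.coords.shape[1])
    cols = {}
    for res in np.unique(topo.residue_id[lig]):
        cols[int(res)] = trace(lig[topo.residue_id[lig] == res])
    return pd.DataFrame(cols)


@dataclass
class InteractionMap:
    """Residue x nucleobase mean interaction-energy matrix, kJ/mol.

    Rows are receptor residues, columns ligand nucleobases; entries are
    the time-mean nonbonded interaction energy between the two bead sets
    over the averaging window.  ``histogram`` (column sums) is the total
    interaction energy of each nucleobase with the whole receptor; the
    ``mask`` highlights entries at or below the threshold (default
    -8.4 kJ/mol, the level used to flag persistent contacts).
    """

    matrix: pd.DataFrame
    window: tuple[int, int]
    threshold: float = -8.4

    @property
    def histogram(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def mask(self) -> pd.DataFrame:
        return self.matrix <= self.threshold


def interaction_map(
    traj: Trajectory,
    topo: BeadTopology,
    ff: ForceFieldParams,
    window: Optional[tuple[int, int]] = None,
    threshold: float = -8.4,
) -> InteractionMap:
    """Mean ligand-receptor interaction energy binned by (residue, nucleobase).

    Each matrix entry is the time average, over the window, of the
    nonbonded cross-pair energy between one receptor residue's beads and
    one nucleobase's beads; the column sums therefore reproduce the
    per-nucleobase interaction histogram and the matrix total equals the
    time-mean total ligand-receptor interaction energy.
    """
    lo, hi = window if window is not None else (0, len(traj))
    if hi <= lo:
        raise InputError("empty averaging window")
    rec = topo.select("receptor")
    lig = topo.select("ligand")
    res_ids = np.unique(topo.residue_id[rec])
    base_ids = np.unique(topo.residue_id[lig])
    res_pos = {r: k for k, r in enumerate(res_ids)}
    base_pos = {b: k for k, b in enumerate(base_ids)}
    acc = np.zeros((len(res_ids), len(base_ids)))
    rows = cols = None
    for f in range(lo, hi):
        conf = traj.frame(f)
        gi, gj, e = cross_pair_energies(conf, topo, ff, lig, rec)
        if rows is None:
            rows = np.array([res_pos[topo.residue_id[j]] for j in gj])
            cols = np.array([base_pos[topo.residue_id[i]] for i in gi])
        np.add.at(acc, (rows, cols), e)
    acc /= hi - lo
    matrix = pd.DataFrame(acc, index=res_ids, columns=base_ids)
    matrix.index.name = "receptor_residue"
    matrix.columns.name = "nucleobase"
    return InteractionMap(matrix, (lo, hi), threshold)


def count_within(
    conf: Conformation,
    topo: BeadTopology,
    around: Selection,
    target_group: Selection,
    cutoff: float,
) -> tuple[int, np.ndarray]:
    """Beads of *target_group* strictly within *cutoff* A of any bead of
    *around* (minimum image when periodic).  Returns (count, bead ids).
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    ia = _indices(topo, around, conf.n_beads)
    it = _indices(topo, target_group, conf.n_beads)
    if it.size == 0 or ia.size == 0:
        return 0, np.array([], dtype=int)
    pa = conf.coords[ia]
    pt = conf.coords[it]
    if conf.box is not None:
        L = np.asarray(conf.box)
        tree = cKDTree(np.mod(pt, L), boxsize=L)
        cand = tree.query_ball_point(np.mod(pa, L), r=cutoff)
    else:
        tree = cKDTree(pt)
        cand = tree.query_ball_point(pa, r=cutoff)
    hits: set[int] = set()
    for a_row, lst in zip(pa, cand):
        for t_k in lst:
            d = displacement(pt[t_k], a_row, conf.box)
            if float(d @ d) < cutoff**2:
                hits.add(int(it[t_k]))
    ids = np.array(sorted(hits), dtype=int)
    return len(ids), ids
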