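"""Bead-level potential energy, forces, and the binding-energy objective.

The model is a MARTINI-style coarse-grained potential:

* harmonic bonds ``0.5 k (r - r0)^2`` and harmonic angles
  ``0.5 k_a (theta - theta0)^2`` (never minimum-imaged);
* 12-6 Lennard-Jones plus screened Coulomb ``k_e q_i q_j / (eps_r r)``
  between all non-excluded pairs, each multiplied by a quintic switching
  polynomial so the potential and its derivative reach exactly zero at
  the cutoff (GROMACS-style shifted MARTINI interactions);
* nonbonded exclusions for 1-2 (bond) and 1-3 (angle) pairs;
* orthorhombic minimum-image convention when a box is present.

Both nonbonded terms carry a uniform ``nonbonded_scale`` factor.  The
search's "discrete molecular dynamics" proposal mode is exactly this
potential with the scale set to 0.01 (:func:`dmd_scaled_params`): beads
rearrange almost freely while bonded structure is preserved.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Union

import numpy as np

from .topology import (
    BeadTopology,
    Conformation,
    ForceFieldParams,
    InputError,
    TopologyError,
)

Selection = Union[str, Sequence[int], np.ndarray]


# --------------------------------------------------------------------------
# cached pair data

class _NBData:
    """Precomputed nonbonded pair lists for one (topology, parameter) pair."""

    __slots__ = ("i", "j", "sigma", "epsilon", "qq", "bonds", "angles")

    def __init__(self, topo: BeadTopology, ff: ForceFieldParams):
        n = topo.n_beads
        iu, ju = np.triu_indices(n, k=1)
        excl = topo.excluded_pairs()
        if excl:
            keep = np.array([(a, b) not in excl for a, b in zip(iu, ju)])
            iu, ju = iu[keep], ju[keep]
        self.i = iu
        self.j = ju
        types = topo.bead_type
        # per-pair LJ parameters via the (possibly tabulated) combination rule
        uniq = {t: k for k, t in enumerate(dict.fromkeys(types))}
        tcode = np.array([uniq[t] for t in types])
        nt = len(uniq)
        sig_tab = np.empty((nt, nt))
        eps_tab = np.empty((nt, nt))
        for ta, ka in uniq.items():
            for tb, kb in uniq.items():
                sig_tab[ka, kb], eps_tab[ka, kb] = ff.pair_params(ta, tb)
        self.sigma = sig_tab[tcode[iu], tcode[ju]]
        self.epsilon = eps_tab[tcode[iu], tcode[ju]]
        self.qq = (
            topo.charge[iu] * topo.charge[ju] * ff.coulomb_prefactor / ff.dielectric
        )
        self.bonds = topo.bonds
        self.angles = topo.angles


def _ff_key(ff: ForceFieldParams) -> tuple:
    return (
        tuple(sorted(ff.lj_sigma.items())),
        tuple(sorted(ff.lj_epsilon.items())),
        tuple(sorted(ff.pair_table.items())),
        ff.dielectric,
        ff.coulomb_prefactor,
    )


def _get_nb(topo: BeadTopology, ff: ForceFieldParams) -> _NBData:
    cache = getattr(topo, "_nb_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(topo, "_nb_cache", cache)
    key = _ff_key(ff)
    if key not in cache:
        cache[key] = _NBData(topo, ff)
    return cache[key]


# --------------------------------------------------------------------------
# switching polynomial

def _switch(r: np.ndarray, r_on: float, r_cut: float):
    """Quintic switch S(r) and dS/dr: S=1 below r_on, 0 beyond r_cut,
    with zero first and second derivatives at both ends."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    w = r_cut - r_on
    mid = (r > r_on) & (r < r_cut)
    t = (r[mid] - r_on) / w
    s[mid] = 1.0 + t**3 * (-10.0 + t * (15.0 - 6.0 * t))
    ds[mid] = -30.0 * t**2 * (1.0 - t) ** 2 / w
    s[r >= r_cut] = 0.0
    return s, ds


# --------------------------------------------------------------------------
# evaluation kernels

def _nb_pair_energy(r, sigma, epsilon, qq, ff):
    """Per-pair switched nonbonded energies (without the global scale)."""
    inv = np.zeros_like(r)
    inside = r < ff.r_cut
    inv[inside] = 1.0 / r[inside]
    sr6 = (sigma * inv) ** 6
    e_lj = 4.0 * epsilon * sr6 * (sr6 - 1.0)
    e_c = qq * inv
    s_lj, _ = _switch(r, ff.lj_shift_start, ff.r_cut)
    s_c, _ = _switch(r, ff.coulomb_shift_start, ff.r_cut)
    return e_lj * s_lj + e_c * s_c


def _nb_eval(coords, box, nb: _NBData, ff: ForceFieldParams, want_forces: bool):
    """Switched, scaled nonbonded energy (and forces) over a pair list."""
    d = coords[nb.i] - coords[nb.j]
    if box is not None:
        L = np.asarray(box)
        d -= L * np.round(d / L)
    r2 = np.einsum("ij,ij->i", d, d)
    r = np.sqrt(r2)
    inside = r < ff.r_cut
    scale = ff.nonbonded_scale
    if not inside.any():
        if want_forces:
            return 0.0, np.zeros_like(coords)
        return 0.0, None
    ri, rj = nb.i[inside], nb.j[inside]
    rr = r[inside]
    dd = d[inside]
    sigma = nb.sigma[inside]
    epsilon = nb.epsilon[inside]
    qq = nb.qq[inside]
    if np.any(rr < 1e-6):
        k = int(np.argmin(rr))
        raise InputError(
            f"bead overlap: pair ({ri[k]}, {rj[k]}) at r={rr[k]:.2e} A"
        )
    inv = 1.0 / rr
    sr6 = (sigma * inv) ** 6
    e_lj = 4.0 * epsilon * sr6 * (sr6 - 1.0)
    e_c = qq * inv
    s_lj, ds_lj = _switch(rr, ff.lj_shift_start, ff.r_cut)
    s_c, ds_c = _switch(rr, ff.coulomb_shift_start, ff.r_cut)
    energy = scale * float(np.sum(e_lj * s_lj + e_c * s_c))
    if not want_forces:
        return energy, None
    # dV/dr of the bare terms
    dlj = 4.0 * epsilon * sr6 * (6.0 - 12.0 * sr6) * inv
    dc = -e_c * inv
    dvdr = scale * (dlj * s_lj + e_lj * ds_lj + dc * s_c + e_c * ds_c)
    fpair = (-dvdr * inv)[:, None] * dd  # force on bead i along +d
    F = _scatter_pair_forces(len(coords), ri, rj, fpair)
    return energy, F


def _scatter_pair_forces(n, i, j, fpair):
    """Accumulate +fpair on beads i and -fpair on beads j (bincount-based;
    much faster than np.add.at for many pairs)."""
    F = np.empty((n, 3))
    for k in range(3):
        F[:, k] = np.bincount(i, weights=fpair[:, k], minlength=n) - np.bincount(
            j, weights=fpair[:, k], minlength=n
        )
    return F


def _bonded_eval(coords, nb: _NBData, want_forces: bool):
    energy = 0.0
    F = np.zeros_like(coords) if want_forces else None
    if nb.bonds.size:
        bi = nb.bonds[:, 0].astype(int)
        bj = nb.bonds[:, 1].astype(int)
        r0 = nb.bonds[:, 2]
        k = nb.bonds[:, 3]
        d = coords[bi] - coords[bj]  # bonded terms are never wrapped
        r = np.linalg.norm(d, axis=1)
        dr = r - r0
        energy += float(np.sum(0.5 * k * dr**2))
        if want_forces:
            with np.errstate(invalid="ignore", divide="ignore"):
                fmag = np.where(r > 0, -k * dr / r, 0.0)
            F += _scatter_pair_forces(len(coords), bi, bj, fmag[:, None] * d)
    if nb.angles.size:
        ai = nb.angles[:, 0].astype(int)
        aj = nb.angles[:, 1].astype(int)
        ak = nb.angles[:, 2].astype(int)
        th0 = np.deg2rad(nb.angles[:, 3])
        ka = nb.angles[:, 4]
        u = coords[ai] - coords[aj]
        v = coords[ak] - coords[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.einsum("ij,ij->i", u, v) / (nu * nv)
        c = np.clip(c, -1.0, 1.0)
        theta = np.arccos(c)
        dth = theta - th0
        energy += float(np.sum(0.5 * ka * dth**2))
        if want_forces:
            s = np.sqrt(np.maximum(1.0 - c**2, 1e-12))
            # dE/dtheta = ka * dth; dtheta/dcos = -1/sin
            coef = ka * dth / s
            du = (v / nv[:, None] - c[:, None] * u / nu[:, None]) / nu[:, None]
            dv = (u / nu[:, None] - c[:, None] * v / nv[:, None]) / nv[:, None]
            fu = coef[:, None] * du
            fv = coef[:, None] * dv
            n_beads = len(coords)
            for k in range(3):
                F[:, k] += (
                    np.bincount(ai, weights=fu[:, k], minlength=n_beads)
                    + np.bincount(ak, weights=fv[:, k], minlength=n_beads)
                    - np.bincount(aj, weights=(fu + fv)[:, k], minlength=n_beads)
                )
    return energy, F


def _validate(conf: Conformation, topo: BeadTopology) -> None:
    if conf.n_beads != topo.n_beads:
        raise TopologyError(
            f"conformation has {conf.n_beads} beads, topology {topo.n_beads}"
        )
    if not np.all(np.isfinite(conf.coords)):
        raise InputError("non-finite coordinates")


# --------------------------------------------------------------------------
# public API

def total_energy(
    conf: Conformation, topo: BeadTopology, ff: ForceFieldParams
) -> float:
    """Total potential energy, kJ/mol (bonds + angles + switched LJ + Coulomb)."""
    _validate(conf, topo)
    nb = _get_nb(topo, ff)
    e_nb, _ = _nb_eval(conf.coords, conf.box, nb, ff, want_forces=False)
    e_b, _ = _bonded_eval(conf.coords, nb, want_forces=False)
    return e_nb + e_b


def energy_and_forces(
    conf: Conformation, topo: BeadTopology, ff: ForceFieldParams
) -> tuple[float, np.ndarray]:
    """Potential energy and per-bead forces (analytic -grad E)."""
    _validate(conf, topo)
    nb = _get_nb(topo, ff)
    e_nb, f_nb = _nb_eval(conf.coords, conf.box, nb, ff, want_forces=True)
    e_b, f_b = _bonded_eval(conf.coords, nb, want_forces=True)
    return e_nb + e_b, f_nb + f_b


def forces(
    conf: Conformation, topo: BeadTopology, ff: ForceFieldParams
) -> np.ndarray:
    """Per-bead forces, kJ mol^-1 A^-1."""
    return energy_and_forces(conf, topo, ff)[1]


def _as_indices(topo: BeadTopology, sel: Selection) -> np.ndarray:
    if isinstance(sel, str):
        return topo.select(sel)
    return np.asarray(sel, dtype=int)


def cross_pair_table(
    topo: BeadTopology,
    ff: ForceFieldParams,
    group_a: Selection,
    group_b: Selection,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed (i, j, sigma, epsilon, qq) arrays over the non-excluded
    cross pairs with i from *group_a*, j from *group_b*.

    ``qq`` already includes the Coulomb prefactor and dielectric.  Cached
    per (topology, parameter set, selection), so repeated per-frame calls
    pay only the geometry cost.
    """
    ia = _as_indices(topo, group_a)
    ib = _as_indices(topo, group_b)
    if np.intersect1d(ia, ib).size:
        raise InputError("selections overlap")
    cache = getattr(topo, "_cross_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(topo, "_cross_cache", cache)
    key = (_ff_key(ff), ia.tobytes(), ib.tobytes())
    if key in cache:
        return cache[key]
    gi, gj = np.meshgrid(ia, ib, indexing="ij")
    gi = gi.ravel()
    gj = gj.ravel()
    excl = topo.excluded_pairs()
    if excl:
        keep = np.array(
            [(min(a, b), max(a, b)) not in excl for a, b in zip(gi, gj)]
        )
        gi, gj = gi[keep], gj[keep]
    sig = np.empty(len(gi))
    eps = np.empty(len(gi))
    tcache: dict = {}
    for k, (a, b) in enumerate(zip(gi, gj)):
        tkey = (topo.bead_type[a], topo.bead_type[b])
        if tkey not in tcache:
            tcache[tkey] = ff.pair_params(*tkey)
        sig[k], eps[k] = tcache[tkey]
    qq = topo.charge[gi] * topo.charge[gj] * ff.coulomb_prefactor / ff.dielectric
    cache[key] = (gi, gj, sig, eps, qq)
    return cache[key]


def switched_pair_energy(
    r: np.ndarray,
    sigma: np.ndarray,
    epsilon: np.ndarray,
    qq: np.ndarray,
    ff: ForceFieldParams,
) -> np.ndarray:
    """Switched, scaled nonbonded pair energies at separations *r*.

    Vectorised over any leading shape; pairs at r >= r_cut contribute
    exactly zero.  Building block for pose-grid scans and interaction maps.
    """
    return ff.nonbonded_scale * _nb_pair_energy(np.asarray(r, float), sigma, epsilon, qq, ff)


def cross_pair_energies(
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    group_a: Selection,
    group_b: Selection,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair nonbonded energies between two disjoint bead selections.

    Returns (i, j, e) arrays over the non-excluded cross pairs with
    i from *group_a*, j from *group_b*.  The energies include the
    switching function and the nonbonded scale; pairs at or beyond the
    cutoff contribute exactly zero (and are still listed).
    """
    _validate(conf, topo)
    gi, gj, sig, eps, qq = cross_pair_table(topo, ff, group_a, group_b)
    d = conf.coords[gi] - conf.coords[gj]
    if conf.box is not None:
        L = np.asarray(conf.box)
        d -= L * np.round(d / L)
    r = np.linalg.norm(d, axis=1)
    e = switched_pair_energy(r, sig, eps, qq, ff)
    return gi, gj, e


def group_interaction_energy(
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    group_a: Selection = "ligand",
    group_b: Selection = "receptor",
) -> float:
    """Nonbonded interaction energy between two disjoint bead selections.

    This cross-group pair sum is the search objective f(x): for the
    default selections it is the ligand-receptor interaction energy,
    excluding all solvent-mediated terms.
    """
    _, _, e = cross_pair_energies(conf, topo, ff, group_a, group_b)
    return float(e.sum())


def _subset_energy(
    conf: Conformation, topo: BeadTopology, ff: ForceFieldParams, mask: np.ndarray
) -> float:
    """Energy of the sub-system formed by the masked beads at fixed coordinates."""
    nb = _get_nb(topo, ff)
    keep = mask[nb.i] & mask[nb.j]
    sub = _NBData.__new__(_NBData)
    sub.i = nb.i[keep]
    sub.j = nb.j[keep]
    sub.sigma = nb.sigma[keep]
    sub.epsilon = nb.epsilon[keep]
    sub.qq = nb.qq[keep]
    if nb.bonds.size:
        bk = mask[nb.bonds[:, 0].astype(int)] & mask[nb.bonds[:, 1].astype(int)]
        sub.bonds = nb.bonds[bk]
    else:
        sub.bonds = nb.bonds
    if nb.angles.size:
        ak = (
            mask[nb.angles[:, 0].astype(int)]
            & mask[nb.angles[:, 1].astype(int)]
            & mask[nb.angles[:, 2].astype(int)]
        )
        sub.angles = nb.angles[ak]
    else:
        sub.angles = nb.angles
    e_nb, _ = _nb_eval(conf.coords, conf.box, sub, ff, want_forces=False)
    e_b, _ = _bonded_eval(conf.coords, sub, want_forces=False)
    return e_nb + e_b


def binding_energy(
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    mode: str = "fixed_geometry",
) -> float:
    """Ligand/receptor binding energy G_BE by fixed-geometry decomposition.

    All four single-point energies are evaluated at the *same* coordinates:
    the full system, the system with the receptor deleted, the system with
    the ligand deleted, and the environment (solvent + ions) alone.  The
    environment term cancels the doubly-counted solvent energy, so for this
    pairwise-additive potential G_BE equals the ligand-receptor cross-pair
    sum exactly.
    """
    if mode != "fixed_geometry":
        raise InputError(f"unknown binding-energy mode {mode!r}")
    _validate(conf, topo)
    lig = topo.group == "ligand"
    rec = topo.group == "receptor"
    if not lig.any() or not rec.any():
        raise InputError("topology must contain both ligand and receptor groups")
    all_mask = np.ones(topo.n_beads, dtype=bool)
    env = ~(lig | rec)
    e_complex = _subset_energy(conf, topo, ff, all_mask)
    e_no_rec = _subset_energy(conf, topo, ff, all_mask & ~rec)
    e_no_lig = _subset_energy(conf, topo, ff, all_mask & ~lig)
    e_env = _subset_energy(conf, topo, ff, env) if env.any() else 0.0
    return e_complex - e_no_rec - e_no_lig + e_env


def dmd_scaled_params(ff: ForceFieldParams) -> ForceFieldParams:
    """Parameters for the softened (DMD) proposal surface.

    Nonbonded LJ and Coulomb strengths are reduced uniformly to 1/100 of
    the physical values; bonded terms are untouched.  Idempotent: an
    already-scaled input is returned unchanged with a warning.
    """
    if ff.nonbonded_scale != 1.0:
        warnings.warn(
            "dmd_scaled_params called on already-scaled parameters; "
            "returning them unchanged",
            stacklevel=2,
        )
        return ff
    return ff.with_scale(0.01)
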