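"""Minimum-energy pathways: steered pulling plus nudged-elastic-band relaxation.

The adsorption path of a ligand onto its receptor is estimated in two
stages.  :func:`pull_path` generates an initial chain of states by slowly
pulling the ligand's centre of mass away from the receptor under a
harmonic COM-distance restraint (steered dynamics), minimizing each
snapshot with the restraint held.  :func:`neb_relax` then relaxes the
chain with the nudged elastic band: each interior image feels the true
force perpendicular to the local path tangent plus a spring force along
it (improved-tangent formulation), endpoints frozen, FIRE descent.  The
band metric covers only ligand and receptor beads; solvent beads relax
under the plain true force, so solvent permutation does not distort the
path.  :func:`barrier_report` summarises the relaxed profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .dynamics import run_nvt
from .forcefield import energy_and_forces, group_interaction_energy, total_energy
from .minimize import local_minimize
from .topology import BeadTopology, Conformation, ForceFieldParams, InputError


@dataclass
class MEPResult:
    """A relaxed minimum-energy pathway.

    ``images[0]`` is the reactant (here: the separated or pulled state
    ordering is whatever the caller supplied — :func:`pull_path` returns
    the bound complex first).  ``barrier`` is the highest total energy
    along the band minus the reactant energy, never negative.
    """

    images: list
    total_energy: np.ndarray
    binding_energy: Optional[np.ndarray]
    com_distance: Optional[np.ndarray]
    barrier: float
    converged: bool

    def __post_init__(self) -> None:
        if len(self.images) < 3:
            raise InputError("a pathway needs at least 3 images")


# --------------------------------------------------------------------------
# generic NEB core (works on any array-valued surface, incl. analytic toys)

def neb_on_surface(
    images: np.ndarray,
    energy: Callable[[np.ndarray], float],
    force: Callable[[np.ndarray], np.ndarray],
    spring_k: float = 10.0,
    force_tol: float = 0.05,
    max_iter: int = 2000,
    climb: bool = False,
    metric_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Relax a chain of states with the nudged elastic band.

    Parameters
    ----------
    images
        Array of shape (m, ...) — m copies of the system coordinates.
        Endpoints are frozen.
    energy, force
        The surface; ``force(x) = -grad E(x)`` with x shaped like one image.
    metric_mask
        Optional boolean mask over one image's entries; tangents and
        springs are computed in the masked subspace only, and unmasked
        degrees of freedom follow the plain true force.
    climb
        If True, the highest interior image climbs (true force with the
        tangential component inverted) — off by default.

    Returns (relaxed images, per-image energies, converged flag).
    """
    x = np.array(images, dtype=float)
    m = x.shape[0]
    if m < 3:
        raise InputError("NEB needs at least 3 images")
    shape = x.shape[1:]
    flat = x.reshape(m, -1)
    if metric_mask is None:
        mask = np.ones(flat.shape[1], dtype=bool)
    else:
        mask = np.asarray(metric_mask, bool).reshape(-1)

    def band_forces(flat_imgs):
        E = np.array([energy(fi.reshape(shape)) for fi in flat_imgs])
        F = np.zeros_like(flat_imgs)
        imax = int(np.argmax(E[1:-1])) + 1
        for i in range(1, m - 1):
            f_true = force(flat_imgs[i].reshape(shape)).reshape(-1)
            dp = (flat_imgs[i + 1] - flat_imgs[i]) * mask
            dm = (flat_imgs[i] - flat_imgs[i - 1]) * mask
            # improved tangent (upwind in energy)
            if E[i + 1] > E[i] > E[i - 1]:
                tau = dp.copy()
            elif E[i + 1] < E[i] < E[i - 1]:
                tau = dm.copy()
            else:
                demax = max(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
                demin = min(abs(E[i + 1] - E[i]), abs(E[i - 1] - E[i]))
                if E[i + 1] > E[i - 1]:
                    tau = dp * demax + dm * demin
                else:
                    tau = dp * demin + dm * demax
            tn = np.linalg.norm(tau)
            if tn > 0:
                tau /= tn
            ft_par = float(np.dot(f_true * mask, tau))
            if climb and i == imax:
                F[i] = f_true - 2.0 * ft_par * tau
                continue
            f_perp = f_true - ft_par * tau
            f_spring = spring_k * (np.linalg.norm(dp) - np.linalg.norm(dm)) * tau
            F[i] = f_perp + f_spring
        return E, F

    # FIRE over the interior images jointly
    dt, dt_max, alpha = 0.02, 0.2, 0.1
    n_min, f_inc, f_dec, f_alpha = 5, 1.1, 0.5, 0.99
    v = np.zeros_like(flat)
    n_pos = 0
    converged = False
    E, F = band_forces(flat)
    for _ in range(max_iter):
        fmax = float(np.abs(F[1:-1]).max()) if m > 2 else 0.0
        if fmax <= force_tol:
            converged = True
            break
        p = float(np.vdot(F, v))
        if p > 0:
            n_pos += 1
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            n_pos = 0
            dt *= f_dec
            alpha = 0.1
            v[:] = 0.0
        v += dt * F
        vn, fn = np.linalg.norm(v), np.linalg.norm(F)
        if fn > 0:
            v = (1.0 - alpha) * v + alpha * (vn / fn) * F
        step = dt * v
        np.clip(step, -0.3, 0.3, out=step)
        flat[1:-1] += step[1:-1]
        E, F = band_forces(flat)
    return flat.reshape((m,) + shape), E, converged


# --------------------------------------------------------------------------
# bead-system interface

def _com(coords: np.ndarray, mass: np.ndarray, idx: np.ndarray) -> np.ndarray:
    m = mass[idx][:, None]
    return (m * coords[idx]).sum(axis=0) / m.sum()


def com_distance(conf: Conformation, topo: BeadTopology) -> float:
    """Ligand-receptor mass-centre distance (no wrapping: pathway systems
    keep the complex whole)."""
    lig = topo.select("ligand")
    rec = topo.select("receptor")
    return float(np.linalg.norm(
        _com(conf.coords, topo.mass, lig) - _com(conf.coords, topo.mass, rec)
    ))


def _com_restraint(topo: BeadTopology, k: float, target_holder: dict):
    """Harmonic restraint on the ligand-receptor COM distance.

    ``target_holder["d"]`` is read at call time so the target can be
    ramped between integrator segments.
    """
    lig = topo.select("ligand")
    rec = topo.select("receptor")
    m = topo.mass
    wl = (m[lig] / m[lig].sum())[:, None]
    wr = (m[rec] / m[rec].sum())[:, None]

    def restraint(coords: np.ndarray):
        rl = _com(coords, m, lig)
        rr = _com(coords, m, rec)
        dvec = rl - rr
        d = float(np.linalg.norm(dvec))
        dd = d - target_holder["d"]
        e = 0.5 * k * dd * dd
        F = np.zeros_like(coords)
        if d > 1e-12:
            g = k * dd * dvec / d  # dE/d(r_l COM)
            F[lig] -= wl * g
            F[rec] += wr * g
        return e, F

    return restraint


def pull_path(
    complex_conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    n_images: int = 16,
    pull_distance: float = 15.0,
    seed: Optional[int] = None,
    restraint_k: float = 50.0,
    velocity: float = 0.01,
    temperature: float = 100.0,
    dt: float = 10.0,
    force_tol: float = 0.05,
) -> list[Conformation]:
    """Steered-pulling initial path: bound complex first, COM distance
    increasing by *pull_distance* A over *n_images* images.

    Between snapshots the ligand-receptor COM distance target advances at
    *velocity* A per dynamics step under a harmonic restraint of stiffness
    *restraint_k* kJ/mol/A^2; each snapshot is then minimized with the
    restraint held at its image distance.
    """
    if n_images < 3:
        raise InputError("need at least 3 images")
    d0 = com_distance(complex_conf, topo)
    if complex_conf.box is not None:
        if d0 + pull_distance > 0.5 * min(complex_conf.box):
            raise InputError(
                "pull distance would move the ligand past the half-box; "
                "use a larger box"
            )
    targets = d0 + np.linspace(0.0, pull_distance, n_images)
    holder = {"d": d0}
    restraint = _com_restraint(topo, restraint_k, holder)

    images: list[Conformation] = []
    conf = complex_conf.copy()
    rng = np.random.default_rng(seed)
    for k, d_t in enumerate(targets):
        if k > 0:
            # steered segment: ramp the target in small constant-velocity chunks
            span = targets[k] - targets[k - 1]
            n_steps = max(int(np.ceil(span / velocity)), 1)
            chunks = max(min(n_steps // 10, 10), 1)
            per = max(n_steps // chunks, 1)
            d_run = targets[k - 1]
            for c in range(chunks):
                d_run = min(d_run + per * velocity, d_t)
                holder["d"] = d_run
                traj = run_nvt(
                    conf, topo, ff, T=temperature, dt=dt, n_steps=per,
                    seed=int(rng.integers(2**31)), sample_every=0,
                    extra=restraint,
                )
                conf = traj.frame(len(traj) - 1)
        holder["d"] = float(d_t)
        mconf, _, _ = local_minimize(
            conf, topo, ff, force_tol=force_tol, max_iter=5000, extra=restraint
        )
        conf = mconf
        images.append(mconf.copy())
    return images


def neb_relax(
    images: list[Conformation],
    topo: BeadTopology,
    ff: ForceFieldParams,
    spring_k: float = 10.0,
    force_tol: float = 0.05,
    max_iter: int = 2000,
    climb: bool = False,
) -> MEPResult:
    """Relax a chain of bead-system images to the minimum-energy pathway.

    Endpoints stay fixed; the band metric includes only ligand and
    receptor beads (solvent follows the plain true force).  Returns the
    relaxed images with total-energy and — when both groups exist —
    binding-energy and COM-distance profiles, plus the barrier relative
    to image 0.
    """
    if len(images) < 3:
        raise InputError("NEB needs at least 3 images")
    box = images[0].box

    def energy(coords):
        return total_energy(Conformation(coords, box), topo, ff)

    def force(coords):
        return energy_and_forces(Conformation(coords, box), topo, ff)[1]

    in_band = np.isin(topo.group, ("ligand", "receptor"))
    mask = np.repeat(in_band, 3)
    stack = np.array([im.coords for im in images])
    relaxed, energies, converged = neb_on_surface(
        stack, energy, force, spring_k=spring_k, force_tol=force_tol,
        max_iter=max_iter, climb=climb, metric_mask=mask,
    )
    out_images = [Conformation(c.copy(), box) for c in relaxed]
    has_groups = (topo.group == "ligand").any() and (topo.group == "receptor").any()
    if has_groups:
        be = np.array([
            group_interaction_energy(im, topo, ff, "ligand", "receptor")
            for im in out_images
        ])
        cd = np.array([com_distance(im, topo) for im in out_images])
    else:
        be, cd = None, None
    barrier = max(float(energies.max() - energies[0]), 0.0)
    return MEPResult(out_images, energies, be, cd, barrier, converged)


def barrier_report(mep: MEPResult) -> tuple[float, int, pd.DataFrame]:
    """Barrier, transition-state image index, and the per-image profile table.

    The table has one row per image (index, COM distance, total energy,
    binding energy, and the binding onset flag: the first image — scanned
    from the reactant end — whose binding energy drops below zero).
    """
    e = mep.total_energy
    ts = int(np.argmax(e))
    barrier = max(float(e[ts] - e[0]), 0.0)
    if barrier == 0.0:
        ts = 0
    n = len(mep.images)
    onset = np.zeros(n, dtype=bool)
    if mep.binding_energy is not None:
        neg = np.flatnonzero(mep.binding_energy < 0)
        if neg.size:
            onset[neg[0]] = True
    table = pd.DataFrame({
        "image": np.arange(n),
        "com_distance": mep.com_distance if mep.com_distance is not None else np.nan,
        "total_energy": e,
        "binding_energy": mep.binding_energy if mep.binding_energy is not None else np.nan,
        "binding_onset": onset,
    })
    return barrier, ts, table
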