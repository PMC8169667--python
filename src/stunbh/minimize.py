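"""Local geometry optimisation: the basin-hopping descent step.

FIRE (fast inertial relaxation engine) is the default; a conjugate-gradient
option backed by :func:`scipy.optimize.minimize` is available.  Both map a
conformation to (a numerical approximation of) the nearest local minimum of
the bead potential, which is what turns raw MD proposals into basin minima
for the Metropolis bookkeeping.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .forcefield import energy_and_forces
from .topology import BeadTopology, Conformation, ForceFieldParams

ExtraPotential = Callable[[np.ndarray], tuple[float, np.ndarray]]


def _objective(conf, topo, ff, extra):
    def f(coords: np.ndarray) -> tuple[float, np.ndarray]:
        c = Conformation(coords, conf.box)
        e, F = energy_and_forces(c, topo, ff)
        if extra is not None:
            e2, F2 = extra(coords)
            e += e2
            F = F + F2
        return e, F

    return f


def _fire(
    coords: np.ndarray,
    fun,
    force_tol: float,
    max_iter: int,
    mobile: Optional[np.ndarray],
    max_step: float = 0.4,
):
    # FIRE 2.0-style parameters; dt is dimensionless (unit pseudo-masses)
    dt, dt_max, alpha = 0.02, 0.25, 0.10
    n_min, f_inc, f_dec, f_alpha = 5, 1.1, 0.5, 0.99
    x = coords.copy()
    v = np.zeros_like(x)
    n_pos = 0
    e, F = fun(x)
    best_x, best_e = x.copy(), e
    converged = False
    for _ in range(max_iter):
        if mobile is not None:
            F = F * mobile[:, None]
        fmax = float(np.sqrt((F**2).sum(axis=1).max())) if len(F) else 0.0
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
            alpha = 0.10
            v[:] = 0.0
        v += dt * F
        vn = float(np.linalg.norm(v))
        fn = float(np.linalg.norm(F))
        if fn > 0:
            v = (1.0 - alpha) * v + alpha * (vn / fn) * F
        step = dt * v
        slen = np.sqrt((step**2).sum(axis=1))
        over = slen > max_step
        if over.any():
            step[over] *= (max_step / slen[over])[:, None]
        x += step
        e, F = fun(x)
        if e < best_e:
            best_e, best_x = e, x.copy()
    if e <= best_e:
        best_e, best_x = e, x
    return best_x, best_e, converged


def local_minimize(
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    force_tol: float = 1e-2,
    max_iter: int = 5000,
    method: str = "fire",
    extra: Optional[ExtraPotential] = None,
    mobile: Optional[np.ndarray] = None,
) -> tuple[Conformation, float, bool]:
    """Relax *conf* to a nearby local minimum.

    Parameters
    ----------
    force_tol
        Convergence threshold on the largest per-bead force norm,
        kJ mol^-1 A^-1.
    method
        ``"fire"`` (default), ``"cg"`` (scipy conjugate gradient) or
        ``"lbfgs"`` (scipy L-BFGS-B; much faster on systems mixing stiff
        bonds with soft intermolecular modes).
    extra
        Optional additional potential ``coords -> (energy, forces)`` added
        to the bead potential (COM restraints, containment, ...).
    mobile
        Optional boolean mask; beads with False are held fixed.

    Returns
    -------
    (minimized conformation, its energy, converged flag).  The returned
    energy never exceeds the input energy; on non-convergence the
    best-so-far structure is returned with ``converged=False``.
    """
    fun = _objective(conf, topo, ff, extra)
    x0 = conf.coords.copy()
    if method == "fire":
        x, e, converged = _fire(x0, fun, force_tol, max_iter, mobile)
    elif method == "lbfgs":
        n = x0.shape[0]
        mob = np.ones(n, dtype=bool) if mobile is None else np.asarray(mobile, bool)

        def fg(flat):
            e, F = fun(flat.reshape(n, 3))
            g = -F
            g[~mob] = 0.0
            return e, g.ravel()

        res = _scipy_minimize(
            fg, x0.ravel(), jac=True, method="L-BFGS-B",
            options={"gtol": 0.5 * force_tol, "ftol": 1e-12,
                     "maxiter": max_iter, "maxcor": 30},
        )
        x = res.x.reshape(n, 3)
        e, F = fun(x)
        F = F * mob[:, None]
        fmax = float(np.sqrt((F**2).sum(axis=1).max())) if n else 0.0
        converged = fmax <= force_tol
    elif method == "cg":
        n = x0.shape[0]
        mob = np.ones(n, dtype=bool) if mobile is None else np.asarray(mobile, bool)

        def fg(flat):
            e, F = fun(flat.reshape(n, 3))
            g = -F
            g[~mob] = 0.0
            return e, g.ravel()

        res = _scipy_minimize(
            fg, x0.ravel(), jac=True, method="CG",
            options={"gtol": force_tol, "maxiter": max_iter},
        )
        x = res.x.reshape(n, 3)
        e, F = fun(x)
        F = F * mob[:, None]
        fmax = float(np.sqrt((F**2).sum(axis=1).max())) if n else 0.0
        converged = fmax <= force_tol
    else:
        raise ValueError(f"unknown minimizer {method!r}; use 'fire' or 'cg'")
    e0, _ = fun(conf.coords)
    if e > e0:  # descent guarantee: never return worse than the input
        x, e = conf.coords.copy(), e0
        converged = False
    return Conformation(x, conf.box), e, converged
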