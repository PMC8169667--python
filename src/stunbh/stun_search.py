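"""STUN-BH-DMD global-minimum search.

The search walks on basin minima (basin hopping): each proposal runs a
short burst of hot NVT dynamics — alternating between the physical
potential (MD) and the 1/100-softened one (DMD) — and relaxes the result
to its local minimum on the *physical* surface.  The objective f(x)
(ligand-receptor interaction energy, or total energy for cluster
benchmarks) is mapped through the stochastic-tunnelling transform

    E_STUN(x) = ln( (f - f0) + sqrt((f - f0)^2 + 1) ) = asinh(f - f0)

which compresses the landscape above the best-found value f0, and
Metropolis acceptance is applied on that transformed surface with an
effective temperature kT that is re-tuned every 20 steps toward a 50%
acceptance rate.  Any proposal that improves on f0 is accepted
unconditionally and becomes the new reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dynamics import DynamicsError, init_velocities, run_nvt
from .forcefield import (
    dmd_scaled_params,
    group_interaction_energy,
    total_energy,
)
from .minimize import local_minimize
from .topology import BeadTopology, Conformation, ForceFieldParams, InputError

logger = logging.getLogger(__name__)

Objective = Callable[[Conformation], float]


# --------------------------------------------------------------------------
# the three printed primitives

def stun_transform(f: float, f0: float) -> float:
    """Stochastic-tunnelling effective energy asinh(f - f0).

    Zero at f = f0, strictly increasing in f, negative exactly when the
    candidate improves on the best value found so far.
    """
    return float(np.arcsinh(np.asarray(f, float) - f0))


def boltzmann_accept(
    e_stun_new: float, stun_last: float, kT: float, u: float
) -> bool:
    """Metropolis decision on the transformed surface.

    Downhill or equal moves are always accepted; uphill moves are accepted
    iff exp[(stun_last - e_stun_new)/kT] exceeds the uniform draw *u*.
    """
    if kT <= 0:
        raise InputError("kT must be positive")
    if e_stun_new <= stun_last:
        return True
    return bool(np.exp((stun_last - e_stun_new) / kT) > u)


@dataclass
class SearchState:
    """Bookkeeping for one STUN-BH-DMD chain."""

    f0: float
    stun_last: float
    x_last: Conformation
    kT: float
    rng: np.random.Generator
    accept_history: list = field(default_factory=list)
    iteration: int = 0
    mode_next: str = "MD"
    best_conf: Conformation = None
    best_f: float = np.inf

    def acceptance_fraction(self, last: Optional[int] = None) -> float:
        h = self.accept_history if last is None else self.accept_history[-last:]
        return float(np.mean(h)) if h else 0.0


def adapt_kT(
    state: SearchState,
    period: int = 20,
    target: float = 0.5,
    factor: float = 1.2,
) -> float:
    """Re-tune kT toward the target acceptance rate.

    Over the last *period* steps: acceptance above target -> cool
    (kT / factor, accept less), below target -> heat (kT * factor).
    kT is clamped to [1e-6, 1e6].  Returns the new kT.
    """
    frac = state.acceptance_fraction(last=period)
    if frac > target:
        state.kT /= factor
    elif frac < target:
        state.kT *= factor
    state.kT = float(np.clip(state.kT, 1e-6, 1e6))
    return state.kT


# --------------------------------------------------------------------------
# moves

@dataclass
class MoveSettings:
    """Proposal-move parameters for one STUN-BH-DMD iteration.

    Defaults follow the method's published operating point for
    MARTINI-scale systems: 300 steps of 10 fs NVT at 600 K.  For
    non-periodic clusters a flat-bottom spherical restraint
    (``containment_k`` > 0, radius ``containment_radius`` about the
    instantaneous COM) prevents evaporation during the hot move; it acts
    only outside the radius and is also applied during the relaxation that
    follows the move.
    """

    temperature: float = 600.0
    dt: float = 10.0
    n_steps: int = 300
    tau: float = 100.0
    containment_k: float = 0.0
    containment_radius: float = 0.0
    force_tol: float = 1e-2
    max_minimize_iter: int = 5000
    minimizer: str = "fire"


def _containment(move: MoveSettings, coords0: np.ndarray):
    """Flat-bottom spherical restraint about the initial COM (or None)."""
    if move.containment_k <= 0:
        return None
    center = coords0.mean(axis=0)
    k, R = move.containment_k, move.containment_radius

    def restraint(coords: np.ndarray):
        d = coords - center
        r = np.linalg.norm(d, axis=1)
        over = np.maximum(r - R, 0.0)
        e = 0.5 * k * float(np.sum(over**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            fmag = np.where(r > 0, -k * over / r, 0.0)
        return e, fmag[:, None] * d

    return restraint


def make_objective(
    topo: BeadTopology, ff: ForceFieldParams, kind: str = "binding"
) -> Objective:
    """Standard objectives: ``"binding"`` (ligand-receptor interaction
    energy, the default for complexes) or ``"total"`` (total potential
    energy, for cluster benchmarks).  Always evaluated with the unscaled
    physical parameters."""
    if ff.nonbonded_scale != 1.0:
        raise InputError("the search objective must use unscaled parameters")
    if kind == "binding":
        return lambda conf: group_interaction_energy(conf, topo, ff, "ligand", "receptor")
    if kind == "total":
        return lambda conf: total_energy(conf, topo, ff)
    raise InputError(f"unknown objective kind {kind!r}")


def init_search_state(
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    objective: Objective,
    move: MoveSettings,
    kT0: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SearchState, Conformation]:
    """Minimize the input and open a chain with f0 from the minimized structure."""
    extra = _containment(move, conf.coords)
    mconf, _, _ = local_minimize(
        conf, topo, ff, force_tol=move.force_tol,
        max_iter=move.max_minimize_iter, method=move.minimizer, extra=extra,
    )
    f = objective(mconf)
    state = SearchState(
        f0=f, stun_last=0.0, x_last=mconf.copy(), kT=kT0,
        rng=rng if rng is not None else np.random.default_rng(),
        best_conf=mconf.copy(), best_f=f,
    )
    return state, mconf


def stun_bh_dmd_step(
    state: SearchState,
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    move: MoveSettings,
    objective: Objective,
    adapt_period: int = 20,
    adapt_target: float = 0.5,
) -> tuple[Conformation, dict]:
    """One search iteration: hot move, relax, evaluate, accept/reject.

    The move runs with physical (MD) or 1/100-scaled (DMD) nonbonded
    parameters depending on ``state.mode_next``; relaxation and the
    objective always use the physical parameters.  On rejection the live
    configuration is restored to the last accepted one.  Returns the next
    live conformation plus a log record.
    """
    mode = state.mode_next
    ff_move = ff if mode == "MD" else dmd_scaled_params(ff)
    extra = _containment(move, conf.coords)
    f = np.nan
    e_stun = np.nan
    accepted = False
    try:
        trial = conf.copy()
        trial.velocities = init_velocities(
            topo, move.temperature, int(state.rng.integers(2**31))
        )
        traj = run_nvt(
            trial, topo, ff_move, move.temperature, move.dt, move.n_steps,
            tau=move.tau, sample_every=0, extra=extra,
        )
        moved = traj.frame(len(traj) - 1)
        mconf, _, _ = local_minimize(
            moved, topo, ff, force_tol=move.force_tol,
            max_iter=move.max_minimize_iter, method=move.minimizer, extra=extra,
        )
        f = objective(mconf)
        if f < state.f0:
            # new global reference: auto-accept, recentre the transform
            state.f0 = f
            state.best_f = f
            state.best_conf = mconf.copy()
            e_stun = stun_transform(f, state.f0)  # = 0 by construction
            state.stun_last = e_stun
            state.x_last = mconf.copy()
            accepted = True
        else:
            e_stun = stun_transform(f, state.f0)
            u = float(state.rng.uniform())
            accepted = boltzmann_accept(e_stun, state.stun_last, state.kT, u)
            if accepted:
                state.stun_last = e_stun
                state.x_last = mconf.copy()
    except DynamicsError as err:
        logger.warning("proposal discarded (%s); step counted as rejected", err)
        accepted = False
    state.accept_history.append(accepted)
    state.iteration += 1
    state.mode_next = "DMD" if mode == "MD" else "MD"
    if state.iteration % adapt_period == 0:
        adapt_kT(state, period=adapt_period, target=adapt_target)
    next_conf = state.x_last.copy()
    record = {
        "iteration": state.iteration, "mode": mode, "f": f, "f0": state.f0,
        "e_stun": e_stun, "kT": state.kT, "accepted": accepted,
    }
    return next_conf, record


def random_orientation(
    conf: Conformation,
    topo: BeadTopology,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> Conformation:
    """Rigidly rotate the receptor about its mass centre, uniformly on SO(3).

    Ligand, solvent and ion beads are untouched; receptor internal
    geometry and COM are preserved exactly.
    """
    rec = topo.select("receptor")
    if rec.size == 0:
        raise InputError("random_orientation requires a non-empty receptor group")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    out = conf.copy()
    m = topo.mass[rec][:, None]
    com = (m * conf.coords[rec]).sum(axis=0) / m.sum()
    out.coords[rec] = rot.apply(conf.coords[rec] - com) + com
    return out


@dataclass
class SearchResult:
    best_conf: Conformation
    best_f: float
    log: pd.DataFrame
    n_starts_completed: int


def run_search(
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    n_starts: int = 1,
    iters_per_start: int = 100,
    seed: Optional[int] = None,
    move: Optional[MoveSettings] = None,
    objective: Union[str, Objective] = "binding",
    kT0: float = 1.0,
    adapt_period: int = 20,
    adapt_target: float = 0.5,
    start_perturbation: float = 0.0,
) -> SearchResult:
    """Multi-start STUN-BH-DMD search.

    Each start re-orients the receptor uniformly at random about its COM
    (for receptor-free systems, e.g. clusters, a Gaussian coordinate kick
    of width ``start_perturbation`` A is applied instead), re-minimizes,
    and runs ``iters_per_start`` chain iterations.  The global best over
    all starts is returned along with a per-iteration log.
    """
    if move is None:
        move = MoveSettings()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(max(n_starts, 1))
    obj = make_objective(topo, ff, objective) if isinstance(objective, str) else objective
    has_receptor = topo.select("receptor").size > 0

    best_conf: Optional[Conformation] = None
    best_f = np.inf
    rows: list[dict] = []
    completed = 0
    for s in range(n_starts):
        rng = np.random.default_rng(child_seeds[s])
        try:
            start_conf = conf.copy()
            if s > 0 or n_starts > 1:
                if has_receptor:
                    start_conf = random_orientation(start_conf, topo, rng)
                elif start_perturbation > 0:
                    start_conf.coords = start_conf.coords + rng.normal(
                        scale=start_perturbation, size=start_conf.coords.shape
                    )
            state, live = init_search_state(
                start_conf, topo, ff, obj, move, kT0=kT0, rng=rng
            )
            rows.append({
                "start": s, "iteration": 0, "mode": "init", "f": state.f0,
                "f0": state.f0, "e_stun": 0.0, "kT": state.kT, "accepted": True,
            })
            for _ in range(iters_per_start):
                live, rec = stun_bh_dmd_step(
                    state, live, topo, ff, move, obj,
                    adapt_period=adapt_period, adapt_target=adapt_target,
                )
                rec["start"] = s
                rows.append(rec)
            if state.best_f < best_f:
                best_f = state.best_f
                best_conf = state.best_conf
            completed += 1
        except Exception as err:  # noqa: BLE001 - a failed start is skipped
            warnings.warn(f"search start {s} failed and was skipped: {err}")
    if completed == 0 or best_conf is None:
        raise RuntimeError("every search start failed")
    log = pd.DataFrame(rows)
    return SearchResult(best_conf, float(best_f), log, completed)
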