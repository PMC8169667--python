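"""NVT coarse-grained molecular dynamics.

Velocity-Verlet integration with Berendsen velocity rescaling.  The same
integrator serves two roles: the 600 K / 300-step proposal moves of the
global search (with physical or 1/100-scaled nonbonded parameters) and
ordinary production relaxation runs.  Velocities are in A/fs; the single
unit conversion needed is 1 amu (A/fs)^2 = 1e4 kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .forcefield import energy_and_forces
from .topology import BeadTopology, Conformation, ForceFieldParams, InputError
from .units import AMU_A2_FS2_TO_KJ_MOL, KJ_MOL_TO_AMU_A2_FS2


class DynamicsError(RuntimeError):
    """MD blow-up or other integration failure."""


@dataclass
class Trajectory:
    """An ordered set of frames with per-frame thermodynamic records.

    ``coords`` has shape (n_frames, n_beads, 3); ``times`` (fs) are strictly
    increasing; ``epot``/``ekin`` are kJ/mol and ``temperature`` K.
    """

    coords: np.ndarray
    times: np.ndarray
    epot: np.ndarray
    ekin: np.ndarray
    temperature: np.ndarray
    box: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.times = np.asarray(self.times, float)
        self.epot = np.asarray(self.epot, float)
        self.ekin = np.asarray(self.ekin, float)
        self.temperature = np.asarray(self.temperature, float)
        nf = len(self.coords)
        if not (len(self.times) == len(self.epot) == len(self.ekin)
                == len(self.temperature) == nf):
            raise InputError("frame count and thermo record count differ")
        if nf > 1 and not np.all(np.diff(self.times) > 0):
            raise InputError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.coords)

    def frame(self, k: int) -> Conformation:
        return Conformation(self.coords[k].copy(), self.box)

    @property
    def frames(self) -> list[Conformation]:
        return [self.frame(k) for k in range(len(self))]


def kinetic_energy(topo: BeadTopology, velocities: np.ndarray) -> float:
    """Kinetic energy in kJ/mol from velocities in A/fs."""
    return float(
        0.5 * np.sum(topo.mass[:, None] * velocities**2) * AMU_A2_FS2_TO_KJ_MOL
    )


def instantaneous_temperature(topo: BeadTopology, velocities: np.ndarray) -> float:
    """Kinetic temperature with 3N-3 degrees of freedom (COM momentum removed)."""
    from .units import KB

    dof = max(3 * topo.n_beads - 3, 1)
    return 2.0 * kinetic_energy(topo, velocities) / (dof * KB)


def init_velocities(
    topo: BeadTopology, T: float, seed: Optional[int] = None
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at temperature *T* with zero total momentum.

    After removing the centre-of-mass drift the velocities are rescaled so
    the kinetic temperature (3N-3 dof) is exactly *T*.
    """
    from .units import KB

    if topo.n_beads == 0:
        raise InputError("cannot draw velocities for an empty topology")
    if T <= 0:
        raise InputError("temperature must be positive")
    rng = np.random.default_rng(seed)
    # sigma_v^2 = kB T / m, converted to (A/fs)^2
    sigma = np.sqrt(KB * T / topo.mass * KJ_MOL_TO_AMU_A2_FS2)
    v = rng.normal(size=(topo.n_beads, 3)) * sigma[:, None]
    p = (topo.mass[:, None] * v).sum(axis=0)
    v -= p / topo.mass.sum()
    t_now = instantaneous_temperature(topo, v)
    if t_now > 0:
        v *= np.sqrt(T / t_now)
    return v


def run_nvt(
    conf: Conformation,
    topo: BeadTopology,
    ff: ForceFieldParams,
    T: float,
    dt: float,
    n_steps: int,
    tau: float = 100.0,
    seed: Optional[int] = None,
    sample_every: int = 10,
    extra: Optional[Callable[[np.ndarray], tuple[float, np.ndarray]]] = None,
) -> Trajectory:
    """Run *n_steps* of NVT dynamics; velocity Verlet + Berendsen rescaling.

    Parameters
    ----------
    T, dt, tau
        Target temperature (K), time step (fs) and thermostat coupling
        time (fs).  ``tau = inf`` disables the thermostat (NVE).
    seed
        Used to draw Maxwell-Boltzmann velocities when *conf* carries none.
    sample_every
        Frame recording stride; the initial and final frames are always
        recorded.
    extra
        Optional additional potential ``coords -> (energy, forces)``
        (restraints); its energy is included in the recorded potential.

    Raises
    ------
    DynamicsError
        On energy overflow, naming the closest bead pair.
    """
    if dt <= 0:
        raise InputError("dt must be positive")
    from .units import KB

    x = conf.coords.copy()
    v = conf.velocities.copy() if conf.velocities is not None else init_velocities(topo, T, seed)
    m = topo.mass[:, None]
    inv_m = KJ_MOL_TO_AMU_A2_FS2 / m  # F [kJ/mol/A] * inv_m -> A/fs^2
    dof = max(3 * topo.n_beads - 3, 1)

    def evaluate(coords):
        try:
            c = Conformation(coords, conf.box)
            e, F = energy_and_forces(c, topo, ff)
        except InputError as err:  # bead overlap / non-finite coordinates
            raise DynamicsError(f"energy overflow during MD: {err}") from err
        if extra is not None:
            e2, F2 = extra(coords)
            e += e2
            F = F + F2
        return e, F

    def check(e, F, coords):
        # 1e9 kJ/mol signals deep bead overlap long before float overflow
        if not (np.isfinite(e) and np.all(np.isfinite(F))) or abs(e) > 1e9:
            d = coords[:, None, :] - coords[None, :, :]
            if conf.box is not None:
                L = np.asarray(conf.box)
                d -= L * np.round(d / L)
            r = np.sqrt((d**2).sum(-1))
            np.fill_diagonal(r, np.inf)
            i, j = np.unravel_index(np.argmin(r), r.shape)
            raise DynamicsError(
                f"energy overflow during MD: closest pair ({i}, {j}) "
                f"at r={r[i, j]:.3f} A"
            )

    e, F = evaluate(x)
    check(e, F, x)

    frames = [x.copy()]
    times = [0.0]
    epot = [e]
    ekin = [kinetic_energy(topo, v)]
    temps = [2.0 * ekin[-1] / (dof * KB)]

    for step in range(1, n_steps + 1):
        v += 0.5 * dt * F * inv_m
        x += dt * v
        e, F = evaluate(x)
        check(e, F, x)
        v += 0.5 * dt * F * inv_m
        ke = kinetic_energy(topo, v)
        t_inst = 2.0 * ke / (dof * KB)
        if np.isfinite(tau) and t_inst > 0:
            lam = np.sqrt(max(1.0 + (dt / tau) * (T / t_inst - 1.0), 0.0))
            v *= lam
            ke = kinetic_energy(topo, v)
            t_inst = 2.0 * ke / (dof * KB)
        if (sample_every > 0 and step % sample_every == 0) or step == n_steps:
            frames.append(x.copy())
            times.append(step * dt)
            epot.append(e)
            ekin.append(ke)
            temps.append(t_inst)

    traj = Trajectory(
        np.array(frames), np.array(times), np.array(epot), np.array(ekin),
        np.array(temps), conf.box,
    )
    traj.final_velocities = v  # ad-hoc attribute; callers may continue the run
    return traj
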