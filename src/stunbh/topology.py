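"""Core data containers: bead topology, force-field parameters, conformations.

A :class:`BeadTopology` describes *what* the beads are (types, masses,
charges, bonded terms, group and residue labels); a :class:`Conformation`
describes *where* they are (coordinates, optional velocities, optional
periodic box); :class:`ForceFieldParams` holds the nonbonded interaction
model.  Keeping the three separate lets the search, dynamics and analysis
layers share one topology across many conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .units import COULOMB_PREFACTOR, KB

GROUPS = ("ligand", "receptor", "solvent", "ion")


class TopologyError(ValueError):
    """Structural inconsistency in a topology (bad indices, lengths...)."""


class InputError(ValueError):
    """Invalid input values (non-finite coordinates, bad selections...)."""


@dataclass
class BeadTopology:
    """Bead identities and bonded structure of a coarse-grained system.

    Parameters
    ----------
    bead_type
        Per-bead type label (e.g. ``"P4"``, ``"LBB"``); keys into the
        force-field type tables.
    mass
        Per-bead masses, amu. Must be positive.
    charge
        Per-bead charges, elementary charge units.
    bonds
        Harmonic bonds ``(i, j, r0 [A], k [kJ/mol/A^2])``; energy is
        ``0.5 * k * (r - r0)**2``.
    angles
        Harmonic angles ``(i, j, k, theta0 [deg], k_a [kJ/mol/rad^2])``
        with *j* the apex; energy ``0.5 * k_a * (theta - theta0)**2``.
    group
        Per-bead group label, one of ``ligand | receptor | solvent | ion``.
    residue_id
        Integer residue (receptor) or nucleobase (ligand) index per bead.
    backbone
        True for ligand backbone beads, False for pendant nucleobase beads
        (and for every non-ligand bead).
    """

    bead_type: np.ndarray
    mass: np.ndarray
    charge: np.ndarray
    bonds: np.ndarray          # (nb, 4) float: i, j, r0, k
    angles: np.ndarray         # (na, 5) float: i, j, k, theta0_deg, k_a
    group: np.ndarray
    residue_id: np.ndarray
    backbone: np.ndarray

    def __post_init__(self) -> None:
        self.bead_type = np.asarray(self.bead_type, dtype=object)
        self.mass = np.asarray(self.mass, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=float).reshape(-1, 4)
        self.angles = np.asarray(self.angles, dtype=float).reshape(-1, 5)
        self.group = np.asarray(self.group, dtype=object)
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.backbone = np.asarray(self.backbone, dtype=bool)
        n = self.n_beads
        for name in ("mass", "charge", "group", "residue_id", "backbone"):
            if len(getattr(self, name)) != n:
                raise TopologyError(
                    f"array length mismatch: {name} has {len(getattr(self, name))} "
                    f"entries for {n} beads"
                )
        if np.any(self.mass <= 0):
            raise TopologyError("all bead masses must be positive")
        for g in np.unique(self.group):
            if g not in GROUPS:
                raise TopologyError(f"unknown group label {g!r}; expected one of {GROUPS}")
        if self.bonds.size:
            idx = self.bonds[:, :2].astype(int)
            if idx.min() < 0 or idx.max() >= n:
                raise TopologyError("bond index out of range")
        if self.angles.size:
            idx = self.angles[:, :3].astype(int)
            if idx.min() < 0 or idx.max() >= n:
                raise TopologyError("angle index out of range")

    @property
    def n_beads(self) -> int:
        return len(self.bead_type)

    def select(self, group: str) -> np.ndarray:
        """Indices of beads belonging to *group*."""
        if group not in GROUPS:
            raise InputError(f"unknown group {group!r}")
        return np.flatnonzero(self.group == group)

    def total_charge(self) -> float:
        return float(self.charge.sum())

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Nonbonded exclusions: 1-2 (bonded) and 1-3 (angle end) pairs."""
        excl: set[tuple[int, int]] = set()
        for b in self.bonds:
            i, j = int(b[0]), int(b[1])
            excl.add((min(i, j), max(i, j)))
        for a in self.angles:
            i, k = int(a[0]), int(a[2])
            excl.add((min(i, k), max(i, k)))
        return excl


@dataclass
class ForceFieldParams:
    """Nonbonded interaction model for typed beads.

    LJ parameters are per-type; cross terms default to Lorentz-Berthelot
    mixing unless an explicit ``(type_a, type_b) -> (sigma, epsilon)``
    entry exists in ``pair_table``.  Both LJ and Coulomb terms are
    multiplied by a quintic switching polynomial between their respective
    ``*_shift_start`` and ``r_cut`` so energies and forces go smoothly to
    exactly zero at the cutoff.

    ``nonbonded_scale`` multiplies every nonbonded pair energy uniformly;
    1.0 is the physical (MD) surface, 0.01 the softened proposal surface
    used by the DMD half of the search.
    """

    lj_sigma: dict = field(default_factory=dict)     # type -> A
    lj_epsilon: dict = field(default_factory=dict)   # type -> kJ/mol
    pair_table: dict = field(default_factory=dict)   # (ta, tb) -> (sigma, eps)
    dielectric: float = 15.0
    coulomb_prefactor: float = COULOMB_PREFACTOR
    r_cut: float = 12.0
    lj_shift_start: float = 9.0
    coulomb_shift_start: float = 0.5
    nonbonded_scale: float = 1.0
    kB: float = KB

    def __post_init__(self) -> None:
        if not (0.0 < self.nonbonded_scale <= 1.0):
            raise InputError("nonbonded_scale must lie in (0, 1]")
        for name in ("lj_shift_start", "coulomb_shift_start"):
            v = getattr(self, name)
            if not (0.0 < v < self.r_cut):
                raise InputError(f"{name}={v} must satisfy 0 < shift_start < r_cut={self.r_cut}")
        if any(e < 0 for e in self.lj_epsilon.values()):
            raise InputError("lj_epsilon values must be >= 0")

    def pair_params(self, type_a: str, type_b: str) -> tuple[float, float]:
        """(sigma, epsilon) for a type pair, honouring the pair table."""
        key = (type_a, type_b)
        if key in self.pair_table:
            return self.pair_table[key]
        key = (type_b, type_a)
        if key in self.pair_table:
            return self.pair_table[key]
        sigma = 0.5 * (self.lj_sigma[type_a] + self.lj_sigma[type_b])
        eps = float(np.sqrt(self.lj_epsilon[type_a] * self.lj_epsilon[type_b]))
        return sigma, eps

    def with_scale(self, scale: float) -> "ForceFieldParams":
        return replace(self, nonbonded_scale=scale)


@dataclass
class Conformation:
    """Coordinates (and optional velocities) of every bead, with optional box.

    ``box`` is an orthorhombic box ``(lx, ly, lz)`` in A, or ``None`` for a
    non-periodic system (clusters, pathway toys).
    """

    coords: np.ndarray
    box: Optional[tuple[float, float, float]] = None
    velocities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        if self.box is not None:
            self.box = tuple(float(b) for b in self.box)
            if any(b <= 0 for b in self.box):
                raise InputError("box lengths must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
            if self.velocities.shape != self.coords.shape:
                raise InputError("velocities shape must match coords")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(
            self.coords.copy(),
            self.box,
            None if self.velocities is None else self.velocities.copy(),
        )


def displacement(
    a: np.ndarray, b: np.ndarray, box: Optional[Sequence[float]]
) -> np.ndarray:
    """Minimum-image displacement vectors ``a - b`` (orthorhombic box)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box is not None:
        L = np.asarray(box, dtype=float)
        d -= L * np.round(d / L)
    return d
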