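"""Run configuration: shipped defaults, file loading, validation.

The defaults are the method's published operating point for MARTINI-scale
bead systems: 10 fs time step, 600 K proposal moves of 300 steps, kT
re-tuned every 20 steps toward 50% acceptance, 12 A cutoff with LJ
switching from 9 A and Coulomb switching from 0.5 A, dielectric 15, and
16 NEB images.  Every key can be overridden from a YAML config file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml

from .topology import InputError


@dataclass
class Settings:
    # integrator / proposal moves
    dt: float = 10.0                 # fs
    t_move: float = 600.0            # K, proposal-move temperature
    steps_per_move: int = 300
    tau: float = 100.0               # fs, Berendsen coupling time
    # STUN / Metropolis controller
    kT0: float = 1.0                 # initial effective temperature (dimensionless surface)
    adapt_period: int = 20
    acceptance_target: float = 0.5
    adapt_factor: float = 1.2
    # nonbonded model
    r_cut: float = 12.0              # A
    lj_shift_start: float = 9.0      # A
    coulomb_shift_start: float = 0.5  # A
    dielectric: float = 15.0
    # minimization
    force_tol: float = 1e-2          # kJ/mol/A
    max_minimize_iter: int = 5000
    minimizer: str = "lbfgs"         # search-pipeline relaxation engine
    # pathway
    neb_images: int = 16
    neb_spring_k: float = 10.0       # kJ/mol/A^2
    neb_climb: bool = False
    pull_restraint_k: float = 50.0   # kJ/mol/A^2
    pull_velocity: float = 0.01      # A per step
    # search orchestration
    n_starts: int = 1
    iters_per_start: int = 100
    seed: Optional[int] = None

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(
    path: Optional[Union[str, Path, dict]] = None, strict: bool = True
) -> Settings:
    """Load settings from a YAML file (or dict); missing keys take defaults.

    Unknown keys raise :class:`InputError` naming the key in strict mode
    and warn otherwise; value validation names the offending key too.
    """
    data: dict = {}
    if isinstance(path, dict):
        data = dict(path)
    elif path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(Settings)}
    unknown = sorted(set(data) - known)
    if unknown:
        if strict:
            raise InputError(f"unknown config keys: {unknown}")
        import warnings

        warnings.warn(f"ignoring unknown config keys: {unknown}")
        data = {k: v for k, v in data.items() if k in known}
    settings = Settings(**data)
    _validate(settings)
    return settings


def _validate(s: Settings) -> None:
    checks = {
        "dt": s.dt > 0,
        "t_move": s.t_move > 0,
        "steps_per_move": s.steps_per_move >= 0,
        "adapt_period": s.adapt_period >= 1,
        "acceptance_target": 0.0 < s.acceptance_target < 1.0,
        "adapt_factor": s.adapt_factor > 1.0,
        "r_cut": s.r_cut > 0,
        "lj_shift_start": 0 < s.lj_shift_start < s.r_cut,
        "coulomb_shift_start": 0 < s.coulomb_shift_start < s.r_cut,
        "dielectric": s.dielectric > 0,
        "neb_images": s.neb_images >= 3,
        "force_tol": s.force_tol > 0,
    }
    bad = [k for k, ok in checks.items() if not ok]
    if bad:
        raise InputError(f"invalid config values for: {bad}")
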