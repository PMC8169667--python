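"""File formats: PDB structures, extended-XYZ trajectories, topology YAML.

Structures travel as PDB (one bead per ATOM record; the bead type is the
atom name, the residue id the PDB residue number, the group a chain id;
occupancy and B-factor carry the group code and residue id redundantly).
A full topology — masses, charges, bonds, angles, labels — does not fit
in a PDB, so :func:`write_system` emits a YAML sidecar next to the PDB and
:func:`read_system` reads the pair back losslessly (PDB coordinates keep
3 decimals; internal coordinates are never rounded elsewhere).

Trajectories are extended-XYZ text: one block per frame, the comment line
carrying ``time_fs``, ``epot``, ``ekin``, ``temp`` and optionally ``box``
as key=value pairs printed with full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from .dynamics import Trajectory
from .topology import BeadTopology, Conformation, InputError

GROUP_TO_CHAIN = {"ligand": "L", "receptor": "R", "solvent": "S", "ion": "I"}
CHAIN_TO_GROUP = {v: k for k, v in GROUP_TO_CHAIN.items()}
GROUP_CODE = {"ligand": 1.0, "receptor": 2.0, "solvent": 3.0, "ion": 4.0}


# --------------------------------------------------------------------------
# PDB structures

def write_structure(path: Union[str, Path], conf: Conformation, topo: BeadTopology) -> None:
    """Write a single structure as PDB (box as CRYST1 when periodic)."""
    n = topo.n_beads
    arr = AtomArray(n)
    arr.coord = conf.coords.astype(np.float32)
    arr.atom_name = np.array([str(t)[:4] for t in topo.bead_type])
    arr.res_name = np.array(["BEA"] * n)
    arr.res_id = topo.residue_id + 1  # PDB residue numbers are 1-based
    arr.chain_id = np.array([GROUP_TO_CHAIN[g] for g in topo.group])
    arr.element = np.array(["C"] * n)
    arr.hetero = np.ones(n, dtype=bool)
    arr.set_annotation("occupancy", np.array([GROUP_CODE[g] for g in topo.group]))
    arr.set_annotation("b_factor", np.minimum(topo.residue_id.astype(float), 999.0))
    if conf.box is not None:
        arr.box = np.diag(conf.box).astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_structure(
    path: Union[str, Path], mapping_config: Union[str, Path, dict]
) -> tuple[BeadTopology, Conformation]:
    """Read a PDB written by this package (or any bead PDB) plus a mapping.

    The mapping declares what the PDB cannot: per-bead-name mass/charge
    (``bead_types``), chain-to-group assignment (``chains``), and optional
    ``bonds`` / ``angles`` lists.  Unknown bead names raise an error that
    lists them.
    """
    if not isinstance(mapping_config, dict):
        with open(mapping_config) as fh:
            mapping_config = yaml.safe_load(fh)
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    types = [str(t) for t in arr.atom_name]
    bead_types = mapping_config.get("bead_types", {})
    unknown = sorted({t for t in types if t not in bead_types})
    if unknown:
        raise InputError(f"bead names missing from the mapping config: {unknown}")
    chains = mapping_config.get("chains", CHAIN_TO_GROUP)
    groups = []
    for c in arr.chain_id:
        if str(c) not in chains:
            raise InputError(f"chain {c!r} missing from the mapping config")
        groups.append(chains[str(c)])
    topo = BeadTopology(
        bead_type=types,
        mass=[float(bead_types[t]["mass"]) for t in types],
        charge=[float(bead_types[t].get("charge", 0.0)) for t in types],
        bonds=np.array(mapping_config.get("bonds", []), dtype=float).reshape(-1, 4),
        angles=np.array(mapping_config.get("angles", []), dtype=float).reshape(-1, 5),
        group=groups,
        residue_id=np.asarray(arr.res_id, dtype=int) - 1,
        backbone=[bool(bead_types[t].get("backbone", False)) for t in types],
    )
    box = None
    if arr.box is not None:
        diag = np.diag(np.asarray(arr.box, dtype=float))
        if np.all(diag > 0):
            box = tuple(diag)
    conf = Conformation(np.asarray(arr.coord, dtype=float), box)
    return topo, conf


# --------------------------------------------------------------------------
# full-fidelity system round trip (PDB + YAML sidecar)

def write_system(prefix: Union[str, Path], conf: Conformation, topo: BeadTopology) -> tuple[Path, Path]:
    """Write ``<prefix>.pdb`` and ``<prefix>.topology.yaml``; returns both paths."""
    prefix = Path(prefix)
    pdb_path = prefix.with_suffix(".pdb")
    topo_path = prefix.parent / (prefix.name + ".topology.yaml")
    write_structure(pdb_path, conf, topo)
    payload = {
        "bead_type": [str(t) for t in topo.bead_type],
        "mass": topo.mass.tolist(),
        "charge": topo.charge.tolist(),
        "bonds": topo.bonds.tolist(),
        "angles": topo.angles.tolist(),
        "group": [str(g) for g in topo.group],
        "residue_id": topo.residue_id.tolist(),
        "backbone": topo.backbone.astype(int).tolist(),
        "box": list(conf.box) if conf.box is not None else None,
    }
    with open(topo_path, "w") as fh:
        yaml.safe_dump(payload, fh, default_flow_style=None)
    return pdb_path, topo_path


def read_system(prefix: Union[str, Path]) -> tuple[BeadTopology, Conformation]:
    """Read a system written by :func:`write_system`."""
    prefix = Path(prefix)
    pdb_path = prefix.with_suffix(".pdb")
    topo_path = prefix.parent / (prefix.name + ".topology.yaml")
    with open(topo_path) as fh:
        payload = yaml.safe_load(fh)
    topo = BeadTopology(
        bead_type=payload["bead_type"],
        mass=payload["mass"],
        charge=payload["charge"],
        bonds=np.array(payload["bonds"], dtype=float).reshape(-1, 4),
        angles=np.array(payload["angles"], dtype=float).reshape(-1, 5),
        group=payload["group"],
        residue_id=payload["residue_id"],
        backbone=np.array(payload["backbone"], dtype=bool),
    )
    pdb = PDBFile.read(str(pdb_path))
    arr = pdb.get_structure(model=1)
    box = tuple(payload["box"]) if payload.get("box") else None
    conf = Conformation(np.asarray(arr.coord, dtype=float), box)
    if conf.n_beads != topo.n_beads:
        raise InputError(
            f"{pdb_path} has {conf.n_beads} beads but the topology sidecar "
            f"declares {topo.n_beads}"
        )
    return topo, conf


# --------------------------------------------------------------------------
# extended-XYZ trajectories

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_trajectory_frame(
    fh,
    coords: np.ndarray,
    types,
    time_fs: float,
    epot: float,
    ekin: float,
    temp: float,
    box: Optional[tuple[float, float, float]] = None,
) -> None:
    """Append one extended-XYZ frame to an open text handle."""
    fh.write(f"{len(coords)}\n")
    comment = (
        f"time_fs={_fmt(time_fs)} epot={_fmt(epot)} "
        f"ekin={_fmt(ekin)} temp={_fmt(temp)}"
    )
    if box is not None:
        comment += ' box="' + " ".join(_fmt(b) for b in box) + '"'
    fh.write(comment + "\n")
    for t, (x, y, z) in zip(types, coords):
        fh.write(f"{t} {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")


def write_trajectory(path: Union[str, Path], traj: Trajectory, topo: BeadTopology) -> None:
    """Write a whole trajectory as concatenated extended-XYZ frames."""
    with open(path, "w") as fh:
        for k in range(len(traj)):
            write_trajectory_frame(
                fh, traj.coords[k], topo.bead_type, traj.times[k],
                traj.epot[k], traj.ekin[k], traj.temperature[k], traj.box,
            )


def read_trajectory(path: Union[str, Path]) -> tuple[Trajectory, list[str]]:
    """Read an extended-XYZ trajectory; returns (Trajectory, bead types)."""
    frames, times, epots, ekins, temps = [], [], [], [], []
    types: list[str] = []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        fields: dict[str, str] = {}
        comment = lines[k + 1]
        # split key=value pairs, honouring quoted values
        import shlex

        for tok in shlex.split(comment):
            if "=" in tok:
                key, val = tok.split("=", 1)
                fields[key] = val
        times.append(float(fields.get("time_fs", len(times))))
        epots.append(float(fields.get("epot", "nan")))
        ekins.append(float(fields.get("ekin", "nan")))
        temps.append(float(fields.get("temp", "nan")))
        if "box" in fields:
            box = tuple(float(b) for b in fields["box"].split())
        block = lines[k + 2 : k + 2 + n]
        if len(block) < n:
            raise InputError(f"truncated frame at line {k + 1} of {path}")
        coords = np.empty((n, 3))
        ftypes = []
        for i, line in enumerate(block):
            parts = line.split()
            ftypes.append(parts[0])
            coords[i] = [float(p) for p in parts[1:4]]
        if not types:
            types = ftypes
        frames.append(coords)
        k += 2 + n
    traj = Trajectory(
        np.array(frames), np.array(times), np.array(epots), np.array(ekins),
        np.array(temps), box,
    )
    return traj, types


# --------------------------------------------------------------------------
# reproducibility manifest

def write_manifest(path: Union[str, Path], config: dict, seed: Optional[int]) -> None:
    """Record what produced a run: config hash, seed, package version."""
    import hashlib

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "stunbh_version": __version__,
        "numpy_version": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
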