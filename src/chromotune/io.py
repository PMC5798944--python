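"""File formats: multi-model PDB and XYZ trajectories, CSV tables, model JSON.

Trajectories are exchanged either as multi-model PDB (MODEL/ENDMDL
records, coordinates in Ångström on disk, converted to nm in memory;
read via biotite) or as a plain whitespace-delimited XYZ-per-frame text
dialect: per frame, a line with the atom count, a comment line, then
one ``name x y z`` line per atom, coordinates in nm.  Atom names are
matched case-insensitively on read.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .fluctuation import RMSFProfile
from .regression import RegressionModel
from .topology import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "write_model_json",
    "read_model_json",
    "write_rmsf_csv",
    "load_reference_lambda_max",
]

_NM_PER_ANGSTROM = 0.1


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (Ångström on disk)."""
    n = traj.n_atoms
    template = AtomArray(n)
    template.chain_id[:] = "A"
    template.res_id[:] = 1
    template.res_name[:] = "LYR"
    template.atom_name = np.array(traj.atom_names)
    template.element = np.array([a[0] for a in traj.atom_names])
    template.hetero[:] = False
    stack = AtomArrayStack(traj.n_frames, n)
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.coords / _NM_PER_ANGSTROM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory_pdb(path: str | Path, pigment_id: str | None = None) -> Trajectory:
    """Read a multi-model PDB trajectory; coordinates converted to nm."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, AtomArray):
        stack = AtomArrayStack(1, stack.array_length())
    names = tuple(str(a) for a in stack.atom_name)
    return Trajectory(
        pigment_id=pigment_id or Path(path).stem,
        atom_names=names,
        coords=np.asarray(stack.coord, dtype=float) * _NM_PER_ANGSTROM,
    )


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write the plain XYZ-per-frame dialect (nm)."""
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"{traj.pigment_id} frame {t}\n")
            for name, (x, y, z) in zip(traj.atom_names, traj.coords[t]):
                fh.write(f"{name} {x:.9f} {y:.9f} {z:.9f}\n")


def read_trajectory_xyz(
    path: str | Path, pigment_id: str | None = None, units: str = "nm"
) -> Trajectory:
    """Read the plain XYZ-per-frame dialect.

    ``units`` is ``"nm"`` (default) or ``"angstrom"`` for files written
    in Ångström.
    """
    scale = {"nm": 1.0, "angstrom": _NM_PER_ANGSTROM}[units]
    frames = []
    names: list[str] | None = None
    with open(path) as fh:
        lines = [ln for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        n = int(line)
        i += 2  # skip comment line
        frame_names = []
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + j].split()
            frame_names.append(parts[0])
            coords[j] = [float(v) for v in parts[1:4]]
        i += n
        if names is None:
            names = frame_names
        elif [a.upper() for a in names] != [a.upper() for a in frame_names]:
            raise ValueError(f"inconsistent atom names across frames in {path}")
        frames.append(coords * scale)
    if names is None:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(
        pigment_id=pigment_id or Path(path).stem,
        atom_names=tuple(names),
        coords=np.stack(frames),
    )


def read_trajectory(
    path: str | Path, pigment_id: str | None = None, units: str | None = None
) -> Trajectory:
    """Read a trajectory, dispatching on file extension (.pdb or .xyz)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return read_trajectory_pdb(path, pigment_id)
    if suffix == ".xyz":
        return read_trajectory_xyz(path, pigment_id, units or "nm")
    raise ValueError(f"unsupported trajectory format {suffix!r} (use .pdb or .xyz)")


def write_model_json(model: RegressionModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")


def read_model_json(path: str | Path) -> RegressionModel:
    with open(path) as fh:
        return RegressionModel.from_dict(json.load(fh))


def write_rmsf_csv(profile: RMSFProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "pigment_id": profile.pigment_id,
            "atom": profile.atoms,
            "rmsf_nm": profile.values,
        }
    ).to_csv(path, index=False)


def load_reference_lambda_max() -> pd.DataFrame:
    """The packaged table of 14 teleost Rh2 pigments and their λ_max (nm).

    Columns: pigment_id, species, opsin, uniprot_accession, lambda_max_nm.
    """
    with resources.files("chromotune.data").joinpath(
        "teleost_rh2_lambda_max.csv"
    ).open() as fh:
        return pd.read_csv(fh)
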