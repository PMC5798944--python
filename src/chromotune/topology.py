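"""Heavy-atom topology of the LYS+RET moiety and trajectory container.

The chromophore of a visual pigment is 11-*cis* retinal bound through a
Schiff-base linkage (C15=NZ) to a lysine residue in the opsin binding
pocket.  All descriptors in this package are defined on the heavy atoms of
that combined moiety ("LYS+RET"): the nine lysine heavy atoms
(N, CA, C, O, CB, CG, CD, CE, NZ) and the twenty retinal carbons
(C1--C20, methyls C16--C20 included).

A :class:`ChromophoreTopology` names the atoms, the torsion and geometric
angle descriptors computed on them, the beta-ionone ring subset, and the
atom ordering used for fluctuation profiles.  The default configuration
defines 15 torsions and 4 geometric angles (19 descriptors); only two of
the torsions have a canonical definition in the source data
(Torsion 1 = C5-C6-C7-C8 on the C6--C7 single bond, and
Torsion 15 = C7-C6-C5-C18 around the ring), so the remaining definitions
walk the conjugated polyene chain and the lysine side chain and are
explicitly overridable from a JSON configuration file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ChromophoreTopology",
    "Trajectory",
    "default_topology",
    "LYSINE_ATOMS",
    "RETINAL_ATOMS",
]

LYSINE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ")
RETINAL_ATOMS: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 21))

#: Atom ordering of fluctuation profiles: lysine backbone, side chain,
#: Schiff base, then the polyene chain towards the beta-ionone ring, with
#: each methyl carbon listed directly after the chain atom it decorates.
DEFAULT_PROFILE_ORDER: tuple[str, ...] = (
    "N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ",
    "C15", "C14", "C20", "C13", "C12", "C11", "C10", "C19", "C9",
    "C8", "C7", "C6", "C18", "C5", "C4", "C3", "C2", "C1", "C16", "C17",
)

#: Beta-ionone ring heavy atoms: the C1--C6 ring plus its methyls.
DEFAULT_RING_ATOMS: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "C5", "C6", "C16", "C17", "C18",
)

# Torsion 1 and Torsion 15 are fixed by the source data; torsions 2-13
# walk the polyene chain from the ring towards the Schiff base and on down
# the lysine side chain, Torsion 14 ends at CA.  Overridable via JSON.
DEFAULT_TORSION_DEFS: dict[str, tuple[str, str, str, str]] = {
    "Torsion 1": ("C5", "C6", "C7", "C8"),
    "Torsion 2": ("C6", "C7", "C8", "C9"),
    "Torsion 3": ("C7", "C8", "C9", "C10"),
    "Torsion 4": ("C8", "C9", "C10", "C11"),
    "Torsion 5": ("C9", "C10", "C11", "C12"),
    "Torsion 6": ("C10", "C11", "C12", "C13"),
    "Torsion 7": ("C11", "C12", "C13", "C14"),
    "Torsion 8": ("C12", "C13", "C14", "C15"),
    "Torsion 9": ("C13", "C14", "C15", "NZ"),
    "Torsion 10": ("C14", "C15", "NZ", "CE"),
    "Torsion 11": ("C15", "NZ", "CE", "CD"),
    "Torsion 12": ("NZ", "CE", "CD", "CG"),
    "Torsion 13": ("CE", "CD", "CG", "CB"),
    "Torsion 14": ("CD", "CG", "CB", "CA"),
    "Torsion 15": ("C7", "C6", "C5", "C18"),
}

DEFAULT_ANGLE_DEFS: dict[str, tuple[str, str, str]] = {
    "Angle 1": ("C6", "C7", "C8"),
    "Angle 2": ("C10", "C11", "C12"),
    "Angle 3": ("CE", "NZ", "C15"),
    "Angle 4": ("C5", "C6", "C7"),
}


class TopologyError(ValueError):
    """Raised when a topology configuration is inconsistent."""


@dataclass(frozen=True)
class ChromophoreTopology:
    """Atom catalogue and angle-descriptor definitions for LYS+RET.

    Parameters
    ----------
    atom_names
        Ordered heavy-atom labels.
    torsion_defs
        Mapping torsion-name -> ordered quadruple of atom labels.
    angle_defs
        Mapping angle-name -> ordered triple of atom labels.
    ring_atoms
        Labels of the beta-ionone ring subset.
    profile_order
        Ordered labels defining the abscissa of fluctuation profiles.
    """

    atom_names: tuple[str, ...] = LYSINE_ATOMS + RETINAL_ATOMS
    torsion_defs: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TORSION_DEFS)
    )
    angle_defs: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ANGLE_DEFS)
    )
    ring_atoms: tuple[str, ...] = DEFAULT_RING_ATOMS
    profile_order: tuple[str, ...] = DEFAULT_PROFILE_ORDER

    def __post_init__(self) -> None:
        names = set(self.atom_names)
        if len(names) != len(self.atom_names):
            raise TopologyError("duplicate atom names in topology")
        for kind, defs, arity in (
            ("torsion", self.torsion_defs, 4),
            ("angle", self.angle_defs, 3),
        ):
            for dname, atoms in defs.items():
                if len(atoms) != arity:
                    raise TopologyError(
                        f"{kind} {dname!r} must name {arity} atoms, got {len(atoms)}"
                    )
                missing = [a for a in atoms if a not in names]
                if missing:
                    raise TopologyError(
                        f"{kind} {dname!r} references unknown atom(s) {missing}"
                    )
        for label, subset in (("ring_atoms", self.ring_atoms),
                              ("profile_order", self.profile_order)):
            if len(set(subset)) != len(subset):
                raise TopologyError(f"duplicate atoms in {label}")
            missing = [a for a in subset if a not in names]
            if missing:
                raise TopologyError(f"{label} references unknown atom(s) {missing}")

    @property
    def descriptor_names(self) -> list[str]:
        """All descriptor names, torsions first."""
        return list(self.torsion_defs) + list(self.angle_defs)

    @property
    def n_descriptors(self) -> int:
        return len(self.torsion_defs) + len(self.angle_defs)

    def atom_index(self, name: str) -> int:
        """Index of an atom label, matched case-insensitively."""
        target = name.upper()
        for i, a in enumerate(self.atom_names):
            if a.upper() == target:
                return i
        raise TopologyError(f"atom {name!r} not in topology")

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromophoreTopology":
        """Load a topology configuration from a JSON file.

        The file may omit any key; omitted keys fall back to the packaged
        defaults, so a configuration overriding a single torsion only
        needs a ``torsion_defs`` entry for that torsion.
        """
        with open(path) as fh:
            cfg = json.load(fh)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ChromophoreTopology":
        torsions = dict(DEFAULT_TORSION_DEFS)
        for k, v in cfg.get("torsion_defs", {}).items():
            torsions[k] = tuple(v)
        angles = dict(DEFAULT_ANGLE_DEFS)
        for k, v in cfg.get("angle_defs", {}).items():
            angles[k] = tuple(v)
        return cls(
            atom_names=tuple(cfg.get("atom_names", LYSINE_ATOMS + RETINAL_ATOMS)),
            torsion_defs=torsions,
            angle_defs=angles,
            ring_atoms=tuple(cfg.get("ring_atoms", DEFAULT_RING_ATOMS)),
            profile_order=tuple(cfg.get("profile_order", DEFAULT_PROFILE_ORDER)),
        )

    def to_dict(self) -> dict:
        return {
            "atom_names": list(self.atom_names),
            "torsion_defs": {k: list(v) for k, v in self.torsion_defs.items()},
            "angle_defs": {k: list(v) for k, v in self.angle_defs.items()},
            "ring_atoms": list(self.ring_atoms),
            "profile_order": list(self.profile_order),
        }


def default_topology() -> ChromophoreTopology:
    """The packaged default LYS+RET topology (19 descriptors)."""
    with resources.files("chromotune.data").joinpath("default_topology.json").open() as fh:
        return ChromophoreTopology.from_dict(json.load(fh))


@dataclass
class Trajectory:
    """Ordered frames of heavy-atom coordinates for one pigment.

    Coordinates are stored in nanometres with shape ``(n_frames, n_atoms, 3)``.
    ``frame_interval_ps`` is informational only.
    """

    pigment_id: str
    atom_names: tuple[str, ...]
    coords: np.ndarray
    frame_interval_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (T, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.atom_names):
            raise ValueError(
                f"{len(self.atom_names)} atom names but coords for "
                f"{self.coords.shape[1]} atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("trajectory contains non-finite coordinates")
        self.atom_names = tuple(self.atom_names)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, name: str) -> int:
        target = name.upper()
        for i, a in enumerate(self.atom_names):
            if a.upper() == target:
                return i
        raise KeyError(f"atom {name!r} not in trajectory {self.pigment_id!r}")

    def atom_indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.atom_index(n) for n in names], dtype=int)

    def subset(self, names: Sequence[str]) -> "Trajectory":
        """New trajectory restricted to the given atoms, in the given order."""
        idx = self.atom_indices(names)
        return Trajectory(
            pigment_id=self.pigment_id,
            atom_names=tuple(self.atom_names[i] for i in idx),
            coords=self.coords[:, idx, :].copy(),
            frame_interval_ps=self.frame_interval_ps,
        )
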