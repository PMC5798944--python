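"""Per-atom positional fluctuation (RMSF) of the LYS+RET moiety.

Rigid-body drift is removed by least-squares (Kabsch) superposition of
every frame onto a reference — by default the iteratively refined mean
structure — before fluctuations are measured.  The per-atom RMSF is

    RMSF_a = sqrt( (1/T) * sum_t || v_t(a) - vbar(a) ||^2 )

with ``v_t(a)`` the position of atom ``a`` in frame ``t`` and ``vbar``
its time-mean position.  Profiles are reported along the topology's
``profile_order`` (lysine backbone towards the beta-ionone ring), and
the scalar features fed to the spectral regression are trapezoidal areas
under these profiles at unit atom spacing: one over all LYS+RET atoms
and one over the beta-ionone ring subset.  Blue-sensitive pigments show
visibly flatter profiles (smaller areas) than green-sensitive ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import DegenerateGeometryError
from .topology import Trajectory

__all__ = ["RMSFProfile", "kabsch_superpose", "rmsf", "rmsf_auc"]


class InsufficientFramesError(ValueError):
    """Raised when a fluctuation statistic needs more frames than given."""


@dataclass
class RMSFProfile:
    """Per-atom RMSF values (nm) along an ordered atom list."""

    pigment_id: str
    atoms: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.atoms),):
            raise ValueError("one RMSF value per atom required")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("RMSF values must be finite and non-negative")
        self.atoms = tuple(self.atoms)

    def restrict(self, atoms: Sequence[str]) -> "RMSFProfile":
        index = {a.upper(): i for i, a in enumerate(self.atoms)}
        idx = [index[a.upper()] for a in atoms]
        return RMSFProfile(self.pigment_id, tuple(atoms), self.values[idx])


def _kabsch_rotations(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotations aligning each centred frame onto a centred ref.

    mobile: (T, m, 3) centred frames; ref: (m, 3) centred reference.
    Returns (T, 3, 3) proper rotations (right-multiply row vectors).
    """
    h = np.einsum("tmi,mj->tij", mobile, ref)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("tij,tjk->tik", u, vt))
    d = np.ones_like(u[:, :, 0])
    d[:, -1] = det
    return np.einsum("tij,tj,tjk->tik", u, d, vt)


def kabsch_superpose(
    traj: Trajectory,
    reference: int | str = "mean",
    fit_atoms: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> Trajectory:
    """Least-squares superposition of every frame onto a reference.

    Parameters
    ----------
    traj
        Input trajectory (not modified).
    reference
        Frame index, or ``"mean"`` to fit against the mean structure,
        iterating fit and mean until the mean moves by less than ``tol``
        nm RMSD or ``max_iter`` iterations.
    fit_atoms
        Atom labels used in the least-squares fit (default: all atoms).
        The resulting rigid transform is applied to every atom.

    Raises
    ------
    DegenerateGeometryError
        If fewer than three fit atoms are given or the fit set is
        collinear in some frame (the rotation is then underdetermined).
    """
    fit_idx = (
        traj.atom_indices(fit_atoms)
        if fit_atoms is not None
        else np.arange(traj.n_atoms)
    )
    if len(fit_idx) < 3:
        raise DegenerateGeometryError(
            "superposition needs >= 3 non-collinear fit atoms"
        )
    coords = traj.coords.copy()
    sub = coords[:, fit_idx, :]
    # collinearity check on the first frame's fit set
    centred0 = sub[0] - sub[0].mean(axis=0)
    if np.linalg.matrix_rank(centred0, tol=1e-10) < 2:
        raise DegenerateGeometryError("fit atoms are collinear")

    def fit_to(ref_sub: np.ndarray) -> np.ndarray:
        ref_c = ref_sub - ref_sub.mean(axis=0)
        cent = sub.mean(axis=1, keepdims=True)
        rot = _kabsch_rotations(sub - cent, ref_c)
        moved = np.einsum("tmi,tij->tmj", coords - cent, rot) + ref_sub.mean(axis=0)
        return moved

    if reference == "mean":
        ref_sub = sub[0]
        prev_mean = None
        for _ in range(max_iter):
            moved = fit_to(ref_sub)
            mean_sub = moved[:, fit_idx, :].mean(axis=0)
            if prev_mean is not None:
                drift = np.sqrt(((mean_sub - prev_mean) ** 2).sum(axis=1).mean())
                if drift < tol:
                    break
            prev_mean = mean_sub
            ref_sub = mean_sub
        coords_out = fit_to(ref_sub)
    else:
        ref_sub = sub[int(reference)]
        coords_out = fit_to(ref_sub)

    return Trajectory(
        pigment_id=traj.pigment_id,
        atom_names=traj.atom_names,
        coords=coords_out,
        frame_interval_ps=traj.frame_interval_ps,
    )


def rmsf(traj: Trajectory, atoms: Sequence[str] | None = None) -> RMSFProfile:
    """Root-mean-square fluctuation per atom, in nm.

    The trajectory is used as given — call :func:`kabsch_superpose`
    first to remove rigid-body motion.  ``atoms`` restricts and orders
    the profile (default: trajectory atom order).
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF requires at least 2 frames")
    if atoms is None:
        atoms = traj.atom_names
    idx = traj.atom_indices(atoms)
    x = traj.coords[:, idx, :]
    mean = x.mean(axis=0)
    vals = np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))
    # atoms that never move are exactly zero, not rounding residue
    static = (x == x[0]).all(axis=(0, 2))
    vals[static] = 0.0
    return RMSFProfile(traj.pigment_id, tuple(atoms), vals)


def rmsf_auc(profile: RMSFProfile) -> float:
    """Trapezoidal area under an RMSF profile at unit atom spacing.

    Units are nm * atom-index; for a profile of m atoms the abscissa runs
    0..m-1, so a constant profile c integrates to c * (m - 1).
    """
    if len(profile.atoms) < 2:
        raise ValueError("AUC requires a profile of at least 2 atoms")
    return float(np.trapezoid(profile.values))
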