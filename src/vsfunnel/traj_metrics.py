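"""Cα trajectory analytics: Kabsch superposition, RMSD, RMSF, radius of gyration.

A trajectory is a uniform-stride stack of frames, each an ordered array of Cα
positions with chain/residue bookkeeping (the two chains of a dimer can be
reported separately). RMSD per frame is computed after least-squares rigid
superposition (Kabsch: centroid translation + SVD rotation with determinant
correction, so reflections are never introduced). RMSF superposes all frames
onto the reference, computes the mean structure, re-superposes onto that mean
(one refinement pass) and reports per-position fluctuation about the mean.
Rg uses unit masses on Cα by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryFrame",
    "Trajectory",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "radius_of_gyration",
    "rg_series",
    "read_ca_trajectory_pdb",
    "write_ca_trajectory_pdb",
    "metrics_table",
]


@dataclass
class TrajectoryFrame:
    coords: np.ndarray  # (n, 3) Å
    chain_ids: np.ndarray | None = None
    res_ids: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")


@dataclass
class Trajectory:
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å
    chain_ids: np.ndarray | None = None
    res_ids: np.ndarray | None = None
    stride_ps: float = 1.0
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> TrajectoryFrame:
        return TrajectoryFrame(self.coords[i], self.chain_ids, self.res_ids, self.masses)


def _as_coords(frame) -> np.ndarray:
    if isinstance(frame, TrajectoryFrame):
        return frame.coords
    return np.asarray(frame, dtype=float)


def kabsch_superpose(ref, mobile):
    """Optimal rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` with
    ``superposed = mobile @ rotation.T + translation``. The rotation is proper
    (det = +1); RMSD is over all positions after superposition.
    """
    ref = _as_coords(ref)
    mob = _as_coords(mobile)
    if ref.shape != mob.shape:
        raise ValueError("frame length mismatch")
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least three positions")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    p = mob - mob_c
    q = ref - ref_c
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_c - rotation @ mob_c
    moved = p @ rotation.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _superpose_coords(ref: np.ndarray, mob: np.ndarray) -> np.ndarray:
    rotation, translation, _ = kabsch_superpose(ref, mob)
    return mob @ rotation.T + translation


def rmsd_series(traj: Trajectory, ref: int = 0) -> np.ndarray:
    """Per-frame RMSD (Å) against a reference frame, after superposition."""
    reference = traj.coords[ref]
    return np.array([kabsch_superpose(reference, traj.coords[i])[2] for i in range(traj.n_frames)])


def rmsf_profile(traj: Trajectory, ref: int = 0) -> np.ndarray:
    """Per-position RMSF (Å) about the mean structure.

    All frames are superposed onto the reference frame, the mean structure is
    formed, frames are re-superposed onto that mean (one refinement pass), and
    RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    aligned = np.array([_superpose_coords(traj.coords[ref], f) for f in traj.coords])
    mean_structure = aligned.mean(axis=0)
    aligned = np.array([_superpose_coords(mean_structure, f) for f in aligned])
    mean_structure = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean_structure) ** 2, axis=2), axis=0))


def radius_of_gyration(frame, masses=None) -> float:
    """Mass-weighted radius of gyration (Å); unit masses by default."""
    xyz = _as_coords(frame)
    if xyz.shape[0] < 1:
        raise ValueError("empty frame")
    if masses is None and isinstance(frame, TrajectoryFrame) and frame.masses is not None:
        masses = frame.masses
    m = np.ones(xyz.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((xyz - com) ** 2, axis=1)).sum() / m.sum()))


def rg_series(traj: Trajectory) -> np.ndarray:
    return np.array([radius_of_gyration(traj.coords[i], traj.masses) for i in range(traj.n_frames)])


def read_ca_trajectory_pdb(path, stride_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL frames), keeping Cα atoms."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdbio.get_structure(pdb_file)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    mask = stack.atom_name == "CA"
    stack = stack[..., mask]
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        chain_ids=np.asarray(stack.chain_id),
        res_ids=np.asarray(stack.res_id),
        stride_ps=stride_ps,
    )


def write_ca_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a Cα trajectory as a multi-model PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = traj.coords[0]
    template.chain_id = traj.chain_ids if traj.chain_ids is not None else np.array(["A"] * n)
    template.res_id = traj.res_ids if traj.res_ids is not None else np.arange(1, n + 1)
    template.res_name = np.array(["ALA"] * n)
    template.atom_name = np.array(["CA"] * n)
    template.element = np.array(["C"] * n)
    frames = []
    for i in range(traj.n_frames):
        frame = template.copy()
        frame.coord = traj.coords[i]
        frames.append(frame)
    pdb_file = pdbio.PDBFile()
    pdbio.set_structure(pdb_file, struc.stack(frames))
    pdb_file.write(str(path))


def metrics_table(traj: Trajectory, ref: int = 0):
    """Per-frame (frame, time_ps, rmsd, rg) and per-position (chain, resnum,
    rmsf) tables."""
    rmsd = rmsd_series(traj, ref)
    rg = rg_series(traj)
    frames = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "time_ps": np.arange(traj.n_frames) * traj.stride_ps,
            "rmsd": rmsd,
            "rg": rg,
        }
    )
    rmsf = rmsf_profile(traj, ref)
    positions = pd.DataFrame(
        {
            "position": np.arange(traj.n_atoms),
            "chain": traj.chain_ids if traj.chain_ids is not None else ["A"] * traj.n_atoms,
            "resnum": traj.res_ids if traj.res_ids is not None else np.arange(1, traj.n_atoms + 1),
            "rmsf": rmsf,
        }
    )
    return frames, positions
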