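"""Superposition, RMSD/RMSF, average structures and reaction-coordinate
selection for dimer trajectories.

Default selections follow the Cα convention: RMSD series are Cα RMSD, and
RMSF is reported per residue via its Cα atom.  Two RMSD references are
supported and named explicitly in outputs: the initial structure
(``reference='initial'``) and the iteratively aligned average structure
(``reference='average'``, the RMSD_ave convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from sarahmd.core import ProtomerPair, Structure, Trajectory

AtomPredicate = Callable[[Structure], np.ndarray]


def ca_selection(s: Structure) -> np.ndarray:
    """Mask selecting Cα atoms (the default RMSD/RMSF selection)."""
    return np.array([n == "CA" for n in s.name])


def all_atoms(s: Structure) -> np.ndarray:
    return np.ones(s.n_atoms, dtype=bool)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation and the resulting RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _matched_indices(
    mobile: Structure, reference: Structure, selection: AtomPredicate
) -> tuple[np.ndarray, np.ndarray]:
    """Atom indices matched by (chain, res_seq, name) within the selection."""
    sel_ref = selection(reference)
    idx_m, idx_r = [], []
    for i in np.flatnonzero(sel_ref):
        key = (
            str(reference.chain_id[i]),
            int(reference.res_seq[i]),
            str(reference.name[i]),
        )
        try:
            j = mobile.atom_index(*key)
        except KeyError:
            continue
        idx_m.append(j)
        idx_r.append(int(i))
    return np.array(idx_m, dtype=int), np.array(idx_r, dtype=int)


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> SuperpositionResult:
    if len(mobile_xyz) < 3:
        raise ValueError("superposition requires at least 3 matched atoms")
    mob_c = mobile_xyz.mean(axis=0)
    ref_c = ref_xyz.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes problem with a proper
    # rotation (Kabsch sign correction built in)
    rot, _ = Rotation.align_vectors(ref_xyz - ref_c, mobile_xyz - mob_c)
    R = rot.as_matrix()
    t = ref_c - mob_c @ R.T
    moved = mobile_xyz @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_xyz) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: AtomPredicate = ca_selection,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto
    ``reference`` over atoms matched by (chain, res_seq, name)."""
    idx_m, idx_r = _matched_indices(mobile, reference, selection)
    if len(idx_m) < 3:
        raise ValueError(
            f"superposition requires >=3 matched atoms, found {len(idx_m)}"
        )
    return _kabsch(mobile.coords[idx_m], reference.coords[idx_r])


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: AtomPredicate = ca_selection,
) -> np.ndarray:
    """Per-frame RMSD (Å) after optimal superposition of each frame."""
    idx_m, idx_r = _matched_indices(traj.topology, reference, selection)
    if len(idx_m) < 3:
        raise ValueError("selection matches fewer than 3 atoms")
    ref_xyz = reference.coords[idx_r]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = _kabsch(traj.frames[f][idx_m], ref_xyz).rmsd
    return out


def average_structure(
    traj: Trajectory,
    selection: AtomPredicate = ca_selection,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> Structure:
    """Iteratively aligned mean structure.

    All frames are superposed (over ``selection``) onto the current mean,
    the mean is recomputed from the full atom set, and the loop repeats
    until the mean moves less than ``tol`` Å (RMS) or ``max_iter`` is hit.
    The fixed point is independent of frame order.
    """
    sel = selection(traj.topology)
    if sel.sum() < 3:
        raise ValueError("selection matches fewer than 3 atoms")
    # seed with the raw arithmetic mean so the fixed point is independent
    # of frame order and pure-translation ensembles average to their
    # geometric midpoint
    mean = traj.frames.mean(axis=0)
    for _ in range(max_iter):
        aligned = np.empty_like(traj.frames)
        for f in range(traj.n_frames):
            sup = _kabsch(traj.frames[f][sel], mean[sel])
            aligned[f] = sup.apply(traj.frames[f])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return traj.topology.with_coords(mean)


def aligned_frames(
    traj: Trajectory,
    reference: Structure,
    selection: AtomPredicate = ca_selection,
) -> np.ndarray:
    """All frames superposed onto ``reference`` over ``selection``."""
    sel = selection(traj.topology)
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        sup = _kabsch(traj.frames[f][sel], reference.coords[sel])
        out[f] = sup.apply(traj.frames[f])
    return out


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue fluctuation (Å) about the trajectory mean position."""

    residues: list[tuple[str, int, str]]  # (chain_id, res_seq, res_name)
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [r[0] for r in self.residues],
                "res_seq": [r[1] for r in self.residues],
                "res_name": [r[2] for r in self.residues],
                "rmsf": self.values,
            }
        )


def rmsf(
    traj: Trajectory, selection: AtomPredicate = ca_selection
) -> RMSFProfile:
    """Residue-level RMSF after alignment to the average structure.

    For each residue, RMSF = sqrt(mean over frames of the squared deviation
    of the residue's selected-atom centroid from its mean position).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single-frame trajectory")
    avg = average_structure(traj, selection)
    frames = aligned_frames(traj, avg, selection)
    sel = selection(traj.topology)
    topo = traj.topology
    groups: dict[tuple[str, int], list[int]] = {}
    names: dict[tuple[str, int], str] = {}
    for i in np.flatnonzero(sel):
        key = (str(topo.chain_id[i]), int(topo.res_seq[i]))
        groups.setdefault(key, []).append(int(i))
        names[key] = str(topo.res_name[i])
    residues = []
    values = []
    for key, idx in groups.items():
        centroid = frames[:, idx, :].mean(axis=1)  # (n_frames, 3)
        mean_pos = centroid.mean(axis=0)
        msd = np.mean(np.sum((centroid - mean_pos) ** 2, axis=1))
        residues.append((key[0], key[1], names[key]))
        values.append(np.sqrt(msd))
    return RMSFProfile(residues=residues, values=np.array(values))


def min_avg_ca_pair(
    traj: Trajectory, pair: ProtomerPair
) -> tuple[tuple[str, int], tuple[str, int]]:
    """Inter-protomer Cα pair with the smallest trajectory-average distance.

    Ties are broken lexicographically by (chain_a res_seq, chain_b res_seq).
    This pair defines the default PMF reaction coordinate.
    """
    topo = traj.topology
    pair.validate(topo)
    is_ca = np.array([n == "CA" for n in topo.name])
    idx_a = np.flatnonzero(is_ca & (topo.chain_id == pair.chain_a))
    idx_b = np.flatnonzero(is_ca & (topo.chain_id == pair.chain_b))
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both chains need CA atoms")
    xa = traj.frames[:, idx_a, :]  # (F, A, 3)
    xb = traj.frames[:, idx_b, :]  # (F, B, 3)
    d = np.linalg.norm(xa[:, :, None, :] - xb[:, None, :, :], axis=-1)
    avg = d.mean(axis=0)  # (A, B)
    best = None
    for ai in range(len(idx_a)):
        for bi in range(len(idx_b)):
            key = (
                avg[ai, bi],
                int(topo.res_seq[idx_a[ai]]),
                int(topo.res_seq[idx_b[bi]]),
            )
            if best is None or key < best[0]:
                best = (key, ai, bi)
    _, ai, bi = best
    return (
        (pair.chain_a, int(topo.res_seq[idx_a[ai]])),
        (pair.chain_b, int(topo.res_seq[idx_b[bi]])),
    )


def distance_series(
    traj: Trajectory,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
) -> np.ndarray:
    """Euclidean distance (Å) per frame between two atoms given as
    (chain_id, res_seq, atom_name)."""
    ia = traj.topology.atom_index(*atom_a)
    ib = traj.topology.atom_index(*atom_b)
    return np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)


def series_to_csv(values: np.ndarray, path, column: str = "value") -> None:
    pd.DataFrame({"frame": np.arange(len(values)), column: values}).to_csv(
        path, index=False
    )
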