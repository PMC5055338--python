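"""Shrake-Rupley solvent-accessible surface area, hydrophobic/hydrophilic
partition, and buried-surface-area series.

Areas are computed by spherical quadrature over a deterministic Fibonacci
point set (960 points by default, probe radius 1.4 Å), with Bondi van der
Waals radii assigned by element when an atom carries none.  The partition
is atom-level: carbon and sulfur count as hydrophobic, nitrogen and oxygen
(with their attached hydrogens) as hydrophilic, so SASA_H + SASA_P equals
the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import biotite.structure as bst

from sarahmd.core import ProtomerPair, Structure, Trajectory

_HYDROPHOBIC_ELEMENTS = {"C", "S"}
_HYDROPHILIC_ELEMENTS = {"N", "O"}


def _load_bondi() -> dict[str, float]:
    ref = resources.files("sarahmd.data").joinpath("vdw_radii.dat")
    out: dict[str, float] = {}
    with resources.as_file(ref) as p, open(p) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            el, r = ln.split()[:2]
            out[el.upper()] = float(r)
    return out


_BONDI = _load_bondi()


def assign_radii(s: Structure) -> np.ndarray:
    """Per-atom vdW radii: the atom's own value if set, else Bondi by
    element; errors on atoms with neither."""
    radii = s.vdw_radius.copy()
    for i in np.flatnonzero(np.isnan(radii)):
        el = str(s.element[i]).upper()
        if el not in _BONDI:
            raise ValueError(
                f"no van der Waals radius for atom {s.name[i]!r} "
                f"(element {el!r}) in residue {s.res_name[i]} {s.res_seq[i]}"
            )
        radii[i] = _BONDI[el]
    return radii


def shrake_rupley(
    s: Structure, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom SASA (Å²), deterministic for fixed ``n_points``."""
    radii = assign_radii(s)
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_seq
    arr.res_name = s.res_name.astype("U5")
    arr.atom_name = s.name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    values = bst.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=radii,
        ignore_ions=False,
    )
    return np.nan_to_num(np.asarray(values, dtype=float))


@dataclass
class SasaResult:
    """Per-atom SASA with its hydrophobic/hydrophilic aggregates (Å²)."""

    per_atom: np.ndarray | None
    sasa_h: float
    sasa_p: float

    @property
    def total(self) -> float:
        return self.sasa_h + self.sasa_p

    @property
    def pct_hydrophobic(self) -> float:
        return 100.0 * self.sasa_h / self.total

    @classmethod
    def from_components(cls, sasa_h: float, sasa_p: float) -> "SasaResult":
        """Build from already-aggregated hydrophobic/hydrophilic areas
        (e.g. components printed by another SASA program)."""
        if sasa_h < 0 or sasa_p < 0:
            raise ValueError("SASA components must be non-negative")
        return cls(per_atom=None, sasa_h=float(sasa_h), sasa_p=float(sasa_p))


def _hydrophobic_mask(s: Structure) -> np.ndarray:
    mask = np.zeros(s.n_atoms, dtype=bool)
    heavy = np.flatnonzero(s.element != "H")
    for i in range(s.n_atoms):
        el = str(s.element[i]).upper()
        if el in _HYDROPHOBIC_ELEMENTS:
            mask[i] = True
        elif el in _HYDROPHILIC_ELEMENTS:
            mask[i] = False
        elif el == "H":
            # hydrogens inherit the bucket of their bonded heavy atom
            d = np.linalg.norm(s.coords[heavy] - s.coords[i], axis=1)
            j = heavy[int(np.argmin(d))]
            mask[i] = str(s.element[j]).upper() in _HYDROPHOBIC_ELEMENTS
        else:
            raise ValueError(
                f"cannot classify element {el!r} as hydrophobic/hydrophilic"
            )
    return mask


def partition_sasa(per_atom: np.ndarray, s: Structure) -> SasaResult:
    """Split per-atom SASA into hydrophobic (C, S) and hydrophilic (N, O,
    attached H) buckets; the two sum exactly to the total."""
    per_atom = np.asarray(per_atom, dtype=float)
    if per_atom.shape != (s.n_atoms,):
        raise ValueError("per-atom SASA length does not match the structure")
    mask = _hydrophobic_mask(s)
    return SasaResult(
        per_atom=per_atom,
        sasa_h=float(per_atom[mask].sum()),
        sasa_p=float(per_atom[~mask].sum()),
    )


def buried_surface(
    obj: Structure | Trajectory,
    pair: ProtomerPair,
    probe: float = 1.4,
    n_points: int = 960,
):
    """Buried surface area BSA = SASA(A) + SASA(B) - SASA(AB).

    Returns a float for a Structure and a per-frame array for a
    Trajectory.
    """
    if isinstance(obj, Trajectory):
        return np.array(
            [
                buried_surface(obj.frame(f), pair, probe, n_points)
                for f in range(obj.n_frames)
            ]
        )
    s = obj
    pair.validate(s)
    complex_sasa = shrake_rupley(s, probe, n_points).sum()
    a = s.subset(s.chain_mask(pair.chain_a))
    b = s.subset(s.chain_mask(pair.chain_b))
    return float(
        shrake_rupley(a, probe, n_points).sum()
        + shrake_rupley(b, probe, n_points).sum()
        - complex_sasa
    )


def sasa_table(results: dict[str, SasaResult]) -> pd.DataFrame:
    """Report with one row per dimer label: SASA_H, SASA_P, total and
    percent hydrophobicity."""
    rows = [
        {
            "dimer": label,
            "sasa_h": r.sasa_h,
            "sasa_p": r.sasa_p,
            "total": r.total,
            "pct_hydrophobic": r.pct_hydrophobic,
        }
        for label, r in results.items()
    ]
    return pd.DataFrame(
        rows, columns=["dimer", "sasa_h", "sasa_p", "total", "pct_hydrophobic"]
    )
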