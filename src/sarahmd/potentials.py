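"""Knowledge-based 20x20 contact-potential scoring of dimer interfaces.

Six matrix slots are supported, named after the contact-potential families
commonly used for interface scoring (HL, BT, MJ99, SJKG, SKO, TSLE).  The
packaged tables are deterministic synthetic stand-ins with the
additive-plus-hydrophobicity structure typical of such potentials (see the
file headers); user-supplied literature tables in the same plain-text
format are loaded identically.

Before scoring, each matrix is normalized by z-scoring its 210 unique
upper-triangle entries (mean 0, sd 1), which places heterogeneous
potentials on one comparable axis and is invariant to the affine offsets
and scales that differ between published parameterizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from sarahmd.core import (
    ONE_TO_THREE,
    THREE_TO_ONE,
    ProtomerPair,
    Structure,
    Trajectory,
    canonical_res_name,
)
from sarahmd.contacts import contact_map
from sarahmd import geometry

MATRIX_NAMES = ("HL", "BT", "MJ99", "SJKG", "SKO", "TSLE")

#: One-letter codes, alphabetical by three-letter code.
AA_ORDER = tuple(THREE_TO_ONE[k] for k in sorted(THREE_TO_ONE))


@dataclass
class ContactPotentialMatrix:
    """Symmetric 20x20 residue-pair energy table."""

    name: str
    values: np.ndarray           # (20, 20), indexed by AA_ORDER
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError("contact potential matrix must be 20x20")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("contact potential matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = _aa_index(pair[0])
        j = _aa_index(pair[1])
        return float(self.values[i, j])

    def unique_entries(self) -> np.ndarray:
        iu = np.triu_indices(20)
        return self.values[iu]


def _aa_index(res: str) -> int:
    """Index into AA_ORDER from a 1- or 3-letter residue code."""
    orig = res
    res = res.upper()
    if len(res) > 1:
        res = THREE_TO_ONE.get(canonical_res_name(res), res)
    if res not in AA_ORDER:
        raise KeyError(
            f"residue {orig!r} is not one of the 20 canonical types"
        )
    return AA_ORDER.index(res)


def load_matrix(name: str, path: str | Path | None = None) -> ContactPotentialMatrix:
    """Load a raw (unnormalized) matrix by slot name, or from ``path``.

    The file format is a residue-order header line of 20 one-letter codes
    followed by 20 whitespace-separated rows; ``#`` lines are comments.
    """
    if name not in MATRIX_NAMES:
        raise KeyError(
            f"unknown contact potential {name!r}; valid names: "
            + ", ".join(MATRIX_NAMES)
        )
    if path is None:
        ref = resources.files("sarahmd.data").joinpath(
            f"contact_potential_{name}_synthetic.dat"
        )
        with resources.as_file(ref) as p:
            return _read_matrix_file(name, p)
    return _read_matrix_file(name, Path(path))


def _read_matrix_file(name: str, path: Path) -> ContactPotentialMatrix:
    rows: list[list[float]] = []
    order: list[str] | None = None
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if order is None:
                order = [p.upper() for p in parts]
                continue
            rows.append([float(x) for x in parts])
    if order is None or len(order) != 20 or len(rows) != 20:
        raise ValueError(f"{path}: expected a 20-code header and 20 rows")
    m = np.array(rows)
    # reorder into AA_ORDER if the file uses a different residue order
    perm = [order.index(a) for a in AA_ORDER]
    m = m[np.ix_(perm, perm)]
    return ContactPotentialMatrix(name=name, values=m, normalized=False)


def normalize_matrix(m: ContactPotentialMatrix) -> ContactPotentialMatrix:
    """Z-score over the 210 unique upper-triangle entries."""
    if m.normalized:
        return m
    entries = m.unique_entries()
    mu = entries.mean()
    sd = entries.std()
    if sd < 1e-12:
        raise ValueError(f"matrix {m.name}: zero variance, cannot normalize")
    return ContactPotentialMatrix(
        name=m.name, values=(m.values - mu) / sd, normalized=True
    )


@dataclass
class InterfaceScore:
    """Summed normalized pair energies over the interface contact set."""

    label: str
    matrix: str
    cutoff: float
    score: float
    n_contacts: int


def interface_score(
    s: Structure,
    pair: ProtomerPair,
    m: ContactPotentialMatrix,
    cutoff: float = 5.5,
    label: str = "",
) -> InterfaceScore:
    """Score = sum of m[res_i, res_j] over the interface contact map.

    Invariant to protomer order; lower (more negative) scores indicate a
    more favorable interface under the given potential.
    """
    if not m.normalized:
        raise ValueError("interface_score requires a normalized matrix")
    contacts = contact_map(s, pair, cutoff)
    # summed in sorted order so the result is exactly invariant to the
    # protomer labelling and set iteration order
    terms = sorted(m[rna, rnb] for (_, _, rna), (_, _, rnb) in contacts)
    score = float(sum(terms))
    return InterfaceScore(
        label=label or f"{pair.chain_a}-{pair.chain_b}",
        matrix=m.name,
        cutoff=cutoff,
        score=score,
        n_contacts=len(contacts),
    )


FRAME_RULES = ("before_md", "min_rmsd_to_average", "max_rmsd_to_average")


def select_frame(traj: Trajectory, frame_rule: str) -> Structure:
    """Representative structure of a trajectory.

    ``before_md`` is frame 0; ``min_rmsd_to_average`` /
    ``max_rmsd_to_average`` pick the frame with the smallest / largest Cα
    RMSD to the iteratively aligned average structure.
    """
    if frame_rule == "before_md":
        return traj.frame(0)
    if frame_rule not in FRAME_RULES:
        raise ValueError(f"unknown frame rule {frame_rule!r}; use {FRAME_RULES}")
    avg = geometry.average_structure(traj)
    series = geometry.rmsd_series(traj, avg)
    idx = int(np.argmin(series) if frame_rule == "min_rmsd_to_average"
              else np.argmax(series))
    return traj.frame(idx)


def compare_dimers(
    structures: dict[str, Structure | Trajectory],
    pairs: dict[str, ProtomerPair],
    matrices: list[str] | None = None,
    cutoffs: tuple[float, ...] = (5.0, 5.5, 6.0),
    frame_rule: str = "before_md",
) -> pd.DataFrame:
    """Full cross-product score table over dimers x matrices x cutoffs,
    with a per-matrix/cutoff rank order of the dimers (rank 1 = lowest,
    i.e. most favorable, score)."""
    matrices = list(matrices or MATRIX_NAMES)
    loaded = {nm: normalize_matrix(load_matrix(nm)) for nm in matrices}
    rows = []
    for label, obj in structures.items():
        s = select_frame(obj, frame_rule) if isinstance(obj, Trajectory) else obj
        for nm in matrices:
            for cut in cutoffs:
                sc = interface_score(s, pairs[label], loaded[nm], cut, label)
                rows.append(
                    {
                        "dimer": label,
                        "matrix": nm,
                        "cutoff": cut,
                        "score": sc.score,
                        "n_contacts": sc.n_contacts,
                        "frame_rule": frame_rule,
                    }
                )
    df = pd.DataFrame(rows)
    df["rank"] = df.groupby(["matrix", "cutoff"])["score"].rank(method="min")
    df["rank"] = df["rank"].astype(int)
    return df
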