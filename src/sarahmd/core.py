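"""Domain types and readers/writers for structures, trajectories and
nonbonded parameter tables.

A :class:`Structure` is an ordered atom table backed by parallel numpy
arrays (column-of-arrays layout, as in biotite's ``AtomArray``), with
residue numbering preserved verbatim from the source PDB record (author
numbering, as printed).  A :class:`Trajectory` couples one topology with a
``(n_frames, n_atoms, 3)`` coordinate array; multi-model PDB files
(MODEL/ENDMDL blocks) are the on-disk trajectory container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bio_pdb


class PDBParseError(ValueError):
    """Raised when a PDB/XYZ file violates the supported subset."""


class ParameterCoverageError(KeyError):
    """Raised when a nonbonded parameter table does not cover an atom."""


#: Backbone atom names excluded from side-chain selections.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Canonical 3-letter -> 1-letter residue codes (20 standard amino acids).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
# Protonated histidine variants map onto HIS for sequence purposes.
_RES_ALIASES = {"HSP": "HIS", "HIP": "HIS", "HSD": "HIS", "HSE": "HIS"}


def canonical_res_name(res_name: str) -> str:
    """Map force-field histidine variants (HSP/HSD/...) onto HIS."""
    return _RES_ALIASES.get(res_name, res_name)


@dataclass(frozen=True)
class Atom:
    """One atom row: identity, coordinates (Å) and optional parameters."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: np.ndarray
    charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.vdw_radius is not None and not self.vdw_radius > 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be > 0")


class Structure:
    """An ordered collection of atoms with unique (chain, res_seq, name) keys."""

    def __init__(self, atoms: Sequence[Atom], title: str = ""):
        if len(atoms) == 0:
            raise ValueError("Structure requires at least one atom")
        self.title = title
        self.serial = np.array([a.serial for a in atoms], dtype=int)
        self.name = np.array([a.name for a in atoms], dtype=object)
        self.element = np.array([a.element for a in atoms], dtype=object)
        self.res_name = np.array([a.res_name for a in atoms], dtype=object)
        self.res_seq = np.array([a.res_seq for a in atoms], dtype=int)
        self.chain_id = np.array([a.chain_id for a in atoms], dtype=object)
        self.coords = np.array([a.coords for a in atoms], dtype=float)
        self.charge = np.array(
            [np.nan if a.charge is None else a.charge for a in atoms], dtype=float
        )
        self.lj_epsilon = np.array(
            [np.nan if a.lj_epsilon is None else a.lj_epsilon for a in atoms],
            dtype=float,
        )
        self.lj_rmin_half = np.array(
            [np.nan if a.lj_rmin_half is None else a.lj_rmin_half for a in atoms],
            dtype=float,
        )
        self.vdw_radius = np.array(
            [np.nan if a.vdw_radius is None else a.vdw_radius for a in atoms],
            dtype=float,
        )
        keys = set()
        for a in atoms:
            key = (a.chain_id, a.res_seq, a.name)
            if key in keys:
                raise ValueError(f"duplicate atom key {key}")
            keys.add(key)
        self._index = {
            (c, r, n): i
            for i, (c, r, n) in enumerate(zip(self.chain_id, self.res_seq, self.name))
        }

    # -- container protocol -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def __len__(self) -> int:
        return self.n_atoms

    def __getitem__(self, i: int) -> Atom:
        def opt(x: float) -> float | None:
            return None if np.isnan(x) else float(x)

        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            res_name=str(self.res_name[i]),
            res_seq=int(self.res_seq[i]),
            chain_id=str(self.chain_id[i]),
            coords=self.coords[i].copy(),
            charge=opt(self.charge[i]),
            lj_epsilon=opt(self.lj_epsilon[i]),
            lj_rmin_half=opt(self.lj_rmin_half[i]),
            vdw_radius=opt(self.vdw_radius[i]),
        )

    @property
    def atoms(self) -> Iterator[Atom]:
        return (self[i] for i in range(self.n_atoms))

    # -- queries ------------------------------------------------------------
    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        try:
            return self._index[(chain_id, res_seq, name)]
        except KeyError:
            raise KeyError(
                f"no atom (chain {chain_id!r}, residue {res_seq}, name {name!r})"
            ) from None

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_id == chain_id

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_seq, res_name) triples."""
        out: dict[tuple[str, int], str] = {}
        for c, r, rn in zip(self.chain_id, self.res_seq, self.res_name):
            if chain_id is None or c == chain_id:
                out.setdefault((str(c), int(r)), str(rn))
        return [(c, r, rn) for (c, r), rn in out.items()]

    def subset(self, mask: np.ndarray, title: str | None = None) -> "Structure":
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError("selection is empty")
        return Structure(
            [self[int(i)] for i in idx],
            title=self.title if title is None else title,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        new = Structure.__new__(Structure)
        new.__dict__.update(self.__dict__)
        new.coords = coords.copy()
        return new


class Trajectory:
    """One topology plus an ordered stack of coordinate frames (Å)."""

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray | Sequence[np.ndarray],
        frame_spacing: float | None = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a nonempty (n_frames, n_atoms, 3) array")
        if frames.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(
                f"every frame must have shape ({topology.n_atoms}, 3); "
                f"got {frames.shape[1:]}"
            )
        self.topology = topology
        self.frames = frames
        self.frame_spacing = frame_spacing

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class ProtomerPair:
    """The two chains forming a dimer."""

    chain_a: str
    chain_b: str

    def __post_init__(self) -> None:
        if self.chain_a == self.chain_b:
            raise ValueError("protomer chains must differ")

    def validate(self, s: Structure) -> None:
        chains = set(s.chains)
        for c in (self.chain_a, self.chain_b):
            if c not in chains:
                raise ValueError(f"chain {c!r} not present in structure")


# ---------------------------------------------------------------------------
# PDB reading/writing (biotite-backed, MODEL/ENDMDL as the frame container)
# ---------------------------------------------------------------------------

def _scan_models(path: Path) -> list[int]:
    """Per-model ATOM/HETATM record counts; validates coordinate fields."""
    counts: list[int] = []
    current = 0
    in_model = False
    any_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                any_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: unreadable coordinate field at line {lineno}"
                    ) from None
                current += 1
    if any_model:
        if in_model:  # MODEL without ENDMDL
            counts.append(current)
    else:
        counts = [current]
    if not counts or counts[0] == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise PDBParseError(
                f"{path}: model {i} has {c} atoms, expected {counts[0]} (model 1)"
            )
    return counts


def _atom_array_to_structure(arr: bst.AtomArray, title: str = "") -> Structure:
    atoms = []
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    for i in range(arr.array_length()):
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).upper(),
                res_name=str(arr.res_name[i]),
                res_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                coords=np.asarray(arr.coord[i], dtype=float),
            )
        )
    return Structure(atoms, title=title)


def read_pdb(path: str | Path) -> Structure | Trajectory:
    """Read a (multi-)model PDB file.

    A single-model file yields a :class:`Structure`; a multi-model file
    yields a :class:`Trajectory` whose topology is model 1.  All models
    must list identical atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    counts = _scan_models(path)
    pdb_file = bio_pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    first = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    topo = _atom_array_to_structure(first, title=path.stem)
    if n_models == 1:
        return topo
    try:
        stack = pdb_file.get_structure(extra_fields=["atom_id"])
    except Exception as exc:  # pragma: no cover - guarded by _scan_models
        raise PDBParseError(f"{path}: inconsistent models ({exc})") from exc
    return Trajectory(topo, np.asarray(stack.coord, dtype=float))


def _structure_to_atom_array(s: Structure) -> bst.AtomArray:
    n = s.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_seq
    arr.res_name = s.res_name.astype("U5")
    arr.atom_name = s.name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", s.serial)
    return arr


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL blocks)."""
    topo = obj.topology if isinstance(obj, Trajectory) else obj
    for nm in topo.name:
        if len(str(nm)) > 4:
            raise ValueError(f"atom name {nm!r} exceeds the 4-character PDB field")
    arr = _structure_to_atom_array(topo)
    if isinstance(obj, Trajectory):
        stack = bst.stack([arr] * obj.n_frames)
        stack.coord = obj.frames.astype(np.float32)
        out = stack
    else:
        out = arr
    pdb_file = bio_pdb.PDBFile()
    pdb_file.set_structure(out)
    pdb_file.write(str(path))


def read_xyz_trajectory(path: str | Path, topology: Structure) -> Trajectory:
    """Read a plain-text XYZ trajectory and attach it to ``topology``.

    Dialect: repeated blocks of ``n_atoms`` / comment line / ``n_atoms``
    lines of ``label x y z``.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_idx += 1
        try:
            n = int(lines[pos].split()[0])
        except ValueError:
            raise PDBParseError(
                f"{path}: frame {frame_idx}: expected atom count, got "
                f"{lines[pos]!r}"
            ) from None
        if n != topology.n_atoms:
            raise PDBParseError(
                f"{path}: frame {frame_idx} declares {n} atoms, topology has "
                f"{topology.n_atoms}"
            )
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise PDBParseError(f"{path}: frame {frame_idx} is truncated")
        coords = np.empty((n, 3))
        for i, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise PDBParseError(
                    f"{path}: frame {frame_idx}: malformed atom line {ln!r}"
                )
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise PDBParseError(f"{path}: no frames")
    return Trajectory(topology, np.stack(frames))


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.frames[f, i]
                fh.write(f"{traj.topology.element[i]:<2s} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def side_chain_atoms(s: Structure, chain_id: str, res_seq: int) -> list[Atom]:
    """Heavy side-chain atoms of one residue.

    Backbone atoms (N, CA, C, O, OXT) and hydrogens are excluded; glycine,
    which has no heavy side chain, is represented by its CA atom so that
    every residue has a side-chain proxy for contact definitions.
    """
    mask = (s.chain_id == chain_id) & (s.res_seq == res_seq)
    if not mask.any():
        raise KeyError(f"no residue {res_seq} in chain {chain_id!r}")
    res_name = canonical_res_name(str(s.res_name[np.flatnonzero(mask)[0]]))
    out = []
    for i in np.flatnonzero(mask):
        if s.element[i] == "H":
            continue
        if res_name == "GLY":
            if s.name[i] == "CA":
                out.append(s[int(i)])
        elif s.name[i] not in BACKBONE_NAMES:
            out.append(s[int(i)])
    return out


def side_chain_mask(s: Structure) -> np.ndarray:
    """Vectorized side-chain-heavy-atom mask (glycine -> CA proxy)."""
    is_h = np.array([e == "H" for e in s.element])
    is_gly = np.array([canonical_res_name(str(r)) == "GLY" for r in s.res_name])
    is_bb = np.array([n in BACKBONE_NAMES for n in s.name])
    is_ca = np.array([n == "CA" for n in s.name])
    return ~is_h & np.where(is_gly, is_ca, ~is_bb)


# ---------------------------------------------------------------------------
# Nonbonded parameter tables
# ---------------------------------------------------------------------------

class NonbondedParams:
    """(res_name, atom_name) -> (charge e, LJ epsilon kcal/mol, Rmin/2 Å).

    The packaged default table uses simplified per-atom charges (integer
    formal charges spread over the terminal side-chain heavy atoms of
    Asp/Glu/Lys/Arg and protonated His, zero elsewhere) and generic LJ
    parameters per element.  A full force-field table in the same
    whitespace-separated format (columns: res_name atom_name charge
    epsilon rmin_half; res_name ``ANY`` matches every residue) may be
    supplied instead.
    """

    def __init__(self, table: dict[tuple[str, str], tuple[float, float, float]]):
        for (rn, an), (q, eps, rmh) in table.items():
            if eps < 0:
                raise ValueError(f"negative LJ epsilon for ({rn}, {an})")
        self.table = dict(table)

    @classmethod
    def from_file(cls, path: str | Path) -> "NonbondedParams":
        table: dict[tuple[str, str], tuple[float, float, float]] = {}
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith("#"):
                    continue
                rn, an, q, eps, rmh = ln.split()[:5]
                table[(rn, an)] = (float(q), float(eps), float(rmh))
        return cls(table)

    @classmethod
    def default(cls) -> "NonbondedParams":
        ref = resources.files("sarahmd.data").joinpath("nonbonded_params.dat")
        with resources.as_file(ref) as p:
            return cls.from_file(p)

    def lookup(self, res_name: str, atom_name: str) -> tuple[float, float, float]:
        rn = canonical_res_name(res_name)
        for key in ((res_name, atom_name), (rn, atom_name), ("ANY", atom_name)):
            if key in self.table:
                return self.table[key]
        raise ParameterCoverageError(
            f"no nonbonded parameters for residue {res_name!r}, atom {atom_name!r}"
        )

    def assign(self, s: Structure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-atom (charge, epsilon, rmin_half) arrays; errors on any gap."""
        n = s.n_atoms
        q = np.empty(n)
        eps = np.empty(n)
        rmh = np.empty(n)
        missing = []
        for i in range(n):
            try:
                q[i], eps[i], rmh[i] = self.lookup(str(s.res_name[i]), str(s.name[i]))
            except ParameterCoverageError:
                missing.append((str(s.res_name[i]), str(s.name[i])))
        if missing:
            raise ParameterCoverageError(
                "parameter table does not cover: "
                + ", ".join(f"({rn}, {an})" for rn, an in sorted(set(missing)))
            )
        return q, eps, rmh
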