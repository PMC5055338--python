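"""Residue-residue contacts across a dimer interface, salt-bridge formation
probabilities, hydrogen-bond occupancies and Ile-Leu packing pairs.

Conventions
-----------
* A residue-residue contact exists when the minimum distance between the
  two residues' side-chain heavy atoms is <= the cutoff (boundary
  inclusive).  Glycine is represented by its CA atom.
* A salt bridge is any basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2;
  protonated His ND1/NE2) within the cutoff (default 4.0 Å, the standard
  Barlow-Thornton-style criterion) of an acidic side-chain oxygen
  (Asp OD1/OD2; Glu OE1/OE2).  Plain HIS is not treated as basic; only the
  explicitly protonated variants HSP/HIP are.
* Formation probabilities are exact frame counts over the frames retained
  after burn-in removal (default: first 10% of frames discarded).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from sarahmd.core import (
    ProtomerPair,
    Structure,
    Trajectory,
    canonical_res_name,
    side_chain_mask,
)

ResidueId = tuple[str, int, str]  # (chain_id, res_seq, res_name)

BASIC_SITE_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HSP": ("ND1", "NE2"),
    "HIP": ("ND1", "NE2"),
}
ACIDIC_SITE_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class ContactTimeSeries:
    """Formed/broken indicator per frame for one residue pair."""

    residue_a: ResidueId
    residue_b: ResidueId
    formed: np.ndarray  # boolean, one per retained frame
    n_frames_used: int

    @property
    def p_formed(self) -> float:
        return float(np.count_nonzero(self.formed)) / self.n_frames_used

    @property
    def n_formed(self) -> int:
        return int(np.count_nonzero(self.formed))


@dataclass
class HBondRecord:
    """One interface hydrogen bond with its trajectory occupancy."""

    donor: tuple[str, int, str, str]     # (chain, res_seq, res_name, atom)
    acceptor: tuple[str, int, str, str]
    occupancy: float
    n_frames_used: int
    donor_chain: str                     # which protomer donates
    hydrogen: str | None = None          # None => ideal-geometry placeholder
    heavy_atom_only: bool = False        # distance-only fallback was used


def burn_in_slice(n_frames: int, burn_in: float) -> slice:
    """Frames retained after discarding the leading ``burn_in`` fraction."""
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be in [0, 1)")
    start = int(np.floor(burn_in * n_frames))
    if start >= n_frames:
        raise ValueError("burn-in removes every frame")
    return slice(start, n_frames)


def _residue_side_chain_indices(
    s: Structure, chain: str
) -> list[tuple[ResidueId, np.ndarray]]:
    sc = side_chain_mask(s)
    out: dict[tuple[str, int], list[int]] = {}
    names: dict[tuple[str, int], str] = {}
    for i in np.flatnonzero(sc & (s.chain_id == chain)):
        key = (chain, int(s.res_seq[i]))
        out.setdefault(key, []).append(int(i))
        names[key] = str(s.res_name[i])
    return [
        ((c, r, names[(c, r)]), np.array(idx, dtype=int))
        for (c, r), idx in out.items()
    ]


def contact_map(
    s: Structure, pair: ProtomerPair, cutoff: float = 5.5
) -> set[tuple[ResidueId, ResidueId]]:
    """All inter-protomer residue pairs whose minimum side-chain
    heavy-atom distance is <= ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pair.validate(s)
    res_a = _residue_side_chain_indices(s, pair.chain_a)
    res_b = _residue_side_chain_indices(s, pair.chain_b)
    if not res_a or not res_b:
        raise ValueError("a protomer has no side-chain atoms")
    contacts = set()
    for (rid_a, ia), (rid_b, ib) in product(res_a, res_b):
        d = np.linalg.norm(
            s.coords[ia][:, None, :] - s.coords[ib][None, :, :], axis=-1
        )
        if d.min() <= cutoff:
            contacts.add((rid_a, rid_b))
    return contacts


def contact_time_series(
    traj: Trajectory,
    pair: ProtomerPair,
    cutoff: float = 5.5,
    burn_in: float = 0.0,
    restrict_res_names: set[str] | None = None,
) -> list[ContactTimeSeries]:
    """Per-frame formed/broken indicators for every residue pair that is in
    contact in at least one retained frame."""
    topo = traj.topology
    pair.validate(topo)
    sl = burn_in_slice(traj.n_frames, burn_in)
    frames = traj.frames[sl]
    res_a = _residue_side_chain_indices(topo, pair.chain_a)
    res_b = _residue_side_chain_indices(topo, pair.chain_b)
    if restrict_res_names is not None:
        res_a = [
            (rid, ia) for rid, ia in res_a
            if canonical_res_name(rid[2]) in restrict_res_names
        ]
        res_b = [
            (rid, ib) for rid, ib in res_b
            if canonical_res_name(rid[2]) in restrict_res_names
        ]
    out = []
    for (rid_a, ia), (rid_b, ib) in product(res_a, res_b):
        d = np.linalg.norm(
            frames[:, ia, None, :] - frames[:, None, ib, :], axis=-1
        )
        formed = d.min(axis=(1, 2)) <= cutoff
        if formed.any():
            out.append(
                ContactTimeSeries(
                    residue_a=rid_a,
                    residue_b=rid_b,
                    formed=formed,
                    n_frames_used=len(frames),
                )
            )
    return out


def salt_bridges(
    traj: Trajectory,
    pair: ProtomerPair,
    cutoff: float = 4.0,
    burn_in: float = 0.10,
) -> list[ContactTimeSeries]:
    """Salt-bridge time series between the two protomers.

    A frame counts as formed iff any basic-N to acidic-O distance of the
    residue pair is <= ``cutoff``.  All candidate pairs (basic on either
    protomer, acid on the other) that form in at least one retained frame
    are reported, sorted by decreasing formation probability.
    """
    topo = traj.topology
    pair.validate(topo)
    sl = burn_in_slice(traj.n_frames, burn_in)
    frames = traj.frames[sl]

    def site_atoms(chain: str, table: dict) -> list[tuple[ResidueId, np.ndarray]]:
        out: dict[tuple[str, int], list[int]] = {}
        names: dict[tuple[str, int], str] = {}
        for i in np.flatnonzero(topo.chain_id == chain):
            rn = str(topo.res_name[i])
            if rn in table and topo.name[i] in table[rn]:
                key = (chain, int(topo.res_seq[i]))
                out.setdefault(key, []).append(int(i))
                names[key] = rn
        return [
            ((c, r, names[(c, r)]), np.array(idx, dtype=int))
            for (c, r), idx in out.items()
        ]

    candidates = []
    for ch_basic, ch_acid in (
        (pair.chain_a, pair.chain_b),
        (pair.chain_b, pair.chain_a),
    ):
        basics = site_atoms(ch_basic, BASIC_SITE_ATOMS)
        acids = site_atoms(ch_acid, ACIDIC_SITE_ATOMS)
        candidates.extend(product(basics, acids))

    out = []
    for (rid_n, idx_n), (rid_o, idx_o) in candidates:
        d = np.linalg.norm(
            frames[:, idx_n, None, :] - frames[:, None, idx_o, :], axis=-1
        )
        formed = d.min(axis=(1, 2)) <= cutoff
        if formed.any():
            out.append(
                ContactTimeSeries(
                    residue_a=rid_n,
                    residue_b=rid_o,
                    formed=formed,
                    n_frames_used=len(frames),
                )
            )
    out.sort(key=lambda c: (-c.p_formed, c.residue_a[:2], c.residue_b[:2]))
    return out


# -- hydrogen bonds ---------------------------------------------------------

# Side-chain donor heavy atoms that chemically bear hydrogens, and acceptor
# heavy atoms, per residue.  Backbone N donates and backbone O/OXT accepts
# for every residue (except proline's N).
_SC_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("NE2",),
    "HSP": ("ND1", "NE2"),
    "HIP": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
}
_SC_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}
_COVALENT_CUT = 1.8  # Å, heavy-atom bond detection for ideal-H placement


def _donor_indices(s: Structure, chain: str) -> list[int]:
    out = []
    for i in np.flatnonzero(s.chain_id == chain):
        rn = str(s.res_name[i])
        nm = str(s.name[i])
        if nm == "N" and canonical_res_name(rn) != "PRO":
            out.append(int(i))
        elif rn in _SC_DONORS and nm in _SC_DONORS[rn]:
            out.append(int(i))
        elif canonical_res_name(rn) in _SC_DONORS and nm in _SC_DONORS[
            canonical_res_name(rn)
        ]:
            out.append(int(i))
    return sorted(set(out))


def _acceptor_indices(s: Structure, chain: str) -> list[int]:
    out = []
    for i in np.flatnonzero(s.chain_id == chain):
        rn = canonical_res_name(str(s.res_name[i]))
        nm = str(s.name[i])
        if nm in ("O", "OXT"):
            out.append(int(i))
        elif rn in _SC_ACCEPTORS and nm in _SC_ACCEPTORS[rn]:
            out.append(int(i))
    return sorted(set(out))


def _attached_hydrogens(s: Structure, donor_idx: int) -> list[int]:
    same_res = (
        (s.chain_id == s.chain_id[donor_idx])
        & (s.res_seq == s.res_seq[donor_idx])
    )
    out = []
    for i in np.flatnonzero(same_res):
        if s.element[i] == "H":
            if np.linalg.norm(s.coords[i] - s.coords[donor_idx]) <= 1.25:
                out.append(int(i))
    return out


def hydrogen_bonds(
    traj: Trajectory,
    pair: ProtomerPair,
    d_cut: float = 3.0,
    angle_cut: float = 20.0,
    burn_in: float = 0.10,
    heavy_atom_only: bool = False,
    heavy_d_cut: float = 3.5,
) -> list[HBondRecord]:
    """Interface hydrogen bonds with occupancies.

    A donor-H-acceptor triple counts in a frame iff the donor-acceptor
    distance is <= ``d_cut`` and the D-H-A deviation from linearity is
    <= ``angle_cut`` degrees (the VMD default criterion).  Hydrogens are
    taken from the structure when present, otherwise reconstructed at
    ideal geometry (1.0 Å from the donor along its antibonding direction,
    recomputed per frame).  With ``heavy_atom_only=True`` a distance-only
    criterion (<= ``heavy_d_cut``) is applied and flagged in the records.

    Records are partitioned by donating protomer via ``donor_chain``.
    """
    topo = traj.topology
    pair.validate(topo)
    sl = burn_in_slice(traj.n_frames, burn_in)
    frames = traj.frames[sl]
    n_used = len(frames)
    records: list[HBondRecord] = []

    for ch_d, ch_a in (
        (pair.chain_a, pair.chain_b),
        (pair.chain_b, pair.chain_a),
    ):
        donors = _donor_indices(topo, ch_d)
        acceptors = _acceptor_indices(topo, ch_a)
        if not donors or not acceptors:
            continue
        acc_idx = np.array(acceptors, dtype=int)
        for di in donors:
            hydrogens = _attached_hydrogens(topo, di)
            d_xyz = frames[:, di, :]                      # (F, 3)
            a_xyz = frames[:, acc_idx, :]                 # (F, A, 3)
            da = np.linalg.norm(a_xyz - d_xyz[:, None, :], axis=-1)
            if heavy_atom_only:
                formed_all = da <= heavy_d_cut            # (F, A)
                h_name = None
            else:
                if hydrogens:
                    h_pos = frames[:, hydrogens, :]       # (F, H, 3)
                    h_name = str(topo.name[hydrogens[0]])
                else:
                    h_pos = _ideal_h_positions(topo, di, frames)
                    h_name = None
                    if h_pos is None:
                        continue
                formed_all = _hbond_criterion(
                    d_xyz, h_pos, a_xyz, da, d_cut, angle_cut
                )
            for k, ai in enumerate(acc_idx):
                occ = float(np.count_nonzero(formed_all[:, k])) / n_used
                if occ > 0:
                    records.append(
                        HBondRecord(
                            donor=(
                                ch_d,
                                int(topo.res_seq[di]),
                                str(topo.res_name[di]),
                                str(topo.name[di]),
                            ),
                            acceptor=(
                                ch_a,
                                int(topo.res_seq[ai]),
                                str(topo.res_name[ai]),
                                str(topo.name[ai]),
                            ),
                            occupancy=occ,
                            n_frames_used=n_used,
                            donor_chain=ch_d,
                            hydrogen=h_name,
                            heavy_atom_only=heavy_atom_only,
                        )
                    )
    records.sort(key=lambda r: (-r.occupancy, r.donor[:2], r.acceptor[:2]))
    return records


def _ideal_h_positions(
    topo: Structure, donor_idx: int, frames: np.ndarray
) -> np.ndarray | None:
    """Per-frame ideal-geometry H position for a donor, shape (F, 1, 3)."""
    ci, ri = topo.chain_id[donor_idx], topo.res_seq[donor_idx]
    near = (
        (topo.chain_id == ci)
        & (np.abs(topo.res_seq - ri) <= 1)
        & (topo.element != "H")
    )
    d0 = np.linalg.norm(
        topo.coords[near] - topo.coords[donor_idx], axis=1
    )
    nbr_idx = np.flatnonzero(near)[(d0 > 1e-6) & (d0 <= _COVALENT_CUT)]
    if len(nbr_idx) == 0:
        return None
    dxyz = frames[:, donor_idx, :]                       # (F, 3)
    u = dxyz[:, None, :] - frames[:, nbr_idx, :]         # (F, B, 3)
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    v = u.sum(axis=1)                                    # (F, 3)
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norms < 1e-8):
        return None
    return (dxyz + v / norms)[:, None, :]


def _hbond_criterion(
    d_xyz: np.ndarray,
    h_pos: np.ndarray,
    a_xyz: np.ndarray,
    da: np.ndarray,
    d_cut: float,
    angle_cut: float,
) -> np.ndarray:
    """Boolean (F, A): distance and D-H-A linearity criterion, taking the
    best hydrogen when several are attached."""
    hd = d_xyz[:, None, :] - h_pos                       # (F, H, 3)
    ha = a_xyz[:, None, :, :] - h_pos[:, :, None, :]     # (F, H, A, 3)
    hd_u = hd / np.linalg.norm(hd, axis=-1, keepdims=True)
    ha_u = ha / np.linalg.norm(ha, axis=-1, keepdims=True)
    # angle at H between D and A; 180 deg = linear
    cosang = np.einsum("fhx,fhax->fha", hd_u, ha_u)
    dha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    deviation = (180.0 - dha).min(axis=1)                # (F, A), best H
    return (da <= d_cut) & (deviation <= angle_cut)


def ile_leu_pairs(
    obj: Structure | Trajectory,
    pair: ProtomerPair,
    cutoff: float = 5.5,
    burn_in: float = 0.0,
):
    """Hydrophobic Ile-Leu packing pairs across the interface.

    For a Structure, the restriction of :func:`contact_map` to pairs where
    both partners are ILE or LEU; for a Trajectory, the corresponding
    :class:`ContactTimeSeries` list.
    """
    hydrophobic = {"ILE", "LEU"}
    if isinstance(obj, Trajectory):
        return contact_time_series(
            obj, pair, cutoff=cutoff, burn_in=burn_in,
            restrict_res_names=hydrophobic,
        )
    return {
        (ra, rb)
        for ra, rb in contact_map(obj, pair, cutoff)
        if canonical_res_name(ra[2]) in hydrophobic
        and canonical_res_name(rb[2]) in hydrophobic
    }


# -- report writers ---------------------------------------------------------

def salt_bridge_table(
    bridges: list[ContactTimeSeries], bold_threshold: float = 0.10
) -> pd.DataFrame:
    """Salt-bridge report: one row per undirected pair, with the formation
    probability and a bold flag for pairs formed in more than
    ``bold_threshold`` of the trajectory."""
    rows = []
    for b in bridges:
        rows.append(
            {
                "residue_a": f"{b.residue_a[2]} {b.residue_a[1]} ({b.residue_a[0]})",
                "residue_b": f"{b.residue_b[2]} {b.residue_b[1]} ({b.residue_b[0]})",
                "p_formed": b.p_formed,
                "bold": b.p_formed > bold_threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["residue_a", "residue_b", "p_formed", "bold"]
    )


def hbond_table(
    records: list[HBondRecord],
    donor_chain_first: str,
    min_occupancy: float = 0.01,
) -> pd.DataFrame:
    """Two-section hydrogen-bond report: first the records where
    ``donor_chain_first`` donates, then those where it accepts.  Only
    records above ``min_occupancy`` are kept."""
    rows = []
    for section, keep in (
        ("donor", lambda r: r.donor_chain == donor_chain_first),
        ("acceptor", lambda r: r.donor_chain != donor_chain_first),
    ):
        for r in records:
            if keep(r) and r.occupancy > min_occupancy:
                rows.append(
                    {
                        "section": section,
                        "donor": f"{r.donor[2]} {r.donor[1]} ({r.donor[0]}:{r.donor[3]})",
                        "acceptor": (
                            f"{r.acceptor[2]} {r.acceptor[1]} "
                            f"({r.acceptor[0]}:{r.acceptor[3]})"
                        ),
                        "occupancy": r.occupancy,
                        "bold": r.occupancy > 0.10,
                        "heavy_atom_only": r.heavy_atom_only,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["section", "donor", "acceptor", "occupancy", "bold",
                 "heavy_atom_only"],
    )
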