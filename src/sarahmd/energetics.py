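"""Inter-protomer nonbonded interaction energy: pairwise electrostatics
plus Lennard-Jones, with CHARMM-form switching between r_on = 9.5 Å and
r_off = 12 Å.

The decomposition is a vacuum-style pairwise sum (dielectric 1, no
reciprocal-space term) over all inter-protomer atom pairs within the
cutoff:

    E_elec = sum C q_i q_j / r * sw(r),        C = 332.0636 kcal Å/(mol e²)
    E_vdw  = sum eps_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ] * sw(r)

with Lorentz-Berthelot-style combination eps_ij = sqrt(eps_i eps_j),
Rmin_ij = rmin_half_i + rmin_half_j, and the CHARMM switching polynomial
sw(r) = 1 for r <= r_on, [(r_off²-r²)² (r_off²+2r²-3 r_on²)] /
(r_off²-r_on²)³ on (r_on, r_off], and 0 beyond.  Absolute values depend on
the parameter table supplied; the packaged simplified table is suitable
for relative comparisons and testing, not for reproducing force-field
energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sarahmd.core import NonbondedParams, ProtomerPair, Structure, Trajectory
from sarahmd.contacts import burn_in_slice

#: Coulomb constant in kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0636


@dataclass(frozen=True)
class EnergyBreakdown:
    """Electrostatic + van der Waals interaction energy (kcal/mol)."""

    elec: float
    vdw: float

    @property
    def total(self) -> float:
        return self.elec + self.vdw


@dataclass
class EnergySummary:
    """Mean/sd, block-averaged standard error and histogram of one term."""

    term: str
    mean: float
    sd: float
    block_se: float
    n_frames_used: int
    n_blocks: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def switching_function(
    r: np.ndarray, r_on: float = 9.5, r_off: float = 12.0
) -> np.ndarray:
    """CHARMM switching polynomial: 1 below r_on, 0 beyond r_off, C1-smooth
    in between."""
    r = np.asarray(r, dtype=float)
    r2 = r * r
    on2, off2 = r_on * r_on, r_off * r_off
    sw = np.where(
        r <= r_on,
        1.0,
        np.where(
            r <= r_off,
            ((off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2)) / (off2 - on2) ** 3,
            0.0,
        ),
    )
    return sw


def pair_energy(
    s: Structure,
    pair: ProtomerPair,
    params: NonbondedParams,
    r_on: float = 9.5,
    r_off: float = 12.0,
) -> EnergyBreakdown:
    """Switched pairwise nonbonded energy between the two protomers."""
    if r_on >= r_off:
        raise ValueError("r_on must be smaller than r_off")
    pair.validate(s)
    q, eps, rmh = params.assign(s)
    ia = np.flatnonzero(s.chain_mask(pair.chain_a))
    ib = np.flatnonzero(s.chain_mask(pair.chain_b))
    return _pair_energy_arrays(
        s.coords[ia], s.coords[ib],
        q[ia], q[ib], eps[ia], eps[ib], rmh[ia], rmh[ib], r_on, r_off,
    )


def _pair_energy_arrays(
    xa, xb, qa, qb, ea, eb, ra, rb, r_on, r_off
) -> EnergyBreakdown:
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    within = d <= r_off
    if not within.any():
        return EnergyBreakdown(elec=0.0, vdw=0.0)
    r = d[within]
    sw = switching_function(r, r_on, r_off)
    qq = np.outer(qa, qb)[within]
    elec = float(np.sum(COULOMB_CONSTANT * qq / r * sw))
    eps_ij = np.sqrt(np.outer(ea, eb))[within]
    rmin_ij = (ra[:, None] + rb[None, :])[within]
    x6 = (rmin_ij / r) ** 6
    vdw = float(np.sum(eps_ij * (x6 * x6 - 2 * x6) * sw))
    return EnergyBreakdown(elec=elec, vdw=vdw)


def energy_series(
    traj: Trajectory,
    pair: ProtomerPair,
    params: NonbondedParams,
    r_on: float = 9.5,
    r_off: float = 12.0,
    burn_in: float = 0.10,
    n_blocks: int = 5,
    n_bins: int = 30,
) -> tuple[list[EnergyBreakdown], dict[str, EnergySummary]]:
    """Per-frame energies after burn-in, with block-averaged summaries.

    The standard error of each term is the standard deviation of the
    ``n_blocks`` contiguous block means divided by sqrt(n_blocks), the
    usual correction for serial correlation in MD time series.
    """
    topo = traj.topology
    pair.validate(topo)
    sl = burn_in_slice(traj.n_frames, burn_in)
    frames = traj.frames[sl]
    if len(frames) < n_blocks:
        raise ValueError(
            f"need at least n_blocks={n_blocks} frames after burn-in, "
            f"have {len(frames)}"
        )
    q, eps, rmh = params.assign(topo)
    ia = np.flatnonzero(topo.chain_mask(pair.chain_a))
    ib = np.flatnonzero(topo.chain_mask(pair.chain_b))
    per_frame = [
        _pair_energy_arrays(
            f[ia], f[ib], q[ia], q[ib], eps[ia], eps[ib], rmh[ia], rmh[ib],
            r_on, r_off,
        )
        for f in frames
    ]
    series = {
        "elec": np.array([e.elec for e in per_frame]),
        "vdw": np.array([e.vdw for e in per_frame]),
        "total": np.array([e.total for e in per_frame]),
    }
    summaries = {
        term: summarize(term, vals, n_blocks, n_bins)
        for term, vals in series.items()
    }
    return per_frame, summaries


def summarize(
    term: str, vals: np.ndarray, n_blocks: int, n_bins: int
) -> EnergySummary:
    blocks = np.array_split(vals, n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    counts, edges = np.histogram(vals, bins=n_bins)
    return EnergySummary(
        term=term,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        block_se=float(block_means.std(ddof=0) / np.sqrt(n_blocks)),
        n_frames_used=len(vals),
        n_blocks=n_blocks,
        hist_counts=counts,
        hist_edges=edges,
    )


def energy_frames_to_table(per_frame: list[EnergyBreakdown]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": np.arange(len(per_frame)),
            "elec": [e.elec for e in per_frame],
            "vdw": [e.vdw for e in per_frame],
            "total": [e.total for e in per_frame],
        }
    )


def summary_table(
    summaries: dict[str, EnergySummary], label: str = ""
) -> pd.DataFrame:
    rows = [
        {
            "dimer": label,
            "term": s.term,
            "mean": s.mean,
            "sd": s.sd,
            "block_se": s.block_se,
            "n_frames": s.n_frames_used,
        }
        for s in summaries.values()
    ]
    return pd.DataFrame(
        rows, columns=["dimer", "term", "mean", "sd", "block_se", "n_frames"]
    )
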