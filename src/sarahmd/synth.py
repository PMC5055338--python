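"""Synthetic structures and trajectories emulating the statistical
structure the analyses assume: ideal α-helical protomers with charged
interface residues, two-state (telegraph) contact dynamics with prescribed
formation probabilities, Gaussian positional jitter, and 1-D overdamped
Langevin dynamics on prescribed potentials.

All generators are pure functions of (spec, seed), using numpy's seeded
PCG64 generator; repeated calls are bit-identical.  Side chains are
minimal — CB plus charged tip atoms — which is sufficient for every
contact, salt-bridge, SASA and energy analysis without a rotamer library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sarahmd.core import Atom, ONE_TO_THREE, Structure, Trajectory

#: Ideal α-helix geometry.
HELIX_RISE = 1.5          # Å per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.3           # Å, Cα distance from the helix axis

# Charged side-chain tip atoms (the salt-bridge-forming sites).
TIP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HSP": ("ND1", "NE2"),
}
_TIP_RADIUS = 3.0         # Å beyond CB along the outward normal
_TIP_SPREAD = 0.8         # Å tangential split for two-atom tips

# Branched hydrophobic side chains get stub atoms at increasing radial
# offsets beyond CB so Ile/Leu packing contacts are representable.
HYDROPHOBIC_TIPS = {
    "ILE": (("CG1", 1.3), ("CD1", 2.6)),
    "LEU": (("CG", 1.3), ("CD1", 2.6), ("CD2", 2.6)),
    "VAL": (("CG1", 1.3), ("CG2", 1.3)),
}


@dataclass(frozen=True)
class HelixSpec:
    """An ideal α-helical protomer.

    ``residues`` maps 1-based helix positions to 3-letter codes for
    non-alanine residues (e.g. ``{5: "LYS"}``); every other position is
    alanine.  ``sequence`` (one-letter string) overrides the poly-ALA
    default entirely.
    """

    n_res: int
    chain_id: str = "A"
    residues: dict[int, str] = field(default_factory=dict)
    sequence: str | None = None
    start_res: int = 1
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST
    phase: float = 0.0     # degrees, azimuth of residue 1

    def __post_init__(self) -> None:
        if self.n_res < 4:
            raise ValueError("a helix needs at least 4 residues")
        if self.sequence is not None and len(self.sequence) != self.n_res:
            raise ValueError("sequence length must equal n_res")

    def res_name(self, i: int) -> str:
        """Residue name at 1-based helix position i."""
        if self.sequence is not None:
            return ONE_TO_THREE[self.sequence[i - 1].upper()]
        return self.residues.get(i, "ALA")


def ideal_helix(spec: HelixSpec) -> Structure:
    """Backbone (N, CA, C, O) + CB + charged tip atoms on an ideal
    α-helical trace along the z axis."""
    atoms: list[Atom] = []
    serial = 1
    for i in range(1, spec.n_res + 1):
        theta = np.radians(spec.phase + (i - 1) * spec.twist)
        z = (i - 1) * spec.rise
        outward = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        ca = CA_RADIUS * outward + np.array([0.0, 0.0, z])
        res_name = spec.res_name(i)
        res_seq = spec.start_res + i - 1

        def add(name: str, element: str, pos: np.ndarray) -> None:
            nonlocal serial
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    res_name=res_name,
                    res_seq=res_seq,
                    chain_id=spec.chain_id,
                    coords=pos,
                )
            )
            serial += 1

        # approximate backbone placement around the Cα trace
        add("N", "N", ca - 0.65 * tangent - np.array([0, 0, 0.8]))
        add("CA", "C", ca)
        add("C", "C", ca + 0.65 * tangent + np.array([0, 0, 0.75]))
        add("O", "O", ca + 0.9 * tangent + 0.9 * outward
            + np.array([0, 0, 0.75]))
        if res_name != "GLY":
            add("CB", "C", ca + 1.5 * outward)
        tips = TIP_ATOMS.get(res_name, ())
        for k, tip_name in enumerate(tips):
            offset = (k - (len(tips) - 1) / 2) * _TIP_SPREAD * tangent
            pos = ca + (1.5 + _TIP_RADIUS) * outward + offset
            add(tip_name, tip_name[0], pos)
        for k, (tip_name, extra) in enumerate(
            HYDROPHOBIC_TIPS.get(res_name, ())
        ):
            offset = (k - 1) * 0.5 * _TIP_SPREAD * tangent
            add(tip_name, "C", ca + (1.5 + extra) * outward + offset)
    return Structure(atoms, title=f"ideal helix {spec.chain_id}")


def two_helix_dimer(
    spec_a: HelixSpec,
    spec_b: HelixSpec,
    separation: float = 9.0,
    orientation: str = "antiparallel",
) -> Structure:
    """Two ideal helices with parallel axes at the given axis separation.

    Chain A runs N→C along +z with side chains facing +x; chain B faces
    chain A (side chains toward -x) and, for ``antiparallel``, has its
    N→C axis direction reversed.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if orientation not in ("parallel", "antiparallel"):
        raise ValueError("orientation must be 'parallel' or 'antiparallel'")
    if spec_a.chain_id == spec_b.chain_id:
        raise ValueError("the two protomers need distinct chain ids")
    a = ideal_helix(spec_a)
    b = ideal_helix(spec_b)
    coords = b.coords.copy()
    if orientation == "antiparallel":
        # rotate 180 deg about the y axis: x -> -x, z -> -z, then lift so
        # the span again starts at z = 0
        coords[:, 0] *= -1
        coords[:, 2] *= -1
        coords[:, 2] += (spec_b.n_res - 1) * spec_b.rise
    else:
        # rotate 180 deg about the z axis so side chains face -x while the
        # N->C direction still runs along +z
        coords[:, 0] *= -1
        coords[:, 1] *= -1
    coords[:, 0] += separation
    b = b.with_coords(coords)
    atoms = list(a.atoms) + list(b.atoms)
    # renumber serials to stay unique
    renum = [
        Atom(
            serial=i + 1,
            name=at.name,
            element=at.element,
            res_name=at.res_name,
            res_seq=at.res_seq,
            chain_id=at.chain_id,
            coords=at.coords,
        )
        for i, at in enumerate(atoms)
    ]
    return Structure(renum, title=f"{orientation} two-helix dimer")


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-state (formed/broken) dynamics for one contact pair.

    ``residue_a`` is the basic-side residue (chain_id, res_seq), whose
    first tip atom anchors the contact; ``residue_b``'s tip atoms are
    placed at ``bound_distance`` or ``unbound_distance`` from it according
    to a two-state Markov chain with stationary P(bound) = p and total
    switching rate ``switch_rate`` per frame.
    """

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    p: float
    bound_distance: float = 3.0
    unbound_distance: float = 8.0
    switch_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not self.bound_distance < self.unbound_distance:
            raise ValueError("bound distance must be below unbound distance")
        k_on = self.switch_rate * self.p
        k_off = self.switch_rate * (1 - self.p)
        if not (0 < k_on <= 1 and 0 < k_off <= 1):
            raise ValueError(
                f"stationary probability {self.p} unattainable at switching "
                f"rate {self.switch_rate}"
            )


def _tip_indices(s: Structure, chain: str, res_seq: int) -> np.ndarray:
    mask = (s.chain_id == chain) & (s.res_seq == res_seq)
    if not mask.any():
        raise KeyError(f"no residue {res_seq} in chain {chain!r}")
    res_name = str(s.res_name[np.flatnonzero(mask)[0]])
    tips = TIP_ATOMS.get(res_name)
    if not tips:
        raise ValueError(f"residue {res_name} {res_seq} has no charged tip")
    idx = [
        int(i) for i in np.flatnonzero(mask) if str(s.name[i]) in tips
    ]
    return np.array(idx, dtype=int)


def telegraph_contact_trajectory(
    base: Structure,
    specs: list[TelegraphSpec],
    n_frames: int,
    seed: int,
    jitter_sigma: float = 0.2,
) -> Trajectory:
    """Trajectory in which each specified contact's tip-atom distance
    alternates between its bound and unbound values under a two-state
    Markov chain, on top of Gaussian jitter of all remaining atoms."""
    rng = np.random.default_rng(seed)
    controlled: set[int] = set()
    plans = []
    for spec in specs:
        ia = _tip_indices(base, *spec.residue_a)
        ib = _tip_indices(base, *spec.residue_b)
        anchor = int(ia[0])
        k_on = spec.switch_rate * spec.p
        k_off = spec.switch_rate * (1 - spec.p)
        # simulate the chain from its stationary distribution
        states = np.empty(n_frames, dtype=bool)
        states[0] = rng.random() < spec.p
        u = rng.random(n_frames - 1)
        for t in range(1, n_frames):
            if states[t - 1]:
                states[t] = u[t - 1] >= k_off
            else:
                states[t] = u[t - 1] < k_on
        plans.append((spec, anchor, ib, states))
        controlled.update(int(i) for i in ib)

    frames = np.repeat(base.coords[None, :, :], n_frames, axis=0)
    if jitter_sigma > 0:
        noise = rng.normal(0.0, jitter_sigma, frames.shape)
        for i in controlled:
            noise[:, i, :] = 0.0
        frames += noise
    for spec, anchor, ib, states in plans:
        d = np.where(states, spec.bound_distance, spec.unbound_distance)
        apos = frames[:, anchor, :]
        for i in ib:
            v = base.coords[i] - base.coords[anchor]
            v = v / np.linalg.norm(v)
            frames[:, i, :] = apos + d[:, None] * v[None, :]
    return Trajectory(base, frames)


def jitter_trajectory(
    base: Structure, n_frames: int, sigma: float, seed: int
) -> Trajectory:
    """i.i.d. Gaussian displacement of every atom in every frame."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    frames = np.repeat(base.coords[None, :, :], n_frames, axis=0)
    if sigma > 0:
        frames = frames + rng.normal(0.0, sigma, frames.shape)
    return Trajectory(base, frames)


# -- canonical demo system --------------------------------------------------

#: Axis separation (Å) of the demo dimer; wide enough that the minimal
#: radial side chains meet near the midplane rather than interpenetrating.
DEMO_SEPARATION = 14.0


def demo_dimer() -> tuple[Structure, "list[TelegraphSpec]"]:
    """An engineered antiparallel two-helix dimer with a charged,
    Ile/Leu-packed interface, plus telegraph specs for its salt bridges.

    Chain A (residues 441-464) carries Lys/Arg/Asp and Ile/Leu at
    positions whose side chains face the partner; chain B (residues
    301-324, phase-shifted so its facing positions meet chain A's at the
    same height) carries the complementary Glu/Asp/Lys and Leu/Ile.  The
    three salt bridges are driven with formation probabilities 0.9, 0.45
    and 0.08, straddling the 10% reporting threshold.
    """
    n = 24
    spec_a = HelixSpec(
        n_res=n, chain_id="A", start_res=441,
        residues={5: "LYS", 12: "ARG", 15: "ASP", 8: "ILE", 19: "LEU"},
    )
    # phase -140 deg makes B's facing residues meet A's at equal height
    spec_b = HelixSpec(
        n_res=n, chain_id="B", start_res=301, phase=220.0,
        residues={20: "GLU", 13: "ASP", 10: "LYS", 17: "LEU", 6: "ILE"},
    )
    dimer = two_helix_dimer(spec_a, spec_b, DEMO_SEPARATION, "antiparallel")
    specs = [
        TelegraphSpec(("A", 445), ("B", 320), p=0.90),   # LYS5 - GLU20
        TelegraphSpec(("A", 452), ("B", 313), p=0.45),   # ARG12 - ASP13
        TelegraphSpec(("B", 310), ("A", 455), p=0.08),   # LYS10 - ASP15
    ]
    # snap each bridge to its bound-state geometry so the static structure
    # shows the same interface the telegraph dynamics samples
    coords = dimer.coords.copy()
    for spec in specs:
        anchor = int(_tip_indices(dimer, *spec.residue_a)[0])
        for i in _tip_indices(dimer, *spec.residue_b):
            v = coords[i] - coords[anchor]
            v /= np.linalg.norm(v)
            coords[i] = coords[anchor] + spec.bound_distance * v
    dimer = dimer.with_coords(coords)
    return dimer, specs


def demo_trajectory(n_frames: int = 400, seed: int = 0) -> Trajectory:
    """Telegraph-contact trajectory of the demo dimer."""
    dimer, specs = demo_dimer()
    return telegraph_contact_trajectory(dimer, specs, n_frames, seed)


# -- 1-D Langevin dynamics --------------------------------------------------

class PolynomialPotential:
    """U(x) given by polynomial coefficients (ascending powers)."""

    def __init__(self, coeffs):
        self.poly = np.polynomial.Polynomial(coeffs)
        self.dpoly = self.poly.deriv()

    def __call__(self, x):
        return self.poly(x)

    def grad(self, x):
        return self.dpoly(x)

    @classmethod
    def harmonic(cls, k: float, x0: float = 0.0) -> "PolynomialPotential":
        """U = k/2 (x - x0)^2."""
        return cls([k / 2 * x0 * x0, -k * x0, k / 2])

    @classmethod
    def double_well(cls, barrier: float, half_width: float = 1.0
                    ) -> "PolynomialPotential":
        """U = h ((x/a)^2 - 1)^2 with minima at ±a and barrier h at 0."""
        a = half_width
        return cls([barrier, 0, -2 * barrier / a**2, 0, barrier / a**4])


def langevin_1d(
    potential,
    n_steps: int,
    dt: float,
    kT: float,
    friction: float = 1.0,
    seed: int = 0,
    x0: float = 0.0,
    bound: float = 1e3,
) -> np.ndarray:
    """Overdamped Brownian dynamics
    x_{t+1} = x_t - (dt/γ) U'(x_t) + sqrt(2 kT dt / γ) ξ_t.

    ``potential`` needs a ``grad(x)`` method (see
    :class:`PolynomialPotential`).  Divergence beyond ``bound`` raises
    with a suggestion to reduce ``dt``.
    """
    if dt <= 0 or friction <= 0 or kT < 0:
        raise ValueError("dt and friction must be positive, kT non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, n_steps)
    amp = np.sqrt(2.0 * kT * dt / friction)
    x = np.empty(n_steps + 1)
    x[0] = x0
    g = potential.grad
    for t in range(n_steps):
        x[t + 1] = x[t] - (dt / friction) * g(x[t]) + amp * noise[t]
        if abs(x[t + 1]) > bound:
            raise FloatingPointError(
                f"trajectory diverged at step {t + 1}; use a smaller dt"
            )
    return x
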