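# Methods

This note documents the estimators implemented in `sarahmd`, the
parameters that matter, the synthetic-data model used to validate them,
and the numerical and design choices that were genuinely open.

## Structures and trajectories

A `Structure` is an ordered atom table (serial, name, element, residue
name/number, chain, coordinates in Å, optional charge/LJ/radius).
Residue numbering is author numbering, preserved verbatim from the PDB
record, so residues can be addressed the way structural papers name them
(e.g. R474, E316).  A `Trajectory` is one topology plus an
`(n_frames, n_atoms, 3)` coordinate stack; multi-model PDB files
(MODEL/ENDMDL) are the on-disk trajectory container, chosen as the
simplest standard format with no binary dependency.  A plain-text XYZ
dialect is accepted when a topology is supplied separately.  All models
of a multi-model file must list identical atoms; the reader names the
offending model otherwise.  No SARAH-domain length is hard-coded
anywhere: chains may have any number of residues, and analyses take the
protomer pair as an explicit `(chain_a, chain_b)` argument.

Side chains are the heavy atoms excluding N, CA, C, O and OXT; glycine,
which has none, is represented by its CA so every residue has a
side-chain proxy for contact definitions.

## Interface contacts and salt bridges

A residue–residue contact exists when the minimum side-chain heavy-atom
distance is ≤ the cutoff, boundary inclusive.  The default cutoff is
5.5 Å, with 5.0 and 6.0 Å used routinely as robustness checks; contact
sets are monotone in the cutoff by construction.

Salt bridges pair basic side-chain nitrogens (Lys NZ; Arg NE/NH1/NH2;
protonated His ND1/NE2) with acidic side-chain oxygens (Asp OD1/OD2;
Glu OE1/OE2); a frame counts as formed iff any N–O distance is ≤ 4.0 Å,
the standard Barlow–Thornton-style criterion.  The criterion is
configurable since conventions in the literature range from 3.5 to
4.5 Å.  Plain `HIS` is not treated as basic — only the explicitly
protonated variants `HSP`/`HIP` — because an unannotated histidine's
protonation state is unknown at analysis time.  Formation probabilities
P_c are exact frame counts over the frames retained after burn-in
(default: first 10% of frames discarded, matching the common practice of
dropping the equilibration segment of a production run).  Reports flag
bridges with P_c > 0.10, the conventional highlighting threshold.

## Hydrogen bonds

A donor–H–acceptor triple counts in a frame iff donor–acceptor distance
≤ 3.0 Å and the D–H–A deviation from linearity is ≤ 20°, the default
criterion of the common MD visualization tools.  Donor and acceptor
heavy atoms come from per-residue chemistry tables (backbone N donates
except proline; backbone O/OXT always accepts).  When the structure
contains hydrogens they are used (best hydrogen per donor per frame);
when it does not, a single hydrogen is reconstructed per frame at 1.0 Å
from the donor along its antibonding direction (opposite the sum of unit
vectors to its covalently bonded heavy neighbours, detected at ≤ 1.8 Å).
This ideal-geometry rule is exact for single-H donors in planar
environments and an approximation for rotatable multi-H donors (NH3+,
OH); a heavy-atom-only fallback (distance ≤ 3.5 Å, no angle) exists for
structures whose donors have no bonded neighbours at all — e.g. minimal
synthetic side chains — and is flagged per record in all outputs.
Records carry the donating protomer, so donor/acceptor report sections
are exhaustive and disjoint; occupancies below 1% are suppressed in
reports by default.

## Contact-potential interface scores

Six 20×20 matrix slots (HL, BT, MJ99, SJKG, SKO, TSLE) are scored
identically: z-score the 210 unique upper-triangle entries to mean 0 and
standard deviation 1, then sum the normalized pair energies over the
interface contact map.  Z-scoring is the one normalization that is
invariant to the affine offsets and scales that differ between published
parameterizations, which is what makes six heterogeneous potentials
comparable on one axis.  Scores are summed in sorted order, making them
exactly invariant to protomer labelling.  Multi-frame inputs are scored
per selected frame, not averaged; frame rules are `before_md` (frame 0),
`min_rmsd_to_average` and `max_rmsd_to_average`.

The packaged matrices are deterministic synthetic stand-ins, labelled as
such in filename and header.  They are generated from the additive-plus-
hydrophobicity structure that knowledge-based contact potentials share
(e_ij = a(h_i+h_j) + b·h_i·h_j + c·q_i·q_j + symmetric noise, with h the
Kyte–Doolittle hydropathy and q the formal charge), so favorable
hydrophobic–hydrophobic and opposite-charge contacts score low.  They
support every structural property of the scoring pipeline
(normalization, symmetry, rank comparisons) but are **not** the
published tables; users reproduce literature scores by supplying those
tables in the same text format (header of 20 one-letter codes, 20 rows).

## SASA and its partition

Per-atom SASA uses Shrake–Rupley spherical quadrature with a
deterministic Fibonacci point set (960 points by default; single-sphere
error < 1%, and < 0.2% at 5000 points), probe radius 1.4 Å, and Bondi
radii by element when atoms carry no explicit radius.  The
hydrophobic/hydrophilic partition is atom-level — C and S hydrophobic,
N and O (with attached hydrogens) hydrophilic — because only an
atom-level split makes SASA_H + SASA_P equal the total identically.
Buried surface area is SASA(A) + SASA(B) − SASA(AB), per frame for
trajectories.  The representative structure for single-structure surface
reports on trajectories is the frame with minimum Cα RMSD to the average
structure, the same selection convention used for contact-potential
comparisons.

## Nonbonded energetics

The inter-protomer interaction energy is a vacuum-style pairwise sum
(dielectric 1, no reciprocal-space term) over all atom pairs within
r_off: Coulomb C·q_i·q_j/r (C = 332.0636 kcal·Å/(mol·e²)) plus
CHARMM-form Lennard-Jones ε_ij[(Rmin_ij/r)¹² − 2(Rmin_ij/r)⁶] with
ε_ij = √(ε_iε_j), Rmin_ij = rmin_half_i + rmin_half_j, both multiplied
by the CHARMM switching polynomial (1 below r_on = 9.5 Å, 0 beyond
r_off = 12 Å, C¹-smooth between).  Time series drop the burn-in
fraction; the standard error of each term is the standard deviation of
5 contiguous block means divided by √5, the usual correction for serial
correlation.  Total = electrostatic + van der Waals holds to machine
precision by construction.

The packaged parameter table is deliberately simple: integer formal
charges spread over the terminal side-chain heavy atoms of
Asp/Glu/Lys/Arg/HSP, zero elsewhere, and generic per-element LJ
parameters.  Absolute energies therefore depend on the table supplied
and are meaningful for relative comparisons, not as force-field values;
a full force-field table in the same format drops in without code
changes.

## Markov-model PMF

Only the unbiased-trajectory limit of the dynamic histogram analysis
method is implemented, since the inputs are unbiased MD distance series.
The coordinate is binned uniformly (default 30 bins over the data span;
half-open convention, interior edges belong to the right bin, the top
edge to the last); lag-1 transition counts are pooled across series
without bridging them; the maximum-likelihood row-stochastic matrix is
restricted to its largest strongly connected component (largest by
contained counts); π is the left eigenvector at eigenvalue 1; and
F_i = −k_B·T·ln π_i with k_B = 0.0019872 kcal/(mol·K), min-shifted to
zero.  Bins outside the component are flagged, never interpolated, and
data with no dominant component raise an error advising more data or
fewer bins.  The default reaction coordinate is the inter-chain Cα pair
with the smallest trajectory-average distance (ties broken
lexicographically by residue numbers).  Convergence diagnostics
recompute the PMF on contiguous thirds (configurable k) of the series on
a shared grid.  Default temperature is 310 K; bin count and lag are
recorded in each profile's provenance.

Out-of-range points are clamped into the edge bins during PMF
estimation.  A consequence worth knowing: comparing a PMF against a
histogram inversion is only like-for-like on the same clamped grid, and
edge bins of a grid narrower than the data carry the clamped tail mass.

## Sequence analysis

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62, gap open 10, gap extend 0.5 by default).
When several alignments share the optimal score, the first alignment in
the aligner's deterministic enumeration order is returned, so results
are reproducible even on ties.  Percent identity divides identical
non-gap columns by the full alignment length (gap columns included);
a `shorter`-sequence denominator is available behind a flag because
aligner conventions differ, and identities quoted from different tools
should be compared within a couple of percentage points for that reason.
Similarity additionally counts columns whose residues share a Clustal
strong or weak group; the published group definitions are packaged as
data, encoding the Gonnet PAM 250 > 0.5 / ≤ 0.5 criteria.  Conservation
lines annotate aligned columns with `*` (identical), `:` (one strong
group), `.` (one weak group), or blank (including any gap).

The three peptide sequences relevant to SARAH-dimer disruption
(PEP_S, PEP_L, SCR) are stored verbatim as printed.  Two documented
oddities: PEP_S has 16 residues although it is sometimes described as a
17-mer, and SCR is not a true permutation of PEP_L (it contains an F
that PEP_L lacks) — `compare_composition` makes both visible.
Comparisons against published SARAH-domain identity values require the
real MST2/RASSF5/RASSF1A sequences (PDB 4LGD chains C and G; UniProt
Q9NS23), which are an optional external input and are not redistributed
with the package.

## Synthetic data

The generator emulates exactly the statistical structure the estimators
assume, and nothing more:

* `ideal_helix` — backbone N/CA/C/O + CB on an ideal α-helical trace
  (rise 1.5 Å/residue, twist 100°, Cα radius 2.3 Å; consecutive Cα–Cα
  3.8 ± 0.1 Å), with minimal charged tip atoms (NZ, NH1/NH2, OD1/OD2,
  OE1/OE2) and stub hydrophobic tips for Ile/Leu/Val.  No rotamers, no
  hydrogens, approximate backbone geometry: fixtures test estimators,
  not chemistry.
* `two_helix_dimer` — parallel or antiparallel axes at a given
  separation, built from proper rotations only so helix handedness is
  preserved.
* `telegraph_contact_trajectory` — each specified contact's tip distance
  alternates between exact bound/unbound values under a two-state Markov
  chain with stationary P(bound) = p and total switching rate s per
  frame (k_on = s·p, k_off = s·(1−p)); all other atoms receive i.i.d.
  Gaussian jitter (σ = 0.2 Å).  The lag-1 autocorrelation of the chain
  is 1 − s, so recovery tests use the autocorrelation-adjusted binomial
  envelope n_eff = n·(1−ρ)/(1+ρ).
* `langevin_1d` — overdamped Euler–Maruyama dynamics
  x ← x − (dt/γ)U′(x) + √(2kT·dt/γ)·ξ on polynomial potentials, with a
  divergence guard that suggests a smaller dt.  The harmonic and
  double-well factories give closed-form ground truths (variance kT/k;
  barrier height and well populations by Boltzmann quadrature).
* `jitter_trajectory` — i.i.d. Gaussian displacement per atom per frame
  (per-residue RMSF → σ√3).

All generators are pure functions of (spec, seed) using numpy's PCG64;
repeated calls are bit-identical.  The demo system (`demo_dimer`)
couples an antiparallel 24-residue dimer with three driven salt bridges
at p = 0.90/0.45/0.08 — straddling the 10% reporting threshold — plus
two facing Ile–Leu pairs, and snaps the bridge tips to bound geometry in
the static structure so structure- and trajectory-level analyses see the
same interface.  What passing on synthetic data does **not** show:
correctness of absolute SASA or energy magnitudes for real proteins
(those depend on full side chains and parameter sets), hydrogen-bond
chemistry beyond the geometric criterion, or PMFs of coordinates with
memory longer than the lag.

## Numerical choices

* Superposition solves the constrained orthogonal Procrustes problem
  (proper rotations only), so mirror solutions cannot occur; RMSD is
  over the matched selection after superposition.
* The average structure is seeded with the raw arithmetic mean of the
  frames and iterated (align all frames to the mean, recompute, until
  the mean shifts < 1e-6 Å RMS or 20 iterations).  Seeding with the mean
  rather than a frame makes the fixed point independent of frame order
  and anchors pure-translation ensembles at their geometric midpoint.
* RMSF is computed per residue from the Cα (selected-atom centroid)
  after alignment to the average structure; the reference is named in
  outputs because an initial-structure reference gives different values.
* Degenerate inputs error loudly: < 3 matched atoms for superposition,
  single-frame RMSF, burn-in that removes every frame, empty bins
  series, zero-variance matrices, uncovered atoms in parameter tables
  (listing every missing (residue, atom) pair).
* Report CSVs are written with a fixed float format and no timestamps,
  so identical configurations reproduce byte-identical outputs.

## Known limitations

* Absolute interaction energies and absolute SASA values depend on the
  supplied parameter/radius tables and the minimal side-chain fixtures;
  only their relative structure is validated.
* The packaged contact-potential matrices are synthetic stand-ins (see
  above), not the literature tables.
* Water-mediated bridges, π-interactions and cation–π contacts are out
  of scope; so are mmCIF and binary trajectory formats, mass-weighted
  superposition, 2-D PMFs and multi-ensemble reweighting estimators.
* The ideal-geometry hydrogen rule places one hydrogen per donor; for
  rotatable multi-proton donors the occupancy is a lower bound relative
  to an explicit-hydrogen trajectory.
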