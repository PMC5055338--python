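"""Pairwise global sequence alignment, percent identity/similarity and
Clustal-style conservation annotation.

Alignment is Needleman-Wunsch with affine gaps (BLOSUM62, gap open 10,
gap extend 0.5 by default), via Bio.Align.PairwiseAligner.  Conservation
symbols follow the Clustal convention: '*' fully conserved, ':' all
residues in one strong similarity group, '.' all in one weak group,
' ' otherwise; the published Clustal group definitions encode the
Gonnet PAM 250 > 0.5 / <= 0.5 criteria.

Percent identity uses the full alignment length (gap columns included) as
denominator by default; ``denominator="shorter"`` divides by the shorter
sequence length instead, which is what some aligners report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: Clustal strong similarity groups (Gonnet PAM 250 score > 0.5).
STRONG_GROUPS = (
    "STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW",
)
#: Clustal weak similarity groups (Gonnet PAM 250 score <= 0.5).
WEAK_GROUPS = (
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
    "NEQHRK", "FVLIM", "HFY",
)


def validate_sequence(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise ValueError(
                f"{name}: illegal character {ch!r} at position {pos}"
            )
    return seq


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment with its conservation annotation."""

    aligned_a: str
    aligned_b: str
    score: float
    conservation: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")
        self.conservation = conservation_line([self.aligned_a, self.aligned_b])

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def pct_identity(self) -> float:
        return percent_identity_similarity(self)[0]

    @property
    def pct_similarity(self) -> float:
        return percent_identity_similarity(self)[1]

    def render(self, width: int = 60, name_a: str = "a", name_b: str = "b") -> str:
        """Clustal-style text rendering in blocks with conservation line."""
        pad = max(len(name_a), len(name_b)) + 2
        out = []
        for start in range(0, self.length, width):
            sl = slice(start, start + width)
            out.append(f"{name_a:<{pad}}{self.aligned_a[sl]}")
            out.append(f"{name_b:<{pad}}{self.aligned_b[sl]}")
            out.append(f"{'':<{pad}}{self.conservation[sl]}")
            out.append("")
        return "\n".join(out)


def _make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring.

    The first alignment in the aligner's deterministic enumeration order
    is returned when several share the optimal score.
    """
    a = validate_sequence(a, "sequence a")
    b = validate_sequence(b, "sequence b")
    if not a and not b:
        raise ValueError("cannot align two empty sequences")
    if not a or not b:
        longer = a or b
        ga = longer if a else GAP * len(b)
        gb = b if b else GAP * len(a)
        return PairwiseAlignment(aligned_a=ga, aligned_b=gb, score=0.0)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(
        aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=float(aln.score)
    )


def percent_identity_similarity(
    aln: PairwiseAlignment, denominator: str = "alignment"
) -> tuple[float, float]:
    """(pct_identity, pct_similarity) of a pairwise alignment.

    Identity counts identical non-gap columns; similarity additionally
    counts columns whose residues share a Clustal strong or weak group.
    ``denominator`` is "alignment" (full length, default) or "shorter"
    (the shorter ungapped sequence length).
    """
    if aln.length == 0:
        raise ValueError("zero-length alignment")
    ident = sum(
        1
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x == y and x != GAP
    )
    simil = ident
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP or y == GAP or x == y:
            continue
        if any(x in g and y in g for g in STRONG_GROUPS) or any(
            x in g and y in g for g in WEAK_GROUPS
        ):
            simil += 1
    if denominator == "alignment":
        denom = aln.length
    elif denominator == "shorter":
        denom = min(
            len(aln.aligned_a.replace(GAP, "")),
            len(aln.aligned_b.replace(GAP, "")),
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * ident / denom, 100.0 * simil / denom


def conservation_line(rows: list[str]) -> str:
    """Clustal-style per-column annotation for >= 2 aligned sequences."""
    if len(rows) < 2:
        raise ValueError("conservation needs at least 2 aligned sequences")
    length = len(rows[0])
    for r in rows[1:]:
        if len(r) != length:
            raise ValueError("aligned sequences must have equal length")
    out = []
    for col in zip(*rows):
        if GAP in col:
            out.append(" ")
        elif len(set(col)) == 1:
            out.append("*")
        elif any(all(c in g for c in col) for g in STRONG_GROUPS):
            out.append(":")
        elif any(all(c in g for c in col) for g in WEAK_GROUPS):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)


def composition(seq: str) -> dict[str, int]:
    """Exact residue counts of a sequence."""
    seq = validate_sequence(seq)
    out: dict[str, int] = {}
    for ch in seq:
        out[ch] = out.get(ch, 0) + 1
    return out


def compare_composition(a: str, b: str) -> dict[str, tuple[int, int]]:
    """Residue-count comparison of two sequences: letter -> (count_a,
    count_b) for every letter present in either."""
    ca, cb = composition(a), composition(b)
    return {
        ch: (ca.get(ch, 0), cb.get(ch, 0))
        for ch in sorted(set(ca) | set(cb))
    }


def read_fasta(path) -> dict[str, str]:
    """Name -> sequence mapping from a FASTA file."""
    return {
        rec.id: validate_sequence(str(rec.seq), rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    }


@dataclass(frozen=True)
class PeptideSet:
    """The designed disruptor peptides and the scrambled control, stored
    verbatim as printed.

    PEP_S is the minimal 16-residue disruptor (sometimes described as a
    17-mer in secondary accounts; the printed sequence has 16 residues and
    is stored as printed), PEP_L adds flanking residues, and SCR is the
    scrambled control with the same length as PEP_L but different
    composition.
    """

    PEP_S: str = "RYTAKRQPILDAMDAK"
    PEP_L: str = "IEELRQRYTAKRQPILDAMDAK"
    SCR: str = "TDKRALDQLRMQEIKARYPFQA"


PEPTIDES = PeptideSet()
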