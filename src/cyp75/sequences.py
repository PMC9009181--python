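"""Sequence containers, translation, coordinate mapping, and global alignment.

Everything downstream (variant calling, domain projection, network building)
works on these primitives.  Coordinates are 1-based and closed on both ends,
matching the way positions are reported in the molecular-genetics literature
("a deletion at position 1,323", "amino acid 441").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
GAP = "-"

_STANDARD = CodonTable.standard_dna_table
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: Default nucleotide scoring: a contiguous mid-sized deletion (e.g. 14 nt)
#: must be cheaper than scattering its gaps, hence the large open penalty.
NT_SCORING = dict(match=2.0, mismatch=-3.0, gap_open=-8.0, gap_extend=-1.0)
AA_GAP_OPEN = -11.0
AA_GAP_EXTEND = -1.0


class InvalidAlphabetError(ValueError):
    """A sequence contained a symbol outside the accepted alphabet."""


@dataclass(frozen=True)
class CodingSequence:
    """A coding DNA sequence (CDS) with a text identifier.

    Only the four unambiguous bases are accepted; ambiguity codes are
    rejected rather than guessed at.
    """

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) < 3:
            raise ValueError(f"{self.id!r}: CDS shorter than one codon")
        bad = set(nt) - DNA_ALPHABET
        if bad:
            raise InvalidAlphabetError(
                f"{self.id!r}: non-ACGT symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.nucleotides[position - 1]


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein; ``terminated_early`` marks a premature stop."""

    id: str
    residues: str
    terminated_early: bool = False

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self):
            raise IndexError(f"residue {position} outside 1..{len(self)}")
        return self.residues[position - 1]


def translate(cds: CodingSequence) -> ProteinRecord:
    """Translate a CDS with the standard genetic code.

    Translation stops at (and excludes) the first stop codon.
    ``terminated_early`` is set when that stop occurs before the final
    complete codon, i.e. the open reading frame is cut short.  A trailing
    partial codon is ignored.
    """
    nt = cds.nucleotides
    n_codons = len(nt) // 3
    residues: list[str] = []
    terminated_early = False
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            terminated_early = i < n_codons - 1
            break
        residues.append(CODON_TO_AA[codon])
    return ProteinRecord(cds.id, "".join(residues), terminated_early)


def nt_to_codon(position: int) -> int:
    """Map a 1-based CDS nucleotide position to its 1-based codon index.

    Codon ``i`` spans nucleotides ``3i-2 .. 3i``, so this is
    ``ceil(position / 3)``; e.g. nucleotide 1,323 lies in codon 441.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return -(-position // 3)


def codon_span(codon_index: int) -> tuple[int, int]:
    """Inclusive 1-based nucleotide span of a codon."""
    if codon_index < 1:
        raise ValueError("codon index must be >= 1")
    return 3 * codon_index - 2, 3 * codon_index


@dataclass
class Alignment:
    """A gapped global pairwise alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def identity(self, n_columns: int | None = None) -> float:
        """Fraction of identical (non-double-gap) columns, optionally over
        the first ``n_columns`` only."""
        a, b = self.aligned_a, self.aligned_b
        if n_columns is not None:
            a, b = a[:n_columns], b[:n_columns]
        pairs = [(x, y) for x, y in zip(a, b) if not (x == GAP and y == GAP)]
        if not pairs:
            return 0.0
        return sum(x == y and x != GAP for x, y in pairs) / len(pairs)

    def column_map(self) -> list[tuple[int | None, int | None]]:
        """Per-column (a_position, b_position), 1-based, None at gaps."""
        out: list[tuple[int | None, int | None]] = []
        ia = ib = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            pa = pb = None
            if x != GAP:
                ia += 1
                pa = ia
            if y != GAP:
                ib += 1
                pb = ib
            out.append((pa, pb))
        return out

    def map_a_to_b(self) -> dict[int, int | None]:
        """Map each 1-based position of ``a`` to its aligned position in
        ``b`` (None where ``a`` aligns to a gap)."""
        return {pa: pb for pa, pb in self.column_map() if pa is not None}


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NT_SCORING["match"]
    aligner.mismatch_score = NT_SCORING["mismatch"]
    aligner.open_gap_score = NT_SCORING["gap_open"]
    aligner.extend_gap_score = NT_SCORING["gap_extend"]
    return aligner


def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = AA_GAP_OPEN
    aligner.extend_gap_score = AA_GAP_EXTEND
    return aligner


def _normalize_left(aligned_a: str, aligned_b: str) -> tuple[str, str]:
    """Shift gap runs as far left as possible without changing the score.

    A gap run in one row may trade places with the letter immediately to
    its left whenever the opposite row carries the same letter at both
    ends of the swap; repeated until a fixed point.  This makes indel
    placement in repeats deterministic and reproducible, which variant
    coordinates depend on.
    """
    a = list(aligned_a)
    b = list(aligned_b)

    def shift_once(row: list[str], other: list[str]) -> bool:
        """Move one gap run one column left if the swap is score-neutral."""
        moved = False
        i = 0
        n = len(row)
        while i < n:
            if row[i] != GAP:
                i += 1
                continue
            j = i
            while j + 1 < n and row[j + 1] == GAP:
                j += 1
            # gap run in `row` covers columns i..j; letter at i-1 may hop to j
            if (
                i > 0
                and row[i - 1] != GAP
                and other[i - 1] != GAP
                and other[j] != GAP
                and other[i - 1] == other[j]
            ):
                row[j] = row[i - 1]
                row[i - 1] = GAP
                moved = True
            i = j + 1
        return moved

    while shift_once(a, b) | shift_once(b, a):
        pass
    return "".join(a), "".join(b)


def align_global(a: str, b: str, kind: str = "nt") -> Alignment:
    """Optimal global alignment with affine gap penalties.

    ``kind`` selects the scoring scheme: ``"nt"`` (match/mismatch with
    affine gaps) or ``"aa"`` (BLOSUM62, gap open -11 / extend -1).  Indels
    in the returned alignment are left-normalized so coordinates are
    reproducible.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _nt_aligner() if kind == "nt" else _aa_aligner()
    result = aligner.align(a, b)
    best = result[0]
    row_a, row_b = str(best[0]), str(best[1])
    row_a, row_b = _normalize_left(row_a, row_b)
    return Alignment(row_a, row_b, float(best.score))


# ---------------------------------------------------------------------------
# FASTA I/O (thin wrappers over Biopython; sequences are upper-cased on read)
# ---------------------------------------------------------------------------

def read_cds_fasta(path) -> list[CodingSequence]:
    return [
        CodingSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_protein_fasta(path) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[CodingSequence | ProteinRecord], path) -> None:
    seqrecs = []
    for rec in records:
        text = rec.nucleotides if isinstance(rec, CodingSequence) else rec.residues
        seqrecs.append(SeqRecord(Seq(text), id=rec.id, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")
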