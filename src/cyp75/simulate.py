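"""Deterministic synthetic F3'5'H haplotype panels with known ground truth.

This module builds a stylized 510-residue flavonoid 3'5'-hydroxylase
(CYP75A) reference CDS carrying all canonical cytochrome-P450 features
(SRS1-6, I-helix, K-helix, ERR-triad/PERF, heme-binding motif
PFGAGRRICAG), and derives from it the nine natural bean haplotypes in the
study system: the functional reference plus eight mutant alleles whose
frameshift, truncation and domain-loss arithmetic is engineered to hold
exactly.  It also produces seeded random mutation panels and planted
recombinants with full truth records for property testing.

The reference sequence is found by a backtracking search over codons:
besides encoding the wanted protein, the nucleotide sequence must place
the *first* stop codon of each relevant shifted reading frame at an exact
position, so that

* a +1 insertion inside codon 358 diverges for 28 residues and stops at
  codon 386 (mutant length 385, truncation 125),
* a 14-nt deletion starting at nt 1,246 diverges at residue 416 for 14
  residues and stops at mutant codon 430,
* a 1-nt deletion at nt 1,323 diverges at residue 441 and stops 16 codons
  downstream (mutant length 456),
* a 4-nt insertion after nt 1,310 stops at mutant codon 446.

All of these are re-verified by literal translation every time the panel
is generated; a violation raises immediately (fixture bug, not data).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from .domains import Domain, DomainMap
from .sequences import (
    CODON_TO_AA,
    CodingSequence,
    STOP_CODONS,
    translate,
    nt_to_codon,
)

REFERENCE_ID = "V_5-593"
REFERENCE_AA_LENGTH = 510
REFERENCE_NT_LENGTH = 3 * (REFERENCE_AA_LENGTH + 1)  # 1,533 incl. stop codon

HEME_MOTIF = "PFGAGRRICAG"
#: codons pinned to exact triplets (1-based codon index -> codon)
_HEME_CODONS = ("CCA", "TTC", "GGA", "GCT", "GGT", "CGT", "CGA", "ATC", "TGC", "GCA", "GGC")

#: the 4-nt insertion text carried by the MDRK haplotype (after nt 1,310)
MDRK_INSERTION = "AGGA"

_SENSE_CODONS = sorted(CODON_TO_AA)

# Edits are ("snp", pos, alt) | ("ins", pos, text)  [insert after pos]
#         | ("del", start, end)                     [inclusive]
Edit = tuple


@dataclass
class TruthRecord:
    """Ground truth for one generated haplotype."""

    haplotype_id: str
    edits: list[Edit]
    expected_variants: list[tuple]  # (kind, cds_position, ref, alt, length)
    functional_class: str  # functional | impaired_substitution | null_truncation
    divergence_start_aa: int | None = None
    altered_run_length_aa: int | None = None
    premature_stop_codon: int | None = None
    mutant_length_aa: int | None = None
    truncation_length_aa: int = 0
    domains_lost: tuple[str, ...] = ()
    parent_5prime: str | None = None
    parent_3prime: str | None = None
    breakpoint_nt: int | None = None
    degenerate: bool = False


class FixtureError(RuntimeError):
    """The generated fixture violated one of its own invariants."""


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

_PINNED_CODONS: dict[int, str] = {
    # 4-fold degenerate codons used as synonymous-SNP targets
    20: "GCT", 60: "GTC", 140: "TCA", 230: "ACG", 280: "CCT",
    # missense-SNP targets for the G19833 haplotype
    30: "AAA", 330: "CTG",
    # synonymous-SNP targets shared by V0491/M0056 (codon 167) and G5686 (codon 100)
    100: "GGT", 167: "CTT",
    # R428 encoded as AGG so a single change at nt 1,283 gives ATG (R428M)
    428: "AGG",
    # the final stop
    511: "TAA",
}
for _i, _codon in enumerate(_HEME_CODONS):
    _PINNED_CODONS[460 + _i] = _codon

_PINNED_RESIDUES: dict[int, str] = {
    114: "G",          # invariant SRS1 glycine
    210: "V",          # SRS2 position 3
    245: "H",          # SRS3 residue under positive selection
    302: "N",          # SRS4 residue under positive selection
    399: "E", 402: "R",  # ExxR of the K-helix
    424: "P", 425: "E", 426: "R", 427: "F",  # PERF motif opening the ERR-triad
    494: "A", 495: "S",  # SRS6 discriminating position under either indexing
}

# first-stop positions demanded in the shifted frames (see module docstring);
# frame B codon m reads nt 3m-3..3m-1, frame C codon k reads nt 3k-1..3k+1.
_FRAME_B_NONSTOP = set(range(359, 386)) | set(range(421, 435)) | set(range(438, 445))
_FRAME_B_STOP = {386, 435, 445}
_FRAME_C_NONSTOP = set(range(442, 457))
_FRAME_C_STOP = {457}


def _candidates(i: int) -> list[str]:
    if i in _PINNED_CODONS:
        return [_PINNED_CODONS[i]]
    if i in _PINNED_RESIDUES:
        aa = _PINNED_RESIDUES[i]
        cands = [c for c in _SENSE_CODONS if CODON_TO_AA[c] == aa]
    else:
        cands = list(_SENSE_CODONS)
    if i == 441:
        # UI 111 loses the T at nt 1,323 (third base of codon 441); the base
        # before it must differ from T so the deletion cannot shift left.
        cands = [c for c in cands if c[2] == "T" and c[1] != "T"]
    rng = random.Random(0x5F35 + i)
    rng.shuffle(cands)
    return cands


def _frame_b(c: list[str | None], m: int) -> str:
    return c[m - 1][2] + c[m][0] + c[m][1]  # type: ignore[index]


def _frame_c(c: list[str | None], k: int) -> str:
    return c[k][1] + c[k][2] + c[k + 1][0]  # type: ignore[index]


def _check(c: list[str | None], i: int) -> bool:
    """Constraints that become decidable once codon ``i`` is placed."""
    codon = c[i]
    assert codon is not None
    if i <= REFERENCE_AA_LENGTH and codon in STOP_CODONS:
        return False
    if i >= 2:
        if i in _FRAME_B_NONSTOP and _frame_b(c, i) in STOP_CODONS:
            return False
        if i in _FRAME_B_STOP and _frame_b(c, i) not in STOP_CODONS:
            return False
    k = i - 1
    if k >= 1 and c[k] is not None:
        if k in _FRAME_C_NONSTOP and _frame_c(c, k) in STOP_CODONS:
            return False
        if k in _FRAME_C_STOP and _frame_c(c, k) not in STOP_CODONS:
            return False
    if i == 358:
        # G19833: a C inserted after nt 1,072 must not shift left, must not
        # create a stop, and must change residue 358 (divergence start).
        mutant = codon[0] + "C" + codon[1]
        if codon[0] == "C" or mutant in STOP_CODONS:
            return False
        if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
            return False
    if i == 420:
        # Mex235 14-nt deletion (nt 1,246-1,259) must be left-maximal
        if c[415][2] == codon[1]:  # type: ignore[index]
            return False
    if i == 421:
        # Mex235 divergence: mutant residue 416 reads frame-B codon 421
        fb = _frame_b(c, 421)
        if fb not in STOP_CODONS and CODON_TO_AA[fb] == CODON_TO_AA[c[416]]:  # type: ignore[index]
            return False
    if i == 442:
        # UI 111: mutant codon 441 reads nt 1,321, 1,322, 1,324
        mutant = c[441][0] + c[441][1] + codon[0]  # type: ignore[index]
        if mutant in STOP_CODONS or CODON_TO_AA[mutant] == CODON_TO_AA[c[441]]:  # type: ignore[index]
            return False
    if i == 438:
        # MDRK 4-nt insertion after nt 1,310: neither inserted codon may stop
        first = c[437][0] + c[437][1] + MDRK_INSERTION[0]  # type: ignore[index]
        second = MDRK_INSERTION[1:4]
        if first in STOP_CODONS or second in STOP_CODONS:
            return False
        if CODON_TO_AA[first] == CODON_TO_AA[c[437]]:  # divergence must start at 437  # type: ignore[index]
            return False
        if MDRK_INSERTION[-1] == c[437][1]:  # left-normalization guard  # type: ignore[index]
            return False
    return True


def _build_reference_nt() -> str:
    n = REFERENCE_AA_LENGTH + 1
    codons: list[str | None] = [None] * (n + 1)  # 1-based
    cand_lists = [None] + [_candidates(i) for i in range(1, n + 1)]
    pointers = [0] * (n + 1)
    i = 1
    while 1 <= i <= n:
        placed = False
        while pointers[i] < len(cand_lists[i]):  # type: ignore[arg-type]
            codons[i] = cand_lists[i][pointers[i]]  # type: ignore[index]
            pointers[i] += 1
            if _check(codons, i):
                placed = True
                break
        if placed:
            i += 1
        else:
            pointers[i] = 0
            codons[i] = None
            i -= 1
    if i == 0:
        raise FixtureError("reference constraint search failed")
    return "".join(codons[1:])  # type: ignore[arg-type]


def _default_domains(protein: str) -> DomainMap:
    spans = [
        ("transmembrane", 5, 25, False),
        ("SRS1", 110, 125, True),
        ("SRS2", 208, 214, True),
        ("SRS3", 244, 250, True),
        ("SRS4", 295, 315, True),
        ("I-helix", 301, 308, True),
        ("K-helix", 392, 402, True),
        ("SRS5", 404, 414, True),
        ("ERR-triad", 424, 433, True),
        ("heme-binding", 460, 470, True),
        ("SRS6", 487, 496, True),
    ]
    return DomainMap([
        Domain(name, s, e, essential, protein[s - 1 : e])
        for name, s, e, essential in spans
    ])


@lru_cache(maxsize=1)
def make_reference() -> tuple[CodingSequence, DomainMap]:
    """Build the synthetic reference CDS and its domain map (deterministic)."""
    nt = _build_reference_nt()
    cds = CodingSequence(REFERENCE_ID, nt)
    protein = translate(cds)
    if len(protein) != REFERENCE_AA_LENGTH or protein.terminated_early:
        raise FixtureError("reference does not translate to 510 clean residues")
    if protein.residues[459:470] != HEME_MOTIF:
        raise FixtureError("heme-binding motif not at residues 460-470")
    for pos, aa in _PINNED_RESIDUES.items():
        if protein.residues[pos - 1] != aa:
            raise FixtureError(f"anchor residue {pos} != {aa}")
    # the heme motif must be unique even under the fuzzy (<=2 mismatch) search
    for start in range(len(protein) - len(HEME_MOTIF) + 1):
        if start == 459:
            continue
        window = protein.residues[start : start + len(HEME_MOTIF)]
        if sum(a != b for a, b in zip(window, HEME_MOTIF)) <= 2:
            raise FixtureError("spurious heme-like motif in reference")
    return cds, _default_domains(protein.residues)


# ---------------------------------------------------------------------------
# edit application
# ---------------------------------------------------------------------------

def _edit_anchor(edit: Edit) -> int:
    return edit[1]


def apply_edits(reference_nt: str, edits: list[Edit]) -> str:
    """Apply non-overlapping edits (1-based reference coordinates)."""
    seq = reference_nt
    for edit in sorted(edits, key=_edit_anchor, reverse=True):
        kind = edit[0]
        if kind == "snp":
            _, pos, alt = edit
            seq = seq[: pos - 1] + alt + seq[pos:]
        elif kind == "ins":
            _, pos, text = edit
            seq = seq[:pos] + text + seq[pos:]
        elif kind == "del":
            _, start, end = edit
            seq = seq[: start - 1] + seq[end:]
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return seq


def _expected_variant(reference_nt: str, edit: Edit) -> tuple:
    """The left-normalized variant call an exact caller should emit."""
    kind = edit[0]
    if kind == "snp":
        _, pos, alt = edit
        return ("SNP", pos, reference_nt[pos - 1], alt, 1)
    if kind == "ins":
        _, pos, text = edit
        while pos >= 1 and text[-1] == reference_nt[pos - 1]:
            text = reference_nt[pos - 1] + text[:-1]
            pos -= 1
        return ("insertion", pos, "", text, len(text))
    _, start, end = edit
    while start > 1 and reference_nt[start - 2] == reference_nt[end - 1]:
        start -= 1
        end -= 1
    return ("deletion", start - 1, reference_nt[start - 1 : end], "", end - start + 1)


# ---------------------------------------------------------------------------
# the nine-haplotype panel
# ---------------------------------------------------------------------------

def _paper_edit_lists() -> dict[str, list[Edit]]:
    g19833_snps: list[Edit] = [
        ("snp", 60, "C"),    # GCT -> GCC   (synonymous, Ala20)
        ("snp", 180, "A"),   # GTC -> GTA   (synonymous, Val60)
        ("snp", 420, "G"),   # TCA -> TCG   (synonymous, Ser140)
        ("snp", 690, "A"),   # ACG -> ACA   (synonymous, Thr230)
        ("snp", 840, "G"),   # CCT -> CCG   (synonymous, Pro280)
        ("snp", 88, "G"),    # AAA -> GAA   (K30E missense, outside domains)
        ("snp", 989, "C"),   # CTG -> CCG   (L330P missense, outside domains)
    ]
    v0491: list[Edit] = [
        ("snp", 501, "C"),   # CTT -> CTC   (synonymous, Leu167)
        ("snp", 1283, "T"),  # AGG -> ATG   (R428M, beside the PERF motif)
    ]
    mdrk = v0491 + [("ins", 1310, MDRK_INSERTION)]
    return {
        "v_G19833": g19833_snps + [("ins", 1072, "C")],
        "vlae_V0491": list(v0491),
        "vlae_MDRK": list(mdrk),
        "vlae_G5686": mdrk + [("snp", 300, "C")],  # GGT -> GGC (synonymous, Gly100)
        "v_Mex235": [("del", 1246, 1259)],
        # the M0056 recombinant: 5' of MDRK (through nt 900) + 3' of Mex235
        "v_M0056": [("snp", 501, "C"), ("del", 1246, 1259)],
        "v_UI111": [("del", 1323, 1323)],
        "v_G2858": [("del", 1381, 1395)],  # in-frame, removes residues 461-465
    }


_ESSENTIAL_STARTS = {
    "SRS1": 110, "SRS2": 208, "SRS3": 244, "SRS4": 295, "I-helix": 301,
    "K-helix": 392, "SRS5": 404, "ERR-triad": 424, "heme-binding": 460,
    "SRS6": 487,
}


def _lost_by_truncation(mutant_len: int) -> tuple[str, ...]:
    return tuple(
        name for name, start in _ESSENTIAL_STARTS.items() if start > mutant_len
    )


def make_paper_panel() -> tuple[list[CodingSequence], dict[str, TruthRecord]]:
    """The nine-haplotype panel (reference first) with truth records.

    Fully deterministic; every haplotype's stated consequence is
    re-derived by literal translation before the panel is returned.
    """
    reference, _ = make_reference()
    ref_nt = reference.nucleotides

    panel = [reference]
    truth: dict[str, TruthRecord] = {
        REFERENCE_ID: TruthRecord(REFERENCE_ID, [], [], "functional",
                                  mutant_length_aa=REFERENCE_AA_LENGTH)
    }

    frameshift_expect = {
        # id: (divergence_start, premature_stop_codon)
        "v_G19833": (358, 386),
        "vlae_MDRK": (437, 446),
        "vlae_G5686": (437, 446),
        "v_Mex235": (416, 430),
        "v_M0056": (416, 430),
        "v_UI111": (441, 457),
    }

    for hap_id, edits in _paper_edit_lists().items():
        seq = CodingSequence(hap_id, apply_edits(ref_nt, edits))
        expected = sorted(
            (_expected_variant(ref_nt, e) for e in edits), key=lambda v: v[1]
        )
        record = TruthRecord(hap_id, list(edits), expected, "null_truncation")
        protein = translate(seq)
        if hap_id in frameshift_expect:
            div, stop = frameshift_expect[hap_id]
            mutant_len = stop - 1
            if not protein.terminated_early or len(protein) != mutant_len:
                raise FixtureError(
                    f"{hap_id}: expected premature stop at codon {stop}, "
                    f"got length {len(protein)} (early={protein.terminated_early})"
                )
            ref_protein = translate(reference)
            first_diff = next(
                (i + 1 for i in range(len(protein))
                 if protein.residues[i] != ref_protein.residues[i]
                 and i + 1 >= div),
                None,
            )
            if first_diff != div:
                raise FixtureError(f"{hap_id}: divergence at {first_diff}, wanted {div}")
            record.divergence_start_aa = div
            record.premature_stop_codon = stop
            record.altered_run_length_aa = stop - div
            record.mutant_length_aa = mutant_len
            record.truncation_length_aa = REFERENCE_AA_LENGTH - mutant_len
            record.domains_lost = _lost_by_truncation(mutant_len)
        elif hap_id == "vlae_V0491":
            if protein.terminated_early or len(protein) != REFERENCE_AA_LENGTH:
                raise FixtureError("V0491 must translate full length")
            if protein.residues[427] != "M":
                raise FixtureError("V0491 must carry R428M")
            record.functional_class = "impaired_substitution"
            record.mutant_length_aa = REFERENCE_AA_LENGTH
        elif hap_id == "v_G2858":
            if protein.terminated_early or len(protein) != REFERENCE_AA_LENGTH - 5:
                raise FixtureError("G2858 must lose exactly residues 461-465")
            record.mutant_length_aa = len(protein)
            record.domains_lost = ("heme-binding",)
        if hap_id == "v_M0056":
            record.parent_5prime = "vlae_MDRK"
            record.parent_3prime = "v_Mex235"
            record.breakpoint_nt = 900
        panel.append(seq)
        truth[hap_id] = record

    # the recombinant must literally equal its parents' splice at nt 900
    by_id = {s.id: s.nucleotides for s in panel}
    spliced = by_id["vlae_MDRK"][:900] + by_id["v_Mex235"][900:]
    if spliced != by_id["v_M0056"]:
        raise FixtureError("M0056 is not the MDRK x Mex235 splice at nt 900")
    return panel, truth


# ---------------------------------------------------------------------------
# random panels
# ---------------------------------------------------------------------------

_DEFAULT_INDEL_LENGTHS = (1, 1, 2, 3, 3, 4, 5, 6, 9, 14, 15)


def make_random_panel(
    n: int,
    snp_rate: float = 0.002,
    indel_rate: float = 0.0005,
    indel_lengths: tuple[int, ...] = _DEFAULT_INDEL_LENGTHS,
    seed: int = 0,
    critical: dict[int, str] | None = None,
) -> tuple[list[CodingSequence], dict[str, TruthRecord]]:
    """Random mutant haplotypes of the synthetic reference with truth labels.

    Edits are kept >= 12 nt apart (so no two edits touch the same codon and
    alignment-based calling is unambiguous), SNPs never create a stop codon
    in the reference frame, and indel flanks are chosen so left-normalized
    coordinates equal the planted ones.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (0 < snp_rate <= 0.05) or not (0 < indel_rate <= 0.05):
        raise ValueError("rates must lie in (0, 0.05]")
    reference, domains = make_reference()
    ref_nt = reference.nucleotides
    ref_aa = translate(reference).residues
    rng = random.Random(seed)
    if critical is None:
        critical = {114: "G", 210: "V", 245: "H", 302: "N", 428: "R", 494: "AS"}

    panel: list[CodingSequence] = []
    truth: dict[str, TruthRecord] = {}
    for idx in range(n):
        hap_id = f"rand_{seed}_{idx:04d}"
        edits = _draw_edits(rng, ref_nt, snp_rate, indel_rate, indel_lengths)
        seq = CodingSequence(hap_id, apply_edits(ref_nt, edits))
        expected = sorted(
            (_expected_variant(ref_nt, e) for e in edits), key=lambda v: v[1]
        )
        label = _truth_class(ref_nt, ref_aa, edits, critical)
        truth[hap_id] = TruthRecord(hap_id, edits, expected, label)
        panel.append(seq)
    return panel, truth


def _draw_edits(rng, ref_nt, snp_rate, indel_rate, indel_lengths) -> list[Edit]:
    length = len(ref_nt)
    usable = range(16, length - 50)  # keep clear of the termini and stop
    n_snp = sum(rng.random() < snp_rate for _ in usable)
    n_indel = sum(rng.random() < indel_rate for _ in usable)
    edits: list[Edit] = []
    taken: list[tuple[int, int]] = []

    def free(lo: int, hi: int) -> bool:
        return all(hi < a - 12 or lo > b + 12 for a, b in taken)

    for _ in range(n_indel):
        for _attempt in range(200):
            size = rng.choice(indel_lengths)
            if rng.random() < 0.5:  # deletion of ref[start..end]
                start = rng.randrange(usable.start, usable.stop - size)
                end = start + size - 1
                if not free(start - 1, end + 1):
                    continue
                if ref_nt[start - 2] == ref_nt[end - 1]:
                    continue  # would left-shift; keep coordinates exact
                edits.append(("del", start, end))
                taken.append((start - 1, end + 1))
                break
            else:  # insertion after `pos`
                pos = rng.randrange(usable.start, usable.stop)
                if not free(pos, pos + 1):
                    continue
                text = "".join(rng.choice("ACGT") for _ in range(size))
                if text[-1] == ref_nt[pos - 1]:
                    continue
                edits.append(("ins", pos, text))
                taken.append((pos, pos + 1))
                break
    for _ in range(n_snp):
        for _attempt in range(200):
            pos = rng.randrange(usable.start, usable.stop)
            if not free(pos, pos):
                continue
            ref_base = ref_nt[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            codon_i = nt_to_codon(pos)
            codon = list(ref_nt[3 * codon_i - 3 : 3 * codon_i])
            codon[(pos - 1) % 3] = alt
            if "".join(codon) in STOP_CODONS:
                continue  # nonsense SNPs would confound the planted labels
            edits.append(("snp", pos, alt))
            taken.append((pos, pos))
            break
    return sorted(edits, key=_edit_anchor)


def _truth_class(ref_nt, ref_aa, edits, critical) -> str:
    """Functional class implied by the planted edits (coordinate arithmetic
    plus literal translation; no alignment involved)."""
    mutant = translate(CodingSequence("x", apply_edits(ref_nt, edits)))
    if mutant.terminated_early:
        if _lost_by_truncation(len(mutant)):
            return "null_truncation"
    for edit in edits:
        if edit[0] == "del" and (edit[2] - edit[1] + 1) % 3 == 0:
            first, last = nt_to_codon(edit[1]), nt_to_codon(edit[2])
            for name, (s, e) in _ESSENTIAL_SPANS.items():
                if first <= e and last >= s:
                    return "null_truncation"
    for edit in edits:
        if edit[0] != "snp":
            continue
        pos, alt = edit[1], edit[2]
        codon_i = nt_to_codon(pos)
        codon = list(ref_nt[3 * codon_i - 3 : 3 * codon_i])
        codon[(pos - 1) % 3] = alt
        new_aa = CODON_TO_AA.get("".join(codon))
        if (
            codon_i in critical
            and new_aa is not None
            and new_aa != ref_aa[codon_i - 1]
            and new_aa not in critical[codon_i]
        ):
            return "impaired_substitution"
    return "functional"


_ESSENTIAL_SPANS = {
    "SRS1": (110, 125), "SRS2": (208, 214), "SRS3": (244, 250),
    "SRS4": (295, 315), "I-helix": (301, 308), "K-helix": (392, 402),
    "SRS5": (404, 414), "ERR-triad": (424, 433), "heme-binding": (460, 470),
    "SRS6": (487, 496),
}


# ---------------------------------------------------------------------------
# planted recombinants
# ---------------------------------------------------------------------------

def plant_recombinant(
    parent_a: TruthRecord,
    parent_b: TruthRecord,
    breakpoint_nt: int,
    child_id: str = "chimera",
) -> tuple[CodingSequence, TruthRecord]:
    """Splice two haplotypes at a reference coordinate.

    The child carries parent A's edits at positions <= breakpoint and
    parent B's edits beyond it.  A deletion straddling the breakpoint is
    an error; a side that contributes no edits leaves the chimera equal to
    one parent, which is flagged ``degenerate``.
    """
    reference, _ = make_reference()
    ref_nt = reference.nucleotides
    if not 1 <= breakpoint_nt < len(ref_nt):
        raise ValueError("breakpoint outside the shared reference coordinates")
    for rec in (parent_a, parent_b):
        for edit in rec.edits:
            if edit[0] == "del" and edit[1] <= breakpoint_nt < edit[2]:
                raise ValueError(
                    f"{rec.haplotype_id}: deletion straddles breakpoint {breakpoint_nt}"
                )
    child_edits = sorted(
        [e for e in parent_a.edits if _edit_anchor(e) <= breakpoint_nt]
        + [e for e in parent_b.edits if _edit_anchor(e) > breakpoint_nt],
        key=_edit_anchor,
    )
    degenerate = (
        child_edits == sorted(parent_a.edits, key=_edit_anchor)
        or child_edits == sorted(parent_b.edits, key=_edit_anchor)
    )
    seq = CodingSequence(child_id, apply_edits(ref_nt, child_edits))
    expected = sorted(
        (_expected_variant(ref_nt, e) for e in child_edits), key=lambda v: v[1]
    )
    record = TruthRecord(
        child_id, child_edits, expected, "unlabelled",
        parent_5prime=parent_a.haplotype_id,
        parent_3prime=parent_b.haplotype_id,
        breakpoint_nt=breakpoint_nt,
        degenerate=degenerate,
    )
    return seq, record


# ---------------------------------------------------------------------------
# on-disk emission (used by the CLI `simulate` subcommand)
# ---------------------------------------------------------------------------

def write_panel(out_dir: str | Path) -> dict[str, Path]:
    """Write the paper panel, its truth table and the domain map to disk."""
    from .sequences import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, domains = make_reference()
    panel, truth = make_paper_panel()
    paths = {
        "reference": out / "reference.fasta",
        "panel": out / "panel.fasta",
        "truth": out / "truth.tsv",
        "domains": out / "domains.tsv",
    }
    write_fasta([reference], paths["reference"])
    write_fasta(panel, paths["panel"])
    domains.to_tsv(paths["domains"])
    with open(paths["truth"], "w") as fh:
        fh.write(
            "haplotype\tn_edits\tfunctional_class\tdivergence_start_aa\t"
            "premature_stop_codon\ttruncation_length_aa\tparent_5prime\t"
            "parent_3prime\tbreakpoint_nt\n"
        )
        for hap_id, rec in truth.items():
            fh.write(
                f"{hap_id}\t{len(rec.edits)}\t{rec.functional_class}\t"
                f"{rec.divergence_start_aa or ''}\t{rec.premature_stop_codon or ''}\t"
                f"{rec.truncation_length_aa}\t{rec.parent_5prime or ''}\t"
                f"{rec.parent_3prime or ''}\t{rec.breakpoint_nt or ''}\n"
            )
    return paths
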