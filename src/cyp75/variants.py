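"""Variant calling between CDS haplotypes and protein-consequence prediction.

Variants are derived from a left-normalized global nucleotide alignment,
so indel coordinates are reproducible in repeat context.  Consequences
come from *literal* translation of the edited sequence — frameshifts that
later restore frame, compound events, and premature stops all fall out of
the translation itself rather than per-variant bookkeeping.  Domain
losses combine two mechanisms: essential domains wholly downstream of a
premature stop, and essential domains overlapping an in-frame deletion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .domains import DomainMap
from .sequences import (
    CODON_TO_AA,
    GAP,
    CodingSequence,
    align_global,
    nt_to_codon,
    translate,
)

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"

FUNCTIONAL = "functional"
IMPAIRED = "impaired_substitution"
NULL = "null_truncation"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
IN_FRAME_INDEL = "in-frame-indel"


class NotComparableError(ValueError):
    """The two sequences are too diverged to call variants between."""


@dataclass(frozen=True)
class VariantCall:
    """One CDS-level difference from the reference.

    ``cds_position`` is the 1-based reference position of a SNP, or the
    reference position immediately left of a left-normalized indel.
    """

    kind: str
    cds_position: int
    ref_allele: str
    alt_allele: str
    length: int

    def __post_init__(self) -> None:
        if self.kind == SNP:
            if self.length != 1 or self.ref_allele == self.alt_allele:
                raise ValueError("SNP must be a single differing base")
        elif self.kind == INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion carries only an alt allele")
        elif self.kind == DELETION:
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion carries only a ref allele")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def frameshifting(self) -> bool:
        return self.kind in (INSERTION, DELETION) and self.length % 3 != 0

    def as_tuple(self) -> tuple:
        return (self.kind, self.cds_position, self.ref_allele, self.alt_allele, self.length)


#: Critical single residues: reference position -> residues considered
#: compatible with full activity at that position.
DEFAULT_CRITICAL_RESIDUES: dict[int, str] = {
    114: "G",   # invariant SRS1 glycine (position 5 of SRS1)
    210: "V",   # SRS2 position 3
    245: "H",   # SRS3, under positive selection
    302: "N",   # SRS4, under positive selection
    428: "R",   # adjacent to the PERF motif of the ERR-triad
    494: "AS",  # SRS6 discriminating position (Ala/Ser in F3'5'H)
}


@dataclass
class ConsequenceReport:
    """Protein-level interpretation of one haplotype's variants."""

    haplotype_id: str
    variants: list[VariantCall]
    variant_classes: list[str]
    divergence_start_aa: int | None
    altered_run_length_aa: int | None
    premature_stop_codon: int | None
    mutant_protein_length_aa: int
    truncation_length_aa: int
    domains_lost: list[str]
    domains_altered: list[str]
    missense_changes: list[tuple[int, str, str]]  # (codon, ref_aa, alt_aa)
    functional_class: str = FUNCTIONAL

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = [v.as_tuple() for v in self.variants]
        return d


def call_variants(
    haplotype: CodingSequence,
    reference: CodingSequence,
    min_identity: float = 0.50,
) -> list[VariantCall]:
    """Call SNPs and indels of a haplotype against the reference.

    Adjacent gap columns merge into a single indel event; indels are
    left-normalized against the reference context; calls are sorted by
    reference position.
    """
    if haplotype.nucleotides == reference.nucleotides:
        return []
    aln = align_global(reference.nucleotides, haplotype.nucleotides, kind="nt")
    if aln.identity() < min_identity:
        raise NotComparableError(
            f"{haplotype.id} vs {reference.id}: identity "
            f"{aln.identity():.2f} below {min_identity:.2f}, not comparable"
        )
    ref_nt = reference.nucleotides
    calls: list[VariantCall] = []
    ref_pos = 0  # last consumed reference position
    col = 0
    ra, rb = aln.aligned_a, aln.aligned_b
    n = len(ra)
    while col < n:
        x, y = ra[col], rb[col]
        if x != GAP and y != GAP:
            ref_pos += 1
            if x != y:
                calls.append(VariantCall(SNP, ref_pos, x, y, 1))
            col += 1
        elif y == GAP:  # run of deletions from the haplotype
            start = ref_pos + 1
            deleted = []
            while col < n and rb[col] == GAP:
                deleted.append(ra[col])
                ref_pos += 1
                col += 1
            end = ref_pos
            while start > 1 and ref_nt[start - 2] == ref_nt[end - 1]:
                start -= 1
                end -= 1
            calls.append(
                VariantCall(DELETION, start - 1, ref_nt[start - 1 : end], "",
                            end - start + 1)
            )
        else:  # run of insertions relative to the reference
            inserted = []
            while col < n and ra[col] == GAP:
                inserted.append(rb[col])
                col += 1
            text = "".join(inserted)
            pos = ref_pos
            while pos >= 1 and text[-1] == ref_nt[pos - 1]:
                text = ref_nt[pos - 1] + text[:-1]
                pos -= 1
            calls.append(VariantCall(INSERTION, pos, "", text, len(text)))
    return sorted(calls, key=lambda v: (v.cds_position, v.kind))


def _snp_consequence(ref_nt: str, variant: VariantCall) -> tuple[str, str, str]:
    """(class, ref_aa, alt_aa) of a SNP in the reference reading frame."""
    codon_i = nt_to_codon(variant.cds_position)
    codon = list(ref_nt[3 * codon_i - 3 : 3 * codon_i])
    if len(codon) < 3:
        return SYNONYMOUS, "", ""  # partial trailing codon; no residue affected
    ref_aa = CODON_TO_AA.get("".join(codon), "*")
    codon[(variant.cds_position - 1) % 3] = variant.alt_allele
    alt_codon = "".join(codon)
    alt_aa = CODON_TO_AA.get(alt_codon, "*")
    if alt_aa == "*":
        return NONSENSE, ref_aa, alt_aa
    return (SYNONYMOUS if alt_aa == ref_aa else MISSENSE), ref_aa, alt_aa


def predict_consequence(
    haplotype: CodingSequence,
    reference: CodingSequence,
    ref_map: DomainMap,
    critical: dict[int, str] | None = None,
) -> ConsequenceReport:
    """Full protein-level consequence report for one haplotype."""
    variants = call_variants(haplotype, reference)
    ref_protein = translate(reference)
    mut_protein = translate(haplotype)
    ref_nt = reference.nucleotides

    classes: list[str] = []
    missense: list[tuple[int, str, str]] = []
    for v in variants:
        if v.kind == SNP:
            cls, ref_aa, alt_aa = _snp_consequence(ref_nt, v)
            classes.append(cls)
            if cls == MISSENSE:
                missense.append((nt_to_codon(v.cds_position), ref_aa, alt_aa))
        else:
            classes.append(FRAMESHIFT if v.frameshifting else IN_FRAME_INDEL)

    premature_stop = len(mut_protein) + 1 if mut_protein.terminated_early else None
    truncation = (
        len(ref_protein) - len(mut_protein) if premature_stop is not None else 0
    )

    # first residue altered by a frame disruption, confirmed on the
    # translated product
    divergence = None
    frameshifts = [v for v in variants if v.frameshifting]
    if frameshifts:
        first = min(frameshifts, key=lambda v: v.cds_position)
        fs_codon = nt_to_codon(first.cds_position + 1)
        divergence = next(
            (
                i + 1
                for i in range(fs_codon - 1, len(mut_protein))
                if i >= len(ref_protein)
                or mut_protein.residues[i] != ref_protein.residues[i]
            ),
            min(fs_codon, len(mut_protein) + 1),
        )
    altered_run = (
        premature_stop - divergence
        if premature_stop is not None and divergence is not None
        else None
    )

    essential = [d for d in ref_map if d.essential]
    lost: list[str] = []
    altered: list[str] = []
    if premature_stop is not None:
        for dom in essential:
            if dom.start_aa > len(mut_protein):
                lost.append(dom.name)
            elif dom.end_aa > len(mut_protein):
                altered.append(dom.name)
    for v in variants:
        if v.kind == DELETION and not v.frameshifting:
            first_codon = nt_to_codon(v.cds_position + 1)
            last_codon = nt_to_codon(v.cds_position + v.length)
            for dom in essential:
                if dom.overlaps(first_codon, last_codon) and dom.name not in lost:
                    lost.append(dom.name)
    if divergence is not None:
        run_end = len(mut_protein)
        for dom in essential:
            if dom.overlaps(divergence, run_end) and dom.name not in lost:
                if dom.name not in altered:
                    altered.append(dom.name)
    for codon_i, _, _ in missense:
        for dom in essential:
            if dom.overlaps(codon_i, codon_i) and dom.name not in lost:
                if dom.name not in altered:
                    altered.append(dom.name)

    report = ConsequenceReport(
        haplotype_id=haplotype.id,
        variants=variants,
        variant_classes=classes,
        divergence_start_aa=divergence,
        altered_run_length_aa=altered_run,
        premature_stop_codon=premature_stop,
        mutant_protein_length_aa=len(mut_protein),
        truncation_length_aa=truncation,
        domains_lost=lost,
        domains_altered=altered,
        missense_changes=missense,
    )
    report.functional_class = classify_function(report, critical)
    return report


def classify_function(
    report: ConsequenceReport,
    critical: dict[int, str] | None = None,
) -> str:
    """Predicted enzyme functionality of one haplotype.

    ``null_truncation`` when any essential domain is lost (by truncation
    or in-frame deletion); otherwise ``impaired_substitution`` when a
    missense change hits a critical residue; otherwise ``functional``.
    Compound haplotypes take the most severe class.
    """
    if critical is None:
        critical = DEFAULT_CRITICAL_RESIDUES
    if report.domains_lost:
        return NULL
    for codon_i, _ref_aa, alt_aa in report.missense_changes:
        allowed = critical.get(codon_i)
        if allowed is not None and alt_aa not in allowed:
            return IMPAIRED
    return FUNCTIONAL


# ---------------------------------------------------------------------------
# tabular / VCF-style output
# ---------------------------------------------------------------------------

def variants_to_tsv(rows: dict[str, list[VariantCall]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tkind\tposition\tref\talt\tlength\n")
        for hap_id, calls in rows.items():
            for v in calls:
                fh.write(
                    f"{hap_id}\t{v.kind}\t{v.cds_position}\t{v.ref_allele}\t"
                    f"{v.alt_allele}\t{v.length}\n"
                )


def variants_to_vcf(
    rows: dict[str, list[VariantCall]],
    reference: CodingSequence,
    path: str | Path,
) -> None:
    """Minimal VCF-style records; indels carry the left anchor base."""
    ref_nt = reference.nucleotides
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.id},length={len(ref_nt)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for hap_id, calls in rows.items():
            for v in calls:
                if v.kind == SNP:
                    pos, ref, alt = v.cds_position, v.ref_allele, v.alt_allele
                else:
                    anchor_pos = max(v.cds_position, 1)
                    anchor = ref_nt[anchor_pos - 1]
                    if v.kind == INSERTION:
                        pos, ref, alt = anchor_pos, anchor, anchor + v.alt_allele
                    else:
                        pos, ref, alt = anchor_pos, anchor + v.ref_allele, anchor
                fh.write(
                    f"{reference.id}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tHAP={hap_id}\n"
                )


def reports_to_json(reports: list[ConsequenceReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1, sort_keys=True)
        fh.write("\n")


def reports_to_tsv(reports: list[ConsequenceReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "haplotype\tn_variants\tdivergence_start_aa\taltered_run_length_aa\t"
            "premature_stop_codon\tmutant_length_aa\ttruncation_length_aa\t"
            "domains_lost\tdomains_altered\tfunctional_class\n"
        )
        for r in reports:
            fh.write(
                f"{r.haplotype_id}\t{len(r.variants)}\t"
                f"{r.divergence_start_aa if r.divergence_start_aa is not None else ''}\t"
                f"{r.altered_run_length_aa if r.altered_run_length_aa is not None else ''}\t"
                f"{r.premature_stop_codon if r.premature_stop_codon is not None else ''}\t"
                f"{r.mutant_protein_length_aa}\t{r.truncation_length_aa}\t"
                f"{','.join(r.domains_lost)}\t{','.join(r.domains_altered)}\t"
                f"{r.functional_class}\n"
            )
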