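"""Cytochrome-P450 domain maps, fuzzy motif search, and domain projection.

A :class:`DomainMap` describes where the conserved P450 features sit on a
reference protein: the six substrate recognition sites (SRS1-6), the
I-helix (inside SRS4), the K-helix with its ExxR motif, the
ERR-triad/PERF region, and the heme-binding motif.  Queries are annotated
by global protein alignment against the reference and interval projection
through the alignment columns, then classified as flavonoid
3'5'-hydroxylase (F3'5'H) or 3'-hydroxylase (F3'H) from the
discriminating SRS6 residue (Ala/Ser versus Thr).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .sequences import ProteinRecord, align_global

HEME_MOTIF = "PFGAGRRICAG"

#: canonical ordering of the P450 features along the sequence
FEATURE_ORDER = (
    "transmembrane", "SRS1", "SRS2", "SRS3", "SRS4", "I-helix",
    "K-helix", "SRS5", "ERR-triad", "heme-binding", "SRS6",
)

PRESENT = "present"
ABSENT = "absent"
TRUNCATED = "truncated"
INTERNAL_DELETION = "internal-deletion"
UNALIGNABLE = "unalignable"

F35H = "F35H"
F3H = "F3H"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class Domain:
    name: str
    start_aa: int
    end_aa: int
    essential: bool
    consensus: str = ""

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.end_aa < self.start_aa:
            raise ValueError(f"{self.name}: bad interval {self.start_aa}-{self.end_aa}")

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start_aa <= end and start <= self.end_aa


class DomainMap:
    """Ordered collection of named domains on one reference protein."""

    def __init__(self, domains: list[Domain]):
        names = [d.name for d in domains]
        if len(set(names)) != len(names):
            raise ValueError("duplicate domain names")
        self.domains = sorted(domains, key=lambda d: (d.start_aa, d.end_aa))
        srs = [d.start_aa for d in self.domains if d.name.startswith("SRS")]
        if srs != sorted(srs):
            raise ValueError("SRS features out of sequence order")

    def __iter__(self):
        return iter(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def __getitem__(self, name: str) -> Domain:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(d.name == name for d in self.domains)

    def essential_names(self) -> list[str]:
        return [d.name for d in self.domains if d.essential]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tstart\tend\tessential\tconsensus\n")
            for d in self.domains:
                fh.write(
                    f"{d.name}\t{d.start_aa}\t{d.end_aa}\t{int(d.essential)}\t{d.consensus}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainMap":
        domains = []
        with open(path) as fh:
            header = fh.readline()
            if not header.lower().startswith("name\t"):
                raise ValueError(f"{path}: not a domain-map TSV")
            for line in fh:
                if not line.strip():
                    continue
                name, start, end, essential, *rest = line.rstrip("\n").split("\t")
                domains.append(
                    Domain(name, int(start), int(end), bool(int(essential)),
                           rest[0] if rest else "")
                )
        return cls(domains)


@dataclass
class DomainStatus:
    """Projection of one reference domain onto a query protein."""

    name: str
    state: str  # present | absent | truncated | internal-deletion | unalignable
    query_start: int | None = None
    query_end: int | None = None
    residues: str = ""  # query residues across the projected interval, '-' at gaps


def find_heme_motif(
    protein: ProteinRecord,
    max_mismatch: int = 2,
    motif: str = HEME_MOTIF,
) -> int | None:
    """Best ungapped match of the heme-binding motif; 1-based start or None.

    Ties are broken leftmost; a protein shorter than the motif yields None
    (it simply cannot carry the site).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    k = len(motif)
    best_pos, best_mm = None, max_mismatch + 1
    seq = protein.residues
    for start in range(len(seq) - k + 1):
        mm = sum(a != b for a, b in zip(seq[start : start + k], motif))
        if mm < best_mm:
            best_pos, best_mm = start + 1, mm
    return best_pos if best_mm <= max_mismatch else None


def project_domains(
    query: ProteinRecord,
    reference: ProteinRecord,
    ref_map: DomainMap,
    min_nterm_identity: float = 0.30,
    nterm_columns: int = 200,
    min_domain_identity: float = 0.30,
) -> dict[str, DomainStatus]:
    """Project every reference domain onto the query through an alignment.

    The query is globally aligned to the reference (BLOSUM62, affine
    gaps); each reference interval is then mapped through the alignment
    columns.  A domain wholly beyond the query's end (e.g. downstream of a
    premature stop) is ``absent``; one cut off by the query's end is
    ``truncated``; one with unaligned reference positions that are flanked
    by aligned query residues is an ``internal-deletion``.  If N-terminal
    identity falls below ``min_nterm_identity`` the query is treated as a
    non-homolog and every domain is ``unalignable``.

    A fully projected domain must still resemble its consensus: below
    ``min_domain_identity`` it is demoted to ``absent``.  This guards
    against frameshift-garbage tails that a global aligner happily smears
    across the C-terminal domains of a truncated protein.
    """
    if not query.residues:
        return {d.name: DomainStatus(d.name, ABSENT) for d in ref_map}
    alignment = align_global(reference.residues, query.residues, kind="aa")
    if alignment.identity(nterm_columns) < min_nterm_identity:
        return {d.name: DomainStatus(d.name, UNALIGNABLE) for d in ref_map}

    ref_to_query = alignment.map_a_to_b()
    last_query_col_ref = max(
        (pa for pa, pb in ref_to_query.items() if pb is not None), default=0
    )
    out: dict[str, DomainStatus] = {}
    for dom in ref_map:
        mapped = [ref_to_query.get(p) for p in range(dom.start_aa, dom.end_aa + 1)]
        residues = "".join(
            query.residues[q - 1] if q is not None else "-" for q in mapped
        )
        present = [q for q in mapped if q is not None]
        if not present:
            out[dom.name] = DomainStatus(dom.name, ABSENT, residues=residues)
            continue
        q_start, q_end = present[0], present[-1]
        if None not in mapped:
            state = PRESENT
            if dom.consensus:
                matched = sum(a == b for a, b in zip(residues, dom.consensus))
                if matched / dom.length < min_domain_identity:
                    state = ABSENT
            out[dom.name] = DomainStatus(dom.name, state, q_start, q_end, residues)
        elif dom.end_aa > last_query_col_ref:
            # the query simply stops inside (or before the end of) the domain
            out[dom.name] = DomainStatus(dom.name, TRUNCATED, q_start, q_end, residues)
        else:
            out[dom.name] = DomainStatus(
                dom.name, INTERNAL_DELETION, q_start, q_end, residues
            )
    return out


def classify_srs6(
    status: dict[str, DomainStatus] | DomainStatus,
    rule_index: int = 8,
) -> tuple[str, str]:
    """F3'5'H / F3'H call from the SRS6 discriminating residue.

    Ala or Ser at the rule position marks a 3'5'-hydroxylase, Thr a
    3'-hydroxylase; a gap, any other residue, or a missing SRS6 yields
    ``unknown``.  Returns ``(class, reason)``.
    """
    srs6 = status["SRS6"] if isinstance(status, dict) else status
    if srs6.state in (ABSENT, UNALIGNABLE, TRUNCATED) and (
        len(srs6.residues.rstrip("-")) < rule_index
    ):
        return UNKNOWN, "domain missing"
    if srs6.state == ABSENT or not srs6.residues:
        return UNKNOWN, "domain missing"
    if rule_index < 1 or rule_index > len(srs6.residues):
        return UNKNOWN, f"rule index {rule_index} outside SRS6"
    residue = srs6.residues[rule_index - 1]
    if residue == "-":
        return UNKNOWN, "gap at rule position"
    if residue in "AS":
        return F35H, f"residue {residue} at SRS6 position {rule_index}"
    if residue == "T":
        return F3H, f"residue T at SRS6 position {rule_index}"
    return UNKNOWN, f"unrecognized residue {residue} at SRS6 position {rule_index}"
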