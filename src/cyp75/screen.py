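"""Rule-based proteome screen for flavonoid 3'5'-hydroxylases.

The screen applies, in order: (1) a fuzzy search for the P450
heme-binding motif PFGAGRRICAG, (2) projection of all essential P450
domains and SRSs onto the query with a completeness check (no deletions
or truncations), and (3) classification from the SRS6 discriminating
residue.  Every intermediate outcome is recorded per protein — nothing
is silently dropped.  Per-domain sequence variability is summarised by
unique-sequence counts and by per-column Shannon information in bits,
the quantity a sequence logo displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import (
    ABSENT,
    DomainMap,
    PRESENT,
    UNKNOWN,
    classify_srs6,
    find_heme_motif,
    project_domains,
)
from .sequences import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(20)


@dataclass
class ScreenRecord:
    protein_id: str
    heme_motif_found: bool
    heme_motif_position: int | None
    domains_complete: bool
    failing_domains: list[str]
    srs6_residue: str  # residue at the rule position, '-' for a gap, '' if missing
    hydroxylase_class: str  # F35H | F3H | unknown
    passed_filter: bool
    domain_residues: dict[str, str]  # projected residue text per domain


def screen_proteome(
    proteins: list[ProteinRecord],
    reference: ProteinRecord,
    ref_map: DomainMap,
    max_mismatch: int = 2,
    rule_index: int = 8,
    essential: list[str] | None = None,
) -> list[ScreenRecord]:
    """Screen a protein set against an annotated reference.

    A protein passes when the heme motif is found, every essential domain
    projects completely (state ``present``), and the SRS6 rule residue
    gives a definite hydroxylase class.
    """
    if essential is None:
        essential = ref_map.essential_names()
    records: list[ScreenRecord] = []
    for protein in proteins:
        heme_pos = find_heme_motif(protein, max_mismatch=max_mismatch)
        status = project_domains(protein, reference, ref_map)
        failing = [
            name for name in essential
            if name in status and status[name].state != PRESENT
        ]
        cls, _reason = classify_srs6(status, rule_index=rule_index)
        srs6 = status.get("SRS6")
        srs6_residue = ""
        if srs6 is not None and len(srs6.residues) >= rule_index and srs6.state != ABSENT:
            srs6_residue = srs6.residues[rule_index - 1]
        records.append(
            ScreenRecord(
                protein_id=protein.id,
                heme_motif_found=heme_pos is not None,
                heme_motif_position=heme_pos,
                domains_complete=not failing,
                failing_domains=failing,
                srs6_residue=srs6_residue,
                hydroxylase_class=cls,
                passed_filter=(heme_pos is not None and not failing and cls != UNKNOWN),
                domain_residues={n: s.residues for n, s in status.items()},
            )
        )
    return records


def unique_domain_sequences(records: list[ScreenRecord], domain: str) -> int:
    """Distinct projected residue texts of one domain among passing records."""
    passing = [r for r in records if r.passed_filter]
    texts = {
        r.domain_residues[domain] for r in passing if domain in r.domain_residues
    }
    if not texts:
        raise ValueError(f"domain {domain!r} absent from every passing record")
    return len(texts)


@dataclass
class LogoMatrix:
    """Per-column residue frequencies and information content (bits)."""

    frequencies: pd.DataFrame  # index: residues, columns: 1-based positions
    information: pd.Series  # bits per column
    gap_fraction: pd.Series
    n: int

    def to_tsv(self, path) -> None:
        rows = []
        for col in self.frequencies.columns:
            for residue in self.frequencies.index:
                freq = self.frequencies.loc[residue, col]
                if freq > 0:
                    rows.append(
                        (col, residue, f"{freq:.6f}", f"{self.information[col]:.4f}")
                    )
        with open(path, "w") as fh:
            fh.write("column\tresidue\tfrequency\tbits\n")
            for col, residue, freq, bits in rows:
                fh.write(f"{col}\t{residue}\t{freq}\t{bits}\n")


def logo_information(
    texts: list[str],
    small_sample_correction: bool = False,
) -> LogoMatrix:
    """Shannon information per column of equal-length aligned texts.

    information = log2(20) - H, with H the entropy of the residue
    frequencies; gaps carry no frequency mass (their fraction is reported
    separately).  The optional small-sample correction subtracts
    e_n = (19 / (2n)) / ln 2, the standard bias term for n sequences.
    """
    if not texts:
        raise ValueError("no sequences supplied")
    width = len(texts[0])
    if any(len(t) != width for t in texts):
        raise ValueError("aligned domain texts must have equal length")
    n = len(texts)
    columns = list(range(1, width + 1))
    freqs = pd.DataFrame(0.0, index=list(AA20), columns=columns)
    gap_fraction = pd.Series(0.0, index=columns)
    info = pd.Series(0.0, index=columns)
    correction = (19.0 / (2.0 * n)) / math.log(2) if small_sample_correction else 0.0
    for j, col in enumerate(columns):
        residues = [t[j] for t in texts]
        gaps = sum(r not in AA20 for r in residues)
        gap_fraction[col] = gaps / n
        observed = [r for r in residues if r in AA20]
        if not observed:
            info[col] = 0.0
            continue
        counts = pd.Series(observed).value_counts()
        p = counts / counts.sum()
        for residue, frac in p.items():
            freqs.loc[residue, col] = frac
        entropy = float(-(p * np.log2(p)).sum())
        info[col] = max(0.0, MAX_BITS - entropy - correction)
    return LogoMatrix(freqs, info, gap_fraction, n)


def screen_to_tsv(records: list[ScreenRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein\theme_motif_found\theme_motif_position\tdomains_complete\t"
            "failing_domains\tsrs6_residue\thydroxylase_class\tpassed_filter\n"
        )
        for r in records:
            fh.write(
                f"{r.protein_id}\t{int(r.heme_motif_found)}\t"
                f"{r.heme_motif_position or ''}\t{int(r.domains_complete)}\t"
                f"{','.join(r.failing_domains)}\t{r.srs6_residue}\t"
                f"{r.hydroxylase_class}\t{int(r.passed_filter)}\n"
            )
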