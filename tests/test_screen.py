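"""Proteome screen cascade and sequence-logo information content."""

import math

import pytest

from cyp75.screen import (
    MAX_BITS,
    logo_information,
    screen_proteome,
    unique_domain_sequences,
)
from cyp75.sequences import CodingSequence, ProteinRecord, translate
from cyp75.variants import FRAMESHIFT


class TestScreenProteome:
    def test_reference_passes_its_own_screen(self, ref_protein, domain_map):
        (record,) = screen_proteome([ref_protein], ref_protein, domain_map)
        assert record.passed_filter
        assert record.hydroxylase_class == "F35H"
        assert record.heme_motif_position == 460

    def test_srs6_thr_variant_passes_as_f3h(self, ref_protein, domain_map):
        residues = list(ref_protein.residues)
        residues[493] = "T"
        query = ProteinRecord("f3h", "".join(residues))
        (record,) = screen_proteome([query], ref_protein, domain_map)
        assert record.passed_filter
        assert record.hydroxylase_class == "F3H"

    def test_truncated_ui111_protein_fails(self, ref_protein, domain_map, panel_by_id):
        protein = translate(panel_by_id["v_UI111"])
        (record,) = screen_proteome([protein], ref_protein, domain_map)
        assert not record.domains_complete
        assert {"heme-binding", "SRS6"} <= set(record.failing_domains)
        assert not record.passed_filter

    def test_frameshifted_haplotypes_fail_completeness(
        self, reference, ref_protein, domain_map, paper_panel
    ):
        from cyp75.variants import predict_consequence

        panel, _ = paper_panel
        for hap in panel:
            report = predict_consequence(hap, reference, domain_map)
            (record,) = screen_proteome([translate(hap)], ref_protein, domain_map)
            if FRAMESHIFT in report.variant_classes:
                assert not record.domains_complete, hap.id
            if hap.id == "v_G2858":  # in-frame deletion inside the heme motif
                assert not record.domains_complete
            if hap.id in ("V_5-593", "vlae_V0491"):
                assert record.domains_complete, hap.id

    def test_relaxing_filter_is_monotone(self, ref_protein, domain_map, paper_panel):
        panel, _ = paper_panel
        proteins = [translate(hap) for hap in panel]
        strict = screen_proteome(
            proteins, ref_protein, domain_map, max_mismatch=0
        )
        loose = screen_proteome(
            proteins, ref_protein, domain_map, max_mismatch=2
        )
        no_srs6 = screen_proteome(
            proteins, ref_protein, domain_map, max_mismatch=2,
            essential=[n for n in domain_map.essential_names() if n != "heme-binding"],
        )
        n_strict = sum(r.passed_filter for r in strict)
        n_loose = sum(r.passed_filter for r in loose)
        n_no_heme = sum(r.passed_filter for r in no_srs6)
        assert n_strict <= n_loose
        assert n_loose <= n_no_heme


class TestUniqueDomainSequences:
    def test_identical_proteins_count_once(self, ref_protein, domain_map):
        records = screen_proteome([ref_protein] * 5, ref_protein, domain_map)
        assert unique_domain_sequences(records, "SRS1") == 1

    def test_planted_srs1_variants_counted(self, ref_protein, domain_map):
        proteins = []
        for i in range(10):
            residues = list(ref_protein.residues)
            # three planted SRS1 alleles (positions 111/112 inside SRS1)
            if i % 3 == 1:
                residues[110] = "Q"
            elif i % 3 == 2:
                residues[111] = "K"
            proteins.append(ProteinRecord(f"p{i}", "".join(residues)))
        records = screen_proteome(proteins, ref_protein, domain_map)
        assert all(r.passed_filter for r in records)
        assert unique_domain_sequences(records, "SRS1") == 3

    def test_absent_domain_errors(self, ref_protein, domain_map):
        records = screen_proteome([ref_protein], ref_protein, domain_map)
        with pytest.raises(ValueError):
            unique_domain_sequences(records, "SRS9")


class TestLogoInformation:
    def test_invariant_column_is_full_bits(self):
        logo = logo_information(["A", "A", "A", "A"])
        assert logo.information[1] == pytest.approx(math.log2(20))

    def test_uniform_column_is_zero_bits(self):
        logo = logo_information(list("ACDEFGHIKLMNPQRSTVWY"))
        assert logo.information[1] == pytest.approx(0.0, abs=1e-12)

    def test_fifty_fifty_column(self):
        logo = logo_information(["A", "A", "C", "C"])
        assert logo.information[1] == pytest.approx(math.log2(20) - 1)

    def test_frequencies_sum_to_one(self):
        logo = logo_information(["AC", "AD", "CC", "AD"])
        for col in logo.frequencies.columns:
            assert logo.frequencies[col].sum() == pytest.approx(1.0, abs=1e-9)
        assert logo.information.between(0, MAX_BITS).all()

    def test_invariant_to_relabelling_and_column_order(self):
        texts = ["AC", "AD", "CC"]
        relabelled = [t.translate(str.maketrans("ACD", "WYH")) for t in texts]
        swapped = [t[::-1] for t in texts]
        base = logo_information(texts).information
        assert logo_information(relabelled).information.tolist() == pytest.approx(
            base.tolist()
        )
        assert logo_information(swapped).information.tolist() == pytest.approx(
            base.tolist()[::-1]
        )

    def test_gaps_carry_no_frequency_mass(self):
        logo = logo_information(["A-", "A-", "AC"])
        assert logo.gap_fraction[2] == pytest.approx(2 / 3)
        assert logo.frequencies[2].sum() == pytest.approx(1.0)
        assert logo.information[1] == pytest.approx(math.log2(20))

    def test_small_sample_correction_reduces_information(self):
        plain = logo_information(["A"] * 4).information[1]
        corrected = logo_information(
            ["A"] * 4, small_sample_correction=True
        ).information[1]
        assert corrected == pytest.approx(plain - (19 / 8) / math.log(2))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            logo_information([])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            logo_information(["AC", "A"])
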