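"""Variant calling against the reference and protein-consequence prediction."""

import random

import pytest

from cyp75.sequences import CodingSequence
from cyp75.simulate import make_random_panel
from cyp75.variants import (
    DELETION,
    FRAMESHIFT,
    FUNCTIONAL,
    IMPAIRED,
    INSERTION,
    NULL,
    SNP,
    NotComparableError,
    call_variants,
    predict_consequence,
)


class TestCallVariants:
    def test_identical_sequences_yield_no_calls(self, reference):
        assert call_variants(reference, reference) == []

    def test_g19833_seven_snps_one_c_insertion(self, reference, panel_by_id):
        calls = call_variants(panel_by_id["v_G19833"], reference)
        kinds = [v.kind for v in calls]
        assert kinds.count(SNP) == 7
        assert kinds.count(INSERTION) == 1
        ins = next(v for v in calls if v.kind == INSERTION)
        assert ins.alt_allele == "C" and ins.length == 1
        assert 1072 <= ins.cds_position <= 1074  # inside codon 358

    def test_v0491_two_snps(self, reference, panel_by_id):
        calls = call_variants(panel_by_id["vlae_V0491"], reference)
        assert [v.kind for v in calls] == [SNP, SNP]
        assert {v.cds_position for v in calls} == {501, 1283}

    def test_mex235_single_14nt_deletion(self, reference, panel_by_id):
        calls = call_variants(panel_by_id["v_Mex235"], reference)
        assert len(calls) == 1
        (deletion,) = calls
        assert deletion.kind == DELETION
        assert deletion.length == 14
        assert deletion.cds_position == 1245

    def test_m0056_one_snp_plus_deletion(self, reference, panel_by_id):
        calls = call_variants(panel_by_id["v_M0056"], reference)
        assert sorted(v.kind for v in calls) == [SNP, DELETION]
        deletion = next(v for v in calls if v.kind == DELETION)
        assert (deletion.cds_position, deletion.length) == (1245, 14)

    def test_hand_built_deletion(self, reference):
        nt = reference.nucleotides
        edited = CodingSequence("edit", nt[:1245] + nt[1259:])
        (deletion,) = call_variants(edited, reference)
        assert (deletion.kind, deletion.cds_position, deletion.length) == (
            DELETION, 1245, 14,
        )

    def test_unrelated_sequence_not_comparable(self, reference):
        rng = random.Random(0)
        junk = "".join(rng.choice("ACGT") for _ in range(1500))
        with pytest.raises(NotComparableError):
            call_variants(CodingSequence("junk", junk), reference)


class TestPredictConsequence:
    def test_reference_report_is_all_clear(self, reference, domain_map):
        report = predict_consequence(reference, reference, domain_map)
        assert report.variants == []
        assert report.premature_stop_codon is None
        assert report.truncation_length_aa == 0
        assert report.domains_lost == []
        assert report.functional_class == FUNCTIONAL

    def test_g19833_frameshift_arithmetic(self, reference, domain_map, panel_by_id):
        report = predict_consequence(panel_by_id["v_G19833"], reference, domain_map)
        assert report.divergence_start_aa == 358
        assert report.altered_run_length_aa == 28
        assert report.mutant_protein_length_aa == 385
        assert report.truncation_length_aa == 125
        assert set(report.domains_lost) == {
            "K-helix", "SRS5", "ERR-triad", "heme-binding", "SRS6",
        }

    def test_ui111_stop_sixteen_codons_downstream(
        self, reference, domain_map, panel_by_id
    ):
        report = predict_consequence(panel_by_id["v_UI111"], reference, domain_map)
        assert report.divergence_start_aa == 441
        assert report.premature_stop_codon == 457
        assert report.premature_stop_codon - report.divergence_start_aa == 16
        assert set(report.domains_lost) == {"heme-binding", "SRS6"}

    def test_mex235_fourteen_altered_residues_from_416(
        self, reference, domain_map, panel_by_id
    ):
        report = predict_consequence(panel_by_id["v_Mex235"], reference, domain_map)
        assert report.divergence_start_aa == 416
        assert report.altered_run_length_aa == 14
        assert "ERR-triad" in report.domains_altered
        assert set(report.domains_lost) == {"heme-binding", "SRS6"}

    def test_v0491_is_impaired_by_r428m(self, reference, domain_map, panel_by_id):
        report = predict_consequence(panel_by_id["vlae_V0491"], reference, domain_map)
        assert (428, "R", "M") in report.missense_changes
        assert report.functional_class == IMPAIRED

    def test_mdrk_compound_takes_most_severe_class(
        self, reference, domain_map, panel_by_id
    ):
        # MDRK carries V0491's R428M *and* a frameshifting insertion
        report = predict_consequence(panel_by_id["vlae_MDRK"], reference, domain_map)
        assert (428, "R", "M") in report.missense_changes
        assert report.functional_class == NULL

    def test_g2858_inframe_deletion_is_null(self, reference, domain_map, panel_by_id):
        report = predict_consequence(panel_by_id["v_G2858"], reference, domain_map)
        assert report.premature_stop_codon is None
        assert report.domains_lost == ["heme-binding"]
        assert report.functional_class == NULL

    def test_panel_class_tally(self, reference, domain_map, paper_panel):
        panel, _ = paper_panel
        classes = [
            predict_consequence(hap, reference, domain_map).functional_class
            for hap in panel
        ]
        assert classes.count(FUNCTIONAL) == 1
        assert classes.count(IMPAIRED) == 1
        assert classes.count(NULL) == 7


@pytest.fixture(scope="module")
def recovered(reference, domain_map):
    out = []
    for seed in (0, 1):
        panel, truth = make_random_panel(50, seed=seed)
        for hap in panel:
            report = predict_consequence(hap, reference, domain_map)
            out.append((truth[hap.id], report))
    return out


class TestRandomPanelProperties:
    def test_planted_edits_recovered(self, recovered):
        hits = sum(
            [v.as_tuple() for v in report.variants] == rec.expected_variants
            for rec, report in recovered
        )
        assert hits / len(recovered) >= 0.99

    def test_planted_class_recovered(self, recovered):
        hits = sum(
            report.functional_class == rec.functional_class
            for rec, report in recovered
        )
        assert hits / len(recovered) >= 0.99

    def test_frameshift_class_iff_length_not_multiple_of_three(self, recovered):
        for _, report in recovered:
            for v, cls in zip(report.variants, report.variant_classes):
                if v.kind in (INSERTION, DELETION):
                    assert (cls == FRAMESHIFT) == (v.length % 3 != 0)

    def test_truncation_plus_mutant_length_is_reference_length(
        self, recovered, ref_protein
    ):
        for _, report in recovered:
            if report.premature_stop_codon is not None:
                assert (
                    report.mutant_protein_length_aa + report.truncation_length_aa
                    == len(ref_protein)
                )
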