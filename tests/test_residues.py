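"""Residue mapping, F/P enzyme calls, and genotype-to-chemotype prediction."""

import io

import pytest

from acylsugar import synth
from acylsugar.pathway import ActivityProfile
from acylsugar.residues import (
    NotHomologError,
    classify_asat2,
    classify_asat3,
    classify_sequence,
    map_positions,
    parse_family,
    percent_identity,
    predict_phenotype,
)


class TestMapPositions:
    def test_reference_maps_to_itself(self, fixtures, asat2_scheme):
        assert map_positions(fixtures["Sl-ASAT2-like"], asat2_scheme) == {
            135: "Q", 136: "Y", 304: "C"
        }

    def test_sp_asat2_letters(self, fixtures, asat2_scheme):
        assert map_positions(fixtures["Sp-ASAT2-like"], asat2_scheme) == {
            135: "H", 136: "C", 304: "G"
        }

    def test_sp_asat3_deletion_dialect(self, fixtures, asat3_scheme):
        """The P-type ASAT3 carries Val at the 354 site and Ser plus a
        one-residue deletion in the 381/382 window."""
        residues = map_positions(fixtures["Sp-ASAT3-like"], asat3_scheme)
        assert residues[161], residues[162] == ("H", "S")
        assert residues[289] == "V"
        assert residues[354] == "V"
        assert sorted((residues[381], residues[382])) == ["-", "S"]

    def test_single_site_mutation_leaves_other_sites_fixed(self, fixtures, asat2_scheme):
        mutant = synth.apply_mutations(fixtures["Sl-ASAT2-like"], {304: "G"})
        assert map_positions(mutant, asat2_scheme) == {135: "Q", 136: "Y", 304: "G"}

    def test_short_query_rejected(self, asat2_scheme):
        with pytest.raises(ValueError, match="length guard"):
            map_positions("ACDEFGHIKL" * 10, asat2_scheme)

    def test_non_homolog_rejected(self, fixtures, asat2_scheme):
        reversed_seq = fixtures["Sl-ASAT2-like"][::-1]
        with pytest.raises(NotHomologError):
            map_positions(reversed_seq, asat2_scheme)


class TestPercentIdentity:
    def test_identical_sequences(self, fixtures):
        assert percent_identity(
            fixtures["Sl-ASAT2-like"], fixtures["Sl-ASAT2-like"]
        ) == 100.0

    def test_ortholog_fixtures_exceed_92(self, fixtures):
        assert percent_identity(fixtures["Sl-ASAT2-like"], fixtures["Sp-ASAT2-like"]) > 92
        assert percent_identity(fixtures["Sl-ASAT3-like"], fixtures["Sp-ASAT3-like"]) > 92

    def test_reversed_sequence_far_below_homolog_floor(self, fixtures):
        seq = fixtures["Sl-ASAT2-like"]
        assert percent_identity(seq, seq[::-1]) < 40

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "ACDEF")


class TestClassifyASAT2:
    @pytest.mark.parametrize(
        "letters,has_F,has_P",
        [
            (("Q", "Y", "C"), True, False),   # cultivated tomato
            (("H", "C", "G"), False, True),   # S. pennellii LA0716 dialect
            (("Q", "Y", "G"), True, True),    # natural hybrid
            (("P", "C", "G"), False, True),   # LA1926 dialect
            (("H", "C", "C"), False, False),  # no activity-associated residues
        ],
    )
    def test_rule_rows(self, letters, has_F, has_P):
        call = classify_asat2(dict(zip((135, 136, 304), letters)))
        assert (call.profile.has_F, call.profile.has_P) == (has_F, has_P)
        assert not call.exception_flag

    def test_single_f_residue_is_not_enough(self):
        # both Q135 and Y136 are needed for the F call
        assert not classify_asat2({135: "Q", 136: "C", 304: "C"}).profile.has_F
        assert not classify_asat2({135: "H", 136: "Y", 304: "C"}).profile.has_F

    def test_unknown_letter_sets_exception_flag(self):
        call = classify_asat2({135: "W", 136: "Y", 304: "C"})
        assert call.exception_flag

    def test_missing_position_rejected(self):
        with pytest.raises(ValueError):
            classify_asat2({135: "Q", 136: "Y"})


class TestClassifyASAT3:
    @pytest.mark.parametrize(
        "letters,has_F,has_P",
        [
            (("Y", "C", "T", "L", "H", "P"), True, False),   # Sl-ASAT3
            (("H", "S", "V", "V", "-", "S"), False, True),   # Sp deletion dialect
            (("H", "S", "V", "V", "S", "-"), False, True),   # same, other gap rendering
            (("H", "S", "V", "L", "H", "P"), True, True),    # P-triad into Sl: hybrid
            (("Y", "C", "T", "V", "-", "S"), False, False),  # neither triad: dead
        ],
    )
    def test_rule_rows(self, letters, has_F, has_P):
        call = classify_asat3(dict(zip((161, 162, 289, 354, 381, 382), letters)))
        assert (call.profile.has_F, call.profile.has_P) == (has_F, has_P)

    @pytest.mark.parametrize(
        "letters", [("H", "C", "T"), ("H", "S", "T"), ("Y", "S", "V")]
    )
    def test_partial_p_triad_is_weak_evidence_only(self, letters):
        residues = dict(zip((161, 162, 289), letters))
        residues.update({354: "L", 381: "H", 382: "P"})
        call = classify_asat3(residues)
        assert not call.profile.has_P
        assert "weak-P" in call.evidence["P-rule"]

    def test_known_exception_list_flags_sequence(self):
        residues = dict(zip((161, 162, 289, 354, 381, 382), "HSVLHP"))
        call = classify_asat3(residues, known_exceptions=["odd1"], sequence_id="odd1")
        assert call.exception_flag
        call = classify_asat3(residues, known_exceptions=["odd1"], sequence_id="fine")
        assert not call.exception_flag


class TestActivityPanel:
    @pytest.mark.parametrize(
        "entry", synth.activity_panel(), ids=lambda e: e.name
    )
    def test_sequence_level_calls_match_planted_activities(self, entry):
        call = classify_sequence(entry.sequence, entry.family, sequence_id=entry.name)
        assert call.profile == entry.expected
        assert not call.exception_flag

    def test_c304g_gain_commutes_with_classification(self, fixtures):
        """The promiscuity gain: C304G flips has_P on while leaving has_F."""
        before = classify_sequence(fixtures["Sl-ASAT2-like"], "ASAT2")
        mutant = synth.apply_mutations(fixtures["Sl-ASAT2-like"], {304: "G"})
        after = classify_sequence(mutant, "ASAT2")
        assert (before.profile.has_F, before.profile.has_P) == (True, False)
        assert (after.profile.has_F, after.profile.has_P) == (True, True)


class TestVariantRecovery:
    def test_planted_profiles_recovered_under_background_noise(self):
        """200 seeded variants with <= 8% background substitutions away from
        diagnostic sites: classification recovers every planted profile."""
        n_trials = 0
        for family in ("ASAT2", "ASAT3"):
            for profile in ("F", "P", "hybrid", "dead"):
                indel = family == "ASAT3" and profile == "P"
                sc = synth.SequenceScenario(
                    family, profile,
                    background_rate=0.08,
                    indel_near_381=indel,
                    n_variants=25,
                    seed=1,
                )
                variants, truth = synth.generate_variants(sc)
                for (vid, seq), (_, row) in zip(variants, truth.iterrows()):
                    call = classify_sequence(seq, family, sequence_id=vid)
                    assert call.profile == ActivityProfile(row.has_F, row.has_P), vid
                    n_trials += 1
        assert n_trials == 200


class TestPredictPhenotype:
    def test_header_family_parsing(self):
        assert parse_family("plant1|ASAT2|allele1") == "ASAT2"
        assert parse_family("x|ASAT3|y extra words") == "ASAT3"
        assert parse_family("seq9", family_map={"seq9": "ASAT2"}) == "ASAT2"
        with pytest.raises(ValueError):
            parse_family("anonymous_sequence")

    def test_multi_allele_plant_unions_to_both_types(self, fixtures):
        """A plant carrying hybrid+F ASAT2 alleles and both ASAT3 alleles
        (the S. habrochaites pattern) is called F+P."""
        hybrid2 = synth.apply_mutations(fixtures["Sl-ASAT2-like"], {304: "G"})
        fasta = io.StringIO(
            f">sh|ASAT2|a1\n{hybrid2}\n"
            f">sh|ASAT2|a2\n{fixtures['Sl-ASAT2-like']}\n"
            f">sh|ASAT3|f\n{fixtures['Sl-ASAT3-like']}\n"
            f">sh|ASAT3|p\n{fixtures['Sp-ASAT3-like']}\n"
        )
        df = predict_phenotype(fasta)
        assert set(df.plant_phenotype) == {"FP"}
        assert len(df) == 4

    def test_plant_without_both_families_rejected(self, fixtures):
        fasta = io.StringIO(f">p1|ASAT2|only\n{fixtures['Sl-ASAT2-like']}\n")
        with pytest.raises(ValueError, match="at least one"):
            predict_phenotype(fasta)

    def test_report_records_alignment_parameters(self, fixtures):
        fasta = io.StringIO(
            f">p1|ASAT2|a\n{fixtures['Sl-ASAT2-like']}\n"
            f">p1|ASAT3|b\n{fixtures['Sl-ASAT3-like']}\n"
        )
        df = predict_phenotype(fasta)
        assert df.attrs["alignment"]["matrix"] == "BLOSUM62"
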