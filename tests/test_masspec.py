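"""Formula arithmetic, exact ion masses, CID prediction, and annotation.

The independent mass oracle is pyteomics' isotope table; the package's own
mass table must agree with it, and with the study's printed calcd adduct
masses, to 4 decimal places.
"""

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pyteomics_mass

from acylsugar.model import AcylSucrose, parse_annotation
from acylsugar.masspec import (
    ADDUCTS,
    CompositionOnlyError,
    DEFAULT_CHAIN_LENGTHS,
    DEFAULT_MAX_CHAINS,
    ElementalFormula,
    FormulaError,
    Peak,
    adduct_mz,
    annotate_peaklist,
    carboxylate_formula,
    chain_increment,
    enumerate_compositions,
    infer_composition,
    infer_ring_distribution,
    molecular_formula,
    monoisotopic_mass,
    ppm_error,
    predict_fragments,
    read_peaklist,
    write_peaklist,
)


def oracle_mass(f: ElementalFormula) -> float:
    """Independent monoisotopic mass: pyteomics isotope table + electron."""
    neutral = pyteomics_mass.calculate_mass(
        composition={"C": f.c, "H": f.h, "O": f.o, "Na": f.na}
    )
    return neutral - f.charge * 0.00054858


class TestFormulaArithmetic:
    def test_addition_is_elementwise(self):
        assert ElementalFormula(1, 2, 3) + ElementalFormula(4, 5, 6) == ElementalFormula(5, 7, 9)

    def test_subtraction_below_zero_errors(self):
        with pytest.raises(FormulaError):
            ElementalFormula(1, 0, 0) - ElementalFormula(0, 1, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.integers(0, 60)] * 3),
        st.tuples(*[st.integers(0, 60)] * 3),
    )
    def test_mass_is_additive_on_neutrals(self, a, b):
        fa, fb = ElementalFormula(*a), ElementalFormula(*b)
        assert monoisotopic_mass(fa + fb) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
        )


class TestMolecularFormula:
    @pytest.mark.parametrize(
        "annotation,expected",
        [
            ("S2:10 (5, 5)", ElementalFormula(22, 38, 13)),
            ("S3:22 (5, 5, 12)", ElementalFormula(34, 60, 14)),
            ("S3:15 (5R2, 5R3, 5R4)", ElementalFormula(27, 46, 14)),
            ("S0:0", ElementalFormula(12, 22, 11)),  # bare sucrose
        ],
    )
    def test_acylation_adds_cnh2n2o_per_chain(self, annotation, expected):
        assert molecular_formula(parse_annotation(annotation)) == expected

    def test_formula_works_from_bare_counts(self):
        # only chain count and total carbons are needed
        assert molecular_formula(parse_annotation("S3:22")) == ElementalFormula(34, 60, 14)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            (ElementalFormula(23, 39, 15, charge=-1), 555.2294),
            (ElementalFormula(28, 47, 16, charge=-1), 639.2870),
            (ElementalFormula(35, 61, 16, charge=-1), 737.3965),
            (ElementalFormula(0, 2, 1), 18.0106),
        ],
    )
    def test_printed_and_derived_values(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(0, 60), st.integers(0, 100), st.integers(0, 30),
        st.sampled_from([-1, 0, 1]),
    )
    def test_agrees_with_pyteomics_oracle(self, c, h, o, charge):
        f = ElementalFormula(c, h, o, charge=charge)
        assert monoisotopic_mass(f) == pytest.approx(oracle_mass(f), abs=1e-6)


class TestAdducts:
    @pytest.mark.parametrize(
        "formula,adduct,expected",
        [
            (ElementalFormula(34, 60, 14), "M+formate", 737.3965),
            (ElementalFormula(12, 22, 11), "M+formate", 387.1144),
            (ElementalFormula(22, 38, 13), "M-H", 509.2240),
        ],
    )
    def test_known_adduct_mzs(self, formula, adduct, expected):
        assert adduct_mz(formula, adduct) == pytest.approx(expected, abs=5e-5)

    def test_every_adduct_agrees_with_oracle(self):
        f = ElementalFormula(22, 38, 13)
        for name, ad in ADDUCTS.items():
            if name == "M-H":
                ion = (f - ElementalFormula(h=1)).replace_charge(-1)
            else:
                ion = (f + ad.delta).replace_charge(ad.charge)
            assert adduct_mz(f, name) == pytest.approx(oracle_mass(ion), abs=1e-6)

    def test_deprotonation_of_hydrogen_free_formula_errors(self):
        with pytest.raises(FormulaError):
            adduct_mz(ElementalFormula(c=1), "M-H")

    def test_charged_input_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(ElementalFormula(1, 1, 1, charge=-1), "M+formate")

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(ElementalFormula(1, 4, 0), "M+X")


class TestFragments:
    def test_negative_mode_carboxylates_by_distinct_length(self):
        frags = predict_fragments(parse_annotation("S3:22 (5R2, 12R3, 5R4)"), "negative")
        by_label = {f.label: f for f in frags}
        assert set(by_label) == {"carboxylate-C5", "carboxylate-C12"}
        assert by_label["carboxylate-C5"].multiplicity == 2
        assert by_label["carboxylate-C5"].mz == pytest.approx(101.0608, abs=5e-5)
        assert by_label["carboxylate-C12"].mz == pytest.approx(199.1704, abs=5e-5)

    def test_sucrose_has_no_fragments(self):
        assert predict_fragments(AcylSucrose.sucrose(), "negative") == []

    def test_positive_mode_splits_chains_by_ring(self):
        p_type = parse_annotation("S3:15 (5R2, 5R3, 5R4)")
        frags = {f.label: f for f in predict_fragments(p_type, "positive")}
        pyr, fur = frags["pyranose+3chains"], frags["furanose+0chains"]
        # all three chain increments on the pyranose fragment, bare furanose core
        assert pyr.formula.c == 6 + 15
        assert fur.formula.c == 6
        f_type = parse_annotation("S3:15 (aiC5R3, iC5R4, iC5R3p)")
        labels = {f.label for f in predict_fragments(f_type, "positive")}
        assert labels == {"pyranose+2chains", "furanose+1chains"}

    def test_positive_mode_needs_placements(self):
        with pytest.raises(CompositionOnlyError):
            predict_fragments(parse_annotation("S3:15 (5,5,5)"), "positive")

    def test_carboxylate_oracle(self):
        for n in (2, 4, 5, 10, 12):
            f = carboxylate_formula(n)
            assert monoisotopic_mass(f) == pytest.approx(oracle_mass(f), abs=1e-6)


class TestInferComposition:
    def test_found_precursor_masses_recover_study_compositions(self):
        # observed ("found") masses, not the calcd ones
        hits = infer_composition(555.2273, [101.061])
        assert hits[0].candidate.composition_only == (5, 5)
        hits = infer_composition(737.3952, [101.061, 199.170])
        assert hits[0].candidate.composition_only == (5, 5, 12)

    def test_out_of_space_precursor_gives_empty_list(self):
        assert infer_composition(1000.0, [], tol_ppm=5) == []

    def test_carboxylate_outside_candidate_excludes_it(self):
        hits = infer_composition(555.2273, [199.170])  # C12 cannot fit S2:10
        assert all(h.candidate.composition_only != (5, 5) for h in hits)

    def test_exact_inverse_of_adduct_mz_over_candidate_space(self):
        """Brute-force oracle: every composition in the bounded space is
        recovered rank-1 from its own noise-free formate precursor."""
        for comp in enumerate_compositions(DEFAULT_MAX_CHAINS, DEFAULT_CHAIN_LENGTHS):
            cand = AcylSucrose.from_composition(comp)
            mz = adduct_mz(molecular_formula(cand), "M+formate")
            carbs = [f.mz for f in predict_fragments(cand, "negative")]
            hits = infer_composition(mz, carbs, tol_ppm=10)
            assert hits, comp
            assert hits[0].candidate.composition_only == comp
            assert abs(hits[0].ppm) < 1e-6

    def test_rejects_nonpositive_tolerance(self):
        with pytest.raises(ValueError):
            infer_composition(555.0, [], tol_ppm=0)


class TestInferRingDistribution:
    def test_all_pyranose_split_is_unique(self):
        cand = parse_annotation("S3:15 (5,5,5)")
        frags = [f.mz for f in predict_fragments(parse_annotation("S3:15 (5R2, 5R3, 5R4)"), "positive")]
        rd = infer_ring_distribution(frags, cand)
        assert rd.unique is not None
        assert rd.unique.pyranose == (5, 5, 5) and rd.unique.furanose == ()

    def test_f_type_split_is_unique(self):
        cand = parse_annotation("S3:15 (5,5,5)")
        frags = [f.mz for f in predict_fragments(parse_annotation("S3:15 (5R3, 5R4, 5R3p)"), "positive")]
        rd = infer_ring_distribution(frags, cand)
        assert rd.unique == type(rd.unique)((5, 5), (5,))

    def test_no_fragments_is_ambiguous_over_all_splits(self):
        rd = infer_ring_distribution([], parse_annotation("S3:15 (5,5,5)"))
        assert rd.ambiguous
        assert len(rd.splits) == 4  # 0..3 C5 chains on the furanose ring


class TestAnnotatePeaklist:
    def test_exact_peak_annotated_at_zero_ppm(self):
        peaks = [Peak(555.2294, 100.0, "negative")]
        res = annotate_peaklist(peaks, [parse_annotation("S2:10 (5,5)")], tol_ppm=5)
        precursors = [a for a in res.annotations if a.role == "precursor"]
        assert len(precursors) == 1
        # the peak sits at the printed 4-d.p. value, so the residual error is
        # the rounding of the last decimal (< 0.1 ppm)
        assert precursors[0].ppm == pytest.approx(0.0, abs=0.1)
        assert not res.unmatched

    def test_internal_standard_only_list_yields_nothing(self):
        # propyl 4-hydroxybenzoate [M-H]- region, no acylsugar candidate matches
        peaks = [Peak(179.0714, 500.0, "negative")]
        res = annotate_peaklist(peaks, [parse_annotation("S2:10 (5,5)")], tol_ppm=10)
        assert res.annotations == []
        assert len(res.unmatched) == 1

    def test_all_annotations_respect_tolerance(self):
        peaks = [
            Peak(555.2294 * (1 + d * 1e-6), 10.0, "negative") for d in (-12, -4, 0, 4, 12)
        ]
        res = annotate_peaklist(peaks, [parse_annotation("S2:10 (5,5)")], tol_ppm=5)
        assert all(abs(a.ppm) <= 5 for a in res.annotations)
        assert len([a for a in res.annotations if a.role == "precursor"]) == 3

    def test_empty_peaklist_rejected(self):
        with pytest.raises(ValueError):
            annotate_peaklist([], [parse_annotation("S2:10 (5,5)")])


class TestPeaklistIO:
    def test_round_trip(self, tmp_path):
        peaks = [
            Peak(555.2294, 100.0, "negative", 3.2),
            Peak(101.0608, 40.0, "negative", 3.2),
        ]
        path = tmp_path / "peaks.tsv"
        write_peaklist(peaks, path)
        back = read_peaklist(path)
        assert [(p.mz, p.intensity, p.polarity, p.rt) for p in back] == [
            (p.mz, p.intensity, p.polarity, p.rt) for p in peaks
        ]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("mz\tintensity\n100.0\t1.0\n")
        with pytest.raises(ValueError, match="polarity"):
            read_peaklist(path)
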