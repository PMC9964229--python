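"""Mass-annotation arithmetic: pinned monoisotopic masses, adduct m/z,
ppm/mDa errors, exhaustive formula matching, and library identification."""

import warnings

import pytest
from hypothesis import given
from hypothesis import strategies as st

from climflav.msannotate import (
    PROTON_MASS,
    MolecularFormula,
    RawPeak,
    UnsupportedElementError,
    adduct_mz,
    annotate_peak,
    load_reference_library,
    mass_error,
    match_formula,
    monoisotopic_mass,
    neutral_loss_mz,
    read_peak_table,
)


class TestMonoisotopicMass:
    def test_carbon_is_exactly_twelve(self):
        assert monoisotopic_mass("C") == 12.0

    def test_flavonol_glycoside_mass(self):
        assert round(monoisotopic_mass("C21H20O12"), 5) == 464.09548

    def test_additivity(self):
        a = monoisotopic_mass("C10H10O5") + monoisotopic_mass("C11H10O7")
        assert a == pytest.approx(monoisotopic_mass("C21H20O12"), abs=1e-12)

    def test_unknown_element_rejected(self):
        with pytest.raises(UnsupportedElementError):
            monoisotopic_mass("C2H5Br")

    def test_cross_check_against_pyteomics(self):
        # independent oracle: pyteomics' own monoisotopic mass table
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for f in ("C27H30O16", "C21H20O12", "C7H6O4", "C28H32O13"):
            assert monoisotopic_mass(f) == pytest.approx(
                pyteomics_mass.calculate_mass(formula=f), abs=5e-5
            )


# Printed deprotonated-ion values the theoretical arithmetic must reproduce
# at the printed number of decimals.
PRINTED_MH = [
    ("C7H6O4", 153.0193),
    ("C32H36O16", 675.1931),
    ("C16H16O8", 335.0772),
    ("C18H26O8", 369.1555),
    ("C21H20O12", 463.0882),
    ("C27H30O16", 609.1461),
    ("C33H48O16", 699.287),
    ("C21H20O11", 447.0933),
    ("C28H32O13", 575.177),
    ("C30H26O14", 609.125),
    ("C20H36O12", 467.2134),
    ("C28H46O8", 509.312),
]


class TestAdductMz:
    @pytest.mark.parametrize("formula, printed", PRINTED_MH)
    def test_deprotonated_ion_reproduces_printed_values(self, formula, printed):
        ndec = len(str(printed).split(".")[1])
        assert round(adduct_mz(formula, "[M-H]-"), ndec) == printed

    def test_deprotonated_dimer(self):
        assert round(adduct_mz("C21H20O12", "[2M-H]-"), 4) == 927.1837

    def test_dimer_identity_exact(self):
        m = monoisotopic_mass("C27H30O16")
        assert adduct_mz("C27H30O16", "[2M-H]-") == 2 * m - PROTON_MASS

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValueError, match="adduct"):
            adduct_mz("C7H6O4", "[M+Na]+")


class TestMassError:
    def test_identity_is_zero(self):
        e = mass_error(609.1461, 609.1461)
        assert e.ppm == 0.0 and e.mda == 0.0

    def test_hand_arithmetic(self):
        e = mass_error(609.14671, 609.1461)
        assert e.ppm == pytest.approx(1.0, abs=0.01)
        assert e.mda == pytest.approx(0.61, abs=0.001)

    def test_antisymmetry(self):
        a = mass_error(447.0933, 447.0910)
        b = mass_error(447.0910, 447.0933)
        assert a.ppm == pytest.approx(-b.ppm * (447.0933 / 447.0910), rel=1e-6)
        assert a.mda == -b.mda

    @given(st.floats(100.0, 1000.0), st.floats(-0.01, 0.01))
    def test_internal_consistency(self, theo, delta):
        e = mass_error(theo + delta, theo)
        assert e.mda == pytest.approx(e.ppm * theo / 1000.0, rel=1e-9, abs=1e-12)

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            mass_error(100.0, 0.0)


class TestMatchFormula:
    def test_rutin_is_top_candidate(self):
        cands = match_formula(609.1461, "[M-H]-", tol_ppm=5.0)
        assert str(cands[0].formula) == "C27H30O16"

    def test_protocatechuate_contained(self):
        cands = match_formula(153.0193, "[M-H]-", tol_ppm=5.0)
        assert "C7H6O4" in {str(c.formula) for c in cands}

    def test_vanishing_tolerance_gives_empty_list(self):
        assert match_formula(609.1461 + 0.01, "[M-H]-", tol_ppm=1e-4) == []

    def test_oversized_search_space_rejected(self):
        with pytest.raises(ValueError, match="combinations"):
            match_formula(609.1, "[M-H]-", bounds={"N": (0, 100), "S": (0, 100)})

    def test_round_trip_over_screening_formulas(self):
        # every generating formula reappears among zero-noise matches
        formulas = sorted({f for f, _ in PRINTED_MH})
        for f in formulas:
            mz = adduct_mz(f, "[M-H]-")
            names = {str(c.formula) for c in match_formula(mz, "[M-H]-", tol_ppm=1.0)}
            assert f in names

    def test_candidates_sorted_by_abs_ppm(self):
        cands = match_formula(463.0882, "[M-H]-", tol_ppm=5.0)
        ppms = [abs(c.error.ppm) for c in cands]
        assert ppms == sorted(ppms)


class TestNeutralLoss:
    def test_fragment_arithmetic_is_subtractive(self):
        parent = adduct_mz("C32H36O16", "[M-H]-")
        frag = neutral_loss_mz(parent, "C7H12O2")
        assert frag == pytest.approx(parent - monoisotopic_mass("C7H12O2"))


@pytest.fixture(scope="module")
def library():
    return load_reference_library()


class TestAnnotatePeak:

    def test_rutin_identified_by_formula_and_uv(self, library):
        peak = RawPeak(7, 29.58, {"[M-H]-": 609.1461, "[M+H]+": 611.1621},
                       (265, 285, 350))
        a = annotate_peak(peak, library)
        assert a.identity == "Rutin" and a.flavonoid_class == "flavonol"
        assert not a.ambiguous

    def test_isoflavone_identified(self, library):
        peak = RawPeak(13, 45.69, {"[M-H]-": 575.177}, (235, 285))
        a = annotate_peak(peak, library)
        assert a.identity == "Genestein G 2"
        assert a.flavonoid_class == "isoflavone"

    def test_shared_formula_disambiguated_by_uv(self, library):
        # two flavonols share C21H20O12; the UV pattern separates them
        a = annotate_peak(RawPeak(6, 25.87, {"[M-H]-": 463.0882}, (283,)), library)
        b = annotate_peak(RawPeak(9, 31.70, {"[M-H]-": 463.0882}, (270, 280, 355)), library)
        assert a.identity == "Isotrifolin"
        assert b.identity == "Myricetin deoxyhexoside"

    def test_unmatchable_mass_is_unknown(self, library):
        peak = RawPeak(99, 1.0, {"[M-H]-": 609.4444}, ())
        a = annotate_peak(peak, library, tol_ppm=1.0)
        assert a.flavonoid_class == "unknown" and a.identity is None

    def test_inconsistent_dimer_flags_ambiguity(self, library):
        # a dimer ion that is not arithmetically 2M-H of the monomer
        peak = RawPeak(9, 31.70, {"[M-H]-": 463.0882, "[2M-H]-": 827.1829},
                       (270, 280, 355))
        with pytest.warns(UserWarning, match="conflicting"):
            a = annotate_peak(peak, library)
        assert a.ambiguous
        assert a.formula == "C21H20O12"  # deprotonated ion carried forward

    def test_bundled_peak_table_annotates_17_peaks(self, library):
        from importlib import resources

        path = resources.files("climflav.data").joinpath("reference_peaks.csv")
        peaks = read_peak_table(path)
        assert len(peaks) == 17
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            annos = [annotate_peak(p, library) for p in peaks]
        identified = {a.identity for a in annos if a.identity}
        assert {"Rutin", "Isotrifolin", "Quercitrin", "Genestein G 2",
                "Quercetin-3-rutinoside", "Myricetin deoxyhexoside",
                "Luteolin 6-C-glucoside"} <= identified
        classes = [a.flavonoid_class for a in annos]
        assert classes.count("flavonol") == 5
        assert classes.count("flavone") == 2
        assert classes.count("isoflavone") == 1
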