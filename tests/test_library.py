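"""Peptidoform enumeration, mass arithmetic and fragment spectra checked
against independent hand arithmetic."""

import numpy as np
import pytest

from histoscope.library import CombinatorialCapWarning
from histoscope import (
    AnnotatedSite,
    Peptide,
    Peptidoform,
    ProteinRecord,
    build_library,
    default_registry,
    enumerate_peptidoforms,
    fragment_spectrum,
    library_manifest,
    peptidoform_neutral_mass,
    precursor_mz,
    write_mgf,
)
from histoscope.digestion import apply_derivatization

# Independent residue monoisotopic masses (standard table, typed by hand,
# 5 decimals) for the hand oracle; deliberately not the library's table.
AA = {"G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
      "V": 99.06841, "T": 101.04768, "L": 113.08406, "N": 114.04293,
      "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259,
      "M": 131.04049, "H": 137.05891, "F": 147.06841, "R": 156.10111,
      "Y": 163.06333, "W": 186.07931, "C": 103.00919, "I": 113.08406}
WATER = 18.01056
PROTON = 1.00728


def pep(seq, start=1, acc="P1"):
    return Peptide(acc, start, start + len(seq) - 1, seq)


class TestEnumerate:
    def test_ksr_variable_mods_max_one(self):
        forms = enumerate_peptidoforms(
            pep("KSR"), variable_mods=("Acetyl", "Methyl"), max_variable=1
        )
        assert [f.placements for f in forms] == [
            (), ((1, "Acetyl"),), ((1, "Methyl"),), ((3, "Methyl"),)
        ]

    def test_no_mods_gives_single_unmodified_form(self):
        forms = enumerate_peptidoforms(pep("KSR"))
        assert len(forms) == 1 and forms[0].placements == ()

    def test_curated_site_outside_peptide_ignored(self):
        sites = [AnnotatedSite("P1", 99, "Acetyl")]
        forms = enumerate_peptidoforms(pep("KSR", start=1), annotated_sites=sites)
        assert len(forms) == 1

    def test_curated_subsets_inside_peptide(self):
        sites = [AnnotatedSite("P1", 1, "Acetyl"), AnnotatedSite("P1", 3, "Methyl")]
        forms = enumerate_peptidoforms(pep("KSR"), annotated_sites=sites)
        assert {f.placements for f in forms} == {
            (), ((1, "Acetyl"),), ((3, "Methyl"),),
            ((1, "Acetyl"), (3, "Methyl")),
        }
        assert {f.provenance for f in forms} == {"fixed-label", "curated-site"}

    def test_cap_overflow_reported_never_silent(self):
        with pytest.warns(CombinatorialCapWarning, match=r"\d+ forms skipped"):
            forms = enumerate_peptidoforms(
                pep("KKKKKKKKKK"),
                variable_mods=("Acetyl", "Methyl", "Dimethyl", "Trimethyl"),
                max_variable=4,
                cap=50,
            )
        assert len(forms) == 50

    def test_fixed_label_displaced_by_existing_mark(self):
        protein = ProteinRecord("P1", "p", "KSR")
        deriv = apply_derivatization(protein)
        forms = enumerate_peptidoforms(
            pep("KSR"), variable_mods=("Acetyl",), max_variable=1,
            derivatization=deriv,
        )
        by_placements = {f.placements for f in forms}
        # unmodified form carries N-term + K1 propionyl
        assert ((0, "Propionyl"), (1, "Propionyl")) in by_placements
        # acetylated K1 keeps acetyl only (plus the N-terminal label)
        assert ((0, "Propionyl"), (1, "Acetyl")) in by_placements


class TestMassArithmetic:
    def test_propionyl_lysine_mz_hand_value(self):
        form = Peptidoform(pep("K"), ((1, "Propionyl"),))
        hand = AA["K"] + WATER + 56.02621 + PROTON  # residue+water+delta+proton
        assert precursor_mz(form, 1) == pytest.approx(203.1390, abs=5e-4)
        assert precursor_mz(form, 1) == pytest.approx(hand, abs=5e-4)

    def test_unmodified_gg_dipeptide_mz(self):
        form = Peptidoform(pep("GG"))
        assert precursor_mz(form, 1) == pytest.approx(133.0608, abs=5e-4)
        assert precursor_mz(form, 1) == pytest.approx(
            2 * AA["G"] + WATER + PROTON, abs=5e-4
        )

    def test_charge_states_share_one_neutral_mass(self, rng):
        residues = list(AA)
        for _ in range(20):
            seq = "".join(rng.choice(residues, size=int(rng.integers(2, 15))))
            form = Peptidoform(pep(seq))
            m1 = precursor_mz(form, 1) * 1 - 1 * 1.00727646688
            m2 = precursor_mz(form, 2) * 2 - 2 * 1.00727646688
            assert m1 == pytest.approx(m2, abs=1e-9)

    def test_mass_additivity_of_placements(self):
        registry = default_registry()
        bare = Peptidoform(pep("KSTR"))
        modded = Peptidoform(pep("KSTR"), ((1, "Acetyl"), (2, "Phospho")))
        gap = peptidoform_neutral_mass(modded) - peptidoform_neutral_mass(bare)
        expected = registry.delta_mass("Acetyl") + registry.delta_mass("Phospho")
        assert gap == pytest.approx(expected, abs=1e-9)


class TestFragmentSpectrum:
    def test_gg_complementarity(self):
        form = Peptidoform(pep("GG"))
        spec = fragment_spectrum(form, 2)
        peaks = {label: mz for mz, _, label in spec.peaks}
        neutral = peptidoform_neutral_mass(form)
        assert peaks["b1"] + peaks["y1"] == pytest.approx(
            neutral + 2 * 1.00727646688, abs=1e-9
        )

    def test_acetyl_on_k1_shifts_b_series_only(self):
        bare = fragment_spectrum(Peptidoform(pep("KSR")), 2)
        mod = fragment_spectrum(Peptidoform(pep("KSR"), ((1, "Acetyl"),)), 2)
        b = lambda s, i: next(mz for mz, _, l in s.peaks if l == f"b{i}")
        y = lambda s, i: next(mz for mz, _, l in s.peaks if l == f"y{i}")
        for i in (1, 2):
            assert b(mod, i) - b(bare, i) == pytest.approx(42.0106, abs=5e-4)
            assert y(mod, i) == pytest.approx(y(bare, i), abs=1e-9)

    def test_hand_oracle_for_modified_tripeptide(self):
        # full hand recomputation of both series for K(ac)SR
        spec = fragment_spectrum(Peptidoform(pep("KSR"), ((1, "Acetyl"),)), 2)
        peaks = {label: mz for mz, _, label in spec.peaks}
        ac = 42.01057
        assert peaks["b1"] == pytest.approx(AA["K"] + ac + PROTON, abs=1e-3)
        assert peaks["b2"] == pytest.approx(AA["K"] + ac + AA["S"] + PROTON, abs=1e-3)
        assert peaks["y1"] == pytest.approx(AA["R"] + WATER + PROTON, abs=1e-3)
        assert peaks["y2"] == pytest.approx(AA["S"] + AA["R"] + WATER + PROTON,
                                            abs=1e-3)

    def test_peak_count_is_2n_minus_2(self, rng):
        residues = list(AA)
        for _ in range(10):
            n = int(rng.integers(2, 20))
            seq = "".join(rng.choice(residues, size=n))
            spec = fragment_spectrum(Peptidoform(pep(seq)), 2)
            assert len(spec.peaks) == 2 * (n - 1)
            mzs = [p[0] for p in spec.peaks]
            assert mzs == sorted(mzs)

    def test_length_one_peptide_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fragment_spectrum(Peptidoform(pep("K")), 2)

    def test_n_term_label_counts_toward_b_series(self):
        bare = fragment_spectrum(Peptidoform(pep("GGR")), 2)
        lab = fragment_spectrum(Peptidoform(pep("GGR"), ((0, "Propionyl"),)), 2)
        b1 = lambda s: next(mz for mz, _, l in s.peaks if l == "b1")
        y2 = lambda s: next(mz for mz, _, l in s.peaks if l == "y2")
        assert b1(lab) - b1(bare) == pytest.approx(56.02621, abs=1e-4)
        assert y2(lab) == pytest.approx(y2(bare), abs=1e-9)


class TestBuildLibrary:
    def test_marksrg_argc_two_spectra(self, marksrg):
        spectra = build_library([marksrg], "argc", 0, charges=(2,), min_length=3)
        assert [s.peptidoform.sequence for s in spectra] == ["MAR", "KSR"]

    def test_empty_protein_collection(self):
        assert build_library([], "trypsin") == []

    def test_doubling_charges_doubles_spectra(self, marksrg):
        one = build_library([marksrg], "argc", 0, charges=(2,), min_length=3)
        two = build_library([marksrg], "argc", 0, charges=(2, 3), min_length=3)
        assert len(two) == 2 * len(one)

    def test_mz_window_filters(self, marksrg):
        spectra = build_library([marksrg], "argc", 0, charges=(2,), min_length=3,
                                mz_range=(50.0, 100.0))
        assert spectra == []

    def test_build_is_deterministic_byte_identical(self, tmp_path, h3_like):
        paths = []
        for i in (1, 2):
            spectra = build_library([h3_like], "trypsin", 1, charges=(2, 3),
                                    variable_mods=("Acetyl",), max_variable=1)
            path = tmp_path / f"lib{i}.mgf"
            write_mgf([s.to_spectrum() for s in spectra], path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_manifest_counts(self, marksrg):
        spectra = build_library([marksrg], "argc", 0, charges=(2, 3), min_length=3)
        manifest = library_manifest(spectra)
        assert manifest["n_spectra"].sum() == len(spectra)
        assert set(manifest["charge"]) == {2, 3}
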