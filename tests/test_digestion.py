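"""Digestion engine vs a brute-force oracle, plus derivatization rules."""

import numpy as np
import pytest

from histoscope import (
    PROTEASES,
    Peptide,
    ProteaseRule,
    ProteinRecord,
    apply_derivatization,
    default_registry,
    digest,
    semi_specific_expand,
)
from conftest import oracle_digest

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def as_triples(peptides):
    return {(p.start, p.end, p.missed_cleavages) for p in peptides}


def test_argc_digest_of_marksrg(marksrg):
    peptides = digest(marksrg, "argc", 0)
    assert [(p.start, p.end, p.sequence) for p in peptides] == [
        (1, 3, "MAR"), (4, 6, "KSR"), (7, 7, "G")
    ]


def test_propionylated_lysine_is_not_cut():
    protein = ProteinRecord("T1", "t", "MAKRS")
    peptides = digest(protein, "trypsin", 0, {3: ("Propionyl",)})
    assert [(p.start, p.end, p.sequence) for p in peptides] == [
        (1, 4, "MAKR"), (5, 5, "S")
    ]


def test_no_cleavage_residues_gives_whole_protein():
    protein = ProteinRecord("T2", "t", "AGSTGLMV")
    peptides = digest(protein, "argc", 3)
    assert as_triples(peptides) == {(1, 8, 0)}


def test_trypsin_skips_cut_before_proline():
    protein = ProteinRecord("T3", "t", "AKPGGRA")
    peptides = digest(protein, "trypsin", 0)
    # K2 is followed by P: no cut there; R6 cuts normally
    assert [(p.start, p.end) for p in peptides] == [(1, 6), (7, 7)]


@pytest.mark.parametrize("enzyme", ["trypsin", "argc", "grx"])
@pytest.mark.parametrize("max_missed", [0, 1, 3])
def test_digest_matches_brute_force_oracle(rng, enzyme, max_missed):
    rule = PROTEASES[enzyme]
    registry = default_registry()
    for _ in range(25):
        n = int(rng.integers(1, 61))
        seq = "".join(rng.choice(list(RESIDUES), size=n))
        protein = ProteinRecord("R1", "r", seq)
        # scatter blocking marks on some K/R
        site_mods = {}
        for p, res in enumerate(seq, start=1):
            if res == "K" and rng.random() < 0.3:
                site_mods[p] = ("Acetyl",)
            elif res == "R" and rng.random() < 0.3:
                site_mods[p] = ("Methyl",)
        blocked = set()
        if rule.respects_blocking:
            blocked = {
                p for p, mods in site_mods.items()
                if any(seq[p - 1] in registry[m].blocks_cleavage_at for m in mods)
            }
        expected = oracle_digest(
            seq, rule.cleave_after, max_missed,
            no_cut_before_p=rule.exclude_before_proline,
            blocked_positions=blocked,
        )
        got = digest(protein, rule, max_missed, site_mods, registry)
        assert as_triples(got) == expected
        for p in got:
            assert p.sequence == seq[p.start - 1:p.end]


def test_zero_missed_digest_reconstructs_protein(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list(RESIDUES), size=int(rng.integers(1, 80))))
        protein = ProteinRecord("R2", "r", seq)
        peptides = sorted(digest(protein, "trypsin", 0), key=lambda p: p.start)
        assert "".join(p.sequence for p in peptides) == seq


def test_grx_equals_argc_without_r_modifications(rng):
    for _ in range(10):
        seq = "".join(rng.choice(list(RESIDUES), size=40))
        protein = ProteinRecord("R3", "r", seq)
        a = as_triples(digest(protein, "argc", 2))
        g = as_triples(digest(protein, "grx", 2))
        assert a == g


def test_grx_cleaves_modified_arginine_argc_does_not():
    protein = ProteinRecord("T4", "t", "AAARKKKRGG")
    mods = {4: ("Methyl",)}  # methylated R4
    argc = as_triples(digest(protein, "argc", 0, mods))
    grx = as_triples(digest(protein, "grx", 0, mods))
    assert (1, 4, 0) in grx and (1, 8, 0) in argc
    assert argc != grx


class TestSemiSpecificExpand:
    def test_ksr_example(self):
        pep = Peptide("H3_TEST", 4, 6, "KSR")
        out = semi_specific_expand([pep], min_length=2)
        coords = {(p.start, p.end, p.specific_n_term, p.specific_c_term) for p in out}
        assert coords == {
            (4, 6, True, True),
            (4, 5, True, False),
            (5, 6, False, True),
        }

    def test_min_length_above_all_lengths_is_identity(self):
        peps = [Peptide("A", 1, 3, "MAR")]
        assert semi_specific_expand(peps, min_length=5) == peps

    def test_output_is_superset_of_input(self, marksrg):
        peps = digest(marksrg, "argc", 1)
        out = as_triples(semi_specific_expand(peps, 2))
        assert {(p.start, p.end) for p in peps} <= {(s, e) for s, e, _ in out}

    def test_rejects_bad_min_length_and_semi_input(self):
        with pytest.raises(ValueError):
            semi_specific_expand([], min_length=0)
        semi = Peptide("A", 1, 3, "MAR", specific_c_term=False)
        with pytest.raises(ValueError, match="fully-specific"):
            semi_specific_expand([semi])


class TestDerivatization:
    def test_unmodified_lysines_get_propionyl(self):
        protein = ProteinRecord("T5", "t", "ARKSK")
        deriv = apply_derivatization(protein)
        assert deriv.site_mods == {3: ("Propionyl",), 5: ("Propionyl",)}
        assert deriv.n_term_label == "Propionyl"

    def test_acetylated_lysine_untouched(self):
        protein = ProteinRecord("T6", "t", "ARKSK")
        deriv = apply_derivatization(protein, existing_mods={3: ("Acetyl",)})
        assert deriv.site_mods[3] == ("Acetyl",)
        assert deriv.site_mods[5] == ("Propionyl",)

    def test_monomethyl_lysine_gains_propionyl_summing_to_butyryl_mass(self):
        registry = default_registry()
        protein = ProteinRecord("T7", "t", "AKA")
        deriv = apply_derivatization(protein, existing_mods={2: ("Methyl",)})
        assert deriv.site_mods[2] == ("Methyl", "Propionyl")
        added = sum(registry.delta_mass(m) for m in deriv.site_mods[2])
        assert round(added, 3) == 70.042
        assert added == pytest.approx(registry.delta_mass("Butyryl"), abs=1e-9)

    def test_unknown_scheme_rejected(self, marksrg):
        with pytest.raises(ValueError, match="scheme"):
            apply_derivatization(marksrg, "acetylation-everywhere")


def test_digest_input_validation(marksrg):
    with pytest.raises(ValueError):
        digest(marksrg, "trypsin", -1)
    bad = ProteinRecord.__new__(ProteinRecord)  # bypass record validation
    object.__setattr__(bad, "accession", "B")
    object.__setattr__(bad, "sequence", "AXB")
    with pytest.raises(ValueError, match="residue"):
        digest(bad, "trypsin", 0)
    with pytest.raises(ValueError):
        ProteaseRule("none", frozenset())
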