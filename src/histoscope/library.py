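"""Theoretical spectral-library generation.

Peptides from the digestion engine are expanded into peptidoforms (curated
sites, variable-modification combinations, fixed chemical labels), massed
exactly from elemental compositions, and turned into b/y fragment spectra
ready for MGF/MSP export.

Fragment intensities are a pluggable strategy.  The default is uniform
(all peaks 1.0): for coverage and search-space assessment the information
sits in the peak *positions*, and a trained intensity predictor would add
nothing the downstream comparisons use.  A toy ``y-dominant`` model is
included for rendering spectra that look vaguely tryptic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

from .digestion import Derivatization, Peptide, ProteaseRule, digest
from .io import AnnotatedSite, ProteinRecord, Spectrum
from .modifications import ModificationRegistry, default_registry

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "Peptidoform",
    "TheoreticalSpectrum",
    "CombinatorialCapWarning",
    "INTENSITY_MODELS",
    "enumerate_peptidoforms",
    "peptidoform_neutral_mass",
    "precursor_mz",
    "fragment_spectrum",
    "build_library",
    "library_manifest",
]

PROTON_MASS = 1.00727646688
WATER_MASS = _pmass.calculate_mass(formula="H2O")

#: Default combinatorial guard: maximum peptidoforms emitted per peptide.
DEFAULT_FORM_CAP = 10_000


class CombinatorialCapWarning(UserWarning):
    """Raised (as a warning) when peptidoform enumeration is truncated."""


@dataclass(frozen=True)
class Peptidoform:
    """A located peptide with localized modifications.

    ``placements`` are (peptide-position, modification-name) pairs with
    position 0 denoting the peptide N-terminus; at most one non-label
    modification per site.  ``provenance`` records how the form arose:
    a curated-site subset, a variable-modification combination, or the
    bare/labelled peptide.
    """

    peptide: Peptide
    placements: tuple[tuple[int, str], ...] = ()
    provenance: str = "fixed-label"

    def __post_init__(self) -> None:
        object.__setattr__(self, "placements", tuple(sorted(self.placements)))

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    def __len__(self) -> int:
        return len(self.peptide.sequence)

    def neutral_mass(self, registry: ModificationRegistry | None = None) -> float:
        return peptidoform_neutral_mass(self, registry)

    def key(self) -> tuple:
        """Canonical sort/identity key."""
        p = self.peptide
        return (p.accession, p.start, p.end, self.placements)


def peptidoform_neutral_mass(
    form: Peptidoform, registry: ModificationRegistry | None = None
) -> float:
    """Monoisotopic neutral mass: residue masses + water + placement deltas."""
    registry = registry if registry is not None else default_registry()
    base = _pmass.fast_mass(form.sequence)
    return base + sum(registry.delta_mass(name) for _, name in form.placements)


def precursor_mz(
    form: Peptidoform, z: int, registry: ModificationRegistry | None = None
) -> float:
    """(neutral mass + z protons) / z."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (peptidoform_neutral_mass(form, registry) + z * PROTON_MASS) / z


# --------------------------------------------------------------------------
# peptidoform enumeration
# --------------------------------------------------------------------------

def _compatible_variable_placements(
    peptide: Peptide,
    variable_mods: Sequence[str],
    registry: ModificationRegistry,
) -> list[tuple[int, str]]:
    pairs = []
    for pep_pos, residue in enumerate(peptide.sequence, start=1):
        for name in variable_mods:
            if registry[name].is_compatible(residue):
                pairs.append((pep_pos, name))
    return pairs


def _apply_fixed_labels(
    placements: tuple[tuple[int, str], ...],
    peptide: Peptide,
    derivatization: Derivatization | None,
) -> tuple[tuple[int, str], ...]:
    if derivatization is None:
        return placements
    occupied = {pos for pos, _ in placements}
    out = list(placements)
    for protein_pos, names in derivatization.site_mods.items():
        if not (peptide.start <= protein_pos <= peptide.end):
            continue
        pep_pos = protein_pos - peptide.start + 1
        if pep_pos in occupied:
            continue  # a variable/curated mark displaces the label
        for name in names:
            out.append((pep_pos, name))
    if derivatization.n_term_label is not None and 0 not in occupied:
        out.append((0, derivatization.n_term_label))
    return tuple(sorted(out))


def _enumerate(
    peptide: Peptide,
    annotated_sites: Sequence[AnnotatedSite] = (),
    variable_mods: Sequence[str] = (),
    max_variable: int = 0,
    derivatization: Derivatization | None = None,
    registry: ModificationRegistry | None = None,
    cap: int = DEFAULT_FORM_CAP,
) -> tuple[list[Peptidoform], int]:
    registry = registry if registry is not None else default_registry()
    if max_variable < 0:
        raise ValueError("max_variable must be >= 0")

    seen: set[tuple[tuple[int, str], ...]] = set()
    forms: list[Peptidoform] = []
    skipped = 0

    def _emit(placements: Iterable[tuple[int, str]], provenance: str) -> None:
        nonlocal skipped
        final = _apply_fixed_labels(tuple(sorted(placements)), peptide, derivatization)
        if final in seen:
            return
        if len(forms) >= cap:
            skipped += 1
            return
        seen.add(final)
        forms.append(Peptidoform(peptide, final, provenance))

    # the unmodified (or labels-only) form always exists
    _emit((), "fixed-label")

    # curated-site subsets restricted to sites inside this peptide
    local_sites = [
        s for s in annotated_sites
        if s.accession == peptide.accession and peptide.start <= s.position <= peptide.end
    ]
    for r in range(1, len(local_sites) + 1):
        for combo in itertools.combinations(local_sites, r):
            positions = [s.position - peptide.start + 1 for s in combo]
            if len(set(positions)) < len(positions):
                continue  # two curated marks on one residue cannot co-occur
            _emit(zip(positions, (s.modification for s in combo)), "curated-site")

    # variable-modification combinations over compatible sites
    pairs = _compatible_variable_placements(peptide, variable_mods, registry)
    for r in range(1, max_variable + 1):
        for combo in itertools.combinations(pairs, r):
            positions = [pos for pos, _ in combo]
            if len(set(positions)) < len(positions):
                continue
            _emit(combo, "variable-combination")

    return forms, skipped


def enumerate_peptidoforms(
    peptide: Peptide,
    annotated_sites: Sequence[AnnotatedSite] = (),
    variable_mods: Sequence[str] = (),
    max_variable: int = 0,
    derivatization: Derivatization | None = None,
    registry: ModificationRegistry | None = None,
    cap: int = DEFAULT_FORM_CAP,
) -> list[Peptidoform]:
    """All peptidoforms of one peptide.

    One unmodified form; one form per subset of curated sites falling inside
    the peptide; every combination of up to ``max_variable`` variable
    modifications over compatible sites; fixed derivatization labels applied
    last (a site already carrying a mark is not labelled).  Enumeration is
    truncated at ``cap`` forms with a :class:`CombinatorialCapWarning`
    reporting the number skipped — never silently.
    """
    forms, skipped = _enumerate(
        peptide, annotated_sites, variable_mods, max_variable,
        derivatization, registry, cap,
    )
    if skipped:
        warnings.warn(
            f"peptidoform cap {cap} reached for {peptide.sequence} "
            f"({peptide.accession} {peptide.start}..{peptide.end}): "
            f"{skipped} forms skipped",
            CombinatorialCapWarning,
        )
    return forms


# --------------------------------------------------------------------------
# fragment spectra
# --------------------------------------------------------------------------

def _uniform_intensity(label: str, i: int, n: int) -> float:
    return 1.0


def _y_dominant_intensity(label: str, i: int, n: int) -> float:
    # crude shape: y series twice as tall, mid-length fragments favoured
    series = 2.0 if label.startswith("y") else 1.0
    return series * (0.5 + 0.5 * min(i, n - i) / max(n / 2, 1))


INTENSITY_MODELS: dict[str, Callable[[str, int, int], float]] = {
    "uniform": _uniform_intensity,
    "y-dominant": _y_dominant_intensity,
}


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """A predicted b/y fragment spectrum of one peptidoform."""

    peptidoform: Peptidoform
    precursor_charge: int
    precursor_mz: float
    peaks: tuple[tuple[float, float, str], ...]

    @property
    def title(self) -> str:
        p = self.peptidoform.peptide
        mods = ",".join(f"{pos}:{name}" for pos, name in self.peptidoform.placements)
        return (
            f"{p.accession}|{p.start}-{p.end}|{self.peptidoform.sequence}"
            f"|mods={mods}|z={self.precursor_charge}"
        )

    def to_spectrum(self) -> Spectrum:
        return Spectrum(self.title, self.precursor_mz, self.precursor_charge,
                        list(self.peaks))


def fragment_spectrum(
    form: Peptidoform,
    z_precursor: int = 2,
    intensity_model: str | Callable[[str, int, int], float] = "uniform",
    registry: ModificationRegistry | None = None,
) -> TheoreticalSpectrum:
    """All singly-charged b_i and y_i ions (1 <= i <= n-1) of a peptidoform.

    Modification deltas are assigned to the correct side of every backbone
    cut: a placement at peptide position p (0 = N-terminus) appears in b_i
    iff p <= i and in y_i iff p > n-i, which preserves the complementarity
    b_i + y_{n-i} = neutral mass + 2 protons.
    """
    registry = registry if registry is not None else default_registry()
    n = len(form)
    if n < 2:
        raise ValueError("fragment spectrum needs a peptide of length >= 2")
    if isinstance(intensity_model, str):
        intensity_model = INTENSITY_MODELS[intensity_model]

    seq = form.sequence
    residue_masses = [_pmass.fast_mass(seq[:i]) - WATER_MASS for i in range(n + 1)]
    delta_prefix = [0.0] * (n + 1)  # summed deltas of placements at positions <= i
    nterm_delta = sum(registry.delta_mass(m) for p, m in form.placements if p == 0)
    deltas_at = {p: sum(registry.delta_mass(m) for q, m in form.placements if q == p)
                 for p in range(1, n + 1)}
    running = nterm_delta
    for i in range(1, n + 1):
        running += deltas_at.get(i, 0.0)
        delta_prefix[i] = running
    delta_prefix[0] = nterm_delta
    total_delta = delta_prefix[n]
    neutral = _pmass.fast_mass(seq) + total_delta

    peaks = []
    for i in range(1, n):
        b = residue_masses[i] + delta_prefix[i] + PROTON_MASS
        y = (neutral + 2 * PROTON_MASS) - b
        peaks.append((b, intensity_model(f"b{i}", i, n), f"b{i}"))
        peaks.append((y, intensity_model(f"y{n - i}", n - i, n), f"y{n - i}"))
    peaks.sort()
    return TheoreticalSpectrum(
        peptidoform=form,
        precursor_charge=z_precursor,
        precursor_mz=(neutral + z_precursor * PROTON_MASS) / z_precursor,
        peaks=tuple(peaks),
    )


# --------------------------------------------------------------------------
# library assembly
# --------------------------------------------------------------------------

def build_library(
    proteins: Iterable[ProteinRecord],
    rule: ProteaseRule | str,
    max_missed: int = 0,
    annotated_sites: Sequence[AnnotatedSite] = (),
    variable_mods: Sequence[str] = (),
    max_variable: int = 0,
    charges: Sequence[int] = (2, 3),
    min_length: int = 4,
    max_length: int | None = None,
    mz_range: tuple[float, float] = (50.0, 5000.0),
    derivatization_scheme: str | None = None,
    registry: ModificationRegistry | None = None,
    intensity_model: str | Callable[[str, int, int], float] = "uniform",
    cap: int = DEFAULT_FORM_CAP,
) -> list[TheoreticalSpectrum]:
    """Digest, enumerate peptidoforms and predict spectra for a proteome.

    Spectra are filtered to the precursor m/z acquisition window and the
    length bounds, and returned in a canonical deterministic order
    (accession, coordinates, placements, charge) so repeated builds are
    byte-identical on export.
    """
    from .digestion import apply_derivatization  # local to avoid cycle noise

    registry = registry if registry is not None else default_registry()
    spectra: list[TheoreticalSpectrum] = []
    for protein in proteins:
        deriv = None
        site_mods = None
        if derivatization_scheme is not None:
            deriv = apply_derivatization(protein, derivatization_scheme,
                                         registry=registry)
            site_mods = deriv.site_mods
        for peptide in digest(protein, rule, max_missed, site_mods, registry):
            if len(peptide) < max(min_length, 2):
                continue
            if max_length is not None and len(peptide) > max_length:
                continue
            forms = enumerate_peptidoforms(
                peptide, annotated_sites, variable_mods, max_variable,
                deriv, registry, cap,
            )
            for form in forms:
                for z in charges:
                    spec = fragment_spectrum(form, z, intensity_model, registry)
                    if mz_range[0] <= spec.precursor_mz <= mz_range[1]:
                        spectra.append(spec)
    spectra.sort(key=lambda s: (*s.peptidoform.key(), s.precursor_charge))
    return spectra


def library_manifest(spectra: Sequence[TheoreticalSpectrum]):
    """Spectrum counts per protein and precursor charge, as a DataFrame."""
    import pandas as pd

    rows = [
        {"accession": s.peptidoform.peptide.accession, "charge": s.precursor_charge}
        for s in spectra
    ]
    if not rows:
        return pd.DataFrame(columns=["accession", "charge", "n_spectra"])
    return (
        pd.DataFrame(rows)
        .groupby(["accession", "charge"], as_index=False)
        .size()
        .rename(columns={"size": "n_spectra"})
    )
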