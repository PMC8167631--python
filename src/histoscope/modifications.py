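"""Registry of residue modifications and isobaric-conflict detection.

Every modification is defined by an elemental composition; its monoisotopic
mass delta is always *derived* from that composition with standard atomic
masses (via :mod:`pyteomics.mass`), never typed in as a decimal.  This keeps
mass arithmetic exact: the delta of a combined multiset equals the delta of
the summed composition bit-for-bit, which is what makes conflicts such as
propionyl + methyl vs. butyryl detectable as *exact* isobars rather than
near-coincidences.

Origin classes separate biology from chemistry: ``biological`` marks are the
analytes (acetylation, methylation states, ubiquitin remnants, ...),
``chemical-label`` marks are deliberately introduced by derivatization
(propionylation of K and peptide N-termini), and ``artifact`` marks are side
reactions (overpropionylation of S/T/Y, formylation, oxidation) that add
chemical noise to a run without carrying epigenetic information.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import yaml
from pyteomics import mass as _pmass

__all__ = [
    "ModificationSpec",
    "ModificationRegistry",
    "IsobaricConflict",
    "default_registry",
    "find_isobaric_conflicts",
    "N_TERM",
    "C_TERM",
]

#: Terminus markers usable in a modification's target set.
N_TERM = "N-term"
C_TERM = "C-term"

_ORIGINS = ("biological", "chemical-label", "artifact")


def _composition_mass(composition: Mapping[str, int]) -> float:
    return _pmass.calculate_mass(composition=_pmass.Composition(dict(composition)))


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass delta with target residues and an origin class.

    Parameters
    ----------
    name:
        Unique registry key, e.g. ``"Acetyl"``.
    composition:
        Element -> count mapping; counts may be negative (e.g. citrullination
        is a net loss of NH against a gain of O).
    targets:
        Residue letters and/or terminus markers this modification may sit on.
    origin:
        ``biological``, ``chemical-label`` or ``artifact``.
    blocks_cleavage_at:
        Residue letters where carrying this modification blocks enzymatic
        cleavage (for proteases that respect blocking).
    """

    name: str
    composition: Mapping[str, int]
    targets: frozenset[str]
    origin: str = "biological"
    blocks_cleavage_at: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no targets")
        if self.origin not in _ORIGINS:
            raise ValueError(
                f"modification {self.name!r}: origin {self.origin!r} not in {_ORIGINS}"
            )
        object.__setattr__(self, "composition", dict(self.composition))
        object.__setattr__(self, "targets", frozenset(self.targets))
        object.__setattr__(self, "blocks_cleavage_at", frozenset(self.blocks_cleavage_at))

    @property
    def delta_mass(self) -> float:
        """Monoisotopic mass delta in Da, derived from the composition."""
        return _composition_mass(self.composition)

    def is_compatible(self, residue_or_terminus: str) -> bool:
        return residue_or_terminus in self.targets


class ModificationRegistry:
    """Ordered name -> :class:`ModificationSpec` mapping with config round-trip."""

    def __init__(self, specs: Iterable[ModificationSpec] = ()) -> None:
        self._specs: dict[str, ModificationSpec] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: ModificationSpec) -> None:
        if spec.name in self._specs:
            raise ValueError(f"duplicate modification name {spec.name!r}")
        self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> ModificationSpec:
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[ModificationSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def delta_mass(self, name: str) -> float:
        return self._specs[name].delta_mass

    def compatible_with(self, residue_or_terminus: str) -> list[ModificationSpec]:
        return [s for s in self if s.is_compatible(residue_or_terminus)]

    def subset(self, names: Iterable[str]) -> "ModificationRegistry":
        return ModificationRegistry(self._specs[n] for n in names)

    # -- plain-text config round-trip -------------------------------------
    def to_yaml(self) -> str:
        doc = {
            s.name: {
                "composition": dict(s.composition),
                "targets": sorted(s.targets),
                "origin": s.origin,
                "blocks_cleavage_at": sorted(s.blocks_cleavage_at),
            }
            for s in self
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModificationRegistry":
        doc = yaml.safe_load(text) or {}
        return cls(
            ModificationSpec(
                name=name,
                composition=entry["composition"],
                targets=frozenset(entry["targets"]),
                origin=entry.get("origin", "biological"),
                blocks_cleavage_at=frozenset(entry.get("blocks_cleavage_at", ())),
            )
            for name, entry in doc.items()
        )


def default_registry() -> ModificationRegistry:
    """The stock modification set for bottom-up histone work.

    Covers the usual variable search set (acetyl, the three methylation
    states, butyryl, crotonyl, phospho, the ubiquitin GG remnant,
    citrullination), the propionyl chemical label (K and peptide N-terminus),
    and the common preparation artifacts (overpropionylation of S/T/Y,
    formylation, methionine oxidation).

    Every modification targeting K blocks tryptic cleavage at that K; R-side
    marks (methylation states, citrullination) block cleavage at R for
    proteases that respect blocking.  Override per-modification via a custom
    registry or the YAML config round-trip.
    """
    K = frozenset("K")
    KR = frozenset("KR")
    specs = [
        ModificationSpec("Acetyl", {"C": 2, "H": 2, "O": 1}, K, "biological", K),
        ModificationSpec("Methyl", {"C": 1, "H": 2}, KR, "biological", KR),
        ModificationSpec("Dimethyl", {"C": 2, "H": 4}, KR, "biological", KR),
        ModificationSpec("Trimethyl", {"C": 3, "H": 6}, K, "biological", K),
        ModificationSpec("Butyryl", {"C": 4, "H": 6, "O": 1}, K, "biological", K),
        ModificationSpec("Crotonyl", {"C": 4, "H": 4, "O": 1}, K, "biological", K),
        ModificationSpec("GG", {"C": 4, "H": 6, "N": 2, "O": 2}, K, "biological", K),
        ModificationSpec("Phospho", {"H": 1, "P": 1, "O": 3}, frozenset("ST"), "biological"),
        # net deamidation chemistry on arginine
        ModificationSpec("Citrullination", {"H": -1, "N": -1, "O": 1}, frozenset("R"),
                         "biological", frozenset("R")),
        ModificationSpec("Propionyl", {"C": 3, "H": 4, "O": 1},
                         frozenset({"K", N_TERM}), "chemical-label", K),
        ModificationSpec("Overpropionyl", {"C": 3, "H": 4, "O": 1},
                         frozenset("STY"), "artifact"),
        ModificationSpec("Formyl", {"C": 1, "O": 1},
                         frozenset({"K", "S", "T", N_TERM}), "artifact", K),
        ModificationSpec("Oxidation", {"O": 1}, frozenset("M"), "artifact"),
    ]
    return ModificationRegistry(specs)


@dataclass(frozen=True)
class IsobaricConflict:
    """Two modification multisets whose total mass deltas (nearly) coincide."""

    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    mass_difference: float
    exact: bool = field(default=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "exact" if self.exact else f"{self.mass_difference:+.6f} Da"
        return f"{{{', '.join(self.set_a)}}} ~ {{{', '.join(self.set_b)}}} ({tag})"


def _summed_composition(registry: ModificationRegistry, names: tuple[str, ...]):
    total = _pmass.Composition()
    for n in names:
        total += _pmass.Composition(dict(registry[n].composition))
    return total


def find_isobaric_conflicts(
    registry: ModificationRegistry,
    max_set_size: int = 2,
    tolerance_da: float = 0.01,
) -> list[IsobaricConflict]:
    """Enumerate pairs of modification multisets indistinguishable by mass.

    All multisets of registered modifications up to ``max_set_size`` are
    compared pairwise; a pair whose total deltas differ by at most
    ``tolerance_da`` is reported, flagged ``exact`` when the summed elemental
    compositions are identical (the propionyl+methyl = butyryl case).
    Results are sorted by absolute mass difference, exact conflicts first
    within ties.
    """
    if max_set_size < 1:
        raise ValueError("max_set_size must be >= 1")
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be > 0")

    names = registry.names
    multisets: list[tuple[str, ...]] = []
    for size in range(1, max_set_size + 1):
        multisets.extend(itertools.combinations_with_replacement(names, size))

    masses = {ms: sum(registry.delta_mass(n) for n in ms) for ms in multisets}
    conflicts: list[IsobaricConflict] = []
    for ms_a, ms_b in itertools.combinations(multisets, 2):
        if Counter(ms_a) == Counter(ms_b):
            continue
        diff = masses[ms_a] - masses[ms_b]
        if abs(diff) <= tolerance_da:
            exact = _summed_composition(registry, ms_a) == _summed_composition(registry, ms_b)
            if exact:
                # identical summed compositions: the difference is exactly 0,
                # independent of float summation order
                diff = 0.0
            conflicts.append(IsobaricConflict(ms_a, ms_b, diff, exact))
    conflicts.sort(key=lambda c: (abs(c.mass_difference), not c.exact, c.set_a, c.set_b))
    return conflicts
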