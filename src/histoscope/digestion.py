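"""Modification-aware in-silico protease digestion.

Coordinates are 1-based inclusive throughout, matching the identification
CSV dialect consumed downstream: a peptide covering protein residues
``start..end`` has ``sequence == protein.sequence[start-1:end]``.

The engine models three protease behaviours relevant to histone work:

* **trypsin** — cleaves after K and R, not before P; modifications on a K
  (acyl marks, the propionyl label, GG) block cleavage at that K, and R-side
  marks block cleavage at that R.
* **argc** — arginine-specific; R-side modifications (methylation states,
  citrullination) block cleavage.
* **grx** — the RgpB endoproteinase: arginine-specific and, unlike ArgC,
  able to cleave modified arginines, so blocking is ignored.

Derivatization (propionylation) is expressed as a site-modification map that
both blocks tryptic cleavage at K and later contributes mass: applying the
``propionylation`` scheme to a protein marks every K that is unmodified or
carries only a mono-methyl with a propionyl group, and flags peptide
N-termini for the N-terminal label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .modifications import ModificationRegistry, default_registry

__all__ = [
    "ProteaseRule",
    "Peptide",
    "Derivatization",
    "PROTEASES",
    "digest",
    "cleavage_sites",
    "semi_specific_expand",
    "apply_derivatization",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity of a protease.

    ``respects_blocking`` controls whether a modification sitting on the
    cleavage residue (whose ``blocks_cleavage_at`` includes that residue)
    suppresses the cut.
    """

    name: str
    cleave_after: frozenset[str]
    exclude_before_proline: bool = False
    respects_blocking: bool = True

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))


#: Shipped protease presets.
PROTEASES: dict[str, ProteaseRule] = {
    "trypsin": ProteaseRule("trypsin", frozenset("KR"),
                            exclude_before_proline=True, respects_blocking=True),
    "argc": ProteaseRule("argc", frozenset("R"), respects_blocking=True),
    "grx": ProteaseRule("grx", frozenset("R"), respects_blocking=False),
}


@dataclass(frozen=True)
class Peptide:
    """A located peptide: protein coordinates plus cleavage provenance."""

    accession: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    sequence: str
    missed_cleavages: int = 0
    specific_n_term: bool = True
    specific_c_term: bool = True

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def fully_specific(self) -> bool:
        return self.specific_n_term and self.specific_c_term


def _site_mod_names(site_modifications, position: int) -> tuple[str, ...]:
    mods = site_modifications.get(position, ()) if site_modifications else ()
    if isinstance(mods, str):
        return (mods,)
    return tuple(mods)


def cleavage_sites(
    sequence: str,
    rule: ProteaseRule,
    site_modifications: Mapping[int, Sequence[str] | str] | None = None,
    registry: ModificationRegistry | None = None,
) -> list[int]:
    """1-based positions *after* which the protease cuts.

    A position ``p`` is a cut site when ``sequence[p-1]`` is in the rule's
    cleavage set, is not followed by proline (if the rule excludes that), and
    carries no blocking modification (if the rule respects blocking).
    """
    registry = registry if registry is not None else default_registry()
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in sequence")
    sites: list[int] = []
    for p in range(1, len(sequence)):  # a cut after the last residue is vacuous
        residue = sequence[p - 1]
        if residue not in rule.cleave_after:
            continue
        if rule.exclude_before_proline and sequence[p] == "P":
            continue
        if rule.respects_blocking:
            blocked = any(
                name in registry and residue in registry[name].blocks_cleavage_at
                for name in _site_mod_names(site_modifications, p)
            )
            if blocked:
                continue
        sites.append(p)
    return sites


def digest(
    protein,
    rule: ProteaseRule | str,
    max_missed: int = 0,
    site_modifications: Mapping[int, Sequence[str] | str] | None = None,
    registry: ModificationRegistry | None = None,
) -> list[Peptide]:
    """All fully-specific peptides with at most ``max_missed`` internal sites.

    ``protein`` is anything with ``accession`` and ``sequence`` attributes.
    Peptides are deduplicated by (start, end) and returned in position order.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if isinstance(rule, str):
        rule = PROTEASES[rule]
    seq = protein.sequence
    sites = cleavage_sites(seq, rule, site_modifications, registry)
    boundaries = [0, *sites, len(seq)]
    peptides: list[Peptide] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(boundaries))):
            start, end = boundaries[i] + 1, boundaries[j]
            peptides.append(
                Peptide(
                    accession=protein.accession,
                    start=start,
                    end=end,
                    sequence=seq[start - 1:end],
                    missed_cleavages=j - i - 1,
                )
            )
    return peptides


def semi_specific_expand(peptides: Iterable[Peptide], min_length: int = 4) -> list[Peptide]:
    """Add every sub-peptide keeping at least one enzymatic terminus.

    For each fully-specific input peptide all prefixes (specific N-terminus)
    and suffixes (specific C-terminus) of length >= ``min_length`` are added,
    with terminus flags set accordingly.  The output is a superset of the
    input; duplicates by coordinates keep the most specific flags.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    out: dict[tuple[str, int, int], Peptide] = {}

    def _add(p: Peptide) -> None:
        key = (p.accession, p.start, p.end)
        prev = out.get(key)
        if prev is None:
            out[key] = p
        else:
            out[key] = replace(
                prev,
                specific_n_term=prev.specific_n_term or p.specific_n_term,
                specific_c_term=prev.specific_c_term or p.specific_c_term,
                missed_cleavages=min(prev.missed_cleavages, p.missed_cleavages)
                if prev.fully_specific == p.fully_specific else
                (prev if prev.fully_specific else p).missed_cleavages,
            )

    for pep in peptides:
        if not pep.fully_specific:
            raise ValueError("semi_specific_expand expects fully-specific input")
        _add(pep)
        n = len(pep)
        for length in range(min_length, n):
            # prefix: keeps the enzymatic N-terminus
            _add(replace(
                pep,
                end=pep.start + length - 1,
                sequence=pep.sequence[:length],
                specific_c_term=False,
            ))
            # suffix: keeps the enzymatic C-terminus
            _add(replace(
                pep,
                start=pep.end - length + 1,
                sequence=pep.sequence[-length:],
                specific_n_term=False,
            ))
    return sorted(out.values(), key=lambda p: (p.accession, p.start, p.end))


@dataclass(frozen=True)
class Derivatization:
    """Result of a chemical-labelling scheme.

    ``site_mods`` maps protein position -> modification names fixed there
    (feed to :func:`digest` for cleavage blocking and to mass computation);
    ``n_term_label`` names the modification applied to every resulting
    peptide N-terminus, if any.
    """

    site_mods: dict[int, tuple[str, ...]] = field(default_factory=dict)
    n_term_label: str | None = None


def apply_derivatization(
    protein,
    scheme: str = "propionylation",
    existing_mods: Mapping[int, Sequence[str] | str] | None = None,
    registry: ModificationRegistry | None = None,
) -> Derivatization:
    """Fix the chemical labels a derivatization scheme deposits.

    ``propionylation``: every K that is unmodified or carries only a
    mono-methyl gains a propionyl group (methylated K stays methylated, so
    the site then carries methyl + propionyl — massed together these equal a
    butyryl); lysines already carrying any other K-mark are untouched.  Every
    peptide N-terminus receives the N-terminal propionyl label.
    """
    if scheme != "propionylation":
        raise ValueError(f"unknown derivatization scheme {scheme!r}")
    registry = registry if registry is not None else default_registry()
    site_mods: dict[int, tuple[str, ...]] = {}
    for p, residue in enumerate(protein.sequence, start=1):
        existing = _site_mod_names(existing_mods, p)
        if existing:
            site_mods[p] = existing
        if residue != "K":
            continue
        if not existing or existing == ("Methyl",):
            site_mods[p] = (*existing, "Propionyl")
    return Derivatization(site_mods=site_mods, n_term_label="Propionyl")
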