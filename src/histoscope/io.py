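"""Readers and writers for the formats the toolkit touches.

FASTA protein databases, UniProt flat-file feature tables (curated
modification sites), identification CSVs in a Mascot-like dialect, and
MGF/MSP spectral libraries.  All coordinates are 1-based inclusive.

The identification CSV dialect is a defined canonical column set —
``accession, pep_start, pep_end, pep_seq, pep_var_mods, pep_score,
pep_is_unique, pep_exp_z, run_id`` — with a column-mapping hook so real
search-engine exports can be adapted.  Modification strings are written as
``"K4: Acetyl; R8: Methyl"`` (residue + *protein* position, semicolon
separated); a tolerant parser also accepts the positional variable-mod
string style (``0.0200.0``) given the ordered variable-mod names.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _pmgf

from .modifications import ModificationRegistry, default_registry

__all__ = [
    "ProteinRecord",
    "AnnotatedSite",
    "IdentificationRecord",
    "Spectrum",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "UNIPROT_NOTE_SYNONYMS",
    "FeatureParseResult",
    "parse_uniprot_features",
    "IDENT_COLUMNS",
    "IdentParseResult",
    "parse_ident_csv",
    "write_ident_csv",
    "format_mod_string",
    "parse_mod_string",
    "write_mgf",
    "read_mgf",
    "write_msp",
    "read_msp",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and variant label."""

    accession: str
    variant_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.accession!r}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True)
class AnnotatedSite:
    """A curated modification site on a protein (1-based position)."""

    accession: str
    position: int
    modification: str
    source_note: str = ""


@dataclass(frozen=True)
class IdentificationRecord:
    """One peptide-spectrum match as exported from a search.

    ``modifications`` holds (position-within-peptide, modification-name)
    pairs; peptide position 1 is the first residue, 0 denotes the peptide
    N-terminus.
    """

    accession: str
    start: int
    end: int
    peptide_sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    score: float = 0.0
    is_unique: bool = False
    charge: int = 2
    run_id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.end - self.start + 1 != len(self.peptide_sequence):
            raise ValueError(
                f"peptide length {len(self.peptide_sequence)} does not match "
                f"coordinates {self.start}..{self.end}"
            )
        object.__setattr__(self, "modifications", tuple(sorted(self.modifications)))


@dataclass
class Spectrum:
    """A minimal spectrum container for MGF/MSP round-trips.

    ``peaks`` is a list of ``(mz, intensity, label)`` triples; ``label`` may
    be empty for empirical peaks.
    """

    title: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float, str]] = field(default_factory=list)


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

class FastaError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None) -> None:
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


def _parse_header(header: str) -> tuple[str, str]:
    """Split a FASTA header into (accession, variant name).

    Understands the ``db|ACC|NAME`` convention; otherwise the first token is
    the accession and the rest of the line the variant name.
    """
    token, _, rest = header.partition(" ")
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1], parts[2] or rest.strip() or parts[1]
    return token, rest.strip() or token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA protein database into :class:`ProteinRecord` objects.

    Sequences are upper-cased and line wrapping removed.  An illegal residue
    or malformed header raises :class:`FastaError` naming the line.
    """
    path = Path(path)
    # track line numbers so alphabet violations can be located
    line_of_header: dict[int, int] = {}
    idx = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                idx += 1
                line_of_header[idx] = lineno
                if not line[1:].strip():
                    raise FastaError("empty FASTA header", lineno)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        accession, variant = _parse_header(rec.description)
        seq = str(rec.seq).upper()
        header_line = line_of_header.get(i, 1)
        if not seq:
            raise FastaError(f"record {accession!r} has an empty sequence", header_line)
        bad = set(seq) - VALID_RESIDUES
        if bad:
            # locate the first offending residue line for the diagnostic
            raise FastaError(
                f"record {accession!r} contains invalid residue(s) {sorted(bad)}",
                _locate_bad_residue(path, header_line, bad),
            )
        if accession in seen:
            raise FastaError(f"duplicate accession {accession!r}", header_line)
        seen.add(accession)
        records.append(ProteinRecord(accession, variant, seq))
    return records


def _locate_bad_residue(path: Path, after_line: int, bad: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= after_line or line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return after_line


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">sp|{p.accession}|{p.variant_name}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")


# --------------------------------------------------------------------------
# UniProt feature table
# --------------------------------------------------------------------------

#: Editable note -> registry-name synonym table.  Matching is by prefix on
#: the note text with qualifiers after ";" stripped, so entries like
#: "N6-acetyllysine; alternate" still map.
UNIPROT_NOTE_SYNONYMS: dict[str, str] = {
    "N6-acetyllysine": "Acetyl",
    "N6-methyllysine": "Methyl",
    "N6,N6-dimethyllysine": "Dimethyl",
    "N6,N6,N6-trimethyllysine": "Trimethyl",
    "N6-butyryllysine": "Butyryl",
    "N6-crotonyllysine": "Crotonyl",
    "N6-propionyllysine": "Propionyl",
    "Omega-N-methylarginine": "Methyl",
    "Omega-N-methylated arginine": "Methyl",
    "Symmetric dimethylarginine": "Dimethyl",
    "Asymmetric dimethylarginine": "Dimethyl",
    "Dimethylated arginine": "Dimethyl",
    "Citrulline": "Citrullination",
    "Phosphoserine": "Phospho",
    "Phosphothreonine": "Phospho",
    "Glycyl lysine isopeptide": "GG",
}

#: Residues a note may legitimately sit on.  Stricter than the registry's
#: target set: "Phosphoserine" names serine, so a threonine position is a
#: curation/parse error even though Phospho itself targets both S and T.
_NOTE_RESIDUES: dict[str, frozenset[str]] = {
    "Phosphoserine": frozenset("S"),
    "Phosphothreonine": frozenset("T"),
}

_FT_KEY = re.compile(r"^FT\s{3}(\w+)\s+(\d+)(?:\.\.(\d+))?\s*$")
_FT_NOTE = re.compile(r'/note="([^"]*)"?')
_AC_LINE = re.compile(r"^AC\s+(\S+?);")


@dataclass
class FeatureParseResult:
    """Sites that mapped, notes that did not, and rejected records."""

    sites: list[AnnotatedSite]
    unmapped: list[tuple[str, int, str]]   # (accession, position, note)
    rejected: list[tuple[str, int, str, str]]  # (accession, position, note, reason)


def parse_uniprot_features(
    text: str,
    proteins: Iterable[ProteinRecord],
    registry: ModificationRegistry | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> FeatureParseResult:
    """Parse UniProt flat-file MOD_RES/CROSSLNK feature lines.

    ``text`` may contain ``AC`` lines switching the current accession; an
    excerpt without any applies to the single protein given (ambiguous
    otherwise).  Notes that match no synonym are collected in ``unmapped``;
    sites whose position is out of range or whose residue is incompatible
    with the mapped modification land in ``rejected`` with a warning.
    """
    registry = registry if registry is not None else default_registry()
    synonyms = dict(UNIPROT_NOTE_SYNONYMS if synonyms is None else synonyms)
    by_acc = {p.accession: p for p in proteins}

    has_ac = any(_AC_LINE.match(ln) for ln in text.splitlines())
    current_acc: str | None = None
    if not has_ac:
        if len(by_acc) == 1:
            current_acc = next(iter(by_acc))
        elif by_acc:
            raise ValueError(
                "feature table has no AC lines and multiple proteins were given"
            )

    result = FeatureParseResult([], [], [])
    pending: tuple[str | None, str, int] | None = None  # (acc, key, position)

    def _flush(note: str) -> None:
        nonlocal pending
        if pending is None:
            return
        acc, key, pos = pending
        pending = None
        if key not in ("MOD_RES", "CROSSLNK"):
            return
        note_head = note.split(";")[0].strip()
        match = next(
            ((prefix, name) for prefix, name in synonyms.items()
             if note_head.startswith(prefix) or note.startswith(prefix)),
            None,
        )
        prefix, mod = match if match else (None, None)
        if acc is None:
            warnings.warn(f"feature at position {pos} has no accession context")
            return
        if acc not in by_acc:
            warnings.warn(f"unknown accession {acc!r} in feature table")
            return
        if mod is None:
            result.unmapped.append((acc, pos, note))
            return
        protein = by_acc[acc]
        if not (1 <= pos <= len(protein)):
            warnings.warn(f"{acc} position {pos} outside protein length {len(protein)}")
            result.rejected.append((acc, pos, note, "position out of range"))
            return
        residue = protein.residue(pos)
        allowed = _NOTE_RESIDUES.get(prefix, registry[mod].targets)
        if residue not in allowed or not registry[mod].is_compatible(residue):
            warnings.warn(
                f"{acc} {residue}{pos}: {note_head!r} ({mod}) does not target "
                f"{residue}; rejected"
            )
            result.rejected.append((acc, pos, note, f"{mod} does not target {residue}"))
            return
        result.sites.append(AnnotatedSite(acc, pos, mod, note))

    for line in text.splitlines():
        m = _AC_LINE.match(line)
        if m:
            _flush("")
            current_acc = m.group(1)
            continue
        m = _FT_KEY.match(line)
        if m:
            _flush("")
            pending = (current_acc, m.group(1), int(m.group(2)))
            continue
        m = _FT_NOTE.search(line)
        if m and pending is not None:
            _flush(m.group(1))
    _flush("")
    return result


# --------------------------------------------------------------------------
# modification-string codec
# --------------------------------------------------------------------------

_MOD_TOKEN = re.compile(r"^(?:([A-Z])|(N-term))(\d*)\s*:\s*(\S.*?)\s*$")


def format_mod_string(record_start: int, peptide_seq: str,
                      placements: Sequence[tuple[int, str]]) -> str:
    """Encode (peptide-position, name) placements as ``"K4: Acetyl; ..."``.

    Positions are converted to protein coordinates; peptide position 0 (the
    N-terminus) is written as ``N-term: Name``.
    """
    parts = []
    for pep_pos, name in sorted(placements):
        if pep_pos == 0:
            parts.append(f"N-term: {name}")
        else:
            residue = peptide_seq[pep_pos - 1]
            parts.append(f"{residue}{record_start + pep_pos - 1}: {name}")
    return "; ".join(parts)


def parse_mod_string(
    text: str,
    start: int,
    peptide_seq: str,
    var_mod_names: Sequence[str] | None = None,
) -> list[tuple[int, str]]:
    """Decode a modification string into (peptide-position, name) pairs.

    Accepts the canonical ``"K4: Acetyl; R8: Methyl"`` dialect (protein
    coordinates) and, when ``var_mod_names`` is given, the positional digit
    string ``"0.0200.0"`` (N-term, one digit per residue, C-term; digit *d*
    selects ``var_mod_names[d-1]``).
    """
    text = text.strip()
    if not text:
        return []
    if re.fullmatch(r"\d+\.\d+\.\d+", text):
        if var_mod_names is None:
            raise ValueError(
                "positional modification string needs var_mod_names to decode"
            )
        nterm, middle, cterm = text.split(".")
        if len(middle) != len(peptide_seq):
            raise ValueError(
                f"positional string length {len(middle)} != peptide length "
                f"{len(peptide_seq)}"
            )
        placements: list[tuple[int, str]] = []
        if int(nterm):
            placements.append((0, var_mod_names[int(nterm) - 1]))
        for i, digit in enumerate(middle, start=1):
            if digit != "0":
                placements.append((i, var_mod_names[int(digit) - 1]))
        if int(cterm):
            placements.append((len(peptide_seq), var_mod_names[int(cterm) - 1]))
        return placements

    placements = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        m = _MOD_TOKEN.match(token)
        if not m:
            raise ValueError(f"unparseable modification token {token!r}")
        residue, nterm, pos_text, name = m.groups()
        if nterm:
            placements.append((0, name))
            continue
        if not pos_text:
            raise ValueError(f"modification token {token!r} lacks a position")
        protein_pos = int(pos_text)
        pep_pos = protein_pos - start + 1
        if not (1 <= pep_pos <= len(peptide_seq)):
            raise ValueError(
                f"modification position {protein_pos} outside peptide "
                f"{start}..{start + len(peptide_seq) - 1}"
            )
        if peptide_seq[pep_pos - 1] != residue:
            raise ValueError(
                f"modification token {token!r}: residue mismatch at {protein_pos} "
                f"(peptide has {peptide_seq[pep_pos - 1]})"
            )
        placements.append((pep_pos, name))
    return placements


# --------------------------------------------------------------------------
# identification CSV
# --------------------------------------------------------------------------

#: Canonical column set of the identification CSV dialect.
IDENT_COLUMNS = (
    "accession", "pep_start", "pep_end", "pep_seq", "pep_var_mods",
    "pep_score", "pep_is_unique", "pep_exp_z", "run_id",
)

_MANDATORY = ("accession", "pep_start", "pep_end", "pep_seq")


@dataclass
class IdentParseResult:
    records: list[IdentificationRecord]
    rejected: list[tuple[int, str]]  # (0-based row index, reason)


def parse_ident_csv(
    path: str | Path,
    proteins: Iterable[ProteinRecord] | None = None,
    column_map: Mapping[str, str] | None = None,
    var_mod_names: Sequence[str] | None = None,
) -> IdentParseResult:
    """Read an identification CSV into :class:`IdentificationRecord` objects.

    ``column_map`` renames canonical column -> actual column so foreign
    exports can be adapted.  When ``proteins`` is given, rows whose peptide
    sequence disagrees with the protein substring at [start, end] are
    rejected with a per-row diagnostic rather than silently kept.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (column_map or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"identification CSV is missing column(s) {missing}")
    by_acc = {p.accession: p for p in proteins} if proteins is not None else None

    result = IdentParseResult([], [])
    for idx, row in df.iterrows():
        try:
            acc = row["accession"]
            start, end = int(row["pep_start"]), int(row["pep_end"])
            seq = row["pep_seq"].upper()
            if by_acc is not None:
                protein = by_acc.get(acc)
                if protein is None:
                    raise ValueError(f"unknown accession {acc!r}")
                if protein.sequence[start - 1:end] != seq:
                    raise ValueError(
                        f"sequence {seq!r} does not match {acc} residues {start}..{end}"
                    )
            mods = parse_mod_string(
                str(row.get("pep_var_mods", "")), start, seq, var_mod_names
            )
            record = IdentificationRecord(
                accession=acc,
                start=start,
                end=end,
                peptide_sequence=seq,
                modifications=tuple(mods),
                score=float(row.get("pep_score", 0) or 0),
                is_unique=str(row.get("pep_is_unique", "")).strip().lower()
                in ("1", "true", "yes"),
                charge=int(row.get("pep_exp_z", 2) or 2),
                run_id=str(row.get("run_id", "")),
            )
        except (ValueError, KeyError, IndexError) as exc:
            result.rejected.append((int(idx), str(exc)))
            continue
        result.records.append(record)
    if result.rejected:
        warnings.warn(
            f"rejected {len(result.rejected)} of {len(df)} identification rows"
        )
    return result


def write_ident_csv(records: Iterable[IdentificationRecord], path: str | Path) -> None:
    rows = [
        {
            "accession": r.accession,
            "pep_start": r.start,
            "pep_end": r.end,
            "pep_seq": r.peptide_sequence,
            "pep_var_mods": format_mod_string(r.start, r.peptide_sequence, r.modifications),
            "pep_score": r.score,
            "pep_is_unique": int(r.is_unique),
            "pep_exp_z": r.charge,
            "run_id": r.run_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(IDENT_COLUMNS)).to_csv(path, index=False)


# --------------------------------------------------------------------------
# MGF / MSP spectral libraries
# --------------------------------------------------------------------------

def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (BEGIN IONS blocks, annotated peak lists)."""
    entries = []
    for s in spectra:
        if not s.precursor_charge:
            raise ValueError(f"spectrum {s.title!r} has no precursor charge")
        entries.append({
            "m/z array": [p[0] for p in s.peaks],
            "intensity array": [p[1] for p in s.peaks],
            "params": {
                "title": s.title,
                "pepmass": round(s.precursor_mz, 6),
                "charge": s.precursor_charge,
            },
        })
    with open(path, "w") as fh:
        _pmgf.write(entries, fh)


def read_mgf(path: str | Path) -> list[Spectrum]:
    out = []
    with _pmgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 0
            pepmass = params.get("pepmass", (0.0,))[0]
            peaks = [
                (float(mz), float(inten), "")
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            ]
            out.append(Spectrum(str(params.get("title", "")), float(pepmass),
                                charge, peaks))
    return out


def write_msp(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MSP (Name:/MW:/Comment:/Num peaks: blocks)."""
    with open(path, "w") as fh:
        for s in spectra:
            if not s.precursor_charge:
                raise ValueError(f"spectrum {s.title!r} has no precursor charge")
            mw = s.precursor_mz * s.precursor_charge
            fh.write(f"Name: {s.title}\n")
            fh.write(f"MW: {mw:.6f}\n")
            fh.write(
                f"Comment: Parent={s.precursor_mz:.6f} Charge={s.precursor_charge}\n"
            )
            fh.write(f"Num peaks: {len(s.peaks)}\n")
            for mz, inten, label in s.peaks:
                tail = f'\t"{label}"' if label else ""
                fh.write(f"{mz:.6f}\t{inten:.6f}{tail}\n")
            fh.write("\n")


def read_msp(path: str | Path) -> list[Spectrum]:
    out: list[Spectrum] = []
    current: Spectrum | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                current = None
                continue
            if line.startswith("Name:"):
                current = Spectrum(line[5:].strip(), 0.0, 0, [])
                out.append(current)
            elif current is None:
                continue
            elif line.startswith("Comment:"):
                m = re.search(r"Parent=([\d.]+)", line)
                if m:
                    current.precursor_mz = float(m.group(1))
                m = re.search(r"Charge=(\d+)", line)
                if m:
                    current.precursor_charge = int(m.group(1))
            elif line.startswith(("MW:", "Num peaks:")):
                continue
            else:
                parts = line.split("\t")
                label = parts[2].strip('"') if len(parts) > 2 else ""
                current.peaks.append((float(parts[0]), float(parts[1]), label))
    return out
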