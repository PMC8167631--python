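"""Synthetic histone-like experiments with known ground truth.

Generates everything the toolkit consumes without any download: histone-like
proteins (short, K/R-dense, heavily modified), curated-site annotations,
ground-truth digests and identification CSVs, and replicate/QC feature
tables with controlled variance.

The emulated design mirrors a four-workflow comparison: ``Tryp`` (plain
tryptic digest), ``PropTryp`` (propionylation then trypsin), ``ArgC`` and
``GRX`` (two arginine-specific enzymes).  Each workflow is prepared in
independent replicates (preparation noise + instrument noise) and measured
alongside repeatedly injected QC pools (instrument noise only), so the
injected variance components can be recovered from the output and compared
with what :func:`histoscope.metrics.cv_decomposition` reports.

Deliberate mechanisms built into the simulation:

* **DDA charge gap** — every ion gets a charge from the workflow's
  charge-state model; singly charged ions appear in the feature tables but
  carry no annotation and are withheld from the identification CSVs (the
  instrument never selects them for fragmentation).  A fraction of multiply
  charged peptidoforms additionally emits a co-eluting singly charged
  satellite ion of the same species, which is what charge-state
  deconvolution can later rescue.  The full ground-truth identity of every
  feature, annotated or not, sits in the ``ground_truth`` column.
* **ArgC degradation** — a configurable fraction of the specific ArgC
  signal is diverted into semi-specific fragments shared (at a low level)
  with GRX, so normalization factors computed on "all" vs "specific"
  feature subsets diverge between the two enzymes.
* **Propionyl retention shift** — retention times come from an additive
  hydrophobicity index rescaled to the gradient window, plus a fixed
  increment per propionyl group; only the ordering is meaningful.

Everything is driven by one integer seed and is byte-identical across
reruns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .digestion import PROTEASES, Peptide, apply_derivatization, digest, semi_specific_expand
from .io import (
    AnnotatedSite,
    IdentificationRecord,
    ProteinRecord,
    write_fasta,
    write_ident_csv,
)
from .library import Peptidoform, precursor_mz
from .modifications import ModificationRegistry, default_registry

__all__ = [
    "ExperimentDesign",
    "WORKFLOW_ENZYMES",
    "make_proteins",
    "SimulationResult",
    "simulate_experiment",
]

#: Workflow name -> (protease preset, derivatization scheme or None).
WORKFLOW_ENZYMES: dict[str, tuple[str, str | None]] = {
    "Tryp": ("trypsin", None),
    "PropTryp": ("trypsin", "propionylation"),
    "ArgC": ("argc", None),
    "GRX": ("grx", None),
}

_DEFAULT_CHARGE_MODELS: dict[str, dict[int, float]] = {
    # propionylation blocks protonation sites: half the ions end up 1+
    "PropTryp": {1: 0.50, 2: 0.40, 3: 0.10},
    "ArgC": {1: 0.20, 2: 0.55, 3: 0.25},
    "GRX": {1: 0.20, 2: 0.55, 3: 0.25},
    # short tryptic peptides: mostly 2+, some 1+
    "Tryp": {1: 0.30, 2: 0.55, 3: 0.15},
}


@dataclass
class ExperimentDesign:
    """Parameters of a simulated multi-workflow comparison."""

    workflows: tuple[str, ...] = ("Tryp", "PropTryp", "ArgC", "GRX")
    replicates_per_workflow: int = 5
    qc_injections: int = 5
    qc_mixtures: tuple[tuple[str, ...], ...] | None = None  # default: one per workflow
    seed: int = 0
    prep_cv_fraction: float = 0.20
    instrument_cv_fraction: float = 0.05
    dropout_rate: float = 0.05
    max_missed: int = 1
    min_length: int = 4
    charge_models: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CHARGE_MODELS.items()}
    )
    # fraction of specific ArgC signal diverted into semi-specific fragments
    argc_degradation_loss: float = 0.5
    # abundance of the shared semi-specific pool relative to its source
    semi_level: dict[str, float] = field(
        default_factory=lambda: {"ArgC": 1.0, "GRX": 0.15}
    )
    # chance a z>=2 ion also shows a co-eluting singly charged satellite
    satellite_z1_rate: float = 0.2
    satellite_z1_fraction: float = 0.5
    base_log10_mean: float = 6.0
    base_log10_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.replicates_per_workflow < 2:
            raise ValueError("need at least 2 replicates per workflow")
        if self.prep_cv_fraction < 0 or self.instrument_cv_fraction < 0:
            raise ValueError("CV fractions must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        for wf in self.workflows:
            if wf not in WORKFLOW_ENZYMES:
                raise ValueError(f"unknown workflow {wf!r}")
            model = self.charge_models.get(wf)
            if model is None:
                raise ValueError(f"no charge model for workflow {wf!r}")
            if abs(sum(model.values()) - 1.0) > 1e-9:
                raise ValueError(f"charge probabilities for {wf!r} must sum to 1")
        if self.qc_mixtures is None:
            self.qc_mixtures = tuple((wf,) for wf in self.workflows)
        for mixture in self.qc_mixtures:
            unknown = set(mixture) - set(self.workflows)
            if unknown:
                raise ValueError(f"QC mixture references unknown workflow(s) {unknown}")


# --------------------------------------------------------------------------
# protein generation
# --------------------------------------------------------------------------

_OTHER_RESIDUES = "AGVLSTPEQDNFYHIM"  # no C/W: histones are cysteine-poor
_SITE_MODS = {
    "K": ("Acetyl", "Methyl", "Dimethyl", "Trimethyl", "Butyryl", "Crotonyl", "GG"),
    "R": ("Methyl", "Dimethyl", "Citrullination"),
    "S": ("Phospho",),
    "T": ("Phospho",),
}


def make_proteins(
    n: int = 6,
    length_range: tuple[int, int] = (120, 160),
    kr_density: float = 0.25,
    sites_per_protein: int = 8,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[AnnotatedSite]]:
    """Histone-like random proteins with curated modification sites.

    Each position is K or R with probability ``kr_density`` (K twice as
    likely as R, echoing histone composition), otherwise a residue from a
    cysteine/tryptophan-free background.  Curated sites are sampled on
    K/R/S/T positions with registry-compatible modifications, so every
    emitted :class:`AnnotatedSite` satisfies residue compatibility by
    construction.
    """
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    sites: list[AnnotatedSite] = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        residues = []
        for _ in range(length):
            if rng.random() < kr_density:
                residues.append("K" if rng.random() < 2 / 3 else "R")
            else:
                residues.append(_OTHER_RESIDUES[rng.integers(len(_OTHER_RESIDUES))])
        seq = "".join(residues)
        acc = f"SYNH{i + 1}"
        proteins.append(ProteinRecord(acc, f"synH{i + 1}.1", seq))
        candidates = [p for p, r in enumerate(seq, start=1) if r in _SITE_MODS]
        k = min(sites_per_protein, len(candidates))
        if k:
            chosen = rng.choice(candidates, size=k, replace=False)
            for pos in sorted(int(p) for p in chosen):
                options = _SITE_MODS[seq[pos - 1]]
                mod = options[rng.integers(len(options))]
                sites.append(AnnotatedSite(acc, pos, mod, f"synthetic {mod} site"))
    return proteins, sites


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _retention_time(form: Peptidoform, gradient: tuple[float, float] = (5.0, 55.0)) -> float:
    """Additive hydrophobicity proxy mapped into the gradient window."""
    score = sum(_KYTE_DOOLITTLE[a] for a in form.sequence) / max(len(form), 1)
    # map the K/R-rich index range [-4.5, 4.5] onto the gradient
    lo, hi = gradient
    rt = lo + (score + 4.5) / 9.0 * (hi - lo)
    n_prop = sum(1 for _, name in form.placements if name in ("Propionyl", "Overpropionyl"))
    return rt + 2.0 * n_prop


@dataclass
class SimulationResult:
    """Feature tables, identification records and the ground-truth ledger."""

    design: ExperimentDesign
    proteins: list[ProteinRecord]
    sites: list[AnnotatedSite]
    feature_tables: dict[str, pd.DataFrame]
    replicate_runs: dict[str, list[str]]
    qc_runs: dict[str, list[str]]
    ident_records: dict[str, list[IdentificationRecord]]
    truth: dict

    def combined_table(self, workflows: Sequence[str]) -> pd.DataFrame:
        """Align several workflows' tables into one cross-workflow project.

        Features are matched by (annotation, charge, feature class); a
        feature absent from a workflow gets zero abundance in its runs —
        which is exactly what makes subset-restricted normalization factors
        informative.
        """
        frames = []
        for wf in workflows:
            t = self.feature_tables[wf].copy()
            t = t.set_index(t["ground_truth"] + "/z" + t["charge"].astype(str))
            frames.append(t)
        index = frames[0].index
        for f in frames[1:]:
            index = index.union(f.index)
        meta = pd.concat(frames)[list(("feature_id", "mz", "rt", "charge",
                                       "annotation", "ground_truth", "specificity"))]
        meta = meta[~meta.index.duplicated()].reindex(index)
        out = meta.copy()
        out["feature_id"] = [f"comb_{i}" for i in range(len(out))]
        for wf, frame in zip(workflows, frames):
            runs = self.replicate_runs[wf] + self.qc_runs[wf]
            cols = frame[runs].reindex(index).fillna(0.0)
            out = pd.concat([out, cols], axis=1)
        return out.reset_index(drop=True)

    def write(self, outdir: str | Path) -> None:
        """Dump everything as the plain-text formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        for wf, table in self.feature_tables.items():
            table.to_csv(outdir / f"features_{wf}.csv", index=False)
        for wf, records in self.ident_records.items():
            write_ident_csv(records, outdir / f"idents_{wf}.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        with open(outdir / "design.json", "w") as fh:
            json.dump(asdict(self.design), fh, indent=1, sort_keys=True, default=list)


def _workflow_peptidoforms(
    workflow: str,
    proteins: Sequence[ProteinRecord],
    sites: Sequence[AnnotatedSite],
    design: ExperimentDesign,
    registry: ModificationRegistry,
) -> list[Peptidoform]:
    from .library import enumerate_peptidoforms

    enzyme, scheme = WORKFLOW_ENZYMES[workflow]
    forms: list[Peptidoform] = []
    for protein in proteins:
        deriv = None
        site_mods = None
        if scheme is not None:
            deriv = apply_derivatization(protein, scheme, registry=registry)
            site_mods = deriv.site_mods
        for peptide in digest(protein, enzyme, design.max_missed, site_mods, registry):
            if len(peptide) < design.min_length:
                continue
            forms.extend(
                enumerate_peptidoforms(peptide, sites, (), 0, deriv, registry)
            )
    forms.sort(key=Peptidoform.key)
    return forms


def _semi_specific_pool(
    proteins: Sequence[ProteinRecord],
    design: ExperimentDesign,
    registry: ModificationRegistry,
    rng: np.random.Generator,
    max_fragments: int = 150,
) -> list[Peptidoform]:
    """Degradation fragments of the R-specific digest, shared by ArgC/GRX."""
    fragments: list[Peptide] = []
    for protein in proteins:
        specific = digest(protein, "argc", 0, None, registry)
        expanded = semi_specific_expand(specific, design.min_length)
        fragments.extend(p for p in expanded if not p.fully_specific)
    fragments.sort(key=lambda p: (p.accession, p.start, p.end))
    if len(fragments) > max_fragments:
        idx = rng.choice(len(fragments), size=max_fragments, replace=False)
        fragments = [fragments[i] for i in sorted(idx)]
    return [Peptidoform(f, (), "fixed-label") for f in fragments]


def simulate_experiment(
    design: ExperimentDesign,
    proteins: Sequence[ProteinRecord] | None = None,
    sites: Sequence[AnnotatedSite] | None = None,
    registry: ModificationRegistry | None = None,
) -> SimulationResult:
    """Run the full in-silico experiment for every workflow in the design.

    Per workflow: digest under its enzyme/derivatization bundle, enumerate
    peptidoforms (curated sites as localized marks), give each ion a base
    abundance (log-normal), a charge from the workflow's charge model and a
    hydrophobicity-proxy retention time; then produce replicate runs
    (preparation x instrument noise), QC runs (instrument noise only, on
    the mixture average) and identification records for every fragmentable
    (z >= 2) specific ion in every replicate where it survived dropout.
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(design.seed)
    if proteins is None or sites is None:
        proteins, sites = make_proteins(seed=design.seed)
    proteins, sites = list(proteins), list(sites)
    by_acc = {p.accession: p for p in proteins}

    semi_pool = _semi_specific_pool(proteins, design, registry, rng)

    feature_tables: dict[str, pd.DataFrame] = {}
    replicate_runs: dict[str, list[str]] = {}
    qc_runs: dict[str, list[str]] = {wf: [] for wf in design.workflows}
    ident_records: dict[str, list[IdentificationRecord]] = {}
    bases: dict[str, dict[tuple[str, int], float]] = {}
    truth_features: dict[str, dict] = {}

    # ---- per-workflow ion populations and replicate runs -----------------
    staged: dict[str, pd.DataFrame] = {}
    for wf in design.workflows:
        forms = _workflow_peptidoforms(wf, proteins, sites, design, registry)
        specificity = ["specific"] * len(forms)
        scale = [1.0] * len(forms)
        if wf in design.semi_level:
            if wf == "ArgC" and design.argc_degradation_loss > 0:
                scale = [1.0 - design.argc_degradation_loss] * len(forms)
            level = design.semi_level[wf]
            forms = forms + semi_pool
            specificity += ["semi_specific"] * len(semi_pool)
            scale += [level] * len(semi_pool)

        model = design.charge_models[wf]
        z_values = np.array(sorted(model))
        z_probs = np.array([model[z] for z in z_values], dtype=float)
        charges = rng.choice(z_values, size=len(forms), p=z_probs)
        base = 10.0 ** rng.normal(design.base_log10_mean, design.base_log10_sd,
                                  size=len(forms))
        base *= np.asarray(scale)

        rows = []
        wf_bases: dict[tuple[str, int], float] = {}

        def _add_row(form: Peptidoform, z: int, b: float, spec_label: str,
                     annotated: bool) -> None:
            p = form.peptide
            mods = ",".join(f"{pos}:{name}" for pos, name in form.placements)
            ground_truth = f"{p.accession}|{p.start}-{p.end}|{p.sequence}|mods={mods}"
            rows.append({
                "feature_id": f"{wf}_f{len(rows)}",
                "mz": precursor_mz(form, z, registry),
                "rt": _retention_time(form),
                "charge": z,
                # DDA never fragments 1+ precursors: no annotation for them
                "annotation": ground_truth if annotated else "",
                "ground_truth": ground_truth,
                "specificity": spec_label,
                "_form": form,
                "_base": float(b),
            })
            wf_bases[(ground_truth, z)] = float(b)

        for form, z, b, spec_label in zip(forms, charges, base, specificity):
            z = int(z)
            _add_row(form, z, float(b), spec_label, annotated=z >= 2)
            if z >= 2 and rng.random() < design.satellite_z1_rate:
                # the same species also shows up singly charged, co-eluting
                _add_row(form, 1, float(b) * design.satellite_z1_fraction,
                         spec_label, annotated=False)
        table = pd.DataFrame(rows)
        bases[wf] = wf_bases

        reps = [f"{wf}_rep{r + 1}" for r in range(design.replicates_per_workflow)]
        replicate_runs[wf] = reps
        n = len(table)
        for run in reps:
            values = (
                table["_base"].to_numpy()
                * _lognormal_factor(rng, design.prep_cv_fraction, n)
                * _lognormal_factor(rng, design.instrument_cv_fraction, n)
            )
            if design.dropout_rate > 0:
                values = np.where(rng.random(n) < design.dropout_rate, np.nan, values)
            table[run] = values
        staged[wf] = table

    # ---- QC mixtures (instrument noise only) -----------------------------
    for m_idx, mixture in enumerate(design.qc_mixtures):
        label = "-".join(mixture)
        for wf in mixture:
            table = staged[wf]
            keys = list(zip(table["ground_truth"], table["charge"].astype(int)))
            mixed_base = np.array([
                float(np.mean([bases[m].get(k, 0.0) for m in mixture])) for k in keys
            ])
            n = len(table)
            for q in range(design.qc_injections):
                run = f"QC{m_idx + 1}_{label}_inj{q + 1}_{wf}"
                table[run] = mixed_base * _lognormal_factor(
                    rng, design.instrument_cv_fraction, n
                )
                qc_runs[wf].append(run)

    # ---- identification records (the DDA rule) ---------------------------
    for wf in design.workflows:
        table = staged[wf]
        records: list[IdentificationRecord] = []
        for _, row in table.iterrows():
            form: Peptidoform = row["_form"]
            if int(row["charge"]) < 2:
                continue  # singly charged precursors are never fragmented
            if row["specificity"] != "specific":
                continue  # only the specific search feeds the standard CSVs
            p = form.peptide
            occurrences = sum(
                1 for prot in proteins if p.sequence in prot.sequence
            )
            is_unique = occurrences == 1
            for run in replicate_runs[wf]:
                if np.isnan(row[run]):
                    continue
                records.append(IdentificationRecord(
                    accession=p.accession,
                    start=p.start,
                    end=p.end,
                    peptide_sequence=p.sequence,
                    modifications=form.placements,
                    score=float(np.round(20.0 + 60.0 * rng.random(), 2)),
                    is_unique=is_unique,
                    charge=int(row["charge"]),
                    run_id=run,
                ))
        ident_records[wf] = records
        truth_features[wf] = {
            "n_features": int(len(table)),
            "n_singly_charged": int((table["charge"] == 1).sum()),
            "n_semi_specific": int((table["specificity"] == "semi_specific").sum()),
        }
        feature_tables[wf] = table.drop(columns=["_form", "_base"])

    truth = {
        "seed": design.seed,
        "prep_cv_fraction": design.prep_cv_fraction,
        "instrument_cv_fraction": design.instrument_cv_fraction,
        "dropout_rate": design.dropout_rate,
        "charge_models": {wf: {str(z): p for z, p in m.items()}
                          for wf, m in design.charge_models.items()},
        "argc_degradation_loss": design.argc_degradation_loss,
        "per_workflow": truth_features,
        "variants": {p.accession: p.variant_name for p in by_acc.values()},
    }
    return SimulationResult(
        design=design,
        proteins=proteins,
        sites=sites,
        feature_tables=feature_tables,
        replicate_runs=replicate_runs,
        qc_runs=qc_runs,
        ident_records=ident_records,
        truth=truth,
    )
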