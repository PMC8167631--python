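"""Workflow-comparison metrics for label-free histone runs.

Feature tables are plain :class:`pandas.DataFrame` objects with the meta
columns ``feature_id, mz, rt, charge, annotation, specificity`` and one
abundance column per run (``NaN`` = missing, 0 allowed).  ``annotation``
holds a peptidoform title (empty/NaN = unannotated); ``specificity`` is
``"specific"`` or ``"semi_specific"`` for annotated features.

Computations covered: unique-variant PSM counting, %CV and its
total-vs-instrumental decomposition (never normalized first — the
constant starting amount is the ground truth, and normalizing would skew
the variance estimate), charge-state distributions, median-log-ratio
normalization factors, singly-charged annotation transfer by charge-state
deconvolution, peptide-length distributions and summed annotated MS1
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import IdentificationRecord, ProteinRecord

__all__ = [
    "PROTON_MASS",
    "META_COLUMNS",
    "FeatureRecord",
    "feature_frame",
    "run_columns",
    "cv_percent",
    "unique_variant_psms",
    "CVDecomposition",
    "cv_decomposition",
    "charge_distribution",
    "normalization_factors",
    "apply_normalization",
    "DeconvolutionTransfer",
    "deconvolute_charge",
    "length_distribution",
    "summed_annotated_signal",
    "pca_view",
]

PROTON_MASS = 1.00727646688

META_COLUMNS = (
    "feature_id", "mz", "rt", "charge", "annotation", "specificity",
    "ground_truth", "by_deconvolution",
)


@dataclass(frozen=True)
class FeatureRecord:
    """One aligned LC-MS feature: an ion with per-run abundances."""

    feature_id: str
    mz: float
    rt: float
    charge: int
    abundances: Mapping[str, float] = field(default_factory=dict)
    annotation: str | None = None
    specificity: str = "specific"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        object.__setattr__(self, "abundances", dict(self.abundances))


def feature_frame(features: Iterable[FeatureRecord]) -> pd.DataFrame:
    """Assemble :class:`FeatureRecord` objects into the canonical table."""
    rows = []
    for f in features:
        row = {
            "feature_id": f.feature_id,
            "mz": f.mz,
            "rt": f.rt,
            "charge": f.charge,
            "annotation": f.annotation or "",
            "specificity": f.specificity,
        }
        row.update(f.abundances)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=list(META_COLUMNS))
    return df


def run_columns(table: pd.DataFrame) -> list[str]:
    """Abundance columns = everything that is not a meta column."""
    return [c for c in table.columns if c not in META_COLUMNS]


def _annotated_mask(table: pd.DataFrame) -> pd.Series:
    ann = table.get("annotation")
    if ann is None:
        return pd.Series(False, index=table.index)
    return ann.notna() & (ann.astype(str).str.len() > 0)


# --------------------------------------------------------------------------
# %CV
# --------------------------------------------------------------------------

def cv_percent(values: Sequence[float]) -> float:
    """100 x sample standard deviation / mean; NaN when undefined.

    Uses the n-1 (sample) standard deviation.  A single value or a
    non-positive mean makes the quantity meaningless and is reported as
    missing (NaN) rather than raising.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass
class CVDecomposition:
    """Per-feature total vs instrumental %CV plus the abundance trend."""

    per_feature: pd.DataFrame      # feature_id, mean_abundance, total_cv, instrumental_cv
    median_total_cv: float
    median_instrumental_cv: float
    binned: pd.DataFrame           # log10 abundance bin -> median total/instr %CV
    n_excluded: int


def cv_decomposition(
    table: pd.DataFrame,
    replicate_runs: Sequence[str],
    qc_runs: Sequence[str],
    n_bins: int = 10,
) -> CVDecomposition:
    """Split workflow variability into total and instrumental %CV.

    Total %CV is computed per feature over the separately prepared
    replicates; instrumental %CV over the repeatedly injected QC pool, which
    saw the instrument but not independent preparation.  Abundances are used
    raw — no normalization — and features missing any run value are excluded
    and counted.  The ``binned`` trend gives median %CVs per log10-abundance
    bin for the %CV-vs-abundance view.
    """
    if len(replicate_runs) < 2 or len(qc_runs) < 2:
        raise ValueError("need at least 2 replicate runs and 2 QC runs")
    reps = table[list(replicate_runs)].astype(float)
    qcs = table[list(qc_runs)].astype(float)
    complete = reps.notna().all(axis=1) & qcs.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    reps, qcs = reps[complete], qcs[complete]

    total = 100.0 * reps.std(axis=1, ddof=1) / reps.mean(axis=1)
    instrumental = 100.0 * qcs.std(axis=1, ddof=1) / qcs.mean(axis=1)
    mean_abund = pd.concat([reps, qcs], axis=1).mean(axis=1)

    per_feature = pd.DataFrame({
        "feature_id": table.loc[complete, "feature_id"].values
        if "feature_id" in table else np.arange(complete.sum()),
        "mean_abundance": mean_abund.values,
        "total_cv": total.values,
        "instrumental_cv": instrumental.values,
    })

    valid = per_feature.dropna(subset=["total_cv", "instrumental_cv"])
    if len(valid):
        log_ab = np.log10(valid["mean_abundance"].clip(lower=1e-12))
        bins = pd.cut(log_ab, bins=min(n_bins, max(1, len(valid))), duplicates="drop")
        binned = (
            valid.assign(log10_abundance=log_ab, bin=bins)
            .groupby("bin", observed=True)
            .agg(
                log10_abundance=("log10_abundance", "median"),
                total_cv=("total_cv", "median"),
                instrumental_cv=("instrumental_cv", "median"),
                n=("total_cv", "size"),
            )
            .reset_index(drop=True)
        )
    else:
        binned = pd.DataFrame(
            columns=["log10_abundance", "total_cv", "instrumental_cv", "n"]
        )

    return CVDecomposition(
        per_feature=per_feature,
        median_total_cv=float(valid["total_cv"].median()) if len(valid) else float("nan"),
        median_instrumental_cv=float(valid["instrumental_cv"].median())
        if len(valid) else float("nan"),
        binned=binned,
        n_excluded=n_excluded,
    )


# --------------------------------------------------------------------------
# unique-variant PSMs
# --------------------------------------------------------------------------

def unique_variant_psms(
    records: Iterable[IdentificationRecord],
    proteins: Iterable[ProteinRecord],
    run_to_workflow: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count unique-flagged PSMs per histone variant per workflow.

    Known variants with zero unique PSMs appear as explicit zero rows — the
    absence of unique peptides is itself the finding (that workflow cannot
    call the variant).  Records flagged unique but naming an unknown
    accession are excluded with a warning.
    """
    variant_of = {p.accession: p.variant_name for p in proteins}
    workflows: list[str] = []
    counts: dict[tuple[str, str], int] = {}
    n_unknown = 0
    for rec in records:
        if not rec.is_unique:
            continue
        if rec.accession not in variant_of:
            n_unknown += 1
            continue
        wf = (run_to_workflow or {}).get(rec.run_id, rec.run_id or "all")
        if wf not in workflows:
            workflows.append(wf)
        key = (variant_of[rec.accession], wf)
        counts[key] = counts.get(key, 0) + 1
    if n_unknown:
        warnings.warn(f"{n_unknown} unique PSM(s) with unknown accession excluded")
    if not workflows:
        workflows = sorted(set((run_to_workflow or {}).values())) or ["all"]
    variants = sorted(set(variant_of.values()))
    out = pd.DataFrame(0, index=variants, columns=workflows, dtype=int)
    for (variant, wf), n in counts.items():
        out.loc[variant, wf] = n
    out.index.name = "variant"
    return out


# --------------------------------------------------------------------------
# charge states
# --------------------------------------------------------------------------

def charge_distribution(
    tables: Mapping[str, pd.DataFrame],
    weight: str = "count",
) -> pd.DataFrame:
    """Per-group proportion of features (or summed abundance) per charge.

    ``weight='count'`` counts features; ``weight='abundance'`` weighs each
    feature by its total abundance over all runs.  Proportions sum to 1 per
    group.
    """
    if weight not in ("count", "abundance"):
        raise ValueError("weight must be 'count' or 'abundance'")
    cols: dict[str, pd.Series] = {}
    for group, table in tables.items():
        if table.empty:
            cols[group] = pd.Series(dtype=float)
            continue
        if weight == "count":
            w = pd.Series(1.0, index=table.index)
        else:
            w = table[run_columns(table)].sum(axis=1, skipna=True)
        totals = w.groupby(table["charge"]).sum()
        cols[group] = totals / totals.sum()
    out = pd.DataFrame(cols).fillna(0.0).sort_index()
    out.index.name = "charge"
    return out


# --------------------------------------------------------------------------
# normalization factors
# --------------------------------------------------------------------------

_SUBSETS = ("all", "annotated", "semi_specific", "specific")


def _subset_mask(table: pd.DataFrame, subset: str) -> pd.Series:
    if subset == "all":
        return pd.Series(True, index=table.index)
    annotated = _annotated_mask(table)
    if subset in ("annotated", "semi_specific"):
        # an aspecific search annotates both specific and semi-specific ions
        return annotated
    if subset == "specific":
        spec = table.get("specificity")
        if spec is None:
            return annotated
        return annotated & (spec == "specific")
    raise ValueError(f"subset must be one of {_SUBSETS}")


def normalization_factors(
    table: pd.DataFrame,
    runs: Sequence[str] | None = None,
    reference: str | None = None,
    subset: str = "all",
) -> pd.Series:
    """Log2 normalization factor per run from a chosen feature subset.

    The factor for run r is ``-median(log2(abundance_r / abundance_ref))``
    over features of the subset with non-zero abundance in both runs;
    multiplying run r by ``2**factor`` equalizes the subset medians.  The
    default reference is the run closest to the median abundance profile.
    Restricting the subset (all features vs annotated vs specifically
    cleaved only) is what exposes sample-degradation gaps between enzymes.
    """
    runs = list(runs) if runs is not None else run_columns(table)
    sub = table[_subset_mask(table, subset)]
    if sub.empty:
        raise ValueError(f"feature subset {subset!r} is empty")
    data = sub[runs].astype(float)

    if reference is None:
        profile = data.median(axis=1)
        # run with the smallest median |log ratio| to the consensus profile
        def _dist(col: pd.Series) -> float:
            ok = (col > 0) & (profile > 0)
            if not ok.any():
                return np.inf
            return float(np.abs(np.log2(col[ok] / profile[ok])).median())
        reference = min(runs, key=lambda r: _dist(data[r]))

    ref = data[reference]
    factors = {}
    for r in runs:
        ok = (data[r] > 0) & (ref > 0) & data[r].notna() & ref.notna()
        if not ok.any():
            raise ValueError(f"no shared non-zero features between {r} and {reference}")
        factors[r] = float(-np.median(np.log2(data.loc[ok, r] / ref[ok])))
    out = pd.Series(factors, name="log2_normalization_factor")
    out.attrs["reference"] = reference
    out.attrs["subset"] = subset
    out.attrs["estimator"] = "median log2 ratio to reference run"
    return out


def apply_normalization(table: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Scale each run column by 2**factor (returns a copy)."""
    out = table.copy()
    for r, f in factors.items():
        out[r] = out[r].astype(float) * (2.0 ** f)
    return out


# --------------------------------------------------------------------------
# charge-state deconvolution
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeconvolutionTransfer:
    donor_id: str
    acceptor_id: str
    annotation: str
    mass_error_ppm: float
    delta_rt: float


def deconvolute_charge(
    table: pd.DataFrame,
    ppm_tol: float = 10.0,
    rt_window: float = 0.5,
) -> tuple[pd.DataFrame, list[DeconvolutionTransfer]]:
    """Transfer annotations from multiply charged ions to co-eluting 1+ ions.

    Singly charged precursors are skipped by DDA and stay unannotated even
    when the same peptidoform was identified at z >= 2.  For every annotated
    feature with z >= 2, an unannotated z = 1 feature whose neutral mass
    matches within ``ppm_tol`` and elutes within ``rt_window`` minutes
    inherits the annotation, flagged ``by_deconvolution``.  Assignment is
    one-to-one and greedy by smallest mass error (ties: smallest |delta
    RT|); existing annotations are never overwritten.
    """
    if ppm_tol <= 0 or rt_window <= 0:
        raise ValueError("ppm_tol and rt_window must be positive")
    out = table.copy()
    if "by_deconvolution" not in out.columns:
        out["by_deconvolution"] = False
    annotated = _annotated_mask(out)
    donors = out[annotated & (out["charge"] >= 2)]
    acceptors = out[~annotated & (out["charge"] == 1)]
    if donors.empty or acceptors.empty:
        return out, []

    candidates = []
    acceptor_mass = acceptors["mz"].astype(float) - PROTON_MASS
    for d_idx, donor in donors.iterrows():
        z = int(donor["charge"])
        neutral = float(donor["mz"]) * z - z * PROTON_MASS
        ppm = (acceptor_mass - neutral) / neutral * 1e6
        drt = (acceptors["rt"].astype(float) - float(donor["rt"])).abs()
        ok = (ppm.abs() <= ppm_tol) & (drt <= rt_window)
        for a_idx in acceptors.index[ok]:
            candidates.append(
                (abs(float(ppm[a_idx])), float(drt[a_idx]), d_idx, a_idx)
            )

    candidates.sort()
    used_donors: set = set()
    used_acceptors: set = set()
    transfers: list[DeconvolutionTransfer] = []
    for err_ppm, drt, d_idx, a_idx in candidates:
        if d_idx in used_donors or a_idx in used_acceptors:
            continue
        used_donors.add(d_idx)
        used_acceptors.add(a_idx)
        annotation = out.at[d_idx, "annotation"]
        out.at[a_idx, "annotation"] = annotation
        if "specificity" in out.columns:
            out.at[a_idx, "specificity"] = out.at[d_idx, "specificity"]
        out.at[a_idx, "by_deconvolution"] = True
        transfers.append(
            DeconvolutionTransfer(
                donor_id=str(out.at[d_idx, "feature_id"]),
                acceptor_id=str(out.at[a_idx, "feature_id"]),
                annotation=str(annotation),
                mass_error_ppm=err_ppm,
                delta_rt=drt,
            )
        )
    return out, transfers


# --------------------------------------------------------------------------
# length distributions & summed signal
# --------------------------------------------------------------------------

def length_distribution(lengths_by_group: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    """Quartile summary of peptide lengths per workflow.

    Accepts sequences of integer lengths or of objects with ``__len__``
    (peptides/peptidoforms).  Empty groups yield NaN rows.
    """
    rows = {}
    for group, items in lengths_by_group.items():
        lengths = np.asarray(
            [x if isinstance(x, (int, np.integer)) else len(x) for x in items],
            dtype=float,
        )
        if lengths.size == 0:
            rows[group] = {"n": 0, "min": np.nan, "q1": np.nan, "median": np.nan,
                           "q3": np.nan, "max": np.nan, "iqr": np.nan}
            continue
        q1, med, q3 = np.percentile(lengths, [25, 50, 75])
        rows[group] = {
            "n": int(lengths.size), "min": float(lengths.min()), "q1": float(q1),
            "median": float(med), "q3": float(q3), "max": float(lengths.max()),
            "iqr": float(q3 - q1),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "workflow"
    return out


def summed_annotated_signal(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Total abundance of annotated features per workflow and the annotated
    fraction of all signal."""
    rows = {}
    for group, table in tables.items():
        runs = run_columns(table)
        total = float(table[runs].sum(axis=1, skipna=True).sum()) if runs else 0.0
        mask = _annotated_mask(table)
        annotated = (
            float(table.loc[mask, runs].sum(axis=1, skipna=True).sum()) if runs else 0.0
        )
        rows[group] = {
            "annotated_signal": annotated,
            "total_signal": total,
            "annotated_fraction": annotated / total if total > 0 else 0.0,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "workflow"
    return out


def pca_view(
    table: pd.DataFrame,
    runs: Sequence[str] | None = None,
    n_components: int = 2,
) -> pd.DataFrame:
    """Run-level PCA of feature abundances (log10(x+1), mean-centred).

    Returns one row per run with the principal-component scores; the
    explained variance ratios are attached as ``attrs['explained']``.
    """
    from sklearn.decomposition import PCA

    runs = list(runs) if runs is not None else run_columns(table)
    data = np.log10(table[runs].astype(float).fillna(0.0).T + 1.0)
    data = data - data.mean(axis=0)
    pca = PCA(n_components=min(n_components, len(runs)))
    scores = pca.fit_transform(data)
    out = pd.DataFrame(
        scores, index=runs,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    out.index.name = "run"
    out.attrs["explained"] = list(map(float, pca.explained_variance_ratio_))
    return out
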