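"""Ion-level workflow comparison on a simulated four-workflow experiment.

Runs the default synthetic design (Tryp, PropTryp, ArgC, GRX; five
replicates each plus QC pools), then computes the comparison metrics:
charge-state distributions, total vs instrumental %CV, normalization-factor
subsets on the combined ArgC-GRX project, charge-state deconvolution and
unique-variant PSM counts.
"""

from histoscope import (
    ExperimentDesign,
    charge_distribution,
    cv_decomposition,
    deconvolute_charge,
    normalization_factors,
    simulate_experiment,
    summed_annotated_signal,
    unique_variant_psms,
)

design = ExperimentDesign(seed=7)
result = simulate_experiment(design)

print("charge-state proportions per workflow (count-weighted):")
print(charge_distribution(result.feature_tables).round(3).to_string())
print("PropTryp's excess of 1+ ions is the charge-blocking effect of the")
print("propionyl label; 1+ precursors are invisible to DDA fragmentation.\n")

print("total vs instrumental %CV (medians; injected: 20% prep, 5% instrument):")
for wf in design.workflows:
    dec = cv_decomposition(result.feature_tables[wf],
                           result.replicate_runs[wf], result.qc_runs[wf])
    print(f"  {wf:9s} total {dec.median_total_cv:5.1f}%   "
          f"instrumental {dec.median_instrumental_cv:4.1f}%")
print()

comb = result.combined_table(("ArgC", "GRX"))
runs = result.replicate_runs["ArgC"] + result.replicate_runs["GRX"]
ref = result.replicate_runs["GRX"][0]
for subset in ("all", "annotated", "specific"):
    f = normalization_factors(comb, runs, reference=ref, subset=subset)
    argc_mean = f[result.replicate_runs["ArgC"]].mean()
    print(f"log2 normalization factor of ArgC runs, subset={subset!r}: "
          f"{argc_mean:+.2f}")
print("The gap between 'all' and 'specific' is diverted ArgC signal:")
print("degradation products carry it, correctly cleaved ions do not.\n")

table = result.feature_tables["GRX"]
_, transfers = deconvolute_charge(table, ppm_tol=10, rt_window=0.5)
n_z1 = int((table["charge"] == 1).sum())
print(f"charge-state deconvolution: {len(transfers)} of {n_z1} unannotated "
      f"1+ GRX features rescued via co-eluting 2+/3+ ions\n")

print("summed MS1 signal and annotated fraction:")
print(summed_annotated_signal(result.feature_tables).round(2).to_string())
print()

run_to_wf = {run: wf for wf, runs_ in result.replicate_runs.items() for run in runs_}
counts = unique_variant_psms(
    [r for recs in result.ident_records.values() for r in recs],
    result.proteins, run_to_wf,
)
print("unique-variant PSMs per workflow:")
print(counts.to_string())
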