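"""Workflow-comparison metrics: %CV, charge states, normalization,
deconvolution, length distributions."""

import numpy as np
import pandas as pd
import pytest

from histoscope import (
    FeatureRecord,
    IdentificationRecord,
    ProteinRecord,
    apply_normalization,
    charge_distribution,
    cv_decomposition,
    cv_percent,
    deconvolute_charge,
    feature_frame,
    length_distribution,
    normalization_factors,
    pca_view,
    run_columns,
    summed_annotated_signal,
    unique_variant_psms,
)

PROTON = 1.00727646688


class TestCvPercent:
    def test_constant_vector_is_zero(self):
        assert cv_percent([100, 100, 100]) == 0.0

    def test_two_values_hand_computed(self):
        # sd = 2.8284 (n-1), mean = 10 -> 28.28%
        assert cv_percent([8, 12]) == pytest.approx(28.28, abs=0.01)

    def test_scale_invariance(self, rng):
        x = rng.uniform(10, 100, size=20)
        assert cv_percent(7.3 * x) == pytest.approx(cv_percent(x), rel=1e-12)

    def test_undefined_cases_reported_missing(self):
        assert np.isnan(cv_percent([5.0]))
        assert np.isnan(cv_percent([0.0, 0.0]))
        assert np.isnan(cv_percent([-2.0, 2.0]))


def make_table(rows, runs):
    records = []
    for i, row in enumerate(rows):
        records.append(FeatureRecord(
            feature_id=f"f{i}", mz=row.get("mz", 500.0), rt=row.get("rt", 10.0),
            charge=row.get("charge", 2),
            abundances=dict(zip(runs, row["abund"])),
            annotation=row.get("annotation"),
            specificity=row.get("specificity", "specific"),
        ))
    return feature_frame(records)


class TestUniqueVariantPsms:
    PROTEINS = [ProteinRecord("A1", "H3.1", "ARTKAAAA"),
                ProteinRecord("B1", "H2A1", "SGRGKQGG")]

    def rec(self, acc, unique, run="r1"):
        seq = {p.accession: p.sequence for p in self.PROTEINS}[acc][:4]
        return IdentificationRecord(acc, 1, 4, seq, (), 30.0, unique, 2, run)

    def test_counts_unique_only(self):
        records = [self.rec("A1", True), self.rec("A1", True), self.rec("A1", False)]
        table = unique_variant_psms(records, self.PROTEINS, {"r1": "Tryp"})
        assert table.loc["H3.1", "Tryp"] == 2

    def test_zero_rows_explicit_for_known_variants(self):
        table = unique_variant_psms([], self.PROTEINS, {"r1": "Tryp"})
        assert set(table.index) == {"H3.1", "H2A1"}
        assert (table == 0).all().all()

    def test_unknown_accession_warned_and_excluded(self):
        bad = IdentificationRecord("ZZ", 1, 4, "AAAA", (), 1.0, True, 2, "r1")
        with pytest.warns(UserWarning, match="unknown accession"):
            table = unique_variant_psms([bad, self.rec("A1", True)],
                                        self.PROTEINS, {"r1": "Tryp"})
        assert table["Tryp"].sum() == 1


class TestCvDecomposition:
    def test_replicates_equal_qcs_give_equal_cv(self, rng):
        runs = ["r1", "r2", "r3", "q1", "q2", "q3"]
        rows = []
        for _ in range(30):
            vals = rng.uniform(50, 150, size=3)
            rows.append({"abund": np.concatenate([vals, vals])})
        table = make_table(rows, runs)
        dec = cv_decomposition(table, runs[:3], runs[3:])
        assert np.allclose(dec.per_feature["total_cv"],
                           dec.per_feature["instrumental_cv"])

    def test_missing_values_excluded_and_counted(self):
        runs = ["r1", "r2", "q1", "q2"]
        table = make_table([
            {"abund": [10, 12, 11, 11]},
            {"abund": [10, np.nan, 11, 11]},
        ], runs)
        dec = cv_decomposition(table, runs[:2], runs[2:])
        assert dec.n_excluded == 1
        assert len(dec.per_feature) == 1

    def test_requires_two_runs_each(self):
        table = make_table([{"abund": [1, 2]}], ["r1", "q1"])
        with pytest.raises(ValueError):
            cv_decomposition(table, ["r1"], ["q1"])


class TestChargeDistribution:
    def test_count_weighted_proportions(self):
        table = make_table(
            [{"charge": z, "abund": [1.0]} for z in (1, 1, 2, 3)], ["r1"]
        )
        dist = charge_distribution({"wf": table})
        assert dist["wf"].to_dict() == {1: 0.5, 2: 0.25, 3: 0.25}

    def test_single_charge_group(self):
        table = make_table([{"charge": 2, "abund": [1.0]}] * 3, ["r1"])
        dist = charge_distribution({"wf": table})
        assert dist["wf"].to_dict() == {2: 1.0}

    def test_abundance_weighting_differs_from_count(self):
        table = make_table([
            {"charge": 1, "abund": [90.0]},
            {"charge": 2, "abund": [10.0]},
        ], ["r1"])
        by_count = charge_distribution({"wf": table}, weight="count")
        by_abund = charge_distribution({"wf": table}, weight="abundance")
        assert by_count["wf"][1] == 0.5
        assert by_abund["wf"][1] == pytest.approx(0.9)

    def test_proportions_sum_to_one(self, sim_result):
        dist = charge_distribution(sim_result.feature_tables)
        assert np.allclose(dist.sum(axis=0), 1.0)


class TestNormalization:
    def test_identical_run_has_zero_factor(self, rng):
        base = rng.uniform(10, 1000, size=40)
        table = make_table([{"abund": [b, b]} for b in base], ["r1", "r2"])
        f = normalization_factors(table, ["r1", "r2"], reference="r1")
        assert f["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_doubled_run_has_factor_minus_one(self, rng):
        base = rng.uniform(10, 1000, size=40)
        table = make_table([{"abund": [b, 2 * b]} for b in base], ["r1", "r2"])
        f = normalization_factors(table, ["r1", "r2"], reference="r1")
        assert f["r2"] == pytest.approx(-1.0, abs=1e-12)

    def test_applying_factors_zeroes_median_log_ratio(self, rng):
        runs = ["r1", "r2", "r3"]
        rows = [{"abund": rng.uniform(10, 1000, size=3)} for _ in range(60)]
        table = make_table(rows, runs)
        f = normalization_factors(table, runs, reference="r1")
        normed = apply_normalization(table, f)
        for r in runs:
            ratios = np.log2(normed[r] / normed["r1"] * 2.0 ** f["r1"])
            assert np.median(ratios) == pytest.approx(0.0, abs=1e-9)

    def test_empty_subset_error_names_filter(self):
        table = make_table([{"abund": [1.0, 1.0]}], ["r1", "r2"])
        table["annotation"] = ""
        with pytest.raises(ValueError, match="annotated"):
            normalization_factors(table, ["r1", "r2"], subset="annotated")

    def test_subset_divergence_on_argc_like_data(self, sim_result):
        comb = sim_result.combined_table(("ArgC", "GRX"))
        runs = (sim_result.replicate_runs["ArgC"]
                + sim_result.replicate_runs["GRX"])
        ref = sim_result.replicate_runs["GRX"][0]
        f_all = normalization_factors(comb, runs, reference=ref, subset="all")
        f_spec = normalization_factors(comb, runs, reference=ref, subset="specific")
        argc = sim_result.replicate_runs["ArgC"]
        gap_all = f_all[argc].mean()
        gap_spec = f_spec[argc].mean()
        # specific-only normalization exposes the diverted ArgC signal
        assert gap_spec > gap_all + 0.25
        assert f_spec[sim_result.replicate_runs["GRX"]].abs().max() < 0.2


class TestDeconvolution:
    @staticmethod
    def table_with(rows):
        return make_table(rows, ["r1"])

    def test_spec_fixture_transfer(self):
        neutral = 2 * 500.0 - 2 * PROTON
        rows = [
            {"mz": 500.0, "rt": 10.0, "charge": 2, "abund": [5.0],
             "annotation": "PEP|1-9"},
            {"mz": neutral + PROTON, "rt": 10.1, "charge": 1, "abund": [9.0]},
        ]
        out, transfers = deconvolute_charge(self.table_with(rows))
        assert len(transfers) == 1
        assert out.loc[1, "annotation"] == "PEP|1-9"
        assert bool(out.loc[1, "by_deconvolution"])

    def test_no_candidates_no_transfer(self):
        rows = [{"mz": 500.0, "charge": 2, "abund": [1.0], "annotation": "X"}]
        out, transfers = deconvolute_charge(self.table_with(rows))
        assert transfers == []

    def test_closest_mass_wins(self):
        neutral = 2 * 500.0 - 2 * PROTON
        rows = [
            {"mz": 500.0, "rt": 10.0, "charge": 2, "abund": [1.0],
             "annotation": "X"},
            {"mz": neutral + PROTON + 0.004, "rt": 10.0, "charge": 1,
             "abund": [1.0]},
            {"mz": neutral + PROTON + 0.001, "rt": 10.3, "charge": 1,
             "abund": [1.0]},
        ]
        out, transfers = deconvolute_charge(self.table_with(rows), ppm_tol=10)
        assert len(transfers) == 1
        assert transfers[0].acceptor_id == "f2"

    def test_never_overwrites_or_double_annotates(self, sim_result):
        table = sim_result.feature_tables["ArgC"]
        before = table["annotation"].copy()
        out, transfers = deconvolute_charge(table)
        previously = before.str.len() > 0
        assert (out.loc[previously, "annotation"] == before[previously]).all()
        acceptors = [t.acceptor_id for t in transfers]
        assert len(acceptors) == len(set(acceptors))
        donors = [t.donor_id for t in transfers]
        assert len(donors) == len(set(donors))

    def test_invalid_tolerances(self):
        with pytest.raises(ValueError):
            deconvolute_charge(self.table_with([]), ppm_tol=0)


class TestLengthAndSignal:
    def test_degenerate_distribution(self):
        out = length_distribution({"wf": [9] * 12})
        assert out.loc["wf", "iqr"] == 0.0
        assert out.loc["wf", "median"] == 9.0

    def test_empty_group(self):
        out = length_distribution({"wf": []})
        assert out.loc["wf", "n"] == 0 and np.isnan(out.loc["wf", "median"])

    def test_r_specific_digest_longer_than_tryptic_when_r_sparse(self, rng):
        from histoscope import ProteinRecord, digest
        seq = "".join(
            "K" if rng.random() < 0.2 else
            ("R" if rng.random() < 0.05 else "A")
            for _ in range(400)
        )
        protein = ProteinRecord("LP", "lp", seq)
        grx = [len(p) for p in digest(protein, "grx", 0)]
        tryp = [len(p) for p in digest(protein, "trypsin", 0)]
        out = length_distribution({"GRX": grx, "Tryp": tryp})
        assert out.loc["GRX", "median"] > out.loc["Tryp", "median"]

    def test_summed_signal_fractions(self):
        annotated = make_table(
            [{"abund": [3.0], "annotation": "X"}, {"abund": [1.0]}], ["r1"]
        )
        out = summed_annotated_signal({"wf": annotated})
        assert out.loc["wf", "annotated_fraction"] == pytest.approx(0.75)
        none = make_table([{"abund": [1.0]}], ["r1"])
        assert summed_annotated_signal({"wf": none}).loc["wf", "annotated_fraction"] == 0
        all_ = make_table([{"abund": [1.0], "annotation": "X"}], ["r1"])
        assert summed_annotated_signal({"wf": all_}).loc["wf", "annotated_fraction"] == 1


def test_pca_view_shapes(sim_result):
    comb = sim_result.combined_table(("ArgC", "GRX"))
    runs = sim_result.replicate_runs["ArgC"] + sim_result.replicate_runs["GRX"]
    scores = pca_view(comb, runs)
    assert list(scores.index) == runs
    assert scores.shape == (len(runs), 2)
    assert len(scores.attrs["explained"]) == 2
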