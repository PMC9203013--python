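"""Collapse, zero-set, QC, t-test and volcano classification."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from cosed.differential import (
    classify,
    collapse_accessions,
    partition_zero_set,
    replicate_qc,
    test_differential,
    volcano_table,
)
from cosed.io import ProteinGroupRecord

test_differential.__test__ = False  # library function, not a test case


def _record(acc, gene, peptides, score):
    return ProteinGroupRecord(
        protein_ids=[acc], gene_name=gene, peptides_total=peptides, score=score
    )


class TestCollapse:
    def test_single_peptide_removed_then_best_score_kept(self):
        records = [
            _record("A1", "g1", 1, 500.0),   # single peptide: dropped first
            _record("A2", "g1", 5, 100.0),
            _record("A3", "g1", 5, 80.0),
            _record("B1", "g2", 3, 10.0),
        ]
        collapsed = collapse_accessions(records)
        assert [r.protein_ids[0] for r in collapsed] == ["A2", "B1"]

    def test_order_invariant(self):
        records = [
            _record("A2", "g1", 5, 100.0),
            _record("A3", "g1", 5, 80.0),
            _record("B1", "g2", 3, 10.0),
        ]
        assert collapse_accessions(records) == collapse_accessions(records[::-1])

    def test_identity_when_unique_genes(self):
        records = [_record("A", "g1", 3, 1.0), _record("B", "g2", 3, 2.0)]
        assert collapse_accessions(records) == sorted(records, key=lambda r: r.gene_key)


class TestZeroPartition:
    def test_rule_enumeration(self, tiny_matrix):
        testable, zero = partition_zero_set(tiny_matrix)
        # geneC only ever appears with a zero control arm -> zero set
        assert zero == ["geneC"]
        assert set(testable.genes) == {"geneA", "geneB"}

    def test_pairs_with_one_zero_arm_excluded_from_test(self, tiny_matrix):
        testable, _ = partition_zero_set(tiny_matrix)
        results = test_differential(testable, min_pairs=2)
        assert results.loc["geneA", "n_pairs_used"] == 3
        assert results.loc["geneB", "n_pairs_used"] == 2  # pair 1 has sample=0


class TestReplicateQC:
    def test_duplicated_replicate_has_slope_one(self):
        control = {f"g{i}": [v, v] for i, v in enumerate([100, 200, 400, 800] * 5)}
        sample = {g: [2 * v[0], 2 * v[1]] for g, v in control.items()}
        qc = replicate_qc(make_matrix(control, sample))
        assert qc["slope"].round(6).tolist() == [1.0, 1.0]
        assert not qc["flagged"].any()

    def test_hundredfold_scaled_pair_flagged(self):
        rng = np.random.default_rng(0)
        base = 2.0 ** rng.normal(20, 2, size=40)
        control = {f"g{i}": [v, v, v * 100] for i, v in enumerate(base)}
        sample = {f"g{i}": [v, v, v * 100] for i, v in enumerate(base)}
        qc = replicate_qc(make_matrix(control, sample))
        # pair 3 is shifted by log2(100) ~ 6.64 > 2 log2 units from the rest
        assert bool(qc.loc["3", "flagged"]) and qc.loc["3", "reason"] == "median"
        assert not qc.loc["1", "flagged"]

    def test_empty_pair_insufficient(self):
        control = {"g1": [100.0, 0.0], "g2": [120.0, 0.0]}
        sample = {"g1": [100.0, 0.0], "g2": [130.0, 0.0]}
        qc = replicate_qc(make_matrix(control, sample))
        assert qc.loc["2", "reason"] == "insufficient"


class TestTTest:
    def test_paired_p_matches_closed_form(self):
        # per-pair log2 differences 0.5, 1.0, 1.5, 2.0 -> t = 3.873 on 3 df
        control = {"g1": [2.0**10] * 4, "pad": [2.0**10] * 4}
        sample = {
            "g1": [2.0 ** (10 + d) for d in (0.5, 1.0, 1.5, 2.0)],
            "pad": [2.0**10] * 4,
        }
        results = test_differential(make_matrix(control, sample))
        assert results.loc["g1", "p_value"] == pytest.approx(0.030466, abs=1e-5)
        assert results.loc["g1", "log_ratio"] == pytest.approx(1.25)

    def test_gene_below_min_pairs_not_tested(self):
        control = {"g1": [100.0, 0.0, 0.0]}
        sample = {"g1": [150.0, 200.0, 0.0]}
        results = test_differential(make_matrix(control, sample), min_pairs=2)
        assert results.loc["g1", "volcano_class"] == "insufficient"
        assert np.isnan(results.loc["g1", "p_value"])

    def test_zero_variance_is_degenerate(self):
        control = {"g1": [100.0, 200.0, 400.0]}
        sample = {"g1": [100.0, 200.0, 400.0]}  # all differences exactly 0
        results = test_differential(make_matrix(control, sample))
        assert bool(results.loc["g1", "degenerate"])
        assert np.isnan(results.loc["g1", "p_value"])
        assert results.loc["g1", "volcano_class"] == "unchanged"

    def test_antisymmetry_under_arm_swap(self, small_experiment):
        from cosed import differential, io

        _, tables, _, _ = small_experiment
        records = {
            label: differential.collapse_accessions(
                io.filter_standard_flags(
                    io.records_from_frame(frame.astype(str))
                )
            )
            for label, frame in tables.items()
        }
        matrix, _ = partition_zero_set(differential.build_matrix(records))
        fwd = test_differential(matrix)
        rev = test_differential(matrix.swap_arms())
        tested = fwd["p_value"].notna() & rev["p_value"].notna()
        assert tested.any()
        np.testing.assert_allclose(
            fwd.loc[tested, "log_ratio"], -rev.loc[tested, "log_ratio"], atol=1e-10
        )
        np.testing.assert_allclose(
            fwd.loc[tested, "p_value"], rev.loc[tested, "p_value"], atol=1e-10
        )

    def test_paired_p_invariant_to_common_pair_shift(self):
        rng = np.random.default_rng(1)
        base = 2.0 ** rng.normal(20, 1, size=(10, 4))
        noise = 2.0 ** rng.normal(0.3, 0.4, size=(10, 4))
        control = {f"g{i}": list(base[i]) for i in range(10)}
        sample = {f"g{i}": list(base[i] * noise[i]) for i in range(10)}
        p0 = test_differential(make_matrix(control, sample))["p_value"]
        # multiply both arms of pair 2 by 2^3: per-pair differences unchanged
        control2 = {g: [v if j != 1 else v * 8 for j, v in enumerate(vals)] for g, vals in control.items()}
        sample2 = {g: [v if j != 1 else v * 8 for j, v in enumerate(vals)] for g, vals in sample.items()}
        p1 = test_differential(make_matrix(control2, sample2))["p_value"]
        np.testing.assert_allclose(p0, p1, atol=1e-10)

    def test_null_pvalues_uniform(self):
        """Paired p-values on pure-noise data pass a KS uniformity check."""
        from scipy import stats

        rng = np.random.default_rng(42)
        n, pairs = 2000, 6
        base = rng.normal(23, 2, size=(n, 1))
        control = 2.0 ** (base + rng.normal(0, 0.5, size=(n, pairs)))
        sample = 2.0 ** (base + rng.normal(0, 0.5, size=(n, pairs)))
        matrix = make_matrix(
            {f"g{i:04d}": list(control[i]) for i in range(n)},
            {f"g{i:04d}": list(sample[i]) for i in range(n)},
        )
        p = test_differential(matrix)["p_value"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestClassify:
    @pytest.mark.parametrize(
        "fc, p, expected",
        [
            (1.6, 0.04, "increased"),
            (1.5, 0.01, "unchanged"),      # strict boundary
            (0.5, 0.01, "decreased"),
            (1.0 / 1.5, 0.01, "unchanged"),  # strict boundary
            (1.6, 0.05, "unchanged"),      # alpha strict
            (2.0, float("nan"), "unchanged"),
        ],
    )
    def test_thresholds(self, fc, p, expected):
        assert classify(np.log2(fc), p) == expected


class TestVolcano:
    def test_empty_results(self):
        empty = pd.DataFrame(
            columns=["n_pairs_used", "log_sam", "log_con", "log_ratio",
                     "p_value", "volcano_class", "degenerate"],
        ).rename_axis("gene")
        table, counts = volcano_table(empty)
        assert len(table) == 0 and counts.sum() == 0

    def test_sorted_and_counts_partition(self, tiny_matrix):
        testable, _ = partition_zero_set(tiny_matrix)
        results = test_differential(testable)
        table, counts = volcano_table(results)
        ratios = table["log_ratio"].dropna()
        assert (ratios.diff().dropna() <= 1e-12).all()
        assert counts.sum() == len(results)

    def test_spiked_proteins_rank_high(self):
        from cosed.pipeline import RunConfig, run_all
        from cosed.simulate import ExperimentConfig

        config = RunConfig(
            outdir="scratch/test_volcano",
            simulation=ExperimentConfig(n_proteins=400, spike_fold_change=4.0, seed=21),
        )
        res = run_all(config)
        table = res["volcano"].dropna(subset=["log_ratio"])
        truth = res["truth"]
        top = table.head(30)["gene"]
        n_spiked_top = sum(truth.direction.get(g) == "up" for g in top)
        assert n_spiked_top >= 15
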