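"""Site import thresholds, consensus scanning, enrichment and composition."""

import numpy as np
import pandas as pd
import pytest

from oracles import binom_two_sided, fisher_two_sided
from cosed.motif import (
    CompositionCounts,
    PredictedSite,
    PredictorThresholds,
    annotate_aurora_context,
    bin_by_fold_change,
    composition_significance,
    directional_enrichment,
    export_count_matrix,
    extract_window,
    import_predictions,
    positional_composition,
    read_count_matrix,
    scan_consensus,
    sites_from_scan,
)
from cosed.simulate import ExperimentConfig, simulate_experiment


def _diff_frame(ratios: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"log_ratio": list(ratios.values())},
        index=pd.Index(list(ratios.keys()), name="gene"),
    )


class TestImportPredictions:
    SEQ = {"prot1": "AAAAAARSYSLPAAAAAA"}

    def _table(self, consensus, ann, pssm, svm):
        return pd.DataFrame(
            [{"protein": "prot1", "position": 10, "ann": ann, "pssm": pssm,
              "svm": svm, "consensus": consensus}]
        )

    @pytest.mark.parametrize(
        "scores, passes",
        [
            ((0.95, 0.6, 0.85, 0.3), True),
            ((0.9, 0.6, 0.85, 0.3), False),   # consensus exactly at threshold
            ((0.95, 0.5, 0.85, 0.3), False),  # ANN below
            ((0.95, 0.6, 0.80, 0.3), False),  # PSSM exactly at threshold
        ],
    )
    def test_strict_thresholds(self, scores, passes):
        sites = import_predictions(self._table(*scores), self.SEQ)
        assert sites[0].passes is passes

    def test_position_beyond_sequence_names_protein(self):
        table = self._table(0.95, 0.6, 0.85, 0.3)
        table.loc[0, "position"] = 99
        with pytest.raises(ValueError, match="prot1"):
            import_predictions(table, self.SEQ)

    def test_missing_sequence_keeps_site_with_empty_window(self):
        sites = import_predictions(self._table(0.95, 0.6, 0.85, 0.3), {})
        assert sites[0].window == ""


class TestScanner:
    def test_planted_consensus_found(self):
        # R at -3 and P at +2 of the S in (1-based) position 7
        assert scan_consensus("AAARSYSLPAAA") == [7]

    def test_poly_a_has_no_sites(self):
        assert scan_consensus("A" * 50) == []

    def test_rejects_non_amino_acid(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            scan_consensus("AAAX1AAA")

    def test_recovers_planted_positions_on_simulated_sequences(self):
        config = ExperimentConfig(n_proteins=1000, motif_rate_spiked=1.0,
                                  motif_rate_background=0.3, seed=13)
        _, sequences, truth = simulate_experiment(config)
        found = missed = 0
        for gene, positions in truth.motif_positions.items():
            acc = f"SIM{int(gene[4:]):05d}"
            hits = set(scan_consensus(sequences[acc]))
            for pos in positions:
                if pos in hits:
                    found += 1
                else:
                    missed += 1
        assert missed == 0 and found > 100


class TestWindowAndAurora:
    def test_window_padding_at_n_terminus(self):
        w = extract_window("STAAAAAAAA", 1)
        assert w == "------S" + "TAAAAA"
        assert len(w) == 13

    @pytest.mark.parametrize(
        "window, expected",
        [
            ("AA" + "KVSLS" + "AAAAAA", True),    # -4..0 = K,V,S,L,S
            ("AA" + "AVSLS" + "AAAAAA", False),   # no R/K at -4
            ("AA" + "KVALS" + "AAAAAA", False),   # no S/T at -2
            ("--" + "--SLS" + "AAAAAA", False),   # padded -4
        ],
    )
    def test_aurora_context(self, window, expected):
        site = PredictedSite(protein="p", position=7, center_residue="S", window=window)
        assert annotate_aurora_context(site) is expected

    def test_borealin_like_context_is_positive(self):
        # phospho-S with S at -2 in an R/K-x-S context, P at +2 (mode-I-like)
        seq = "AAAAAAKRSKSVPAAAAA"
        sites = sites_from_scan("borr-like", seq)
        assert any(s.aurora_context for s in sites)


class TestDirectionalEnrichment:
    def test_printed_counts_not_significant(self):
        # 448 up / 456 down among proteins without predicted sites
        ratios = {f"u{i}": 1.0 for i in range(448)}
        ratios.update({f"d{i}": -1.0 for i in range(456)})
        result = directional_enrichment(_diff_frame(ratios), set())
        assert result.p_without == pytest.approx(0.82, abs=0.005)

    def test_symmetric_split_gives_p_one(self):
        ratios = {f"u{i}": 0.5 for i in range(10)}
        ratios.update({f"d{i}": -0.5 for i in range(10)})
        result = directional_enrichment(_diff_frame(ratios), set(ratios))
        assert result.p_with == 1.0

    def test_nine_one_matches_tail_enumeration(self):
        ratios = {f"u{i}": 0.5 for i in range(9)}
        ratios["d0"] = -0.5
        result = directional_enrichment(_diff_frame(ratios), set(ratios))
        assert result.p_with == pytest.approx(0.021484375, abs=1e-9)

    @pytest.mark.parametrize("n_up", range(0, 21, 4))
    def test_agrees_with_binomial_enumeration(self, n_up):
        n_down = 20 - n_up
        ratios = {f"u{i}": 1.0 for i in range(n_up)}
        ratios.update({f"d{i}": -1.0 for i in range(n_down)})
        result = directional_enrichment(_diff_frame(ratios), set(ratios))
        assert result.p_with == pytest.approx(binom_two_sided(n_up, 20), rel=1e-9)

    def test_empty_partition_undefined(self):
        result = directional_enrichment(_diff_frame({"a": 1.0}), {"a"})
        assert np.isnan(result.p_without)


class TestBinning:
    def test_ten_genes_five_bins_in_ratio_order(self):
        ratios = {f"g{i}": float(10 - i) for i in range(10)}
        bins = bin_by_fold_change(_diff_frame(ratios))
        assert bins[["g0", "g1"]].tolist() == [1, 1]
        assert bins[["g8", "g9"]].tolist() == [5, 5]

    def test_bin_sizes_differ_by_at_most_one_and_cover_all(self):
        ratios = {f"g{i:03d}": np.sin(i * 1.7) for i in range(103)}
        bins = bin_by_fold_change(_diff_frame(ratios))
        sizes = bins.value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 103 and bins.index.is_unique

    def test_tied_ratios_stable_across_runs(self):
        ratios = {f"g{i}": (0.5 if i in (4, 5) else float(i)) for i in range(10)}
        b1 = bin_by_fold_change(_diff_frame(ratios))
        b2 = bin_by_fold_change(_diff_frame(ratios))
        pd.testing.assert_series_equal(b1, b2)

    def test_fewer_genes_than_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            bin_by_fold_change(_diff_frame({"a": 1.0, "b": 2.0}), n_bins=5)


def _site(protein, window):
    return PredictedSite(
        protein=protein, position=7, center_residue=window[6], window=window, passes=True
    )


class TestComposition:
    def test_single_site_counts(self):
        counts = positional_composition([_site("p1", "AAAAAASAAAAAA")], {"p1"})
        assert counts.n_sites == 1
        assert counts.counts.loc["A"].sum() == 12
        assert counts.counts.loc["S", 0] == 1

    def test_n_terminal_overhang_excluded_from_denominators(self):
        counts = positional_composition([_site("p1", "---AAASAAAAAA")], {"p1"})
        denom = counts.denominators()
        assert denom[-6] == 0 and denom[-4] == 0 and denom[-3] == 1

    def test_three_site_hand_tally(self):
        sites = [
            _site("p1", "AAAAAASAAAAAA"),
            _site("p1", "CCCCCCTCCCCCC"),
            _site("p2", "ARKAAASAAPAAA"),
        ]
        counts = positional_composition(sites, {"p1", "p2"})
        # hand tally at position 0: S, T, S
        assert counts.counts.loc["S", 0] == 2
        assert counts.counts.loc["T", 0] == 1
        # position -5: A, C, R
        assert counts.counts.loc["R", -5] == 1
        assert counts.counts.loc["C", -5] == 1
        assert counts.counts.loc["A", -5] == 1
        assert counts.denominators().sum() == 3 * 13

    def test_input_order_invariant(self):
        sites = [
            _site("p1", "AAAAAASAAAAAA"),
            _site("p2", "ARKAAASAAPAAA"),
        ]
        c1 = positional_composition(sites, {"p1", "p2"})
        c2 = positional_composition(sites[::-1], {"p1", "p2"})
        pd.testing.assert_frame_equal(c1.counts, c2.counts)


class TestCompositionSignificance:
    def _counts(self, label, frame):
        return CompositionCounts(label=label, counts=frame, n_sites=0)

    def test_identical_frequencies_give_p_one(self):
        sites = [_site("p1", "AAAAAASAAAAAA")] * 5
        top = positional_composition(sites, {"p1"})
        result = composition_significance(top, top)
        assert (result["p_value"] == 1.0).all()
        assert not result["significant"].any()

    def test_matches_fisher_enumeration(self):
        rng = np.random.default_rng(3)
        windows_top = ["".join(rng.choice(list("ASKP"), size=13)) for _ in range(12)]
        windows_rest = ["".join(rng.choice(list("ASTR"), size=13)) for _ in range(10)]
        top = positional_composition([_site("t", w[:6] + "S" + w[7:]) for w in windows_top], {"t"})
        rest = positional_composition([_site("r", w[:6] + "S" + w[7:]) for w in windows_rest], {"r"})
        result = composition_significance(top, rest)
        for _, row in result.sample(30, random_state=0).iterrows():
            expected = fisher_two_sided(
                row["count_top"], row["denom_top"] - row["count_top"],
                row["count_rest"], row["denom_rest"] - row["count_rest"],
            )
            assert row["p_value"] == pytest.approx(expected, rel=1e-6)

    def test_planted_imbalance_flagged(self):
        # top group: K at -1 in 30/40 sites; rest: K at -1 in 2/40
        top_sites = [_site("t", "AAAAAKSAAAAAA") for _ in range(30)] + [
            _site("t", "AAAAAASAAAAAA") for _ in range(10)
        ]
        rest_sites = [_site("r", "AAAAAKSAAAAAA") for _ in range(2)] + [
            _site("r", "AAAAAASAAAAAA") for _ in range(38)
        ]
        # the helper placed K at -1 (window index 5)
        top = positional_composition(top_sites, {"t"})
        rest = positional_composition(rest_sites, {"r"})
        result = composition_significance(top, rest, alpha=0.01)
        cell = result.query("position == -1 and residue == 'K'").iloc[0]
        assert cell["significant"] and cell["direction"] == "over"


class TestCountMatrixExport:
    def test_round_trip_and_column_sums(self, tmp_path):
        sites = [
            _site("p1", "AAAAAASAAAAAA"),
            _site("p1", "---KAATAAAAAA"),
        ]
        counts = positional_composition(sites, {"p1"})
        path = tmp_path / "counts.tsv"
        export_count_matrix(counts, path)
        back = read_count_matrix(path)
        pd.testing.assert_frame_equal(
            back.counts, counts.counts, check_dtype=False
        )
        assert back.n_sites == counts.n_sites
        # column sums equal per-position denominators (pad excluded)
        assert back.counts.sum(axis=0).tolist() == counts.denominators().tolist()

    def test_empty_counts_export(self, tmp_path):
        counts = positional_composition([], set())
        path = tmp_path / "empty.tsv"
        export_count_matrix(counts, path)
        back = read_count_matrix(path)
        assert back.n_sites == 0 and int(back.counts.to_numpy().sum()) == 0
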