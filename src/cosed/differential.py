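"""Accession collapsing, zero-set partitioning, log2-ratio testing and volcano classes.

The pipeline follows the quantification scheme of the co-sedimentation
experiment: single-peptide accessions are removed, accessions are collapsed
to one per gene keeping the highest search score, each gene's per-pair log2
ratio is ``log2(sample) - log2(control)``, genes for which an arm intensity
is 0 in every pair where they appear are routed to a separate "zero set",
and genes doubly detected in at least two replicate pairs are tested with a
two-tailed t-test (paired on per-pair differences by default; an unpaired
two-sample mode is available).  A gene is called *increased* when its fold
change exceeds 1.5 with p < 0.05, *decreased* below a fold change of 1/1.5
(0.6667) with p < 0.05 — strict inequalities on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cosed.io import ProteinGroupRecord, ReplicatePairMatrix

FC_UP_DEFAULT = 1.5
FC_DOWN_DEFAULT = 1.0 / 1.5
ALPHA_DEFAULT = 0.05


def collapse_accessions(records: list[ProteinGroupRecord]) -> list[ProteinGroupRecord]:
    """Collapse to one accession per gene.

    Accessions assigned only one peptide are removed first (they cannot be
    confidently identified); then, when more than one accession maps to the
    same gene, only the highest-scored accession is retained.  Ties break on
    the lead accession so input order never affects the output, which is
    returned sorted by gene key.
    """
    multi = [r for r in records if r.peptides_total > 1]
    best: dict[str, ProteinGroupRecord] = {}
    for rec in multi:
        key = rec.gene_key
        cur = best.get(key)
        if cur is None or (rec.score, rec.protein_ids[0]) > (cur.score, cur.protein_ids[0]):
            best[key] = rec
    return [best[k] for k in sorted(best)]


def build_matrix(records_per_pair: dict[str, list[ProteinGroupRecord]]) -> ReplicatePairMatrix:
    """Merge per-pair collapsed records into a gene x (pair, arm) matrix.

    ``records_per_pair`` maps a replicate label to that pair's collapsed
    records; each record must carry intensities keyed ``(label, arm)``.
    Genes absent from a pair get 0 (not detected) in both arms.
    """
    genes = sorted({r.gene_key for recs in records_per_pair.values() for r in recs})
    columns = pd.MultiIndex.from_product(
        [sorted(records_per_pair), ["control", "sample"]]
    )
    data = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=columns)
    for label, recs in records_per_pair.items():
        for rec in recs:
            for arm in ("control", "sample"):
                data.loc[rec.gene_key, (label, arm)] = rec.intensities.get((label, arm), 0.0)
    return ReplicatePairMatrix(data)


def partition_zero_set(matrix: ReplicatePairMatrix) -> tuple[ReplicatePairMatrix, list[str]]:
    """Split genes into a testable matrix and the zero-set list.

    A gene joins the zero set when, in every replicate pair where it appears
    at all, exactly one arm is 0 — i.e. it was never detected in both arms
    of the same pair.  (Such genes are analysed separately, outside the
    ratio statistics.)  Genes with at least one doubly-detected pair stay
    testable; their single-zero pairs are simply unusable for that gene's
    test and are dropped later by :func:`test_differential`.
    """
    con = matrix.data.xs("control", axis=1, level=1)
    sam = matrix.data.xs("sample", axis=1, level=1)
    appears = (con > 0) | (sam > 0)
    both = (con > 0) & (sam > 0)
    in_zero_set = appears.any(axis=1) & ~both.any(axis=1)
    zero_genes = sorted(matrix.data.index[in_zero_set])
    testable = ReplicatePairMatrix(matrix.data.loc[~in_zero_set])
    return testable, zero_genes


def replicate_qc(
    matrix: ReplicatePairMatrix,
    median_threshold: float = 2.0,
    slope_range: tuple[float, float] = (0.5, 2.0),
    min_genes: int = 10,
) -> pd.DataFrame:
    """Per-pair consistency report on log2 distributions and best-fit lines.

    For each replicate pair: median and IQR of log2 values of each arm over
    doubly-detected genes, and the least-squares slope/intercept of
    log2(sample) vs log2(control).  A pair is flagged when its pooled median
    deviates from the cross-pair median by more than ``median_threshold``
    log2 units or its slope falls outside ``slope_range``; pairs with fewer
    than ``min_genes`` doubly-detected genes are flagged "insufficient".
    """
    rows = []
    for pair in matrix.pairs:
        con = matrix.arm(pair, "control")
        sam = matrix.arm(pair, "sample")
        both = (con > 0) & (sam > 0)
        lc, ls = np.log2(con[both]), np.log2(sam[both])
        if both.sum() < min_genes:
            rows.append(
                {
                    "pair": pair,
                    "n_genes": int(both.sum()),
                    "median_control": np.nan,
                    "median_sample": np.nan,
                    "iqr_control": np.nan,
                    "iqr_sample": np.nan,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "pooled_median": np.nan,
                    "flagged": True,
                    "reason": "insufficient",
                }
            )
            continue
        slope, intercept = np.polyfit(lc, ls, 1)
        rows.append(
            {
                "pair": pair,
                "n_genes": int(both.sum()),
                "median_control": float(np.median(lc)),
                "median_sample": float(np.median(ls)),
                "iqr_control": float(np.subtract(*np.percentile(lc, [75, 25]))),
                "iqr_sample": float(np.subtract(*np.percentile(ls, [75, 25]))),
                "slope": float(slope),
                "intercept": float(intercept),
                "pooled_median": float(np.median(np.concatenate([lc, ls]))),
                "flagged": False,
                "reason": "",
            }
        )
    report = pd.DataFrame(rows).set_index("pair")
    ok = ~report["pooled_median"].isna()
    if ok.any():
        center = report.loc[ok, "pooled_median"].median()
        off_median = (report["pooled_median"] - center).abs() > median_threshold
        off_slope = (report["slope"] < slope_range[0]) | (report["slope"] > slope_range[1])
        bad = ok & (off_median | off_slope)
        report.loc[bad, "flagged"] = True
        report.loc[ok & off_median, "reason"] = "median"
        report.loc[ok & off_slope, "reason"] = "slope"
    return report


def classify(
    log_ratio: float,
    p_value: float,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> str:
    """Volcano class of one gene: increased / decreased / unchanged.

    Thresholds are strict and applied on the natural fold-change scale:
    increased iff ``2**log_ratio > fc_up`` and ``p < alpha``; decreased iff
    ``2**log_ratio < fc_down`` and ``p < alpha``.  An undefined p-value
    yields "unchanged".
    """
    if p_value is None or np.isnan(p_value):
        return "unchanged"
    fc = 2.0**log_ratio
    if fc > fc_up and p_value < alpha:
        return "increased"
    if fc < fc_down and p_value < alpha:
        return "decreased"
    return "unchanged"


def test_differential(
    matrix: ReplicatePairMatrix,
    min_pairs: int = 2,
    mode: str = "paired",
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Per-gene log2 ratio, t-test p-value and volcano class.

    Only replicate pairs in which a gene is detected in *both* arms
    contribute; genes with fewer than ``min_pairs`` such pairs are classed
    "insufficient" with no p-value.  ``log_sam``/``log_con`` are the means
    of the used log2 intensities and ``log_ratio = log_sam - log_con``.
    ``mode="paired"`` runs a two-tailed one-sample t-test on the per-pair
    log2 differences; ``mode="unpaired"`` a two-tailed two-sample t-test on
    the two arms.  Zero variance of the differences makes the test
    degenerate: no p-value, class "unchanged", ``degenerate`` flag set.
    Benjamini-Hochberg q-values over the tested genes are added as an extra
    column (no correction is applied to the classification itself).
    """
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"unknown mode {mode!r}")
    con = matrix.data.xs("control", axis=1, level=1).to_numpy()
    sam = matrix.data.xs("sample", axis=1, level=1).to_numpy()
    genes = matrix.genes

    rows = []
    for i, gene in enumerate(genes):
        used = (con[i] > 0) & (sam[i] > 0)
        n_used = int(used.sum())
        if n_used < min_pairs:
            rows.append(
                {
                    "gene": gene,
                    "n_pairs_used": n_used,
                    "log_sam": np.nan,
                    "log_con": np.nan,
                    "log_ratio": np.nan,
                    "p_value": np.nan,
                    "volcano_class": "insufficient",
                    "degenerate": False,
                }
            )
            continue
        lc = np.log2(con[i][used])
        ls = np.log2(sam[i][used])
        log_sam, log_con = float(ls.mean()), float(lc.mean())
        log_ratio = log_sam - log_con
        diffs = ls - lc
        degenerate = False
        if mode == "paired":
            if np.ptp(diffs) < 1e-12:
                p = np.nan
                degenerate = True
            else:
                p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
        else:
            if np.ptp(ls) < 1e-12 and np.ptp(lc) < 1e-12:
                p = np.nan
                degenerate = True
            else:
                p = float(stats.ttest_ind(ls, lc).pvalue)
        rows.append(
            {
                "gene": gene,
                "n_pairs_used": n_used,
                "log_sam": log_sam,
                "log_con": log_con,
                "log_ratio": log_ratio,
                "p_value": p,
                "volcano_class": classify(log_ratio, p, fc_up, fc_down, alpha),
                "degenerate": degenerate,
            }
        )
    results = pd.DataFrame(rows).set_index("gene")
    tested = results["p_value"].notna()
    results["q_value"] = np.nan
    if tested.any():
        results.loc[tested, "q_value"] = multipletests(
            results.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return results


def volcano_table(
    results: pd.DataFrame, plot_path: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Ordered volcano report plus class-count summary (and optional plot).

    Rows are sorted by log_ratio descending (ties on gene name); the
    summary counts every class including insufficient so the counts always
    partition the input.  When ``plot_path`` is given, a log2-ratio vs
    -log10(p) scatter coloured by class is written there.
    """
    table = results.reset_index()
    table = table.sort_values(
        ["log_ratio", "gene"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    counts = table["volcano_class"].value_counts()

    if plot_path is not None and len(table):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plotted = table.dropna(subset=["p_value"])
        colors = {"increased": "tab:red", "decreased": "tab:blue", "unchanged": "0.6"}
        fig, ax = plt.subplots(figsize=(5, 4))
        for cls, grp in plotted.groupby("volcano_class"):
            ax.scatter(
                grp["log_ratio"],
                -np.log10(grp["p_value"]),
                s=6,
                c=colors.get(cls, "0.6"),
                label=f"{cls} (n={len(grp)})",
            )
        ax.axhline(-np.log10(ALPHA_DEFAULT), ls=":", c="k", lw=0.8)
        ax.axvline(np.log2(FC_UP_DEFAULT), ls=":", c="k", lw=0.8)
        ax.axvline(np.log2(FC_DOWN_DEFAULT), ls=":", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change (inhibitor / control)")
        ax.set_ylabel("-log10 p")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)

    return table, counts
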