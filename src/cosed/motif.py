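"""14-3-3 site annotation, directional enrichment and positional composition.

Candidate 14-3-3 binding phospho-sites come either from an external
predictor's per-site score table (ANN / PSSM / SVM / consensus scores, kept
when all four exceed their thresholds strictly) or from a simple built-in
consensus scanner — a documented stand-in for the external tool, matching
mode-I-like contexts (basic residue at -3/-4, proline at +2 around an S/T).

Downstream statistics: a two-sided exact binomial test of the
increased/decreased split among proteins with vs without passing sites
against 50:50; fold-change quintile binning; residue x position (-6..+6)
composition counts per bin group with per-cell Fisher exact tests between
the top-20% group and the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
WINDOW_RADIUS = 6  # 13-residue window, phospho-site at the centre
PAD = "-"
POSITIONS = tuple(range(-WINDOW_RADIUS, WINDOW_RADIUS + 1))


@dataclass(frozen=True)
class PredictorThresholds:
    """Strict lower bounds on the predictor scores ("above" the defaults)."""

    consensus: float = 0.9
    ann: float = 0.55
    pssm: float = 0.80
    svm: float = 0.25


@dataclass
class PredictedSite:
    """A candidate 14-3-3 binding phospho-site.

    ``position`` is the 1-based residue index of the phospho-S/T; ``window``
    is the 13-residue context (positions -6..+6) with ``-`` padding where
    the window overhangs the sequence end, or "" if no sequence was
    available.
    """

    protein: str
    position: int
    center_residue: str
    window: str
    score_ann: float = np.nan
    score_pssm: float = np.nan
    score_svm: float = np.nan
    score_consensus: float = np.nan
    passes: bool = False
    aurora_context: bool = False

    def __post_init__(self) -> None:
        if self.center_residue not in ("S", "T"):
            raise ValueError(
                f"center residue must be S or T, got {self.center_residue!r} "
                f"({self.protein} position {self.position})"
            )
        if self.window and len(self.window) != 2 * WINDOW_RADIUS + 1:
            raise ValueError(f"window must have {2 * WINDOW_RADIUS + 1} residues")


@dataclass
class CompositionCounts:
    """Residue x position counts over the 13-residue windows of one group."""

    label: str
    counts: pd.DataFrame  # index: residues, columns: positions -6..+6
    n_sites: int

    def denominators(self) -> pd.Series:
        """Non-padded window count at each position."""
        return self.counts.sum(axis=0)


@dataclass
class EnrichmentResult:
    """Directional (increase vs decrease) split within each site partition."""

    n_with_sites_up: int
    n_with_sites_down: int
    n_without_up: int
    n_without_down: int
    p_with: float = np.nan
    p_without: float = np.nan


def extract_window(sequence: str, position: int) -> str:
    """13-residue window around a 1-based position, ``-``-padded at overhangs."""
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    i = position - 1
    left = sequence[max(0, i - WINDOW_RADIUS) : i]
    right = sequence[i + 1 : i + 1 + WINDOW_RADIUS]
    return (
        PAD * (WINDOW_RADIUS - len(left))
        + left
        + sequence[i]
        + right
        + PAD * (WINDOW_RADIUS - len(right))
    )


def import_predictions(
    table: pd.DataFrame | str | Path,
    sequences: dict[str, str],
    thresholds: PredictorThresholds = PredictorThresholds(),
) -> list[PredictedSite]:
    """Build :class:`PredictedSite` records from a predictor score table.

    ``table`` needs columns ``protein, position, ann, pssm, svm, consensus``
    (TSV path or DataFrame).  A site passes iff *all four* scores strictly
    exceed their thresholds.  A position beyond the protein's sequence is an
    error naming the protein; a missing sequence keeps the site with an
    empty window (logged).
    """
    import logging

    logger = logging.getLogger(__name__)
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"protein", "position", "ann", "pssm", "svm", "consensus"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing predictor columns: {sorted(missing)}")

    sites = []
    for _, row in table.iterrows():
        protein = str(row["protein"])
        position = int(row["position"])
        seq = sequences.get(protein)
        if seq is None:
            logger.warning("no sequence for %s; site kept with empty window", protein)
            window, center = "", "S"
        else:
            if position > len(seq):
                raise ValueError(
                    f"position {position} beyond sequence of {protein} (length {len(seq)})"
                )
            window = extract_window(seq, position)
            center = seq[position - 1]
        passes = (
            float(row["consensus"]) > thresholds.consensus
            and float(row["ann"]) > thresholds.ann
            and float(row["pssm"]) > thresholds.pssm
            and float(row["svm"]) > thresholds.svm
        )
        site = PredictedSite(
            protein=protein,
            position=position,
            center_residue=center,
            window=window,
            score_ann=float(row["ann"]),
            score_pssm=float(row["pssm"]),
            score_svm=float(row["svm"]),
            score_consensus=float(row["consensus"]),
            passes=passes,
        )
        site.aurora_context = annotate_aurora_context(site)
        sites.append(site)
    return sites


def scan_consensus(
    sequence: str,
    basic_offsets: tuple[int, ...] = (-3, -4),
    basic_residues: str = "RK",
    proline_offset: int = 2,
) -> list[int]:
    """Scan one sequence for mode-I-like 14-3-3 consensus candidates.

    Reports every S/T (1-based positions) with a basic residue (R/K) at one
    of ``basic_offsets`` and a proline at ``proline_offset``.  This is a
    deliberately simple stand-in for the external site predictor; it shares
    its output shape so downstream statistics run unchanged.
    """
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    hits = []
    for i, residue in enumerate(sequence):
        if residue not in "ST":
            continue
        has_basic = any(
            0 <= i + off < len(sequence) and sequence[i + off] in basic_residues
            for off in basic_offsets
        )
        j = i + proline_offset
        has_pro = 0 <= j < len(sequence) and sequence[j] == "P"
        if has_basic and has_pro:
            hits.append(i + 1)
    return hits


def sites_from_scan(protein: str, sequence: str) -> list[PredictedSite]:
    """Run the consensus scanner and wrap hits as passing PredictedSites."""
    sites = []
    for pos in scan_consensus(sequence):
        site = PredictedSite(
            protein=protein,
            position=pos,
            center_residue=sequence[pos - 1],
            window=extract_window(sequence, pos),
            passes=True,
        )
        site.aurora_context = annotate_aurora_context(site)
        sites.append(site)
    return sites


def annotate_aurora_context(site: PredictedSite) -> bool:
    """True iff the -2 residue is S/T preceded two upstream by R/K.

    This matches the Aurora B phosphorylation consensus (R/K-x-S/T) sitting
    at the -2 position of the 14-3-3 site, the configuration seen at
    Borealin S161/S163.  Padded -2 or -4 positions yield False.
    """
    w = site.window
    if not w:
        return False
    minus2 = w[WINDOW_RADIUS - 2]
    minus4 = w[WINDOW_RADIUS - 4]
    return minus2 in "ST" and minus4 in "RK"


def directional_enrichment(
    diff_results: pd.DataFrame, proteins_with_sites: set[str]
) -> EnrichmentResult:
    """Test the increase/decrease split against 50:50 within site partitions.

    All genes with a defined, non-zero log_ratio are used (sign of the
    ratio, not the p<0.05 classes): each partition — proteins with at least
    one passing site and proteins without — gets a two-sided exact binomial
    test of its number of increased genes against p=0.5.  An empty
    partition leaves its p-value undefined (NaN).
    """
    defined = diff_results.dropna(subset=["log_ratio"])
    defined = defined[defined["log_ratio"] != 0]
    up = defined["log_ratio"] > 0
    with_sites = defined.index.isin(proteins_with_sites)

    n_with_up = int((up & with_sites).sum())
    n_with_down = int((~up & with_sites).sum())
    n_without_up = int((up & ~with_sites).sum())
    n_without_down = int((~up & ~with_sites).sum())

    result = EnrichmentResult(n_with_up, n_with_down, n_without_up, n_without_down)
    if n_with_up + n_with_down > 0:
        result.p_with = float(
            stats.binomtest(n_with_up, n_with_up + n_with_down, 0.5).pvalue
        )
    if n_without_up + n_without_down > 0:
        result.p_without = float(
            stats.binomtest(n_without_up, n_without_up + n_without_down, 0.5).pvalue
        )
    return result


def bin_by_fold_change(diff_results: pd.DataFrame, n_bins: int = 5) -> pd.Series:
    """Assign genes to contiguous fold-change quantile bins (1 = largest increase).

    Genes are ranked by log_ratio descending with gene-name tie-breaks for
    determinism; any remainder goes to the top bins so bin sizes differ by
    at most one.  Raises when fewer genes than bins.
    """
    defined = diff_results.dropna(subset=["log_ratio"])
    n = len(defined)
    if n < n_bins:
        raise ValueError(f"cannot split {n} genes into {n_bins} bins")
    order = defined.reset_index().sort_values(
        ["log_ratio", "gene"], ascending=[False, True]
    )["gene"]
    base, extra = divmod(n, n_bins)
    sizes = [base + 1] * extra + [base] * (n_bins - extra)
    labels = np.repeat(np.arange(1, n_bins + 1), sizes)
    return pd.Series(labels, index=order, name="bin")


def group_bins(bins: pd.Series, n_bins: int = 5) -> dict[str, set[str]]:
    """Standard top-20% / middle-60% / bottom-20% grouping of quintile bins."""
    return {
        "top20": set(bins.index[bins == 1]),
        "mid60": set(bins.index[bins.isin(range(2, n_bins))]),
        "bottom20": set(bins.index[bins == n_bins]),
    }


def positional_composition(
    sites: list[PredictedSite], genes: set[str], label: str = "custom"
) -> CompositionCounts:
    """Count residues at each window position over passing sites of a group.

    Every passing site of a protein in ``genes`` contributes its window;
    padded overhang positions are not counted, so per-position denominators
    shrink near sequence ends.
    """
    counts = pd.DataFrame(0, index=pd.Index(AMINO_ACIDS, name="residue"), columns=POSITIONS)
    n_sites = 0
    for site in sites:
        if not site.passes or site.protein not in genes or not site.window:
            continue
        n_sites += 1
        for pos, residue in zip(POSITIONS, site.window):
            if residue != PAD:
                counts.loc[residue, pos] += 1
    return CompositionCounts(label=label, counts=counts, n_sites=n_sites)


def composition_significance(
    top: CompositionCounts,
    rest: CompositionCounts,
    alpha: float = 0.01,
    correct: bool = False,
) -> pd.DataFrame:
    """Per-(position, residue) Fisher tests between two composition groups.

    Each cell tests the 2x2 table (this residue vs any other residue) x
    (top group vs rest) at that window position, two-sided.  Cells whose
    position has a zero denominator in either group are skipped.  Returns a
    tidy frame with columns position, residue, count/denominator per group,
    odds direction ("over"/"under" for the top group), p-value and a
    significance flag at ``alpha`` (Benjamini-Hochberg-adjusted when
    ``correct``).
    """
    denom_top = top.denominators()
    denom_rest = rest.denominators()
    rows = []
    for pos in POSITIONS:
        nt, nr = int(denom_top[pos]), int(denom_rest[pos])
        if nt == 0 or nr == 0:
            continue
        for residue in AMINO_ACIDS:
            a = int(top.counts.loc[residue, pos])
            b = int(rest.counts.loc[residue, pos])
            table = [[a, nt - a], [b, nr - b]]
            p = float(stats.fisher_exact(table).pvalue)
            freq_top = a / nt
            freq_rest = b / nr
            rows.append(
                {
                    "position": pos,
                    "residue": residue,
                    "count_top": a,
                    "denom_top": nt,
                    "count_rest": b,
                    "denom_rest": nr,
                    "freq_top": freq_top,
                    "freq_rest": freq_rest,
                    "direction": "over" if freq_top > freq_rest else "under",
                    "p_value": p,
                }
            )
    result = pd.DataFrame(rows)
    if correct and len(result):
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result["significant"] = result["p_adjusted"] < alpha
    elif len(result):
        result["significant"] = result["p_value"] < alpha
    return result


def export_count_matrix(counts: CompositionCounts, path: str | Path) -> None:
    """Write a TRANSFAC-like position-count matrix (positions -6..+6 as rows)."""
    frame = counts.counts.T.copy()
    frame.index.name = "position"
    with open(path, "w") as fh:
        fh.write(f"# group: {counts.label}\n# n_sites: {counts.n_sites}\n")
        frame.to_csv(fh, sep="\t")


def read_count_matrix(path: str | Path) -> CompositionCounts:
    """Round-trip reader for :func:`export_count_matrix` output."""
    with open(path) as fh:
        label = fh.readline().split(":", 1)[1].strip()
        n_sites = int(fh.readline().split(":", 1)[1])
        frame = pd.read_csv(fh, sep="\t", index_col="position")
    counts = frame.T
    counts.index.name = "residue"
    counts.columns = [int(c) for c in counts.columns]
    return CompositionCounts(label=label, counts=counts, n_sites=n_sites)
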