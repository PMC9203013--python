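"""Re-analysis of the study's deposited tables, where available locally.

These functions re-run the pipeline on the deposited supplementary
spreadsheets of the co-sedimentation study (raw per-replicate protein-groups
sheets, the quantified log-intensity sheet, the composition count table, the
per-oocyte GFP signal table and the bi-orientation count table).  The files
are not redistributed with the package; point the functions at a directory
containing them (see the README's reproduction section for the expected
filenames).  Everything here goes through the same code paths as the
synthetic analyses — no statistics are special-cased.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from cosed import differential, io, motif, signal_stats

#: expected filenames under the user-provided data directory
RAW_REPLICATE_FILES = {
    "1": "s2_table_replicate1.xlsx",
    "2": "s3_table_replicate2.xlsx",
    "5": "s4_table_replicate5.xlsx",
    "6": "s5_table_replicate6.xlsx",
    "7": "s6_table_replicate7.xlsx",
    "8": "s7_table_replicate8.xlsx",
}
QUANTIFIED_FILE = "s1_table_quantified.xlsx"
COMPOSITION_FILE = "s8_table_composition.xlsx"
GFP_SIGNAL_FILE = "s10_table_gfp_signal.xlsx"
ORIENTATION_FILE = "s11_table_orientation.xlsx"


def detected_and_quantifiable(
    data_dir: str | Path, min_pairs: int = 2
) -> tuple[int, int]:
    """Detected and quantifiable protein counts from the six raw replicate sheets.

    Parses each replicate's protein-groups sheet, removes decoy /
    contaminant / only-by-site rows, collapses accessions per gene, merges
    into the replicate-pair matrix and counts genes detected anywhere
    (detected) and genes with both arms detected in >= ``min_pairs`` pairs
    (quantifiable).
    """
    data_dir = Path(data_dir)
    records_per_pair = {}
    for label, name in RAW_REPLICATE_FILES.items():
        path = data_dir / name
        if not path.exists():
            raise FileNotFoundError(path)
        records = io.read_protein_groups(path, dialect="supplementary-xlsx")
        records_per_pair[label] = differential.collapse_accessions(
            io.filter_standard_flags(records)
        )
    matrix = differential.build_matrix(records_per_pair)
    n_detected = len(matrix.genes)
    con = matrix.data.xs("control", axis=1, level=1)
    sam = matrix.data.xs("sample", axis=1, level=1)
    n_quantifiable = int((((con > 0) & (sam > 0)).sum(axis=1) >= min_pairs).sum())
    return n_detected, n_quantifiable


def volcano_counts(data_dir: str | Path) -> tuple[int, int, pd.DataFrame]:
    """Increased / decreased counts from the deposited quantified sheet.

    Reads the per-gene log2 intensity sheet, reruns the paired t-test and
    classification at fold change > 1.5 / < 1/1.5 and p < 0.05, and returns
    (n_increased, n_decreased, full result table).
    """
    matrix = io.read_quantified_table(Path(data_dir) / QUANTIFIED_FILE)
    results = differential.test_differential(matrix, min_pairs=2, mode="paired")
    counts = results["volcano_class"].value_counts()
    return int(counts.get("increased", 0)), int(counts.get("decreased", 0)), results


def gfp_signal_reductions(
    data_dir: str | Path, reference: str = "WT"
) -> pd.DataFrame:
    """Median percent reductions of GFP signal per genotype vs the wild type.

    Expects a long-format sheet with a genotype/group column and an
    intensity column.  Returns one row per non-reference genotype with the
    medians, the percent reduction and the two-sided rank-sum p-value.
    """
    frame = pd.read_excel(Path(data_dir) / GFP_SIGNAL_FILE)
    cols = {str(c).strip().lower(): c for c in frame.columns}
    group_col = next(
        (cols[k] for k in ("genotype", "group", "construct") if k in cols), None
    )
    value_col = next(
        (cols[k] for k in ("intensity", "signal", "gfp") if k in cols), None
    )
    if group_col is None or value_col is None:
        raise ValueError("could not identify genotype and intensity columns")
    frame = frame.dropna(subset=[value_col])
    groups = {g: frame.loc[frame[group_col] == g, value_col].to_numpy() for g in frame[group_col].unique()}
    ref_key = next((g for g in groups if str(g).strip().upper().startswith(reference.upper())), None)
    if ref_key is None:
        raise ValueError(f"reference genotype {reference!r} not found")
    rows = []
    for g, values in groups.items():
        if g == ref_key:
            continue
        med_ref, med_g, pct, p = signal_stats.compare_intensities(groups[ref_key], values)
        rows.append(
            {
                "genotype": g,
                "median_reference": med_ref,
                "median": med_g,
                "percent_reduction": pct,
                "rank_sum_p": p,
            }
        )
    return pd.DataFrame(rows)


def biorientation_frequencies(
    data_dir: str | Path, control: str = "control"
) -> pd.DataFrame:
    """Mono-orientation frequencies per genotype with Fisher tests vs control.

    Expects a sheet with genotype, bi-oriented and mono-oriented count
    columns.  Returns per-genotype frequency plus the two-sided Fisher
    exact p against the control genotype.
    """
    frame = pd.read_excel(Path(data_dir) / ORIENTATION_FILE)
    cols = {str(c).strip().lower(): c for c in frame.columns}
    geno = next((cols[k] for k in ("genotype", "group") if k in cols), frame.columns[0])
    bi = next((cols[k] for k in cols if "bi" in k), None)
    mono = next((cols[k] for k in cols if "mono" in k), None)
    if bi is None or mono is None:
        raise ValueError("could not identify bi-/mono-orientation count columns")
    frame = frame.set_index(geno)
    ctrl_key = next(
        (g for g in frame.index if control.lower() in str(g).lower()), None
    )
    if ctrl_key is None:
        raise ValueError(f"control genotype {control!r} not found")
    rows = []
    for g in frame.index:
        n_bi, n_mono = int(frame.loc[g, bi]), int(frame.loc[g, mono])
        if g == ctrl_key:
            p = 1.0
        else:
            counts = pd.DataFrame(
                {
                    "bioriented": [int(frame.loc[ctrl_key, bi]), n_bi],
                    "monooriented": [int(frame.loc[ctrl_key, mono]), n_mono],
                },
                index=pd.Index(["control", "other"], name="group"),
            )
            _, p = signal_stats.biorientation_test(counts)
        rows.append(
            {
                "genotype": g,
                "n": n_bi + n_mono,
                "mono_frequency": n_mono / (n_bi + n_mono),
                "fisher_p_vs_control": p,
            }
        )
    return pd.DataFrame(rows)


def composition_flags(data_dir: str | Path, alpha: float = 0.01) -> pd.DataFrame:
    """Significant residue/position cells of the deposited composition table.

    The spreadsheet stores raw residue-by-position counts (positions 1..13,
    the phospho-site at position 7) for the five fold-change bins, one
    sheet (or column block) per group; groups 2-4 are the middle 60%.
    Tests the top-20% group against all other groups pooled, two-sided
    Fisher per cell, and returns the cells significant at ``alpha``.
    """
    path = Path(data_dir) / COMPOSITION_FILE
    sheets = pd.read_excel(path, sheet_name=None, index_col=0)
    groups = {}
    for name, frame in sheets.items():
        frame = frame.dropna(how="all").dropna(axis=1, how="all")
        frame.index = [str(i).strip().upper()[:1] for i in frame.index]
        frame = frame.loc[[i for i in frame.index if i in motif.AMINO_ACIDS]]
        frame.columns = list(motif.POSITIONS)[: len(frame.columns)]
        counts = frame.reindex(
            index=pd.Index(motif.AMINO_ACIDS, name="residue"),
            columns=list(motif.POSITIONS),
            fill_value=0,
        ).fillna(0).astype(int)
        groups[name] = counts
    names = sorted(groups)
    top_name = next((n for n in names if "1" in n or "top" in n.lower()), names[0])
    top = motif.CompositionCounts(
        label="top20", counts=groups[top_name], n_sites=int(groups[top_name].loc["S", 0] + groups[top_name].loc["T", 0])
    )
    rest_counts = sum(groups[n] for n in names if n != top_name)
    rest = motif.CompositionCounts(
        label="rest", counts=rest_counts, n_sites=int(rest_counts.loc["S", 0] + rest_counts.loc["T", 0])
    )
    sig = motif.composition_significance(top, rest, alpha=alpha)
    return sig[sig["significant"]]
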