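"""Readers and validators for protein-groups tables, FASTA, predictor and edge tables.

Two protein-groups dialects are supported and must be named explicitly
(never sniffed): the MaxQuant ``proteinGroups`` tab-separated dialect and
the deposited-study XLSX dialect whose intensity columns are named
``LFQ intensity CON<r>`` / ``LFQ intensity SAM<r>`` per replicate pair.
An intensity of 0 always means "not detected" and is preserved, never
imputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_INTENSITY_RE = re.compile(r"^LFQ intensity (CON|SAM)\s*(\S+)$")
_PEPTIDES_RE = re.compile(r"^Peptides (CON|SAM)\s*(\S+)$")

#: arm naming: "control" = untreated, "sample" = inhibitor (R18) treated
ARM_BY_TAG = {"CON": "control", "SAM": "sample"}


@dataclass
class ProteinGroupRecord:
    """One row of a protein-groups table."""

    protein_ids: list[str]
    majority_ids: list[str] = field(default_factory=list)
    gene_name: str = ""
    peptides_total: int = 0
    peptides_per_column: dict[str, int] = field(default_factory=dict)
    razor_unique_peptides: int = 0
    unique_peptides: int = 0
    score: float = 0.0
    intensities: dict[tuple[str, str], float] = field(default_factory=dict)
    flag_reverse: bool = False
    flag_contaminant: bool = False
    flag_only_by_site: bool = False

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError("protein_ids must be non-empty")
        if self.peptides_total < 0 or self.razor_unique_peptides < 0:
            raise ValueError("peptide counts must be >= 0")
        for key, value in self.intensities.items():
            if value < 0:
                raise ValueError(f"negative intensity for {key}")

    @property
    def gene_key(self) -> str:
        """Analysis key: first gene symbol, or the lead accession if unnamed."""
        if self.gene_name:
            return self.gene_name.split(";")[0].strip()
        return self.protein_ids[0]


class ReplicatePairMatrix:
    """Genes x replicate pairs of (control, sample) intensity pairs.

    Backed by a DataFrame with a (pair label, arm) MultiIndex on columns;
    a cell of 0 means not detected.  Every gene appears exactly once.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex):
            raise ValueError("expected (pair, arm) MultiIndex columns")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate genes in matrix: {dupes[:5]}")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def pairs(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def arm(self, pair: str, arm: str) -> pd.Series:
        return self.data[(pair, arm)]

    def swap_arms(self) -> "ReplicatePairMatrix":
        """Return a matrix with control and sample arms exchanged."""
        swapped = self.data.copy()
        swapped.columns = pd.MultiIndex.from_tuples(
            [
                (p, {"control": "sample", "sample": "control"}[a])
                for p, a in self.data.columns
            ]
        )
        return ReplicatePairMatrix(swapped[self.data.columns])

    def to_tsv(self, path: str | Path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{arm}_{pair}" for pair, arm in self.data.columns]
        flat.index.name = "gene"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReplicatePairMatrix":
        flat = pd.read_csv(path, sep="\t", index_col="gene")
        cols = []
        for c in flat.columns:
            arm, pair = c.split("_", 1)
            cols.append((pair, arm))
        flat.columns = pd.MultiIndex.from_tuples(cols)
        return cls(flat)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReplicatePairMatrix):
            return NotImplemented
        return self.data.equals(other.data)


def _parse_flag(value: object) -> bool:
    return str(value).strip() == "+"


def _load_table(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "maxquant-tsv":
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "supplementary-xlsx":
        frame = pd.read_excel(path, dtype=str)
        return frame.fillna("")
    raise ValueError(f"unknown dialect {dialect!r}")


def read_protein_groups(
    path: str | Path, dialect: str = "maxquant-tsv"
) -> list[ProteinGroupRecord]:
    """Parse a protein-groups table into records.

    ``dialect`` is ``"maxquant-tsv"`` or ``"supplementary-xlsx"``; the two
    share column semantics and differ only in container format and the
    accession column name.  "+" flags map to booleans; absent intensity
    cells read as 0.  A missing mandatory column raises a schema error
    naming the column; an unparseable numeric cell raises an error carrying
    the row index.
    """
    frame = _load_table(path, dialect)
    return records_from_frame(frame, source=str(path))


def records_from_frame(
    frame: pd.DataFrame, source: str = "<frame>"
) -> list[ProteinGroupRecord]:
    """Parse an already-loaded protein-groups table (shared by both dialects)."""
    path = source
    id_col = "Protein IDs"
    if id_col not in frame.columns and "Accession No" in frame.columns:
        id_col = "Accession No"
    required = [id_col]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing} in {path}")

    intensity_cols: list[tuple[str, str, str]] = []
    for col in frame.columns:
        m = _INTENSITY_RE.match(str(col))
        if m:
            intensity_cols.append((col, m.group(2), ARM_BY_TAG[m.group(1)]))
    if not intensity_cols:
        raise ValueError(f"missing mandatory column(s): no 'LFQ intensity CON/SAM' columns in {path}")

    peptide_cols = [
        (col, m.group(1) + m.group(2))
        for col in frame.columns
        if (m := _PEPTIDES_RE.match(str(col)))
    ]

    def _num(value: str, row: int, col: str) -> float:
        text = str(value).strip()
        if text in ("", "NaN", "nan", "NA"):
            return 0.0
        try:
            return float(text)
        except ValueError as exc:
            raise ValueError(f"unparseable numeric cell at row {row}, column {col!r}: {value!r}") from exc

    records: list[ProteinGroupRecord] = []
    for idx, row in frame.iterrows():
        ids = [x for x in str(row[id_col]).split(";") if x]
        if not ids:
            raise ValueError(f"empty protein id at row {idx}")
        intensities = {
            (label, arm): _num(row[col], idx, col) for col, label, arm in intensity_cols
        }
        peptides_per_column = {
            key: int(_num(row[col], idx, col)) for col, key in peptide_cols
        }
        if "Peptides" in frame.columns:
            peptides_total = int(_num(row["Peptides"], idx, "Peptides"))
        else:
            # deposited per-replicate sheets carry only per-column counts
            peptides_total = max(peptides_per_column.values(), default=0)
        records.append(
            ProteinGroupRecord(
                protein_ids=ids,
                majority_ids=[x for x in str(row.get("Majority protein IDs", "")).split(";") if x],
                gene_name=str(row.get("Gene names", "")).strip(),
                peptides_total=peptides_total,
                peptides_per_column=peptides_per_column,
                razor_unique_peptides=int(
                    _num(row.get("Razor + unique peptides", 0), idx, "Razor + unique peptides")
                ),
                unique_peptides=int(_num(row.get("Unique peptides", 0), idx, "Unique peptides")),
                score=_num(row.get("Score", 0), idx, "Score"),
                intensities=intensities,
                flag_reverse=_parse_flag(row.get("Reverse", "")),
                flag_contaminant=_parse_flag(row.get("Potential contaminant", "")),
                flag_only_by_site=_parse_flag(row.get("Only identified by site", "")),
            )
        )
    return records


def filter_standard_flags(records: list[ProteinGroupRecord]) -> list[ProteinGroupRecord]:
    """Drop reverse-decoy, contaminant and only-identified-by-site records."""
    kept = [
        r
        for r in records
        if not (r.flag_reverse or r.flag_contaminant or r.flag_only_by_site)
    ]
    n_removed = len(records) - len(kept)
    if n_removed:
        logger.info(
            "filter_standard_flags: removed %d of %d records "
            "(reverse=%d, contaminant=%d, only-by-site=%d)",
            n_removed,
            len(records),
            sum(r.flag_reverse for r in records),
            sum(r.flag_contaminant for r in records),
            sum(r.flag_only_by_site for r in records),
        )
    return kept


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {accession: uppercase sequence}.

    Duplicate identifiers and empty sequences are rejected.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA identifier: {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {record.id}")
        sequences[record.id] = seq
    return sequences


def read_edge_table(
    path: str | Path, min_score: float = 0.400, physical_only: bool = True
) -> set[frozenset[str]]:
    """Read a STRING-export-style TSV into an undirected edge set.

    Only edges whose ``combined_score`` strictly exceeds ``min_score``
    ("above medium confidence") are kept.  Reversed duplicates collapse to
    one edge and self-loops are dropped.  Malformed rows are skipped with a
    warning.
    If ``physical_only`` and an ``interaction_type`` column exists, only
    rows labelled "physical" are kept.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(frame.columns)
    if len(cols) < 3:
        raise ValueError("edge table needs two endpoint columns plus a score column")
    score_col = "combined_score" if "combined_score" in cols else cols[2]
    a_col, b_col = cols[0], cols[1]

    edges: set[frozenset[str]] = set()
    for idx, row in frame.iterrows():
        try:
            score = float(row[score_col])
        except (TypeError, ValueError):
            logger.warning("read_edge_table: skipping malformed row %d", idx)
            continue
        if (
            physical_only
            and "interaction_type" in cols
            and str(row["interaction_type"]).strip().lower() != "physical"
        ):
            continue
        a, b = str(row[a_col]).strip(), str(row[b_col]).strip()
        if not a or not b or a == b:
            continue
        if score > min_score:
            edges.add(frozenset((a, b)))
    return edges


def read_quantified_table(path: str | Path) -> ReplicatePairMatrix:
    """Read a deposited quantified-result sheet (logSAM<r>/logCON<r> columns).

    The sheet stores per-replicate log2 intensities keyed by gene name
    (replicate labels are exposed verbatim, e.g. 1, 2, 5, 6, 7, 8).  Missing
    log cells denote non-detection and map to intensity 0.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path, sep="\t")
    gene_col = next(
        (c for c in frame.columns if str(c).lower() in ("genename", "gene", "gene names")),
        None,
    )
    if gene_col is None:
        raise ValueError("missing mandatory column: geneName")
    log_re = re.compile(r"^log(SAM|CON)(\S+)$")
    pairs: dict[tuple[str, str], str] = {}
    for col in frame.columns:
        m = log_re.match(str(col).strip())
        if m:
            pairs[(m.group(2), ARM_BY_TAG[m.group(1)])] = col
    if not pairs:
        raise ValueError("missing mandatory column(s): no logSAM/logCON columns")
    data = {}
    for key, col in sorted(pairs.items()):
        values = pd.to_numeric(frame[col], errors="coerce")
        data[key] = np.where(values.isna(), 0.0, 2.0**values)
    matrix = pd.DataFrame(data, index=frame[gene_col].astype(str))
    matrix.columns = pd.MultiIndex.from_tuples(matrix.columns)
    matrix = matrix[~matrix.index.duplicated(keep="first")]
    return ReplicatePairMatrix(matrix)
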