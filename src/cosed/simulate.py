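"""Seeded synthetic data emulating a paired microtubule co-sedimentation experiment.

The generator mirrors the experimental design the analysis assumes: soluble
extract split into a control arm and an inhibitor-treated ("sample") arm for
each of several biological replicate pairs, with label-free intensities on a
log-normal scale, zero-inflated missingness (an intensity of 0 means "not
detected", never a measured value), a spiked subset of truly regulated
proteins with multiplicative fold changes, and protein sequences carrying
planted 14-3-3 consensus motifs whose presence correlates with the spiked
direction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Planted mode-I-like 14-3-3 motif.  Relative to the central phospho-serine
#: (index 4 of the 7-mer) it reads  K(-4) R(-3) S(-2) K(-1) S(0) V(+1) P(+2):
#: a basic residue at -3, a proline at +2, and an Aurora-consensus serine at
#: -2 preceded by a basic residue at -4.
PLANTED_MOTIF = "KRSKSVP"
PLANTED_MOTIF_CENTER = 4  # 0-based offset of the phospho-S within the motif


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one simulated co-sedimentation experiment.

    Defaults describe the regime of the real experiment: six biological
    replicate pairs, log-normal LFQ-style intensities around 2^23, and a
    missing rate chosen so that roughly 42% of detected proteins are
    quantifiable (both arms detected) in at least two pairs.
    """

    n_proteins: int = 2000
    n_replicate_pairs: int = 6
    baseline_log2_mean: float = 23.0
    baseline_log2_sd: float = 2.0
    replicate_noise_sd: float = 0.5
    missing_rate: float = 0.55
    n_spiked_up: int = 60
    n_spiked_down: int = 25
    spike_fold_change: float = 2.0
    motif_rate_spiked: float = 0.6
    motif_rate_background: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field."""
        for name in ("n_proteins", "n_replicate_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_spiked_up", "n_spiked_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_spiked_up + self.n_spiked_down > self.n_proteins:
            raise ValueError(
                "n_spiked_up + n_spiked_down exceeds n_proteins "
                f"({self.n_spiked_up} + {self.n_spiked_down} > {self.n_proteins})"
            )
        for name in ("missing_rate", "motif_rate_spiked", "motif_rate_background"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.spike_fold_change <= 0:
            raise ValueError(f"spike_fold_change must be > 0, got {self.spike_fold_change}")
        for name in ("baseline_log2_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class GroundTruth:
    """Per-protein truth recorded by the generator.

    ``direction`` maps every simulated gene to "up", "down" or "null";
    ``fold_change`` holds the true multiplicative sample/control fold change
    (1.0 for null proteins); ``motif_positions`` holds the 1-based position of
    the planted phospho-serine for every sequence that carries a motif.
    """

    direction: dict[str, str] = field(default_factory=dict)
    fold_change: dict[str, float] = field(default_factory=dict)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.direction:
            rows.append(
                {
                    "gene": gene,
                    "direction": self.direction[gene],
                    "fold_change": self.fold_change[gene],
                    "motif_positions": ";".join(
                        str(p) for p in self.motif_positions.get(gene, [])
                    ),
                }
            )
        return pd.DataFrame(rows)


def ground_truth_lookup(truth: GroundTruth, protein: str) -> tuple[str, float, list[int]]:
    """Return (direction, fold change, motif positions) for one protein.

    Raises ``KeyError`` for a protein the generator never produced.
    """
    if protein not in truth.direction:
        raise KeyError(f"protein {protein!r} not present in ground truth")
    return (
        truth.direction[protein],
        truth.fold_change[protein],
        list(truth.motif_positions.get(protein, [])),
    )


def _logistic_location(mean: float, sd: float, tau: float, rate: float) -> float:
    """Location c such that E_z[1/(1+exp((z-c)/tau))] = rate for z ~ N(mean, sd).

    Solved by Gauss-Hermite quadrature + bisection; makes the overall
    expected dropout fraction equal the configured missing rate.
    """
    from scipy.optimize import brentq

    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    z = mean + sd * nodes
    w = weights / weights.sum()

    def mean_dropout(c: float) -> float:
        return float(np.sum(w / (1.0 + np.exp((z - c) / tau))))

    lo, hi = mean - 20 * sd - 1, mean + 20 * sd + 1
    return float(brentq(lambda c: mean_dropout(c) - rate, lo, hi, xtol=1e-10))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_experiment(
    config: ExperimentConfig,
    *,
    missing_mode: str = "abundance",
    single_peptide_rate: float = 0.05,
    duplicate_accession_rate: float = 0.05,
    n_contaminants: int = 15,
    n_reverse: int = 10,
) -> tuple[dict[str, pd.DataFrame], dict[str, str], GroundTruth]:
    """Simulate protein-groups tables, sequences and their ground truth.

    Returns ``(tables, sequences, truth)`` where ``tables`` maps a replicate
    label ("1", "2", ...) to a protein-groups table in the tab-separated
    dialect :func:`cosed.io.read_protein_groups` reads, ``sequences`` maps
    accession to amino-acid sequence, and ``truth`` records the planted
    regulation and motifs.

    Model per protein *i* and replicate pair *r* (all on log2 scale):
    shared baseline ``b_i ~ N(mean, sd)``, pair effect ``e_ir ~ N(0, noise)``
    common to both arms, independent arm noise ``~ N(0, noise)``, and a spike
    term ``±log2(spike_fold_change)`` added to the sample arm of spiked
    proteins.  Intensities are materialised as ``2**x`` so zeros arise only
    from the missingness mechanism.

    ``missing_mode`` selects the dropout model.  ``"abundance"`` (default)
    follows the standard label-free dropout picture: each cell's missing
    probability is logistic in the protein's baseline log2 abundance,
    ``1 / (1 + exp((b_i - c) / tau))`` with ``tau = 0.75 * baseline_log2_sd``
    and the location ``c`` calibrated so the expected overall zero fraction
    equals ``missing_rate``, while low-abundance proteins drop out
    preferentially.
    ``"mcar"`` drops every cell independently at exactly ``missing_rate``.

    Realism knobs: a fraction of accessions carry a single peptide (removed
    later by the collapse step), some genes get a second lower-scored
    accession, and a few reverse-decoy / contaminant rows are appended.
    """
    config.validate()
    if missing_mode not in ("abundance", "mcar"):
        raise ValueError(f"unknown missing_mode {missing_mode!r}")

    rng = np.random.default_rng([config.seed, 0x5EED])
    n = config.n_proteins
    genes = [f"gene{i:05d}" for i in range(n)]
    accessions = [f"SIM{i:05d}" for i in range(n)]

    # Planted regulation: the first n_spiked_up proteins go up, the next
    # n_spiked_down go down, the rest are null.
    direction = np.array(["null"] * n, dtype=object)
    direction[: config.n_spiked_up] = "up"
    direction[config.n_spiked_up : config.n_spiked_up + config.n_spiked_down] = "down"
    log2_fc = np.zeros(n)
    log2_fc[direction == "up"] = np.log2(config.spike_fold_change)
    log2_fc[direction == "down"] = -np.log2(config.spike_fold_change)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    scores = np.round(rng.uniform(10, 400, size=n), 2)
    peptides = 2 + rng.poisson(8, size=n)
    single = rng.random(n) < single_peptide_rate
    peptides[single] = 1

    truth = GroundTruth(
        direction={g: d for g, d in zip(genes, direction)},
        fold_change={g: float(2.0**f) for g, f in zip(genes, log2_fc)},
    )

    # Sequences with planted motifs correlated with the spiked direction.
    seq_rng = np.random.default_rng([config.seed, 0xFA57A])
    sequences: dict[str, str] = {}
    for i, (gene, acc) in enumerate(zip(genes, accessions)):
        length = int(seq_rng.integers(200, 600))
        seq = _random_sequence(seq_rng, length)
        rate = (
            config.motif_rate_spiked
            if direction[i] == "up"
            else config.motif_rate_background
        )
        if seq_rng.random() < rate:
            pos = int(seq_rng.integers(10, length - 10))
            seq = seq[:pos] + PLANTED_MOTIF + seq[pos + len(PLANTED_MOTIF) :]
            truth.motif_positions[gene] = [pos + PLANTED_MOTIF_CENTER + 1]
        sequences[acc] = seq

    tables: dict[str, pd.DataFrame] = {}
    for r in range(1, config.n_replicate_pairs + 1):
        pair_rng = np.random.default_rng([config.seed, 0x9A17, r])
        pair_effect = pair_rng.normal(0, config.replicate_noise_sd, size=n)
        log2_con = baseline + pair_effect + pair_rng.normal(0, config.replicate_noise_sd, size=n)
        log2_sam = (
            baseline
            + pair_effect
            + log2_fc
            + pair_rng.normal(0, config.replicate_noise_sd, size=n)
        )
        con = 2.0**log2_con
        sam = 2.0**log2_sam

        if missing_mode == "mcar":
            p_miss = np.full(n, config.missing_rate)
        elif config.missing_rate in (0.0, 1.0) or config.baseline_log2_sd == 0:
            p_miss = np.full(n, config.missing_rate)
        else:
            tau = 0.75 * config.baseline_log2_sd
            c = _logistic_location(
                config.baseline_log2_mean,
                config.baseline_log2_sd,
                tau,
                config.missing_rate,
            )
            p_miss = 1.0 / (1.0 + np.exp((baseline - c) / tau))
        con[pair_rng.random(n) < p_miss] = 0.0
        sam[pair_rng.random(n) < p_miss] = 0.0

        label = str(r)
        frame = pd.DataFrame(
            {
                "Protein IDs": accessions,
                "Majority protein IDs": accessions,
                "Gene names": genes,
                "Peptides": peptides,
                "Razor + unique peptides": peptides,
                "Unique peptides": np.maximum(1, peptides - 1),
                "Score": scores,
                f"Peptides CON{label}": np.where(con > 0, peptides, 0),
                f"Peptides SAM{label}": np.where(sam > 0, peptides, 0),
                f"LFQ intensity CON{label}": np.round(con, 1),
                f"LFQ intensity SAM{label}": np.round(sam, 1),
                "Only identified by site": "",
                "Reverse": "",
                "Potential contaminant": "",
            }
        )

        # Duplicate-gene accessions exercise the collapse rule; identical
        # across pairs so the collapsed output stays consistent.
        dup_rng = np.random.default_rng([config.seed, 0xD0B])
        dup_idx = np.where(dup_rng.random(n) < duplicate_accession_rate)[0]
        dup_rows = frame.iloc[dup_idx].copy()
        dup_rows["Protein IDs"] = [f"SIMDUP{i:05d}" for i in dup_idx]
        dup_rows["Score"] = dup_rows["Score"] * 0.5  # always the lower-scored twin
        for col in (f"LFQ intensity CON{label}", f"LFQ intensity SAM{label}"):
            dup_rows[col] = dup_rows[col] * 0.9

        junk_rng = np.random.default_rng([config.seed, 0xBAD, r])
        junk_int = np.round(2.0 ** junk_rng.normal(20, 2, size=n_contaminants + n_reverse), 1)
        junk = pd.DataFrame(
            {
                "Protein IDs": [f"CONTAM{i:03d}" for i in range(n_contaminants)]
                + [f"REV{i:03d}" for i in range(n_reverse)],
                "Majority protein IDs": "",
                "Gene names": "",
                "Peptides": 5,
                "Razor + unique peptides": 5,
                "Unique peptides": 5,
                "Score": 50.0,
                f"Peptides CON{label}": 5,
                f"Peptides SAM{label}": 5,
                f"LFQ intensity CON{label}": junk_int,
                f"LFQ intensity SAM{label}": junk_int,
                "Only identified by site": "",
                "Reverse": [""] * n_contaminants + ["+"] * n_reverse,
                "Potential contaminant": ["+"] * n_contaminants + [""] * n_reverse,
            }
        )
        tables[label] = pd.concat([frame, dup_rows, junk], ignore_index=True)

    return tables, sequences, truth


def simulate_phenotype(
    n_per_group: int,
    median_shift: float,
    mono_rate_a: float,
    mono_rate_b: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-oocyte signal intensities and 2x2 orientation counts.

    Group B intensities are group-A-like log-normal draws scaled by
    ``1 - median_shift`` (so ``median_shift`` is the expected fractional
    reduction of the median).  Orientation counts are binomial draws of
    mono-oriented oocytes at ``mono_rate_a`` / ``mono_rate_b``.
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    for name, rate in (("mono_rate_a", mono_rate_a), ("mono_rate_b", mono_rate_b)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    if not 0.0 <= median_shift < 1.0:
        raise ValueError(f"median_shift must be in [0, 1), got {median_shift}")

    rng = np.random.default_rng([seed, 0x0C17])
    a = 2.0 ** rng.normal(10.0, 0.5, size=n_per_group)
    b = 2.0 ** rng.normal(10.0, 0.5, size=n_per_group) * (1.0 - median_shift)
    intensities = pd.DataFrame(
        {
            "group": ["A"] * n_per_group + ["B"] * n_per_group,
            "intensity": np.concatenate([a, b]),
        }
    )
    mono_a = int(rng.binomial(n_per_group, mono_rate_a))
    mono_b = int(rng.binomial(n_per_group, mono_rate_b))
    counts = pd.DataFrame(
        {
            "bioriented": [n_per_group - mono_a, n_per_group - mono_b],
            "monooriented": [mono_a, mono_b],
        },
        index=pd.Index(["A", "B"], name="group"),
    )
    return intensities, counts


def simulate_edges(
    truth: GroundTruth,
    *,
    background_rate: float = 0.002,
    spiked_rate: float = 0.08,
    score_range: tuple[float, float] = (0.4, 0.999),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a STRING-export-style physical-interaction edge table.

    Pairs of spiked-up proteins interact at ``spiked_rate``; every other pair
    at ``background_rate`` — emulating a candidate set that is genuinely more
    connected than a random draw.  Returns a DataFrame with columns
    ``protein1, protein2, combined_score``.
    """
    rng = np.random.default_rng([seed, 0xED9E])
    genes = sorted(truth.direction)
    up = {g for g, d in truth.direction.items() if d == "up"}
    rows = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            rate = spiked_rate if (g1 in up and g2 in up) else background_rate
            if rng.random() < rate:
                rows.append(
                    (g1, g2, round(float(rng.uniform(*score_range)), 3))
                )
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def write_experiment(
    outdir: str | Path,
    tables: dict[str, pd.DataFrame],
    sequences: dict[str, str],
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the simulated experiment to disk in the dialects the io module reads.

    Produces ``protein_groups_<label>.tsv`` per replicate pair, a FASTA of
    sequences, and a ground-truth TSV sidecar.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label, frame in tables.items():
        p = outdir / f"protein_groups_{label}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[f"table_{label}"] = p
    fasta = outdir / "sequences.fasta"
    with open(fasta, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["fasta"] = fasta
    sidecar = outdir / "ground_truth.tsv"
    truth.to_frame().to_csv(sidecar, sep="\t", index=False)
    paths["truth"] = sidecar
    return paths


def config_to_dict(config: ExperimentConfig) -> dict:
    return dataclasses.asdict(config)
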