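"""End-to-end orchestration: ingest (or simulate) -> differential -> motif -> network.

`run_all` chains the stages on a directory of inputs or an in-memory
simulation, writes every stage output plus a consolidated summary into a run
directory, and is deterministic for a fixed config and seed (no timestamps
in outputs, one seeded generator stream).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import cosed
from cosed import differential, io, motif, network, simulate
from cosed.motif import PredictorThresholds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``input_dir`` (containing ``protein_groups_<label>.tsv`` tables
    and ``sequences.fasta``) or ``simulation`` must be provided.  Thresholds
    default to the study's: fold change > 1.5 / < 1/1.5 at p < 0.05, paired
    test over >= 2 doubly-detected pairs, quintile bins, predictor scores
    above (0.9, 0.55, 0.80, 0.25), composition alpha 0.01, edge score > 0.4.
    """

    outdir: str = "runs/run"
    input_dir: str | None = None
    simulation: simulate.ExperimentConfig | None = None
    dialect: str = "maxquant-tsv"
    mode: str = "paired"
    min_pairs: int = 2
    fc_up: float = differential.FC_UP_DEFAULT
    fc_down: float = differential.FC_DOWN_DEFAULT
    alpha: float = differential.ALPHA_DEFAULT
    drop_flagged_pairs: bool = True
    predictor_table: str | None = None
    thresholds: PredictorThresholds = field(default_factory=PredictorThresholds)
    composition_alpha: float = 0.01
    n_bins: int = 5
    edges_path: str | None = None
    min_edge_score: float = 0.400
    n_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.input_dir is None and self.simulation is None:
            raise ValueError("one of input_dir or simulation is required")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_up <= 0 or self.fc_down <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if not 0 < self.composition_alpha < 1:
            raise ValueError(f"composition_alpha must be in (0, 1), got {self.composition_alpha}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    # outdir is presentation, not analysis: two runs of the same analysis
    # into different directories hash identically
    d = config.to_dict()
    d.pop("outdir", None)
    text = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns a dict of in-memory results (summary, volcano table, QC report,
    enrichment, composition significance, network enrichment, ground truth
    when simulated).  Any stage error propagates with the stage named in
    the log.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}

    # --- ingest -----------------------------------------------------------
    t0 = _stage("ingest")
    truth = None
    if config.simulation is not None:
        tables, sequences, truth = simulate.simulate_experiment(config.simulation)
        records_per_pair = {
            label: io.filter_standard_flags(
                io.records_from_frame(frame.astype(str), source=f"simulated pair {label}")
            )
            for label, frame in tables.items()
        }
        results["truth"] = truth
    else:
        indir = Path(config.input_dir)
        table_paths = sorted(indir.glob("protein_groups_*.tsv"))
        if not table_paths:
            raise FileNotFoundError(f"no protein_groups_*.tsv under {indir}")
        records_per_pair = {}
        for p in table_paths:
            label = p.stem.replace("protein_groups_", "")
            records_per_pair[label] = io.filter_standard_flags(
                io.read_protein_groups(p, dialect=config.dialect)
            )
        sequences = io.read_fasta(indir / "sequences.fasta")
    n_accessions = sum(len(v) for v in records_per_pair.values())
    logger.info("ingest: %d records over %d pairs (%.1fs)", n_accessions, len(records_per_pair), time.time() - t0)

    # --- differential -----------------------------------------------------
    t0 = _stage("differential")
    collapsed = {
        label: differential.collapse_accessions(recs)
        for label, recs in records_per_pair.items()
    }
    acc_to_gene = {
        rec.protein_ids[0]: rec.gene_key
        for recs in collapsed.values()
        for rec in recs
    }
    matrix = differential.build_matrix(collapsed)
    n_detected = len(matrix.genes)

    qc = differential.replicate_qc(matrix)
    qc.to_csv(outdir / "replicate_qc.tsv", sep="\t")
    results["qc"] = qc
    if config.drop_flagged_pairs and qc["flagged"].any():
        kept = [p for p in matrix.pairs if not qc.loc[p, "flagged"]]
        logger.info("replicate_qc: dropping flagged pairs %s", sorted(set(matrix.pairs) - set(kept)))
        matrix = io.ReplicatePairMatrix(matrix.data[[c for c in matrix.data.columns if c[0] in kept]])

    testable, zero_set = differential.partition_zero_set(matrix)
    (outdir / "zero_set.txt").write_text("\n".join(zero_set) + ("\n" if zero_set else ""))
    diff = differential.test_differential(
        testable,
        min_pairs=config.min_pairs,
        mode=config.mode,
        fc_up=config.fc_up,
        fc_down=config.fc_down,
        alpha=config.alpha,
    )
    volcano, class_counts = differential.volcano_table(diff, plot_path=str(outdir / "volcano.png"))
    volcano.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
    results["diff"] = diff
    results["volcano"] = volcano
    logger.info("differential: %d genes (%.1fs)", len(diff), time.time() - t0)

    # --- motif ------------------------------------------------------------
    t0 = _stage("motif")
    gene_sequences = {
        acc_to_gene[acc]: seq for acc, seq in sequences.items() if acc in acc_to_gene
    }
    if config.predictor_table is not None:
        sites = motif.import_predictions(
            config.predictor_table, gene_sequences, config.thresholds
        )
    else:
        sites = [
            s
            for gene in sorted(gene_sequences)
            for s in motif.sites_from_scan(gene, gene_sequences[gene])
        ]
    pd.DataFrame(
        [
            {
                "protein": s.protein,
                "position": s.position,
                "center": s.center_residue,
                "window": s.window,
                "passes": s.passes,
                "aurora_context": s.aurora_context,
            }
            for s in sites
        ]
    ).to_csv(outdir / "sites.tsv", sep="\t", index=False)
    with_sites = {s.protein for s in sites if s.passes}

    quantified = diff[diff["n_pairs_used"] >= config.min_pairs]
    enrichment = motif.directional_enrichment(quantified, with_sites)
    results["enrichment"] = enrichment

    composition_sig = pd.DataFrame()
    try:
        bins = motif.bin_by_fold_change(quantified, n_bins=config.n_bins)
        groups = motif.group_bins(bins, n_bins=config.n_bins)
        comps = {
            label: motif.positional_composition(sites, genes, label=label)
            for label, genes in groups.items()
        }
        for label, comp in comps.items():
            motif.export_count_matrix(comp, outdir / f"composition_{label}.tsv")
        rest = motif.CompositionCounts(
            label="rest",
            counts=comps["mid60"].counts + comps["bottom20"].counts,
            n_sites=comps["mid60"].n_sites + comps["bottom20"].n_sites,
        )
        composition_sig = motif.composition_significance(
            comps["top20"], rest, alpha=config.composition_alpha
        )
        composition_sig.to_csv(outdir / "composition_significance.tsv", sep="\t", index=False)
        results["bins"] = bins
        results["composition"] = comps
    except ValueError as exc:
        logger.warning("motif composition skipped: %s", exc)
    results["composition_significance"] = composition_sig
    logger.info("motif: %d sites (%.1fs)", len(sites), time.time() - t0)

    # --- network ----------------------------------------------------------
    t0 = _stage("network")
    net = None
    if config.edges_path is not None:
        edges = io.read_edge_table(config.edges_path, min_score=config.min_edge_score)
        candidates = set(diff.index[diff["volcano_class"] == "increased"])
        background = set(quantified.index)
        if candidates and len(background) > len(candidates):
            net = network.permutation_null(
                candidates,
                background,
                edges,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            pd.DataFrame([dataclasses.asdict(net)]).to_csv(
                outdir / "network_enrichment.tsv", sep="\t", index=False
            )
    results["network"] = net
    logger.info("network: done (%.1fs)", time.time() - t0)

    # --- report -----------------------------------------------------------
    summary = {
        "provenance": {
            "package_version": cosed.__version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
        },
        "counts": {
            "accession_rows": n_accessions,
            "detected_genes": n_detected,
            "zero_set_genes": len(zero_set),
            "insufficient": int((diff["volcano_class"] == "insufficient").sum()),
            "quantifiable": int((diff["n_pairs_used"] >= config.min_pairs).sum()),
            "increased": int(class_counts.get("increased", 0)),
            "decreased": int(class_counts.get("decreased", 0)),
            "unchanged": int(class_counts.get("unchanged", 0)),
            "proteins_with_sites": len(with_sites & set(diff.index)),
        },
        "enrichment": {
            "with_sites_up": enrichment.n_with_sites_up,
            "with_sites_down": enrichment.n_with_sites_down,
            "without_sites_up": enrichment.n_without_up,
            "without_sites_down": enrichment.n_without_down,
            "p_with": None if pd.isna(enrichment.p_with) else enrichment.p_with,
            "p_without": None if pd.isna(enrichment.p_without) else enrichment.p_without,
        },
    }
    if net is not None:
        summary["network"] = dataclasses.asdict(net)
    results["summary"] = summary
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "summary.txt").write_text(write_report(summary))
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return results


def write_report(summary: dict) -> str:
    """Render the consolidated summary as a human-readable report."""
    lines = ["microtubule co-sedimentation differential analysis", ""]
    prov = summary["provenance"]
    lines.append(
        f"package {prov['package_version']}  config {prov['config_hash']}  seed {prov['seed']}"
    )
    lines.append("")
    lines.append("counts:")
    for key in sorted(summary["counts"]):
        lines.append(f"  {key}: {summary['counts'][key]}")
    enr = summary["enrichment"]
    lines.append("")
    lines.append("directional enrichment (sign of log ratio vs 50:50):")
    lines.append(
        f"  with predicted sites: {enr['with_sites_up']} up / {enr['with_sites_down']} down"
        f" (p = {enr['p_with']})"
    )
    lines.append(
        f"  without sites:        {enr['without_sites_up']} up / {enr['without_sites_down']} down"
        f" (p = {enr['p_without']})"
    )
    if "network" in summary:
        net = summary["network"]
        lines.append("")
        lines.append(
            "network: observed %d edges, null mean %.2f, empirical p %.4g (%d permutations)"
            % (
                net["observed_edges"],
                net["expected_edges"],
                net["empirical_p"],
                net["n_permutations"],
            )
        )
    return "\n".join(lines) + "\n"
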