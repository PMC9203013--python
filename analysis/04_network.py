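#!/usr/bin/env python
"""Physical-interaction enrichment of the increased set vs a permutation null.

Counts edges of the synthetic interaction table that fall inside the set of
proteins called increased, and compares the count with a seeded permutation
null of equal-size random draws from the quantifiable background (the
sampling frame of the candidate set).  Output under results/network/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from cosed import io, network

ROOT = Path(__file__).resolve().parents[1] / "results"
OUTDIR = ROOT / "network"


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    volcano = pd.read_csv(ROOT / "differential" / "volcano.tsv", sep="\t").set_index("gene")
    edges = io.read_edge_table(ROOT / "simulated_experiment" / "edges.tsv", min_score=0.400)

    quantified = volcano[volcano["n_pairs_used"] >= 2]
    candidates = set(quantified.index[quantified["volcano_class"] == "increased"])
    background = set(quantified.index)
    print(
        f"{len(candidates)} increased proteins in a background of "
        f"{len(background)} quantifiable; {len(edges)} edges above confidence 0.400"
    )
    result = network.permutation_null(
        candidates, background, edges, n_permutations=10_000, seed=1
    )
    pd.DataFrame([dataclasses.asdict(result)]).to_csv(
        OUTDIR / "enrichment.tsv", sep="\t", index=False
    )
    print(
        f"observed {result.observed_edges} internal edges; "
        f"null mean {result.expected_edges:.2f}; "
        f"empirical p = {result.empirical_p:.4g} ({result.n_permutations} permutations)"
    )


if __name__ == "__main__":
    main()
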