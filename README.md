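# cosed — differential analysis of microtubule co-sedimentation proteomics

`cosed` implements the quantitative analysis behind a microtubule
co-sedimentation screen for proteins whose microtubule binding is controlled
by the phospho-docking protein 14-3-3. In the underlying experiment, soluble
*Drosophila* ovary extract is split into two aliquots; one receives the
14-3-3 inhibitor peptide R18, microtubules are polymerised with paclitaxel
in both, and the pelleted microtubule-associated proteins are quantified by
label-free LC-MS/MS over six paired biological replicates. The package takes
the analysis from raw protein-groups tables to the volcano classification,
14-3-3 motif statistics, interaction-network enrichment and the downstream
imaging/phenotype statistics — with a seeded synthetic-data generator that
emulates the experimental design so every stage is testable without the
deposited data (ProteomeXchange accession PXD030445).

## The statistics at the core

For gene *g* with control and inhibitor ("sample") intensities over
replicate pairs *r*:

* pairs with a zero (not-detected) arm are unusable for that gene; genes
  never detected in both arms of the same pair form a separate "zero set";
* over the usable pairs, `logratio(g) = mean(log2 SAM) − mean(log2 CON)`,
  tested with a two-tailed paired t-test on the per-pair differences
  (an unpaired two-sample mode is available); genes need ≥ 2 usable pairs;
* a gene is **increased** if `2^logratio > 1.5` and `p < 0.05`, **decreased**
  if `2^logratio < 1/1.5` and `p < 0.05` (strict inequalities, raw p-values).

Around that core: per-gene accession collapsing (single-peptide accessions
removed, highest search score kept per gene), replicate QC on log2
distributions and best-fit slopes, 14-3-3 site annotation (external
predictor scores with strict thresholds consensus > 0.9, ANN > 0.55,
PSSM > 0.80, SVM > 0.25, or a built-in mode-I consensus scanner), a
two-sided exact binomial test of the increased/decreased split among
proteins with vs without sites, fold-change quintile binning with per-cell
Fisher tests on residue composition in a −6..+6 window around the
phospho-site, a permutation null for interaction-edge counts, the
densitometry background-subtraction formula
`I_S − N_S·(I_L − I_S)/(N_L − N_S)`, Wilcoxon rank-sum median comparisons
and Fisher tests on bi-/mono-orientation counts.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_differential.py
```

prints (seeded, so exactly reproducible):

```
2000 proteins x 6 pairs (12744 table rows), 85 spiked (60 up / 25 down, fold change 2.0)
...
detected 1901 genes across 6 replicate pairs
replicate QC: 0 of 6 pairs flagged
798 quantifiable in >=2 pairs (42% of detected); 612 zero-set genes analysed separately
volcano classes: {'unchanged': 763, 'insufficient': 491, 'decreased': 18, 'increased': 17}
of 17 genes called increased, 6 are truly spiked up
```

1,901 simulated proteins were detected somewhere; 42% were quantifiable in
at least two replicate pairs (the regime of the real screen); 17 were called
increased at fold change > 1.5 and p < 0.05. At the default spike (fold
change 2, a weak-effect regime) the call list mixes true spikes with
borderline false positives — exactly the behaviour the volcano thresholds
imply. `analysis/03_motif_enrichment.py`, `04_network.py` and
`05_signal_phenotype.py` continue with the motif, network and phenotype
stages; `cosed-diff all --outdir runs/demo` runs everything end to end from
one command.

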