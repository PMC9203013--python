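# Methods

## The experimental design being modelled

The screen compares, within each biological replicate, two aliquots of the
same soluble ovary extract: a control arm and an arm treated with the 14-3-3
inhibitor peptide R18. Microtubules polymerised in both arms are pelleted
and their associated proteins quantified by label-free LC-MS/MS. Because the
two arms of a replicate share the same extract, the natural statistic is the
per-pair log2 ratio, and the default test is a paired one: a two-tailed
one-sample t-test on the per-pair differences of log2 intensities. An
unpaired two-sample mode is exposed as a flag because the two conventions
(paired per-replicate ratios vs pooled arms) are both defensible for this
design; the paired mode is the default since the deposited result table is
organised around per-pair ratios. No cross-replicate intensity normalisation
is applied — the LFQ intensities are taken as already normalised.

## Filtering and collapsing

Reverse-decoy, contaminant and only-identified-by-site protein groups are
removed first. Accessions with a single assigned peptide are dropped (one
peptide cannot identify a protein confidently), then accessions are
collapsed to one per gene keeping the highest search score, with
deterministic tie-breaking on the accession so input order never matters.
Records without a gene symbol are keyed by their lead accession.

An intensity of 0 always means "not detected". A replicate pair in which
exactly one arm is 0 is unusable for that gene's ratio and is dropped from
its test rather than imputed; a gene whose every observed pair has a zero
arm goes to a separate zero-set list (it may be an on/off responder, but no
ratio statistic is defined for it — the pipeline lists these genes and
leaves their interpretation to the analyst). Genes with at least two usable
pairs are tested; a zero-variance difference vector is reported as
degenerate with no p-value rather than p = 0.

## Thresholds

Volcano classes use strict inequalities on the natural scale: increased
means fold change > 1.5 and p < 0.05; decreased means fold change < 1/1.5
(0.6667) and p < 0.05. Raw p-values are used for classification, matching
the screen's design; Benjamini–Hochberg q-values are emitted as an extra
column for users who want FDR control. Predictor thresholds (consensus
> 0.9, ANN > 0.55, PSSM > 0.80, SVM > 0.25, all strict) and the
interaction-score cutoff (combined score > 0.400, physical subnetwork) are
likewise strict "above" comparisons.

## Motif statistics

The site window is fixed at 13 residues (−6..+6 around the phospho-S/T);
overhangs at sequence ends are padded and excluded from per-position
denominators. The directional-enrichment test classifies every quantified
gene by the *sign* of its log ratio (not the p < 0.05 classes — the split is
a population-level question, and signs use all 1,500-odd quantifiable
proteins) and runs a two-sided exact binomial test against 0.5 within the
with-sites and without-sites partitions separately. Every passing site of a
protein contributes a window to the composition counts (sites, not
proteins, are the unit — a choice, since either convention is defensible).
Composition cells are tested with two-sided Fisher exact tests
(residue-vs-other × top-vs-rest at each position), reported at raw p < 0.01
by default with a BH option. The built-in consensus scanner (S/T with R/K
at −3 or −4 and P at +2) is a deliberately simple stand-in for the external
site predictor, sharing its output shape so all downstream statistics run
unchanged; it is not a reimplementation of the predictor's ANN/PSSM/SVM
models. The Aurora-context annotation marks sites whose −2 residue is S/T
preceded at −4 by R/K, the R/K-x-S/T kinase consensus seen two residues
upstream of the 14-3-3 phospho-serine in Borealin (S161/S163).

## Network enrichment

The external interaction database's own expected-edge model is
version-dependent, so enrichment is assessed with a seeded permutation
null: `n` uniform random sets of the same size are drawn from a background
and their internal edge counts collected. The background defaults to the
quantifiable proteins — the frame the candidate set was drawn from — not
the whole proteome. The empirical p-value uses the add-one convention
`(1 + #{null ≥ observed}) / (n + 1)`, which cannot return 0.

## Signal quantification

Band and image signals use the nested-box estimator
`I_S − N_S·(I_L − I_S)/(N_L − N_S)`: the per-pixel background is estimated
from the ring between the two boxes and subtracted from the inner box. The
estimator is exactly unbiased for any constant per-pixel background and any
box sizes with `N_L > N_S` (property-tested over random geometries), and is
linear in the intensity totals at fixed geometry. Negative results are
returned as-is and flagged, never clipped. Median comparisons report
`100·(median_A − median_B)/median_A` with a two-sided Wilcoxon rank-sum
p-value — exact for small tie-free samples, normal-approximated with tie
correction otherwise (ties disable exact enumeration). Orientation counts
use the two-sided Fisher exact test.

## The synthetic-data generator

The generator emulates the design, not the biology: per protein a shared
log2 baseline `N(23, 2)` (typical LFQ log2 scale), a per-pair effect and
independent per-arm noise each `N(0, 0.5)`, and a multiplicative spike
(default fold change 2, 60 up / 25 down of 2,000 proteins — a few percent
of the proteome truly regulated, as in the screen). Intensities are
materialised as `2^x`, so zeros arise only from the dropout mechanism.

Dropout is abundance-dependent by default: the per-cell missing probability
is logistic in the baseline log2 abundance with scale `0.75·sd` and a
location solved numerically so the expected zero fraction equals
`missing_rate` (default 0.55). This is the standard picture of label-free
missingness — low-abundance proteins drop out preferentially — and it
matters: with purely random (MCAR) dropout at the rate that reproduces the
screen's ~42% quantifiable fraction, about two thirds of quantifiable genes
would have exactly two usable pairs, where a paired t-test has one degree
of freedom (critical |t| = 12.7) and essentially no power, so no realistic
spike would be detectable at any majority rate. Abundance-driven dropout
reproduces the same 42% summary with a realistic pair-count spectrum. MCAR
remains available as an explicit mode and is what the binomial
zero-fraction checks use. The default `missing_rate = 0.55` was calibrated
once against the quantifiable-fraction summary (40–42% across seeds) and
then frozen.

Sequences are uniform-random over the 20 amino acids with a planted 7-mer
motif `KRSKSVP` (basic residue at −3, Aurora-consensus serine at −2, lysine
at −1, proline at +2 around the central phospho-serine) inserted at rate
0.6 in spiked-up proteins and 0.15 elsewhere — roughly the 600-of-1,504
with-site fraction of the screen. Phenotype data are log-normal per-oocyte
intensities with a configurable median reduction, and binomial
bi-/mono-orientation counts.

What the generator does **not** model: peptide-level quantification and
razor-peptide assignment, correlated protein complexes, realistic amino-acid
composition or disorder, batch effects between replicates beyond a shared
pair shift, and biologically structured interaction networks (the synthetic
edge table plants excess edges among spiked-up proteins uniformly). Tests
passing on synthetic data therefore validate the statistical machinery and
its operating characteristics — type-I error, power monotonicity,
determinism, exactness of the small-sample tests — not the biological
conclusions of any particular dataset.

## Problem sizes and numerical choices

Simulation-based checks use 2,000–6,000 proteins × 6 pairs, sizes at which
the measured operating characteristics (type-I error within 3 standard
errors of 0.05 over ≥ 2,000 tested null genes; majority recovery of
quantifiable spiked proteins at fold change 4) are stable across seeds
while a full test run stays in tens of seconds. Spike-in recovery is
evaluated among spiked proteins that are quantifiable (detected in both
arms in ≥ 2 pairs): dropout is independent of the spike, and a protein
never observed twice is invisible to any downstream method. Quantile bins
distribute any remainder to the top bins and break ties on gene name, so
bin sizes differ by at most one and assignments are reproducible.
Degenerate inputs (zero variance, empty partitions, zero denominators,
all-zero count tables) yield explicit flags, NaN p-values or errors — never
silent zeros.

## Reproduction against the deposited tables

`cosed.reproduce` re-runs the same code paths on the study's deposited
supplementary spreadsheets (raw per-replicate protein-groups sheets, the
quantified log-intensity sheet keyed by gene with replicate labels 1, 2, 5,
6, 7, 8 exposed verbatim, the residue-composition workbook, the per-oocyte
GFP table and the orientation counts). The spreadsheets are not
redistributed; the corresponding acceptance tests pass only with local
copies under `data/supplementary/`. The reproduction path is itself
exercised end to end on synthetic spreadsheets written in the same dialects
(`tests/test_reproduce.py`), with every expected value hand-computable.

## Known limitations

The zero-set list is reported but not statistically summarised (no
principled ratio exists for on/off proteins without an imputation model,
which is deliberately avoided). The consensus scanner's background hit rate
on random sequences is substantial (~1 hit per 1,000 residues), so
with-site partitions in synthetic runs are noisier than predictor-based
ones. Replicate QC flags pairs by median shift and slope only; it does not
attempt batch correction. The unpaired t-test mode ignores the pairing and
is provided for comparability, not recommended.
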