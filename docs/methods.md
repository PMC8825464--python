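# Methods

`dielsc` re-implements, as a tested and reusable pipeline, the bespoke
computational steps of a diel (end-of-day / end-of-night) single-cell
transcriptome analysis of Arabidopsis root and shoot tissue: UMI
quantification and cell filtering, clustering with a subsampling-based
robustness score, one-vs-rest marker statistics with cross-clustering
overlap, and rule-based detection of di-cistronic (including mRNA–tRNA
read-through) transcripts. This note records the models, conventions and
design choices; empirical behaviour is established by the test suite and
`scripts/acceptance.py`, not restated here.

## Coordinates and read assignment

Gene models and aligned blocks are held 0-based, half-open internally;
GFF3 I/O converts from the format's 1-based closed convention at the
boundary. A read is assigned to a gene when **any** aligned block overlaps
the gene interval by ≥1 bp, strand-matched by default (strand-specific
counting is required for antisense analyses and is the package default). A
molecule is a distinct (cell barcode, UMI) pair; a gene's count in a cell
is the number of its molecules. Reads whose blocks overlap two or more
genes are *excluded* from expression counts and treated as read-through
evidence instead — counting them toward both genes would double-count the
very molecules the di-cistronic caller is meant to find.

## Cell filtering

Cells are retained when total transcripts ≥ 500, detected genes ≥ 200 and
plastid-transcript fraction ≤ 0.2 (all configurable). The first two
defaults are the root-library cutoffs; the plastid cutoff has no published
value, so 0.2 was fixed once as this package's default — protoplasts
dominated by plastidial RNA are broken or stressed cells. Filtering is
idempotent, and raising the cutoffs is monotone (the retained set shrinks
and per-cell means rise).

## Clustering and the robustness score

Clustering wraps the standard droplet workflow — counts-per-10,000
normalization, ln(1+x), highly-variable-gene selection, PCA, kNN graph,
Leiden — deterministically seeded; any backend honouring the same contract
can be swapped in, and a post-PCA `batch_correct` hook (identity by
default) is where a harvest-time batch correction would act.

Robustness of each original cluster is scored from `n_replicates = 100`
random subsamples at `fraction = 0.8` of the counts. Subsampling is
binomial thinning of the UMI matrix — each count c becomes Binomial(c,
0.8) — the matrix-level surrogate for resampling 80% of library reads:
every molecule keeps inclusion probability 0.8. Each replicate is
reclustered **with the original variable genes** and the original
settings (PCs are recomputed on the thinned counts; re-selecting genes per
replicate would measure gene-selection noise, not cluster stability). The
co-occurrence of original cluster C in a replicate is
max over replicate clusters C′ of |C ∩ C′| / |C| — best-match containment,
the most literal reading of "what proportion of cells still co-occur in a
single cluster"; a per-cell pairwise variant was considered and rejected
as quadratic with no added interpretability. Scores are 100 × the mean
over replicates, binned closed-on-the-left into stars:
[75, 100] → ***, [50, 75) → **, [25, 50) → *, else none. Closed-left
boundaries are a convention choice; the published bin labels overlap and
do not specify boundary membership.

## Marker statistics

Markers are one-vs-rest: per cluster and gene, a two-sided Wilcoxon
rank-sum of in-cluster versus all remaining cells on log-normalized
expression. The p-value is exact (full permutation null) when both groups
have ≤ 8 cells and the column is tie-free, otherwise a tie-corrected
normal approximation without continuity correction. Fold change is
ln(mean_in + ε) − ln(mean_out + ε) with ε = 1e−9, on the **linear**
depth-normalized scale (the convention of the standard marker function;
means of log-transformed values double-compress the effect and would make
the 0.25 threshold mean something different). A gene is a marker when
Bonferroni-adjusted p < 0.05 (multiplier = the matrix's gene count, again
the standard function's convention; Benjamini–Hochberg available by flag),
log-FC ≥ 0.25 and ≥ 5% of in-cluster cells express it. Note that
Bonferroni controls familywise error at 5% *per marker scan*: across many
scans, isolated borderline false markers at p_adj just under 0.05 are the
expected behaviour of the procedure, not a defect.

Cross-clustering overlap is the Jaccard index J = |A∩B| / |A∪B| of marker
sets for every cluster pair (J ≡ 0 and flagged when both sets are empty),
computed on the fully filtered marker sets. Time-point composition
reports per-cluster ED/EN fractions; a cluster is "mixed" when the
minority time point holds ≥ 0.25 of its cells (a display convention made
explicit and configurable). Time-split marker analysis reruns detection on
ED cells and EN cells separately and reports markers exclusive to one time
point together with whether each such gene is globally ED/EN
differentially expressed — typically it is not, which is the point of the
split. Category enrichment is the upper-tail hypergeometric p with
significance at unadjusted p < 0.05, as in the original procedure (BH
optional).

## Di-cistronic calling and TLS classification

A read supports a coordinate-ordered gene pair when its blocks overlap
both genes — strand-agnostic at the read level, since the rule concerns
alignment coordinates only; strand enters through the pair filter. A pair
is called di-cistronic when supported by ≥ 100 reads **and** either both
genes are protein-coding on the same strand or at least one gene is
non-coding (tRNA counts as non-coding here). When support and the
strand/biotype rule both fail, `low_support` is reported (support is the
first filter applied). A read overlapping ≥ 3 genes contributes to every
pair it covers and is logged. Raising the support threshold can only
remove calls.

For a host gene with a tRNA locus downstream on the same strand, host-gene
molecules are classified `tls` when ≥ 1 read block overlaps the tRNA
interval and `mono` otherwise; the "reads end one base before the tRNA
start" phrasing of the source rule is treated as describing that boundary,
not as an extra requirement — demanding exact termination would
misclassify every short molecule. Mono molecules that read *past* the tRNA
without touching it are kept as mono but flagged. Molecules with no
host-overlapping read are excluded; because a molecule only counts as
`tls` when a junction-covering read was actually observed, the estimated
read-through ratio systematically underestimates the true one — a known
bias of the rule, reproduced by the package and strongest for short,
thinly covering reads.

Per-cluster enrichment builds two per-cell pseudo-genes (tls and mono
molecule counts, depth-normalized like any gene) and calls a cluster
enriched when tls passes a two-tailed rank-sum marker test at unadjusted
p < 0.05 (higher inside the cluster) and mono does not.

## The synthetic-data generator

The generator is first-class, tested code: it emulates the features the
pipeline must recover, records everything it plants in `SimTruth`, and is
byte-deterministic per seed.

* **Annotation**: flat gene models on one chromosome — adjacent pairs
  5–60 bp apart (read-through candidates), singletons isolated by 500 bp,
  and optionally a protein-coding host with a tRNA (72 bp, the tRNA-Gly
  scale) starting 20 bp downstream on the same strand.
* **Reads**: single-block fragments of 60 bp with a 12 nt barcode / 8 nt
  UMI (droplet conventions), 2–5 reads per molecule. Multiple coverage per
  UMI is the realistic droplet regime and keeps junction loss — read-through
  molecules with no host-overlapping read — a small perturbation rather
  than the dominant effect; the short-read bias regime is exercised
  explicitly in tests at 30 bp single/double coverage. Planted
  di-cistronic pairs contribute *exactly* their planted support in
  junction-spanning reads. Host molecules read through into the tRNA with
  the planted per-cluster probability; each read-through molecule carries
  one read guaranteed to overlap the tRNA (its remaining reads fall
  anywhere on the host-to-tRNA span), mono molecules never extend past the
  base before the tRNA start. Barcodes and UMIs are collision-free (the
  source pipeline's collision handling is unstated).
* **Counts**: negative-binomial with var = μ + αμ², α = 0.3, per-gene
  means log-normal (σ = 1) scaled to an expected per-cell depth of 2,000
  (the root libraries average ≈ 2,000 transcripts/cell); per-cell depth
  factors log-normal (σ = 0.25). Planted markers are raised e-fold
  (marker_logfc = 1) in their cluster, with their baseline mean floored at
  the average gene mean — a marker is by construction a detectably
  expressed gene. Plastid genes are boosted 50-fold in designated
  high-plastid cells; designated batch genes are shifted on the log scale
  in EN cells; low-depth cells are exactly downsampled (multivariate
  hypergeometric) to a total of 100–400, safely under the 500 cutoff.

What the generator does **not** emulate: base-level sequence content and
errors, polyA/priming artefacts, barcode collisions and correction,
doublets, ambient RNA, and the mean–variance and gene–gene correlation
structure of real tissue. Passing tests therefore demonstrate that the
*procedures* are implemented correctly and recover what was planted — not
that the biological conclusions of any particular dataset would be
reproduced.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so every stage
is exercised with adequate statistical power: 80–300 cells, 50–500 genes,
10-seed replication for the stochastic recovery checks, 100 replicates ×
0.8 for the robustness calibration, and ≈ 3,000 classified host molecules
per TLS run (3σ binomial error ≈ 1 percentage point on the global
read-through ratio).

## Known limitations

* The Leiden backend is deterministic per seed but not guaranteed stable
  across library versions; the robustness scorer takes any reclustering
  callable for full reproducibility.
* The tie-corrected normal approximation for the rank-sum test is
  accurate to a few tens of percent in the far tail for heavily tied
  columns; near a Bonferroni boundary this can move individual borderline
  markers in either direction.
* The di-cistronic caller pools support across all reads it is given;
  per-sample thresholds are available by splitting the read stream.
* Molecule classification assumes one host/tRNA pair per call; multi-tRNA
  3′ arrangements are out of scope.
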