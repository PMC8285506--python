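# Methods

## Scope and model

`binsig` re-implements, as a reusable and tested pipeline, the analytics
used to characterize graft-infiltrating "Bin" (B-innate-like) cells:
single-cell QC and isotype calling, differential-expression clustering,
cross-species covariant-gene signatures scored against a murine B-cell
atlas, B-cell-receptor clonality, HLA-bead serology and IP-MS antigen
ranking. Each stage is a pure function over standard containers (AnnData,
pandas frames); the `workbench` module chains them into one seeded,
manifest-checked run.

## Single-cell core

Raw counts are normalized to `log2(1 + CPM)`. "Log-count per million" is
interpreted in base 2, consistent with the log2 scaling used for plotting
and fold changes; no other base is stated anywhere in the protocol this
emulates. Spike-ins (reserved `ERCC-` prefix) are excluded from the
library size and the expressed-gene tally by default, because spike-in
content varies per well and the filters concern endogenous genes.

Cell QC has two filters, evaluated jointly (and hence order-independently):

* expressed-gene window: `min_genes <= n_expressed <= max_genes`, with a
  gene "expressed" iff its raw count is positive. The published window for
  deep libraries is 3,000–15,000 with 1,000 as the lower bound for a
  shallower cohort; both bounds are config values, never constants in code.
  "Less than 3,000" is read exclusively: 2,999 fails, 3,000 passes.
* B-cell identity: the summed log2-CPM of the nine IgH constant-region
  genes must reach `ig_logcpm_min` (default 5, in log2 units).

Isotype is the argmax over constant-region genes; IgM/IgD = unswitched,
everything else switched; all-zero cells are `undetermined`. Ties are
broken by a fixed precedence list (the biological 5'→3' locus order) and
flagged — the source protocol is silent on ties, and determinism is
required for testing. The plasma-cell call is by marker expression
(PRDM1): the cluster with the highest mean must exceed the runner-up by a
configurable ratio (default 2x). A ratio rule makes the qualitative
"identified by PRDM1 expression" criterion testable; with the default the
call is insensitive to the exact value over a wide range because the
planted contrast is ~100x.

## Differential expression and clustering

Per-gene Welch (unequal-variance) two-sided t-tests on log-scale values;
the protocol says only "independent two-sided t-tests", and Welch is the
robust default. Genes expressed in fewer than 10% of either group are
excluded *before* testing, so they do not enter the BH denominator.
A gene is differential iff BH-FDR <= 0.05 and |log2FC| >= 1, both
inclusive, with log2FC the difference of group means on the log2 scale
(consistent with testing log-scale values).

DEG structure over the four tissue x switch populations: population means
per gene, row-wise Z-scores (constant rows become all-zero and are
flagged), complete-linkage Euclidean hierarchical clustering cut at k = 6.
Metric and linkage are not stated in the source protocol; complete/
Euclidean is the common heatmap default, and the package treats k as a
parameter rather than asserting that six clusters are recoverable under
other choices. Cluster indices are relabeled deterministically (size
descending, ties by smallest member gene) because dendrogram-derived
indices are arbitrary.

Gene-set scores are Z-sums: each member gene scaled to zero mean / unit
variance across samples, then summed per sample. No background-gene
subtraction is applied — this mirrors the original score definition, and
means scores are comparable within one matrix only. The DN
(double-negative B cell) score is the difference of an up-set and a
down-set Z-sum. Atlas cluster scores are computed per replicate, averaged
within subsets, then row-scaled across subsets.

## Covariant signature

The signature of a seed gene is every atlas gene whose subset-mean
profile has Pearson r >= 0.8 with the seed's profile. Correlation is on
subset means (the profile the source analysis plots), with a
replicate-level option behind a flag; Pearson is used where the protocol
says only "correlation coefficient". Constant profiles are excluded and
reported (undefined correlation). The enrichment universe is every
atlas-detected gene (nonzero in >= 1 replicate); signatures and clusters
are intersected with the universe before the one-sided hypergeometric
over-representation test, p = P[X >= k]. A robustness variant recomputes
enrichment with the seed gene removed.

## Repertoire

A clonal family is the exact key (patient, V gene, D gene, J gene, CDR3
length). Gene-level calls are obtained by stripping the `*` allele
suffix; a missing D call becomes `"none"` and matches only other D-less
records (merging with any D would over-cluster). CDR3 length defaults to
amino acids (configurable to nucleotides); clonality is scoped within
patient. Mutation recounting on pre-aligned sequence/germline pairs counts
positions where both characters are unambiguous bases and differ; gaps and
N are ignored. Indel handling beyond gap-skipping, and germline inference
itself, are out of scope (annotated records are accepted as input).

## Serology

The screening readout is NBG_i = (S_i − S_0)/(N_i − N_0); positivity at
NBG >= 2.2 inclusive; log2 display floors the ratio at 1. A non-positive
denominator (negative serum not above the negative bead) marks the bead
invalid rather than producing signed infinities — it indicates an assay
artifact. Serum-block comparison pairs class-wise maxima between the PBS
and serum-diluted runs; `lost_binding` = positive in PBS and negative when
blocked. SAB hits use sample trimmed MFI strictly above 1,000, while
ranking uses the sample-minus-negative delta; the two quoted readouts are
combined this way because the source states both, and a delta-threshold
alternative is available. Frequencies are reported as exact fractions plus
percentages rounded half-up; the two-group test is chi-squared with Yates
continuity correction by default (this variant reproduces the published
p-values; a flag disables it).

## Proteomics

Flagged rows (contaminant / reverse / site-only) are dropped; a protein
must be detected (> 0) in at least two replicates of at least one
condition — the conjunctive "every condition" reading is available by
flag, since the source wording is ambiguous. Median normalization divides
each sample's nonzero intensities by that sample's median nonzero
intensity; zeros encode non-detection and are preserved. Fold change is
log2((mean test + c)/(mean of per-control-antibody means + c)) with
pseudocount c defaulting to the smallest nonzero normalized intensity,
keeping undetected-in-control proteins finite without dominating the
ranking.

## Synthetic data: what it emulates and what it does not

All generators derive their randomness from one master seed with a fixed
stream key per generator, so any subset of generators is reproducible.

The single-cell generator emulates a two-tissue (kidney/tonsil) design
with ~70% unswitched cells per tissue, negative-binomial counts with
gene-level dispersion plus Bernoulli dropout, ERCC spike-in rows, IgH
constant genes planted so each cell's intended isotype is a strict
maximum, a PRDM1-high plasma cluster, and a configurable fraction of
cells violating QC (too few expressed genes, or no Ig expression).
Baseline NB means are lognormal around 20 counts with 10% dropout,
emulating deep plate-based full-length libraries where a typical detected
gene has tens of counts; with shallower settings a planted multiplicative
fold change of 2^2 is not faithfully realized on the log2-CPM scale (the
mean-of-log attenuates it below the |log2FC| >= 1 gate), which would break
the invariant that planted truth is recoverable. Differential genes are
planted by multiplying NB means by 2^lfc (half up, half down) between
tissues. Not emulated: batch effects and their correction, sequencing-depth
differences between cohorts, gene–gene correlation beyond the planted
structures, cell-cycle or ambient contamination. Passing recovery suites
therefore demonstrates correctness of the statistical machinery under the
stated model, not robustness to those real-data complications.

The atlas generator plants a covariant block sharing a peritoneal-B1-high
profile with additive subset-level noise; replicate deviations are
centered within subsets so subset means equal the planted profiles exactly
and the zero-noise case correlates at exactly 1. The recorded covariant
truth is re-derived from the generated values, so with nonzero noise it is
the set of block (and chance) genes actually at r >= 0.8. Ortholog
mapping covers a configurable fraction of genes, includes one-to-many
pairs, leaves two block genes unmapped, and addresses the same human gene
namespace as the single-cell generator so cross-module compositions share
a universe.

Bead panels are built by inverting the NBG definition (a planted positive
gets S = S_0 + NBG·(N − N_0) exactly); serum blocking multiplies the
sample-specific excess of positive beads by `blocking_effect`, so serum
NBG = blocking_effect x PBS NBG. The IP-MS generator plants per-antibody
enriched proteins at a configurable fold (default 8), plus flagged rows
and proteins detected in a single replicate everywhere.

## Problem sizes and numerics

Default suite sizes: DE null/power at 100 cells per group x 2,000 genes
over 20 generator seeds; signature recovery over 10 seeds; repertoire,
bead and IP-MS recovery over 10 seeds each; hypergeometric closed form
vs exact-binomial enumeration over all ~44,000 instances with N <= 25.
Equality-style oracle checks use 1e-12 absolute tolerance; Z-row zero-sum
uses 1e-9. Degenerate inputs are errors, not silent results: empty
matrices, all-zero cells/samples, missing markers or seeds, overlapping
DE groups, panels without a negative-control bead, duplicate SAB alleles.

## Known limitations

* The six-cluster DEG structure is parameter k, not an inference; other
  metrics/linkages may not reproduce a given k on real data.
* Scores are not cell-count calibrated (no control-gene-set subtraction).
* The repertoire module does not align sequences; mutation counts are
  recounted only on pre-aligned pairs.
* The serology module accepts instrument-exported trimmed MFI; no MFI
  trimming or vendor-format parsing is performed.
* Real-data batch correction (spike-in factor analysis, variance
  stabilization, location/scale integration) is accepted as input via the
  `corrected` layer tag but not implemented.
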