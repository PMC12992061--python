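# Methods

This note defines each statistic the package computes, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Data model and quality control

Counts are sparse non-negative integer UMI matrices (genes × cells) read
from MatrixMarket triplet directories (matrix.mtx + features.tsv +
barcodes.tsv, plain or gzipped). A cell table aligned on barcode carries
the sample group (age × sex), the subpopulation label, per-cell QC
metrics, and optional external flags.

QC retains a cell iff it detects ≥ 200 unique genes, has ≥ 5,000 UMIs and
a mitochondrial read fraction ≤ 0.05 (a fraction of exactly 0.05 is
retained; only values *exceeding* the threshold are removed). Mitochondrial
genes are recognized by the configurable id prefix `mt-` (mouse
convention). External quality models — doublet callers, bivariate
mixture-model posteriors — are deliberately not reimplemented; their
verdicts enter as boolean flag columns that QC can be told to honor
(`drop_flagged`). The QC report counts removals per criterion
non-exclusively, so the columns need not sum to the number removed.

Normalization is `ln(1 + 10⁴ · c / total)` per entry; zeros map to zeros
and the statistic is invariant to per-cell sequencing depth. Variable
genes are the top 2,000 by binned standardized dispersion
(variance/mean of normalized expression, z-scored within 20 mean-quantile
bins; ties broken by gene id). PCA uses centered, unit-scaled expression
of the selected genes; 20 components by default. Each component is
sign-fixed so its largest-magnitude gene loading is positive, making
coordinates bit-reproducible. The embedding here feeds only the
heterogeneity statistic and the graph pseudotime; clustering and 2-D
visualization embeddings are out of scope, and subpopulation labels are an
input (from annotation or from simulation truth).

## Differential abundance (composition)

For two groups a, b with subpopulation proportions p̂ₐ, p̂ᵦ the effect
size is the log2 fold difference `log2(p̂ₐ / p̂ᵦ)`. When either
proportion is zero, a pseudo-proportion of 1/nₐ and 1/nᵦ is added to both
sides; applying the guard only in the zero case keeps the reported
estimate equal to the plug-in value whenever it is finite (so 90/100 vs
10/100 reports exactly log2(9) ≈ 3.17) while still protecting empty
cells. The null distribution permutes group labels over the pooled cells;
since a uniformly random relabeling makes each subpopulation's group-a
count multivariate hypergeometric, the null is drawn directly from that
law — one vectorized draw per permutation, distribution-identical to
explicit shuffles (tests verify agreement with exhaustive enumeration on
tiny inputs). Two-sided p-values use |log2FD| with the add-one rule,
`p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, so p ≥ 1/(n_perm+1).
Confidence intervals come from a separate within-group multinomial
bootstrap (same number of resamples); p and CI are thus two labeled
resampling schemes, not one. BH-FDR is applied across subpopulations
within one contrast, matching per-sex reporting. The permutation and
bootstrap streams are consumed in group-label-sorted order, so swapping
the groups negates every estimate and leaves every p-value unchanged
under the same seed.

## Sample-level statistics

**Intercellular heterogeneity** of a group is the mean Euclidean distance
from each of its cells to the group centroid in PC space (20 components).
It is translation- and rotation-invariant and scales linearly under
uniform coordinate scaling. Group comparisons use the two-sided rank-sum
test on the per-cell distances (exact for small groups, below), with a
bootstrap difference-of-means interval as a secondary descriptor.

**Transcriptional divergence** depth-matches per-group pseudobulk totals
by sampling reads without replacement — a multivariate hypergeometric
draw — to a shared depth (the minimum group total, capped at 10⁶), then
ranks genes by total descending (ties by gene id), splits the list in
half and reports mean(top half)/mean(lower half). With an odd gene count
the extra gene joins the lower half (the conservative choice — it can
only shrink the ratio). Zero-count genes are retained in the lower half
by default; `drop_zeros` flips this, since the source procedure does not
pin the gene universe down. An all-zero lower half returns +inf with a
warning. Because one draw is stochastic, the reported value averages 25
downsampling draws by default; `n_draws=1` reproduces the literal
single-draw procedure.

## Differential expression

The tested universe is genes expressed (normalized value > 0) in ≥ 5% of
cells in *either* group — the standard min-pct convention; a `both` mode
is provided because the source phrasing is ambiguous — minus exclusions:
`mt-` genes, ribosomal genes (prefixes `Rps`, `Rpl`, configurable) and
the rRNA-contamination genes *Gm42418*, *Malat1*, *Gm26917*, *AY036118*.

The test is the two-sided Wilcoxon rank-sum on log-normalized values.
When both groups have ≤ 25 cells the p-value is exact: a dynamic program
over doubled midranks enumerates the full permutation distribution of the
rank sum, ties included (counts stay integral in float64 up to pooled
n = 50, so the division happens once and an all-inclusive tail is exactly
1). Larger groups use the tie-corrected normal approximation with
continuity correction, vectorized across genes; all-tied genes report
p = 1. The fold change is `log2((mean(expm1 aᵢ)+1)/(mean(expm1 bᵢ)+1))` —
de-logged means with a pseudocount of 1, which keeps estimates finite;
the estimator is stated here because the source does not define one.
Significance = BH-adjusted p < 0.05 and |avg log2FC| > 0.25.

**Concordance** between two contrasts (e.g. old-vs-young in males and in
females) correlates the per-gene change in expressing-cell fraction
(Δpct = pctₐ − pctᵦ) across the shared universe (Pearson r with its p),
also reporting r over genes significant in at least one contrast —
both are emitted because either convention is defensible — and classifies
each gene as significant in both (concordant or opposite log2FC sign),
in one contrast, or in neither.

## Pathway enrichment

Genes are ranked by the signed weight `W = −log10(p) · log2(FC)` with p
floored at 1e-300 (weights stay finite; W = 0 whenever p = 1 or FC = 1).
The enrichment score is the weighted Kolmogorov–Smirnov running sum
(exponent 1): members add |W|/Σ|W_members|, non-members subtract
1/(N − k); the score is the running sum's largest-magnitude deviation,
signed, and the implementation evaluates only the 2k candidate extrema at
member positions (verified against a full walk in tests). The null draws
random same-size gene sets from the ranked universe — gene-label
permutation, chosen because the ranking is already a group-level summary
so there are no sample labels left to permute. p is add-one two-sided on
|ES|; NES = ES / mean|null ES|; BH-FDR across tested sets; the leading
edge is the members at or before (after, for negative scores) the
extremum. Sets with fewer than 10 members present in the ranked list are
skipped.

Per-cell pathway activity is a documented stand-in for kernel-CDF
methods: for each set gene, cells are midranked across the population;
a cell's score is the mean rank fraction `(rank − ½)/n` over set genes,
minus ½. It reproduces comparative uses (distribution shifts between
groups), not any other method's numerical values; a constant gene
contributes exactly zero.

## Trajectory analysis

Pseudotime is the multi-source shortest-path distance from the root
subpopulation's cells (default `Ly6C+`, the infiltrating population) over
a symmetric k-nearest-neighbor graph (k = 15) with Euclidean edge weights
in PC space, min-max rescaled to [0, 1]; disconnected cells are flagged
orphans (warning above 5%). This is an explicitly labeled stand-in for
principal-graph pseudotime learners — the analyses of interest here are
the density and trend comparisons, not the graph learner — and externally
computed pseudotime/branch TSVs (barcode, pseudotime, branch_id) can be
ingested instead. Branches are the union of predecessor-path vertices
from the root region to each terminal subpopulation's cells; membership
is a relation, not a partition, because root-proximal cells legitimately
precede every terminus.

Per (branch, group) cell densities are Gaussian KDEs (Silverman
bandwidth) of the group's pseudotime values, evaluated on a uniform grid
spanning the branch's pooled range and renormalized to integrate to 1 by
the trapezoid rule — per-group normalization makes curve *shapes*
comparable between groups of different sizes, which is the comparison the
depletion analysis needs. Groups with < 5 cells on a branch are omitted.
A zero-variance group falls back to a narrow Gaussian spike at the common
value rather than failing.

Expression trends are unpenalized least-squares fits of a natural cubic
spline basis (df = 5; boundary knots at the branch range, interior knots
at pseudotime quantiles). The basis nests linear functions, so a linear
signal is reproduced exactly; df is reduced with a warning when there are
too few distinct pseudotime values. Fixed-df regression splines were
chosen over penalized smoothers because no smoothing parameters are
specified by the procedure being modeled and fixed df keeps fits linear
in the response (doubling expression exactly doubles the fit).

## Synthetic data generator

The generator emulates the study design so downstream statistics can be
validated by recovery of planted truth: four pooled groups (young/old ×
M/F, one pooled sample per group — replicate structure within groups is
deliberately not modeled because pooled designs provide none), ~4,000
cells per group by default, and five subpopulations whose default
per-group proportions are the study's reported percentages renormalized
to sum to one.

Counts are negative binomial via a gamma–Poisson mixture with shared
per-gene dispersion 0.3 — the standard overdispersion model for UMI
counts. Library sizes are lognormal (median ≈ 9,000 UMIs, log-sd 0.25),
truncated above 1.3× the QC UMI floor so cells pass QC unless failures
are explicitly planted (`qc_fail_fraction` gives the planted cells ~1,200
UMI libraries). Baseline relative expression is lognormal (log-sd 1.2)
across genes; marker genes (10 per subpopulation by default, +2 log2
units in their subpopulation) occupy the leading gene indices, and a
trailing `mt-` block receives each cell's mitochondrial fraction, drawn
Beta(2, 98) (mean 0.02, ~7% of cells above the 0.05 QC threshold).
Planted expression effects multiply a gene's relative expression by
2^log2fc in one (group, subpopulation) stratum. `choose_de_genes` selects
effect genes from the upper half of the baseline distribution: a fold
change planted in a gene with near-zero baseline is invisible at any
realistic depth, so recovery experiments plant effects where recovery is
in principle possible — this is experiment design, not tuning.

Latent pseudotime: each cell's subpopulation is drawn multinomially from
the group's proportions (so composition targets hold exactly); the cell
is then placed on a branch containing that subpopulation (branch choice
weighted per group) with t drawn from the branch's per-group
piecewise-constant density, restricted to the subpopulation's equal-width
interval along the branch sequence. Lowering the density bins around a
branch midpoint for one group plants a localized depletion — the
mechanism behind the trajectory acceptance experiment. Pseudotime-
responsive genes multiply expression by `2^(A·σ(s(t − t₀)))`, monotone in
t. An optional ADT layer simulates NB tag counts tracking a designated
marker gene; it is carried through I/O but not analyzed.

All randomness flows from a single seed through `SeedSequence` stream
splitting, so identical configs are byte-identical and individual stages
can be re-derived independently (`base_expression` re-creates the gene
baseline without simulating counts). The null generator
(`simulate_null`) removes every group contrast — expression effects,
proportion differences, branch weights, t-densities — making groups
exchangeable by construction; it is the calibration harness for the
permutation tests.

What the generator does **not** emulate: ambient RNA, batch effects,
doublet expression profiles (only an optional flag column), gene–gene
correlation beyond subpopulation/pseudotime structure, and any fit to the
real deposited data — parameters are synthetic by design. Passing tests
therefore demonstrate statistical correctness (calibration, power on
planted effects, invariances), not biological fidelity of any particular
dataset.

## Problem sizes and numerical conventions

Calibration experiments use 200 null replicates at 2,000 cells/group with
2,000 permutations; power uses 100 replicates of a 4× proportion shift;
DE recovery uses 20 replicates of 50 planted 2-fold genes among 2,000 at
300 vs 300 cells; enrichment calibration uses 200 random 20-gene sets on
a 500-gene list. These sizes give stable estimates (binomial SE ≈ 0.7%
on the type-I rate) while keeping the full suite fast on a single CPU.
Ties are always broken by gene id; permutation p-values use the add-one
rule; BH-FDR uses statsmodels; TSVs are written with a fixed float format
and the pipeline manifest carries no timestamps, so identical runs are
byte-identical.

## Known limitations

- The kNN shortest-path pseudotime measures transcriptional-similarity
  distance, not developmental time; with external pseudotime ingest the
  density machinery applies unchanged.
- The exact Wilcoxon path is O(nₓ · n · Σranks) per gene and is only
  engaged when both groups have ≤ 25 cells.
- The divergence statistic depends on the downsampling draw; the
  seed-averaged default quantifies (and mostly removes) that noise, but
  single-draw mode inherits it.
- Composition p-values treat cells as exchangeable under the null, which
  is the pooled-sample assumption; with biological replicates a
  replicate-aware method would be preferable, and none is provided here.
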