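# Methods

This note documents the models, numerical choices and limitations of the
pipeline, and what the synthetic validation does and does not establish.

## Count model and differential expression

Counts are modelled as negative binomial, `Var(y) = mu + phi * mu^2`, with
a log link and per-sample offsets `log(library size x TMM factor)`.  For a
two-group comparison the full model is `~ group` (plus a patient factor
for the paired PP-vs-PN comparison); the test statistic is
`2 * (l_full - l_reduced)` referred to chi-squared with 1 df, since a
single group coefficient is tested in every comparison.  Fitting uses
Fisher-scoring IRLS vectorised across genes (all genes share one design),
with step-halving on likelihood decreases; genes whose fit does not
converge receive no p-value and are excluded from the BH denominator so an
undefined p cannot inflate `m`.

*Fold change.* The reported logFC is the group coefficient converted to
log2 units, not a ratio of group-mean FPKM; group means are emitted
separately (`mean_expr_g1/g2`).

*Detection.* Both clauses of the detection rule are strict inequalities:
cpm exactly 0.25, or a zero count (whose exact-Poisson lower bound is
exactly 0), never counts as detectable.  The FPKM confidence interval is
the Garwood interval on the raw count — `chi2(alpha/2, 2k)/2` to
`chi2(1-alpha/2, 2k+2)/2` — scaled by `1e9 / (length x library)`.  This is
a deliberate, fully specified replacement for an assembler-derived
interval: it preserves the operative behaviour of the detection clause
(zero counts fail, any positive count passes) without modelling
quantification uncertainty beyond counting noise.

*TMM.* The reference sample is the one whose 75th percentile of
count fractions is closest to the mean; genes zero in either column are
dropped; the M-values are trimmed at 30% (per tail, by M) and 5% (by A)
following the original TMM recipe, weighted by delta-method inverse
variances, and factors are rescaled to geometric mean 1.  Scale
invariance under a uniform depth change of one sample is exact for the
M-values but only approximate (a few percent) when the rescaled sample is
the reference, because the weights are depth-dependent.

*Dispersion.* Per-gene phi maximises the Cox–Reid adjusted profile
likelihood (the likelihood at the profiled mean parameters minus half the
log-determinant of their Fisher information), evaluated on a 25-point
log-spaced grid from 1e-6 to 4 and refined by parabolic interpolation in
log-phi.  Shrinkage adds `prior_df / residual_df` times the all-gene mean
APL curve to each gene's curve before the argmax (weighted-likelihood
empirical Bayes); `prior_df` defaults to 10 and `prior_df = inf`
reproduces the common estimate exactly.  The test suite verifies the
Poisson limit (median phi < 0.01 on Poisson data), recovery of phi = 0.2
within [0.1, 0.3], and agreement of the LRT p-values with edgeR at fixed
dispersion to 1e-8.

## Modules and DEMs

The reference matrix is gene-centred, then each sample column is
standardised to mean 0, variance 1; clustering is average-linkage on
Euclidean distances.  The dendrogram cut is a static `maxclust` cut that
deliberately over-segments (default one cluster per ~10 genes), followed
by a deterministic merge pass: the smallest sub-25 cluster is repeatedly
absorbed into the cluster with the nearest centroid.  The over-segment-
then-merge design replaces a dynamic tree-cut: a cut near the expected
module count wastes branches on outlier singletons and lets genuine
modules coalesce below the cut, whereas over-segmentation splits modules
into pure fragments that the merge pass reassembles (planted-partition
recovery is exact in the validation scenarios).

Module summaries: centroid = per-sample mean over members;
representatives = the 25 members nearest the centroid (ties broken by
gene id); medoid = member minimising summed Euclidean distance to the
rest (tie: gene id).  The DEM test compares the representatives' log fold
changes to those of all clustered genes outside the module, two-sided
Wilcoxon rank-sum with exact enumeration when both groups have <= 25
observations and no ties, and the tie-corrected normal approximation
otherwise; BH runs across modules and direction is the sign of the
representatives' median FC at FDR < 0.05.  Restricting to 25
representatives keeps the null rejection rate flat across module sizes
25–200 (verified by simulation), which is the point of the subsample.
Modules are labelled by the member with the most GO annotations plus the
module size; without GO data the medoid id is used.

## GWAS proximity

Gene–locus distance is TSS-to-SNP (single well-defined anchor; a
gene-body option would need a body interval the annotation does not
carry).  The filter keeps the minimum-p locus per region with
deterministic tie-breaks (position, then SNP id).  The Fisher universe is
the comparison's detected genes, not the whole annotation, so
never-expressed genes cannot manufacture enrichment.  Distance windows
are closed intervals; nesting `near(d1) ⊆ near(d2)` for `d1 <= d2` is a
tested invariant.  Top-altered sets rank signed genes by ascending
p-value with |logFC| and gene id as tie-breaks.

## Motif enrichment

Scanning computes log2-odds scores against a positive background
(pseudocounted PWMs; a zero background frequency is an error) on both
strands; a hit is any window at or above 80% of the maximal achievable
score (configurable), and overlapping hits are retained.  Minus-strand
offsets refer to the window start on the scanned sequence; scanning a
sequence and its reverse complement yields mirrored hit sets with equal
scores (tested).

The enrichment model regresses DEG-set membership on the per-gene hit
count plus a centred cubic B-spline basis (8 functions) in promoter GC
fraction, and in region length when it varies; the p-value is a Wald test
of the hit-count coefficient.  The spline basis is unpenalised: with
>= 1000 genes per fit and <= 10 basis functions, penalisation changes the
hit-count coefficient negligibly while a per-motif smoothing search over
a 500–3000 motif panel would dominate the runtime, so regression splines
with fixed df were chosen over GCV-selected penalised splines.  Complete
separation falls back to a ridge-penalised fit and is flagged.  The GC
adjustment is validated by a confounding simulation: when plants track GC
and the DEG set is GC-biased, the adjusted model rejects no more often
than the unadjusted one.

Promoter extraction uses 0-based half-open coordinates: a plus-strand
gene with TSS `t` spans `[t-5000, t+500)`; a minus-strand gene is the
reverse complement of `[t-500, t+5000)`.  The oriented TSS offset is 5000
(plus) vs 4999 (minus); exact symmetry is impossible with half-open
spans and the 1-base discrepancy is irrelevant at 5500 bp scale.

## Structure QC

Sample clustering uses 1 − Spearman correlation on log2(x+1) expression
with average linkage; PCA runs on gene-standardised log expression.
Residualisation subtracts each gene's per-subject mean (idempotent by
construction).  Factor attribution adds each design factor last to a
model containing the other two and measures the deviance gained; because
subject (6 estimable df once status is present) would beat tissue (1 df)
on noise alone, dominance compares deviance *per estimable degree of
freedom*.  Aliased columns (status NN is confounded with the
control-vs-patient subject contrast) are dropped by pivoted-QR rank
detection, so each factor contributes only its estimable span.

## Synthetic-data generator

The generator is the package's study-condition definition, not a tuning
surface.  Defaults: 4 patients + 4 controls (24 samples), 4000 genes,
NB dispersion 0.1, library sizes uniform on [10M, 25M] (drawn per sample
so TMM is exercised non-trivially), lognormal baseline abundances
(log-SD 1.5) with 2% of genes forced below the detection limit,
a per-subject per-gene lognormal multiplier (log2-SD 0.7) shared across
that subject's KC and skin samples — this is what makes samples cluster
by subject before tissue or status — a lognormal tissue effect
(log2-SD 0.5), and planted disease effects of |log2 FC| 2 applied to the
PP and PN samples of the affected tissue, with the PN effect attenuated
to 70% of the PP effect (uninvolved skin is the milder phenotype; the
attenuation is also what leaves a PP-vs-PN contrast for the paired
comparison and for subject-residual analysis).  The planted direction
asymmetry (5% KC-down, 3% KC-up, 1% skin-down, 4% skin-up) mirrors the
headline pattern of more KC-decreased than skin-decreased genes, with
skin skewed toward increases.

The reference matrix gives genes of a module a shared per-sample latent
factor with latent correlation `module_cor` (default 0.8), exponentiated
with a mild amplitude spread (log-SD 0.25 baseline, 0.4 noise).  Default
modules (90 of 25–60 genes) cover nearly all genes, as a dynamic-tree-cut
partition of real data would; planted KC-decreased genes are packed into
the first modules so count-level repression and reference co-expression
agree, as they would for a real disease-repressed pathway.  The mild
amplitude spread is a deliberate simplification: real FPKM matrices have
much heavier per-gene amplitude heterogeneity, which degrades Euclidean
clustering, so module-recovery results here certify the procedure under
comparable-amplitude conditions only.

Loci default to 129 rows in 67 regions, 60% of regions placed within
30 kb of a planted KC-decreased gene and the rest uniform; extra loci are
scattered inside existing regions with inflated p-values.  Promoters are
i.i.d.-base sequences (GC configurable, default uniform) with motif
consensus strings inserted at recorded offsets on either strand; a
companion genome builder pastes the oriented promoters back into random
contigs so extraction round-trips exactly.  Annotation spaces genes 60 kb
apart (non-overlapping bodies, strictly increasing TSS per chromosome),
and gives each planted module a unique maximally-GO-annotated member so
labels have a well-defined answer.

What the generator does *not* model: read-level noise or mapping
artefacts, isoforms, gene-length-dependent counting, correlated
disease effects across genes (each planted gene shifts independently),
GC-dependent count bias, or the amplitude heterogeneity noted above.
Passing tests therefore certify the statistical machinery under the
stated model, not robustness to those real-data pathologies.

## Problem sizes

Validation runs use desk-scale sizes chosen to keep the whole suite fast
while leaving estimates stable: 2000 genes for calibration/power
simulations, 600 for dispersion recovery, 3200 genes / 100 modules × 20
replicates for DEM recovery, 239 direct-built modules × 10 replicate FC
draws for DEM null calibration, 2200 promoters × 12 PWMs for the motif
scan, and the 4000-gene default scenario end to end.

## Known limitations

- The static cut + merge clustering is deterministic but can absorb
  outlier genes into the nearest module; representatives buffer the DEM
  test against this contamination, module membership lists less so.
- Unpaired comparisons are mildly anti-conservative when subject effects
  are large (the subject variance is not separable from overdispersion at
  n = 4 + 4); only the paired PP-vs-PN model is calibrated under strong
  subject effects, and the tests assert exactly that.
- The Wald p of the motif model relies on asymptotics; with very sparse
  hit counts the ridge fallback is conservative.
- FPKM uses annotation exonic length with no effective-length correction.
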