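# Methods

## Model

Bulk expression is modeled as a nonnegative mixture: the observed
gene-by-sample matrix V (FPKM or microarray intensity scale) is
approximately W·H, where the columns of W are latent expression
programs (tumor subtype programs, stromal programs, an immune
program) and the rows of H are per-sample program weights. The
factorization minimizes the generalized Kullback–Leibler divergence

D(V‖WH) = Σ_ij [ V_ij log(V_ij/(WH)_ij) − V_ij + (WH)_ij ]

by the classical multiplicative updates, which decrease D
monotonically. Initialization is seeded uniform noise scaled by
√(mean(V)/k); a small ε = 1e−12 guards divisions. Iteration stops
when the relative divergence change stays below `tol` for 10
consecutive iterations or at `max_iter`. A Frobenius objective is
available behind a flag. NMF runs on the raw nonnegative scale
(log-transformed data would violate the additive mixture reading);
clustering, differential expression and template prediction run on
log2(x+1), and each result records the transform applied.

Rank selection is consensus-based: for each candidate k, repeated
seeded factorizations assign every sample to its maximal-weight
factor (ties to the lowest index); the 0/1 co-assignment matrices are
averaged into a consensus matrix, and the cophenetic coefficient —
the Pearson correlation between off-diagonal consensus distances
(1 − C) and the cophenetic distances of their average-linkage
dendrogram — summarizes stability. The coefficient is reported
per k; the final rank is a judgment call, not automated. The default
number of restarts is 30.

## Subtype discovery

Only the 5000 genes with the highest median expression enter NMF
(ties at the cutoff break lexicographically); enrichment scoring uses
the full matrix. The immune factor is the factor whose H-row has the
highest Spearman correlation with a per-sample immune enrichment
score (ssGSEA of an immune signature); Spearman rather than Pearson
because enrichment scores are skewed, and ties go to the lowest
factor index with the full correlation table kept for audit. An
alternative reading — the factor whose top-weight samples have the
highest mean score — was considered and not implemented.

The factor's top-50 genes by loading ("exemplar genes") feed
consensus clustering: 1000 subsamples of 80% of samples (without
replacement), average-linkage hierarchical clustering per subsample,
co-clustering counts divided by co-sampling counts, and a final
average-linkage cut of 1 − consensus at k = 2.

Within-subsample distances are Euclidean on median-centered log2
expression by default; 1 − Pearson is available via
`metric="pearson"`. The correlation default of the clustering-tool
family was tried first and rejected on evidence: over a coherent
marker panel (every panel gene rises and falls together with the
class) each sample's centered profile is approximately a constant
level shift plus noise, and Pearson correlation between samples
subtracts exactly that shift — on synthetic cohorts it produced
near-degenerate splits, while Euclidean distance, which retains the
level, separates the planted classes cleanly. On real panels with
heterogeneous sub-signals the two metrics behave more similarly.

Labels are then refined by one out-of-bag random-forest pass (500
trees, seeded): the forest is trained on exemplar-gene expression
with the consensus labels, and each sample's refined label is its
out-of-bag prediction. One pass, not iterated to a fixed point, and
OOB rather than a held-out scheme — both choices documented here
because the refinement procedure is otherwise underdetermined. The
class with the higher mean immune score is named Immune; equal means
are treated as degenerate and require manual naming.

## Enrichment scores

ssGSEA: per sample, genes are ranked by expression (average ranks for
ties; rank N = highest); walking the list in descending rank order,
the score is the summed difference between the rank-weighted in-set
ECDF (weight = rank^α, α = 0.25) and the unweighted out-of-set ECDF.
Scores are invariant to any strictly increasing per-sample transform.
ESTIMATE-style immune/stromal scores are unnormalized ssGSEA at
α = 0.25; panel exports optionally divide by the global score range.
The true ESTIMATE signature lists are external inputs (GMT); the
synthetic generator emits its own ground-truth GMT so tests need no
downloads. Cytolytic activity is √((GZMA+ε)(PRF1+ε)), ε = 0.01.

## Classifier and template prediction

Differential expression uses a moderated t: per-gene pooled
variances are shrunk toward a prior estimated by the method of
moments on the log sample variances (mean and variance of
log s² matched to digamma/trigamma expressions; the prior degrees of
freedom solve a trigamma equation, capped at 1e6 when no excess
dispersion exists), and the t-test gains the prior degrees of
freedom. A plain Welch-t fallback is selectable. Genes with BH
q < 0.05 and |log2 FC| ≥ 1.5 (literally 1.5 on the log2 scale, a
fold change of ≈2.83) form the signed classifier: positive log2 FC →
Immune markers, negative → Nonimmune markers.

Nearest-template prediction standardizes each gene across the cohort
(z-scores of log2(x+1)), builds one signed ±1 template per class over
the classifier genes present (≥50% presence required), and assigns
each sample to the class with the smaller cosine distance (ties to
Immune). Significance: n_null = 1000 random gene sets of the same
sizes build null templates; p = (1 + #{null min-distance ≤
observed})/(1 + n_null), BH-adjusted across samples; samples above
the confidence threshold keep their label but are flagged, since a
validation workflow assigns every sample a class. Signed two-class
templates (rather than one-class 0/1 templates) use the markers of
both classes; cosine on standardized values stands in for the
original module's correlation distance, which is unstated.

## Immunogenomic statistics

TMB counts nonsynonymous mutations (missense, nonsense, frameshift
insertion/deletion, in-frame insertion/deletion, splice site; not
silent/other) per sample divided by the exome size in megabases
(default 38, configurable; the sequencing denominator is a
convention, not a measurement). Class-association tests: Pearson
chi-square **without** continuity correction (required to reproduce
the worked SMAD4 example from its printed counts — Yates correction
changes the third decimal), Fisher's exact test (2×2,
point-probability rule), Wilcoxon rank-sum (exact for combined
n ≤ 20 without ties, normal approximation with tie correction
otherwise; all-identical values give p = 1 by convention), and
Cramér's V = √(χ²/(n·min(r−1, c−1))). Pathway-level mutation
comparisons can count gene-sample pairs (genes × class size as the
denominator), matching how pathway mutation frequencies are reported.

## Survival

Kaplan–Meier product-limit curves with Greenwood-based confidence
intervals; the median is the first time S(t) ≤ 0.5 and is reported
as not reached when the curve never crosses. Log-rank chi-square
across groups. Cox proportional hazards is fit via lifelines with
Efron tie handling (a from-scratch Breslow Newton–Raphson solver is
available behind `tie_method="breslow"`); constant covariates and
non-convergence raise with the covariate named. The multivariable
helper enters covariates with univariable p < 0.05 (threshold
configurable); categorical covariates are expanded against a declared
reference level.

## Subclass mapping

For each class a of cohort A, the top m = 100 genes by pooled
two-sample t (a vs rest) are tested for enrichment toward the top of
cohort B's (b vs rest) t-ranked list with a weighted KS statistic
(weights |t|); the null permutes B's labels (n = 1000). Both
directions are computed and the pairwise p is the larger
(conservative mutual mapping); Bonferroni multiplies by the number of
class pairs. Plain pooled t (not moderated) keeps the statistic
exactly invariant to per-gene affine rescaling. Each direction's
permutation stream is seeded from the permuted cohort's sample-id
digest so that swapping the cohorts transposes the p-matrix exactly.
This module approximates the published subclass-mapping procedure;
the original tool's exact ES weighting is not reproduced. Note that
in a two-class contrast t(B vs rest) = −t(A vs rest): a class with no
positive markers of its own (the Nonimmune side of a one-sided
signature, as here) is legitimately unmappable.

## Synthetic cohorts

The generator emulates the assumed data-generating process, with
defaults fixed at the study conditions:

- **Programs**: K = 5 (tumor-classical, tumor-basal, stroma-normal,
  stroma-activated, immune), 60 exclusive marker genes each among
  2000 genes. Marker loadings ~ Gamma(4, 1); background loadings
  ~ U(0, 0.05). Disjoint marker sets make recovery metrics
  unambiguous. The two cytolytic-activity genes (GZMA, PRF1) are
  planted inside the immune marker set.
- **Weights**: lognormal(0, 0.5) per program; the immune weight is
  bimodal — lognormal(1.2, 0.3) for the immune-high fraction (0.31 of
  samples, Bernoulli), lognormal(−1.2, 0.4) otherwise, with redraws
  enforcing that the immune-high flag and the mid-point threshold
  agree exactly.
- **Noise**: multiplicative lognormal, sd 0.4 on the natural-log
  scale. Lognormal rather than Poisson because the pipeline consumes
  FPKM/intensity-scale data and one parameter preserves
  nonnegativity.
- **Survival**: exponential, baseline hazard ln 2 / 17.9 per month
  (median 17.9 months in the unfavorable class), hazard ratio 0.56
  for the immune-high class; uniform censoring on [0, c] with c
  solved analytically so the expected censored fraction is 0.35. A
  proportional-hazards Weibull option exists behind a flag.
- **Mutations**: per-gene class-conditional Bernoulli (SMAD4 0.156
  immune-high vs 0.327 otherwise; 12 WNT-pathway genes at
  3/(45·12) vs 19/(101·12); KRAS/TP53/CDKN2A class-independent),
  plus Poisson background nonsynonymous loads (means 60 vs 40) and
  ~25% additional silent rows, giving the immune-high class the
  higher TMB.
- **CNA burdens**: class-conditional Poisson with rates chosen so the
  class medians land on 0/2/0/0 (immune-high) vs 3/7/0/9 events for
  arm-amplification/arm-deletion/focal-amplification/focal-deletion.
- **Purity**: Beta(2.5, 8.5) for immune-high vs Beta(4, 6) —
  immune-rich samples have lower tumor purity.

What the generator does **not** emulate: genome-scale gene counts,
correlated marker programs, batch or platform effects, non-
proportional hazards, and mutation-signature structure. Tests passing
on these cohorts demonstrate that the pipeline recovers the structure
it assumes; they do not certify performance on real cohorts where
those assumptions are degraded.

## Problem sizes in the test suite

The unit and end-to-end suites run the discovery pipeline at k = 6
on the generator's 5-program cohorts, restricted to the top 1000
genes, with 200–300 consensus resamples and NMF capped at 500–600
iterations — sizes at which the planted structure is comfortably
recoverable and a full discovery run takes a few seconds. The
survival-effect recovery experiment uses 200 replicates of n = 149
with a reduced gene count (320), since the expression matrix never
enters the Cox fit. Degenerate inputs are handled explicitly: all-zero
genes are dropped before NMF with a warning, zero-variance genes with
zero group difference get p = 1, samples never out-of-bag keep their
input label, and undefined statistics (cophenetic coefficient of a
constant consensus, Cramér's V of a one-level labeling, median
survival never reached) return an explicit undefined flag rather than
NaN surprises.
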