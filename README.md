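# immunodissect

Virtual microdissection of immune molecular subtypes from bulk tumor
gene expression.

Bulk tumor samples mix transcripts from tumor cells, stroma, and
infiltrating immune cells. `immunodissect` separates these latent
expression programs without physical dissection: it factorizes a
nonnegative gene-by-sample matrix V ≈ W·H by NMF (generalized
Kullback–Leibler objective, multiplicative updates), identifies the
factor whose sample weights track an immune enrichment score (ssGSEA
of an immune signature), and clusters samples on that factor's top
loaded "exemplar" genes to call a two-class subtype — an *Immune
Class* of immune-infiltrated samples versus the rest. Downstream
modules quantify what the subtype means: a signed marker-gene
classifier (moderated-t differential expression, FDR < 0.05 and
|log2 FC| ≥ 1.5) transferable to external cohorts by nearest-template
prediction; mutation and copy-number burden contrasts (chi-square,
Fisher, Wilcoxon rank-sum, Cramér's V); Kaplan–Meier / log-rank /
Cox proportional-hazards survival analysis; and cross-cohort subclass
mapping with permutation p-values. It is written for computational
oncologists working with TCGA-style bulk cohorts (FPKM or microarray
intensities) who want a reproducible, testable implementation of this
subtype-discovery workflow.

A synthetic-cohort generator (`immunodissect.simulate`) produces
cohorts with the statistical structure the pipeline assumes —
nonnegative program mixtures, ~31% immune-high samples, a favorable
hazard ratio of 0.56 for the immune-high class, class-linked mutation
frequencies, copy-number burdens and tumor purity — with full ground
truth, so every stage is testable without external downloads.

## Worked example

Simulate a 150-sample training cohort, discover the subtype, validate
the classifier on an independent cohort, and test the survival
association:

```sh
immunodissect simulate --out cohort --seed 7 --n-samples 150 --n-genes 2000
immunodissect discover --expression cohort/expression.tsv \
    --immune-gmt cohort/markers.gmt --k 6 --top-genes 1000 \
    --n-resamples 300 --seed 7 --out discovery
immunodissect simulate --out external --seed 99 --n-samples 150 --n-genes 2000
immunodissect validate --classifier discovery/classifier.tsv \
    --cohort external/expression.tsv --seed 1 --out validation
immunodissect survive --clinical cohort/clinical.tsv \
    --subtypes discovery/subtypes.tsv --out km.tsv
```

which prints:

```
Immune Class: 47/150 samples (31.3%); classifier 60 up / 0 down genes; results in discovery
    cohort   n  n_immune  immune_fraction
expression 150        50         0.333333
    group   n  events    median
Nonimmune 103      73 16.371735
   Immune  47      30 26.515724
log-rank chi2=3.776 p=0.052
Cox HR (Immune vs Nonimmune) = 0.66 (95% CI 0.43-1.01, p=0.0537)
```

Reading the numbers: the discovery stage calls 47/150 samples Immune
Class, close to the generator's planted 31% immune-high fraction; the
60 up-genes are the recovered immune markers. Nearest-template
prediction transfers the classifier to the unseen cohort and again
finds an immune fraction near one third. Median overall survival is
longer in Immune Class (26.5 vs 16.4 months) and the Cox hazard ratio
of 0.66 points in the favorable direction of the planted 0.56; at
n=150 a single cohort estimates the HR with wide confidence bounds,
which is why recovery is asserted as an average over replicates (see
below).

The same workflow runs on real data: any nonnegative gene-by-sample
TSV (or GCT) plus an immune signature GMT for `discover`, and a saved
classifier TSV for `validate` — including published classifier gene
lists in the same two-column format.

## Layout

| module | contents |
| --- | --- |
| `dataio` | TSV/GCT/GMT readers and writers, probe collapsing, quantile normalization, top-median-gene filter |
| `nmf` | KL-NMF with multiplicative updates, consensus/cophenetic rank selection, exemplar genes |
| `enrichment` | ssGSEA, ESTIMATE-style immune/stromal scores, cytolytic activity, signature panels |
| `subtyping` | immune-factor selection, consensus clustering, random-forest label refinement, class naming |
| `classifier` | moderated-t differential expression, classifier construction, nearest-template prediction |
| `immunogenomics` | TMB, contingency tests, rank-sum comparisons, Cramér's V, CNA burden reports |
| `survival` | Kaplan–Meier, log-rank, Cox proportional hazards (Efron/Breslow) |
| `submap` | cross-cohort subclass mapping with permutation nulls |
| `simulate` | ground-truth synthetic cohort generator |
| `pipeline`, `cli` | composite discovery/validation workflows and the `immunodissect` command |

See `docs/methods.md` for the model details, parameter defaults, and
design decisions.
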