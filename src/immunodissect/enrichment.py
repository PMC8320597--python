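"""Single-sample gene-set enrichment scoring.

Implements rank-based per-sample enrichment (ssGSEA): for one sample,
genes are ranked by expression and the score integrates the difference
between the rank-weighted empirical CDF of in-set genes and the
unweighted ECDF of out-of-set genes over the descending-rank gene list.
Immune and stromal signature scores (ESTIMATE-style, alpha = 0.25) and
the cytolytic-activity statistic (geometric mean of GZMA and PRF1) are
thin wrappers over the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import DataError, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25


@dataclass
class ScoreMatrix:
    """Signature-by-sample enrichment scores plus class-comparison p-values."""

    scores: pd.DataFrame  # signatures x samples
    alpha: float
    normalized: bool
    pvalues: pd.Series | None = None  # per-signature rank-sum p (may hold NaN)
    qvalues: pd.Series | None = None


def _single_sample_score(
    expression: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """ssGSEA score of one sample for one membership mask.

    ``expression`` is the per-gene expression of the sample; genes are
    ranked ascending (rank N = highest expression, average ranks for
    ties), then walked in descending-rank order accumulating the
    weighted in-set ECDF (weight = rank^alpha) minus the out-of-set
    ECDF; the score is the sum of that difference over all positions.
    """
    n = expression.shape[0]
    ranks = stats.rankdata(expression, method="average")
    order = np.argsort(-ranks, kind="stable")
    in_ordered = in_set[order]
    weights = ranks[order] ** alpha
    w_in = np.where(in_ordered, weights, 0.0)
    total_in = w_in.sum()
    n_out = n - int(in_set.sum())
    ecdf_in = np.cumsum(w_in) / total_in
    ecdf_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_score(
    matrix: ExpressionMatrix,
    gene_set: list[str],
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> pd.Series:
    """Per-sample ssGSEA scores for one gene set.

    Genes of the set absent from the matrix are dropped (logged). The
    set must neither miss the matrix entirely nor cover all of its
    genes. With ``normalize`` the scores are divided by their range.
    """
    if alpha <= 0:
        raise DataError("alpha must be positive")
    present = [g for g in dict.fromkeys(gene_set) if g in set(matrix.gene_ids)]
    dropped = len(set(gene_set)) - len(present)
    if dropped:
        logger.info("ssgsea_score: %d set genes absent from matrix", dropped)
    if not present:
        raise DataError("no gene of the set is present in the matrix")
    if len(present) == matrix.n_genes:
        raise DataError("gene set covers every gene; out-of-set ECDF undefined")
    in_set = np.isin(np.asarray(matrix.gene_ids), present)
    scores = np.array(
        [
            _single_sample_score(matrix.values[:, j], in_set, alpha)
            for j in range(matrix.n_samples)
        ]
    )
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return pd.Series(scores, index=list(matrix.sample_ids), name="score")


def estimate_scores(
    matrix: ExpressionMatrix,
    immune_set: list[str],
    stromal_set: list[str],
) -> pd.DataFrame:
    """ESTIMATE-style immune and stromal enrichment scores.

    Both are unnormalized ssGSEA scores at the conventional exponent
    alpha = 0.25. Returns a samples x {immune_score, stromal_score}
    frame.
    """
    immune = ssgsea_score(matrix, immune_set, alpha=0.25, normalize=False)
    stromal = ssgsea_score(matrix, stromal_set, alpha=0.25, normalize=False)
    return pd.DataFrame({"immune_score": immune, "stromal_score": stromal})


def cytolytic_activity(
    matrix: ExpressionMatrix,
    gene_a: str = "GZMA",
    gene_b: str = "PRF1",
    epsilon: float = 0.01,
) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 expression.

    ``epsilon`` keeps the statistic defined when either gene is zero.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.gene_ids:
            raise DataError(f"gene {g!r} not present in the matrix")
    sub = matrix.subset_genes([gene_a, gene_b]).values
    cyt = np.sqrt((sub[0] + epsilon) * (sub[1] + epsilon))
    return pd.Series(cyt, index=list(matrix.sample_ids), name="cytolytic_activity")


def score_panel(
    matrix: ExpressionMatrix,
    signatures: GeneSetCollection,
    labels: pd.Series | dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> ScoreMatrix:
    """Score a signature panel and compare classes per signature.

    Each signature is ssGSEA-scored per sample; a two-sided Wilcoxon
    rank-sum test compares the two classes per signature (exact when
    feasible). p-values are reported unadjusted with a BH column. With
    ``normalize`` all scores are divided by the global range of the
    panel, matching heatmap-style presentation. If either class has
    fewer than 2 samples the p-values are undefined (NaN).
    """
    labels = pd.Series(labels)
    missing = [s for s in matrix.sample_ids if s not in labels.index]
    if missing:
        raise DataError(f"labels missing for samples: {missing[:5]}")
    labels = labels.loc[list(matrix.sample_ids)]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"expected exactly 2 classes, got {classes}")

    rows = {
        name: ssgsea_score(matrix, genes, alpha=alpha, normalize=False)
        for name, genes in signatures.sets.items()
    }
    scores = pd.DataFrame(rows).T
    scores = scores[list(matrix.sample_ids)]

    degenerate = min((labels == c).sum() for c in classes) < 2
    pvals = {}
    for name in scores.index:
        if degenerate:
            pvals[name] = np.nan
            continue
        a = scores.loc[name, labels == classes[0]].to_numpy()
        b = scores.loc[name, labels == classes[1]].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[name] = 1.0
            continue
        pvals[name] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
        )
    pvalues = pd.Series(pvals, name="p")
    if pvalues.notna().all():
        qvalues = pd.Series(
            multipletests(pvalues.to_numpy(), method="fdr_bh")[1],
            index=pvalues.index,
            name="q",
        )
    else:
        qvalues = pd.Series(np.nan, index=pvalues.index, name="q")

    if normalize:
        rng = float(scores.to_numpy().max() - scores.to_numpy().min())
        if rng > 0:
            scores = scores / rng
    return ScoreMatrix(
        scores=scores, alpha=alpha, normalized=normalize,
        pvalues=pvalues, qvalues=qvalues,
    )
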