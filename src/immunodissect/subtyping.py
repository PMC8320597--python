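"""Immune subtype discovery on exemplar genes.

Workflow: identify the immune NMF factor (the factor whose sample
weights track an immune enrichment score), consensus-cluster samples on
that factor's exemplar genes, refine the cluster labels with an
out-of-bag random-forest pass, and name the class with the higher mean
immune score "Immune".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier

from .dataio import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

IMMUNE = "Immune"
NONIMMUNE = "Nonimmune"


@dataclass
class SubtypeAssignment:
    """Final Immune/Nonimmune call per sample with provenance.

    ``labels`` holds the refined class names; ``consensus_labels`` the
    pre-refinement integer cluster ids; ``confusion`` the 2x2 counts of
    consensus vs refined cluster membership.
    """

    labels: pd.Series  # sample -> Immune / Nonimmune
    consensus_labels: pd.Series
    consensus_matrix: pd.DataFrame
    confusion: pd.DataFrame | None = None
    immune_factor: int | None = None
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def immune_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == IMMUNE])


def select_immune_factor(
    H: np.ndarray,
    immune_scores: pd.Series | np.ndarray,
    sample_ids: list[str] | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the NMF factor whose weights best track the immune score.

    Spearman correlation is computed between each factor's H-row and
    the per-sample immune enrichment scores; the argmax factor is
    returned together with the full correlation table. Zero-variance
    rows are skipped (correlation undefined). Ties go to the lowest
    factor index.
    """
    H = np.asarray(H, dtype=float)
    if isinstance(immune_scores, pd.Series):
        if sample_ids is not None:
            immune_scores = immune_scores.loc[list(sample_ids)]
        scores = immune_scores.to_numpy()
    else:
        scores = np.asarray(immune_scores, dtype=float)
    if H.shape[1] != scores.shape[0]:
        raise DataError(
            f"H has {H.shape[1]} samples but immune_scores has {scores.shape[0]}"
        )
    rows = []
    for f in range(H.shape[0]):
        if np.ptp(H[f]) == 0 or np.ptp(scores) == 0:
            rows.append((f, np.nan))
            continue
        rho = stats.spearmanr(H[f], scores).statistic
        rows.append((f, float(rho)))
    table = pd.DataFrame(rows, columns=["factor", "spearman_rho"]).set_index("factor")
    valid = table["spearman_rho"].dropna()
    if valid.empty:
        raise DataError("no factor has a defined correlation with immune scores")
    best = valid.max()
    winners = valid.index[valid == best]
    if len(winners) > 1:
        logger.info("select_immune_factor: tie among factors %s", list(winners))
    return int(winners.min()), table


def consensus_cluster(
    matrix: ExpressionMatrix,
    k: int = 2,
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    log_transform: bool = True,
    center_genes: bool = True,
    metric: str = "euclidean",
) -> tuple[pd.Series, pd.DataFrame]:
    """Consensus clustering of samples on (exemplar-gene) expression.

    Per resample, a ``subsample_frac`` fraction of samples is drawn
    without replacement and clustered by average-linkage hierarchical
    clustering on median-centered log2(x+1) expression, cut at ``k``.
    Co-clustering counts divided by co-sampling counts give the
    consensus matrix; final labels come from average-linkage clustering
    of 1 - consensus cut at ``k``.

    ``metric`` is "euclidean" (default) or "pearson" (distance
    1 - Pearson sample correlation). Over a marker panel that moves
    coherently — every gene shifts up or down together with the class —
    each sample's centered profile is a level shift plus noise, and
    Pearson correlation between samples subtracts exactly that shift;
    Euclidean distance retains it, so it is the default for exemplar-
    gene clustering.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    if not 0 < subsample_frac <= 1:
        raise DataError("subsample_frac must lie in (0, 1]")
    if metric not in ("euclidean", "pearson"):
        raise DataError(f"unknown metric {metric!r}")
    X = matrix.log2p1().values if log_transform else matrix.values
    if center_genes:
        X = X - np.median(X, axis=1, keepdims=True)
    n = matrix.n_samples
    if n < k:
        raise DataError("fewer samples than clusters")
    n_sub = max(k, int(round(subsample_frac * n)))
    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = X[:, idx]
        if metric == "pearson":
            dist = 1.0 - np.corrcoef(sub.T)
            np.fill_diagonal(dist, 0.0)
            condensed = squareform(dist, checks=False)
        else:
            condensed = pdist(sub.T)
        Z = hierarchy.linkage(condensed, method="average")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        same = labels[:, None] == labels[None, :]
        co_sample[np.ix_(idx, idx)] += 1
        co_cluster[np.ix_(idx, idx)] += same
    never = (co_sample + np.eye(n) == 0).all(axis=1)
    if never.any():
        raise DataError(
            "some samples were never co-sampled; increase n_resamples"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2

    final_dist = 1.0 - consensus
    np.fill_diagonal(final_dist, 0.0)
    Z = hierarchy.linkage(squareform(final_dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    ids = list(matrix.sample_ids)
    return (
        pd.Series(labels, index=ids, name="consensus_cluster"),
        pd.DataFrame(consensus, index=ids, columns=ids),
    )


def refine_labels_random_forest(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    log_transform: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Refine cluster labels by an out-of-bag random-forest pass.

    A random forest is trained on the (exemplar-gene) expression with
    the consensus labels as targets; each sample's refined label is its
    out-of-bag predicted class. Samples with no out-of-bag vote (rare
    with many trees) keep their input label. The 2x2 confusion matrix
    of consensus vs refined labels is returned alongside.
    """
    labels = pd.Series(labels).loc[list(matrix.sample_ids)]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise DataError("refinement needs two classes in the input labels")
    if min((labels == c).sum() for c in classes) < 2:
        raise DataError("each class needs at least 2 samples")
    X = (matrix.log2p1().values if log_transform else matrix.values).T
    y = labels.to_numpy()
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    oob = rf.oob_decision_function_
    refined = []
    for i in range(len(y)):
        if np.isnan(oob[i]).any() or oob[i].sum() == 0:
            refined.append(y[i])  # never out-of-bag: keep input label
        else:
            refined.append(rf.classes_[int(np.argmax(oob[i]))])
    refined = pd.Series(refined, index=labels.index, name="refined_cluster")
    confusion = pd.crosstab(labels, refined).reindex(
        index=classes, columns=classes, fill_value=0
    )
    return refined, confusion


def name_classes(
    labels: pd.Series,
    immune_scores: pd.Series,
) -> pd.Series:
    """Name the class with the higher mean immune score "Immune".

    Exactly two classes are required; equal class means are degenerate
    and raise (manual naming required).
    """
    labels = pd.Series(labels)
    immune_scores = pd.Series(immune_scores).loc[labels.index]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"expected 2 classes, got {classes}")
    means = {c: immune_scores[labels == c].mean() for c in classes}
    if means[classes[0]] == means[classes[1]]:
        raise DataError("class mean immune scores are equal; name classes manually")
    immune_class = max(classes, key=lambda c: means[c])
    return labels.map(
        lambda c: IMMUNE if c == immune_class else NONIMMUNE
    ).rename("class_name")


def assign_subtypes(
    exemplar_matrix: ExpressionMatrix,
    immune_scores: pd.Series,
    k: int = 2,
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    n_trees: int = 500,
    seed: int = 0,
    immune_factor: int | None = None,
) -> SubtypeAssignment:
    """Consensus clustering + RF refinement + naming, in one call."""
    consensus_labels, consensus = consensus_cluster(
        exemplar_matrix, k=k, n_resamples=n_resamples,
        subsample_frac=subsample_frac, seed=seed,
    )
    refined, confusion = refine_labels_random_forest(
        exemplar_matrix, consensus_labels, n_trees=n_trees, seed=seed
    )
    names = name_classes(refined, immune_scores)
    return SubtypeAssignment(
        labels=names,
        consensus_labels=consensus_labels,
        consensus_matrix=consensus,
        confusion=confusion,
        immune_factor=immune_factor,
        seed=seed,
        provenance={
            "k": k, "n_resamples": n_resamples,
            "subsample_frac": subsample_frac, "n_trees": n_trees,
            "transform": "log2(x+1), gene median-centered", "metric": "euclidean",
        },
    )
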