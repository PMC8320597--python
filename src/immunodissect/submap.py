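"""Subclass mapping: do subtypes in two cohorts correspond?

For each class ``a`` of cohort A, its top marker genes (by a pooled
two-sample t, a vs rest) are tested for enrichment toward the top of cohort B's
(b vs rest) t-ranked gene list with a weighted Kolmogorov-Smirnov
statistic; the null comes from label permutations within B. The
symmetric direction (B's markers ranked in A) is computed as well and
the pairwise p-value is the more conservative (larger) of the two;
Bonferroni correction multiplies by the number of class pairs.

This is an approximation of the published subclass-mapping procedure
sufficient for cross-cohort correspondence testing; the exact weighting
of the original tool is not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import DataError, ExpressionMatrix


@dataclass
class SubmapResult:
    p_matrix: pd.DataFrame  # classes in A x classes in B, nominal p
    bonferroni_matrix: pd.DataFrame
    m_markers: int
    n_perm: int
    seed: int


def _two_group_t(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t per gene (mask vs rest)."""
    n1 = int(mask.sum())
    n2 = X.shape[1] - n1
    g1, g2 = X[:, mask], X[:, ~mask]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    # plain pooled t: per-gene affine rescaling cancels exactly
    se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t


def _weighted_ks(t_ranked_members: np.ndarray, weights: np.ndarray, n_genes: int) -> float:
    """Max positive deviation of the weighted in-set ECDF over the
    uniform out-of-set ECDF along a ranked gene list.

    ``t_ranked_members`` holds the 0-based positions of the marker set
    in the descending t-ranking; ``weights`` their (nonnegative)
    weights in that order.
    """
    member = np.zeros(n_genes, dtype=bool)
    member[t_ranked_members] = True
    w = np.zeros(n_genes)
    w[t_ranked_members] = weights
    total = w.sum()
    if total <= 0:
        w[t_ranked_members] = 1.0
        total = w.sum()
    hit = np.cumsum(w) / total
    miss = np.cumsum(~member) / (n_genes - member.sum())
    return float(np.max(hit - miss))


def _direction(
    XA: np.ndarray,
    labels_a: pd.Series,
    XB: np.ndarray,
    labels_b: pd.Series,
    classes_a: list,
    classes_b: list,
    m_markers: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """p[a, b]: enrichment of A's class-a markers in B's class-b ranking."""
    # marker sets from A
    markers: dict = {}
    for a in classes_a:
        t = _two_group_t(XA, (labels_a == a).to_numpy())
        markers[a] = np.argsort(-t, kind="stable")[:m_markers]

    def scores_for(lb: pd.Series) -> np.ndarray:
        out = np.empty((len(classes_a), len(classes_b)))
        for jb, b in enumerate(classes_b):
            t_b = _two_group_t(XB, (lb == b).to_numpy())
            order = np.argsort(-t_b, kind="stable")
            pos = np.empty_like(order)
            pos[order] = np.arange(len(order))
            for ia, a in enumerate(classes_a):
                mpos = np.sort(pos[markers[a]])
                out[ia, jb] = _weighted_ks(
                    mpos, np.abs(t_b[order])[mpos], XB.shape[0]
                )
        return out

    observed = scores_for(labels_b)
    exceed = np.zeros_like(observed)
    perm_labels = labels_b.to_numpy().copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        null = scores_for(pd.Series(perm_labels, index=labels_b.index))
        exceed += null >= observed
    return (1 + exceed) / (1 + n_perm)


def subclass_map(
    matrix_a: ExpressionMatrix,
    labels_a: pd.Series | dict,
    matrix_b: ExpressionMatrix,
    labels_b: pd.Series | dict,
    m_markers: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
    min_shared_genes: int = 200,
    min_class_size: int = 5,
    log_transform: bool = True,
) -> SubmapResult:
    """Permutation test of subtype correspondence between two cohorts.

    With ``log_transform`` (default) expression is log2(x+1)-transformed
    before computing the per-gene t statistics.
    """
    labels_a = pd.Series(labels_a).loc[list(matrix_a.sample_ids)]
    labels_b = pd.Series(labels_b).loc[list(matrix_b.sample_ids)]
    shared = sorted(set(matrix_a.gene_ids) & set(matrix_b.gene_ids))
    if len(shared) < min_shared_genes:
        raise DataError(
            f"cohorts share only {len(shared)} genes (< {min_shared_genes})"
        )
    for lab, name in ((labels_a, "A"), (labels_b, "B")):
        sizes = lab.value_counts()
        if (sizes < min_class_size).any():
            raise DataError(f"cohort {name} has a class below {min_class_size} samples")
    XA = matrix_a.subset_genes(shared)
    XB = matrix_b.subset_genes(shared)
    XA = XA.log2p1().values if log_transform else XA.values
    XB = XB.log2p1().values if log_transform else XB.values
    classes_a = sorted(labels_a.unique())
    classes_b = sorted(labels_b.unique())
    # seed each direction from the permuted cohort's identity so that
    # swapping A and B transposes the p-matrix exactly
    import zlib

    def rng_for(permuted_ids: list[str]) -> np.random.Generator:
        digest = zlib.crc32("|".join(permuted_ids).encode())
        return np.random.default_rng((seed, digest))

    p_ab = _direction(XA, labels_a, XB, labels_b, classes_a, classes_b,
                      m_markers, n_perm, rng_for(list(matrix_b.sample_ids)))
    p_ba = _direction(XB, labels_b, XA, labels_a, classes_b, classes_a,
                      m_markers, n_perm, rng_for(list(matrix_a.sample_ids)))
    p = np.maximum(p_ab, p_ba.T)
    n_pairs = p.size
    p_matrix = pd.DataFrame(p, index=classes_a, columns=classes_b)
    bonf = (p_matrix * n_pairs).clip(upper=1.0)
    return SubmapResult(p_matrix, bonf, m_markers, n_perm, seed)
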