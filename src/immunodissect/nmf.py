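"""Nonnegative matrix factorization for virtual microdissection.

Bulk tumor expression is modeled as a nonnegative mixture V ~ W.H of
latent expression programs (tumor, stroma, immune compartments). The
factorization minimizes the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by the classical multiplicative updates, which are monotone in D. Rank
selection follows the consensus/cophenetic approach: repeated seeded
factorizations per candidate rank, sample-to-factor argmax assignments
aggregated into a consensus matrix, and its cophenetic correlation used
as a stability readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataio import DataError, ExpressionMatrix

# guard against 0/0 inside multiplicative updates
_EPS = 1e-12


@dataclass
class NMFResult:
    """Factorization V ~ W.H at rank ``k``.

    W holds gene loadings (genes x k), H factor weights (k x samples).
    ``divergence_trace`` records the generalized KL divergence per
    recorded iteration and is non-increasing.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    divergence_trace: np.ndarray
    seed: int
    n_iter: int
    gene_ids: list[str]
    sample_ids: list[str]
    converged: bool


@dataclass
class RankSelection:
    k_values: list[int]
    cophenetic: dict[int, float | None]
    consensus_matrices: dict[int, np.ndarray]
    sample_ids: list[str]


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH)."""
    WH = W @ H
    ratio = V / (WH + _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(V > 0, V * np.log(ratio + _EPS), 0.0)
    return float(np.sum(logterm - V + WH))


def nmf_factorize(
    V: ExpressionMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    objective: str = "kl",
) -> NMFResult:
    """Factorize a nonnegative matrix by seeded multiplicative updates.

    Parameters
    ----------
    V
        Nonnegative matrix (genes x samples). All-zero rows are dropped
        with a warning (they carry no information and break the KL
        updates); all-zero columns are an error.
    k
        Factorization rank, 1 <= k <= min(genes, samples).
    seed
        Seed for the uniform random initialization.
    max_iter, tol
        The iteration stops when the relative divergence change stays
        below ``tol`` for 10 consecutive iterations, or at ``max_iter``.
    objective
        "kl" (default) or "frobenius".
    """
    if isinstance(V, ExpressionMatrix):
        gene_ids, sample_ids = list(V.gene_ids), list(V.sample_ids)
        X = V.values.copy()
    else:
        X = np.asarray(V, dtype=float).copy()
        gene_ids = [f"g{i}" for i in range(X.shape[0])]
        sample_ids = [f"s{j}" for j in range(X.shape[1])]
    if (X < 0).any():
        raise DataError("NMF input must be nonnegative")
    zero_rows = ~(X > 0).any(axis=1)
    if zero_rows.any():
        import warnings

        warnings.warn(f"dropping {int(zero_rows.sum())} all-zero rows before NMF")
        X = X[~zero_rows]
        gene_ids = [g for g, z in zip(gene_ids, zero_rows) if not z]
    if not (X > 0).any(axis=0).all():
        raise DataError("NMF input has an all-zero column")
    if not 1 <= k <= min(X.shape):
        raise DataError(f"rank k={k} out of range for shape {X.shape}")
    if objective not in ("kl", "frobenius"):
        raise DataError(f"unknown objective {objective!r}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k)
    W = scale * rng.uniform(size=(X.shape[0], k)) + _EPS
    H = scale * rng.uniform(size=(k, X.shape[1])) + _EPS

    trace = [kl_divergence(X, W, H) if objective == "kl"
             else 0.5 * float(np.sum((X - W @ H) ** 2))]
    below = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if objective == "kl":
            WH = W @ H + _EPS
            H *= (W.T @ (X / WH)) / (W.sum(axis=0)[:, None] + _EPS)
            WH = W @ H + _EPS
            W *= ((X / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
            d = kl_divergence(X, W, H)
        else:
            H *= (W.T @ X) / (W.T @ W @ H + _EPS)
            W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
            d = 0.5 * float(np.sum((X - W @ H) ** 2))
        prev = trace[-1]
        trace.append(d)
        rel = abs(prev - d) / max(abs(prev), _EPS)
        below = below + 1 if rel < tol else 0
        if below >= 10:
            converged = True
            break
    return NMFResult(
        W=W, H=H, k=k, divergence_trace=np.asarray(trace), seed=seed,
        n_iter=n_iter, gene_ids=gene_ids, sample_ids=sample_ids,
        converged=converged,
    )


def factor_assignments(H: np.ndarray) -> np.ndarray:
    """Assign each sample to its maximal-weight factor (ties: lowest index)."""
    return np.argmax(H, axis=0)


def connectivity_matrix(assignments: np.ndarray) -> np.ndarray:
    a = np.asarray(assignments)
    return (a[:, None] == a[None, :]).astype(float)


def select_rank(
    V: ExpressionMatrix | np.ndarray,
    k_range: list[int],
    n_restarts: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> RankSelection:
    """Consensus-based rank selection.

    For each candidate rank, ``n_restarts`` seeded factorizations are
    run; each run's sample-to-factor argmax assignment yields a 0/1
    connectivity matrix, and their average is the consensus matrix whose
    cophenetic coefficient summarizes assignment stability.
    """
    if not k_range:
        raise DataError("k_range is empty")
    rng = np.random.default_rng(seed)
    cophenetic: dict[int, float | None] = {}
    consensus_matrices: dict[int, np.ndarray] = {}
    sample_ids = (
        list(V.sample_ids) if isinstance(V, ExpressionMatrix)
        else [f"s{j}" for j in range(np.asarray(V).shape[1])]
    )
    for k in k_range:
        acc = None
        for _ in range(n_restarts):
            run_seed = int(rng.integers(0, 2**31 - 1))
            res = nmf_factorize(V, k, seed=run_seed, max_iter=max_iter, tol=tol)
            C = connectivity_matrix(factor_assignments(res.H))
            acc = C if acc is None else acc + C
        consensus = acc / n_restarts
        consensus_matrices[k] = consensus
        cophenetic[k] = cophenetic_coefficient(consensus)
    return RankSelection(list(k_range), cophenetic, consensus_matrices, sample_ids)


def cophenetic_coefficient(consensus: np.ndarray) -> float | None:
    """Cophenetic correlation of a consensus matrix.

    Pearson correlation between the off-diagonal entries of
    ``1 - consensus`` and the cophenetic distances induced by
    average-linkage hierarchical clustering of that distance matrix.
    Returns None (undefined) when either distance vector is constant.
    """
    consensus = np.asarray(consensus, dtype=float)
    if consensus.ndim != 2 or consensus.shape[0] != consensus.shape[1]:
        raise DataError("consensus must be square")
    if not np.allclose(consensus, consensus.T, atol=1e-12):
        raise DataError("consensus matrix must be symmetric")
    if (consensus < -1e-12).any() or (consensus > 1 + 1e-12).any():
        raise DataError("consensus entries must lie in [0, 1]")
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if condensed.std() == 0:
        return None
    Z = hierarchy.linkage(condensed, method="average")
    coph = hierarchy.cophenet(Z)
    if coph.std() == 0:
        return None
    r = np.corrcoef(condensed, coph)[0, 1]
    return float(r)


def exemplar_genes(
    result: NMFResult | np.ndarray,
    factor: int,
    n: int = 50,
    gene_ids: list[str] | None = None,
) -> list[str]:
    """Top ``n`` genes of one factor by descending loading.

    Ties are broken by lexicographic gene id. Requesting more genes than
    exist returns all of them with a warning.
    """
    if isinstance(result, NMFResult):
        W, gene_ids = result.W, result.gene_ids
    else:
        W = np.asarray(result)
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(W.shape[0])]
    if not 0 <= factor < W.shape[1]:
        raise DataError(f"factor index {factor} out of range")
    if n < 1:
        raise DataError("n must be >= 1")
    if n > W.shape[0]:
        import warnings

        warnings.warn(f"requested {n} exemplar genes but only {W.shape[0]} exist")
        n = W.shape[0]
    loadings = W[:, factor]
    order = sorted(range(len(gene_ids)), key=lambda i: (-loadings[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:n]]
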