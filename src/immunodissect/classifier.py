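"""Two-class marker discovery and nearest-template prediction.

Differential expression between the Immune and Nonimmune classes uses a
moderated t-statistic: per-gene pooled variances are shrunk toward a
prior variance whose scale and degrees of freedom are estimated by the
method of moments on the log sample variances, and the t-test gains the
prior degrees of freedom. Genes passing FDR < 0.05 and
|log2 fold change| >= 1.5 form the signed "Immune Classifier", which is
transferred to external cohorts by nearest-template prediction (NTP):
cosine distance of each standardized sample profile to signed +-1 class
templates, with significance from random gene-set null templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .dataio import DataError, ExpressionMatrix
from .subtyping import IMMUNE, NONIMMUNE


@dataclass
class DEResult:
    """Per-gene two-class differential-expression statistics."""

    table: pd.DataFrame  # index gene; log2_fc, t_stat, p, q, mean_<class>...
    classes: tuple[str, str]  # (positive, negative) for the fold change
    prior_df: float
    prior_var: float
    method: str


@dataclass
class ClassifierGeneSet:
    """Signed two-class marker list (the Immune Classifier)."""

    up_genes: list[str]  # markers of the positive (Immune) class
    down_genes: list[str]  # markers of the negative (Nonimmune) class
    stats: pd.DataFrame
    fdr_thresh: float
    lfc_thresh: float

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise DataError("up and down marker lists overlap")

    @property
    def genes(self) -> list[str]:
        return self.up_genes + self.down_genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "class": [IMMUNE] * len(self.up_genes)
                + [NONIMMUNE] * len(self.down_genes),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClassifierGeneSet":
        up = list(frame.loc[frame["class"] == IMMUNE, "gene"])
        down = list(frame.loc[frame["class"] == NONIMMUNE, "gene"])
        return cls(up, down, pd.DataFrame(), np.nan, np.nan)


@dataclass
class NTPResult:
    """Nearest-template class call per sample with permutation p-values."""

    table: pd.DataFrame  # sample; predicted_class, dist_*, p, q, confident
    classes: tuple[str, str]
    n_null: int
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def predicted(self) -> pd.Series:
        return self.table["predicted_class"]


def _moment_match_prior(log_s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df and variance from log sample variances.

    Under the hierarchical variance model, e_g = log s2_g follows a
    shifted log-F; matching the observed mean and variance of e_g to
    digamma/trigamma expressions yields (d0, s0^2). Infinite d0 (no
    excess dispersion) is capped at a large finite value.
    """
    e = log_s2 - special.digamma(df / 2) + np.log(df / 2)
    excess = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if excess <= 1e-8:
        d0 = 1e6  # essentially no gene-to-gene variance heterogeneity
    else:
        # solve trigamma(d0/2) = excess
        f = lambda x: special.polygamma(1, x / 2) - excess
        d0 = brentq(f, 1e-3, 1e7)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0_sq


def differential_expression(
    matrix: ExpressionMatrix,
    labels: pd.Series | dict,
    positive_class: str = IMMUNE,
    method: str = "moderated",
) -> DEResult:
    """Moderated-t differential expression between two classes.

    Expression is log2(x+1)-transformed internally. The fold change is
    ``positive_class`` minus the other class on the log2 scale.
    ``method``: "moderated" (empirical-Bayes variance shrinkage,
    default) or "welch" (plain Welch t-test).
    """
    labels = pd.Series(labels).loc[list(matrix.sample_ids)]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"expected exactly 2 classes, got {classes}")
    if positive_class not in classes:
        raise DataError(f"positive_class {positive_class!r} not in labels")
    negative_class = next(c for c in classes if c != positive_class)
    n1 = int((labels == positive_class).sum())
    n2 = int((labels == negative_class).sum())
    if min(n1, n2) < 2:
        raise DataError("both classes need at least 2 samples")

    X = matrix.log2p1().values
    g1 = X[:, (labels == positive_class).to_numpy()]
    g2 = X[:, (labels == negative_class).to_numpy()]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    diff = m1 - m2

    if method == "welch":
        t, p = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
        t = np.asarray(t)
        p = np.asarray(p)
        p = np.where(np.isnan(p), 1.0, p)  # zero variance, zero difference
        prior_df, prior_var = np.nan, np.nan
    elif method == "moderated":
        v1 = g1.var(axis=1, ddof=1)
        v2 = g2.var(axis=1, ddof=1)
        df_g = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_g
        positive = pooled > 0
        if positive.sum() >= 2:
            prior_df, prior_var = _moment_match_prior(
                np.log(pooled[positive]), df_g
            )
        else:
            prior_df, prior_var = 1e6, float(pooled[positive].mean() if positive.any() else 1.0)
        s2_tilde = (prior_df * prior_var + df_g * pooled) / (prior_df + df_g)
        se = np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / se, 0.0)
        df_total = min(prior_df + df_g, 1e6)
        p = 2 * stats.t.sf(np.abs(t), df_total)
        # zero variance in both groups with zero difference -> p = 1
        p = np.where((se == 0) & (diff == 0), 1.0, p)
    else:
        raise DataError(f"unknown method {method!r}")

    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2_fc": diff,
            "t_stat": t,
            "p": p,
            "q": q,
            f"mean_{positive_class}": m1,
            f"mean_{negative_class}": m2,
        },
        index=list(matrix.gene_ids),
    )
    return DEResult(
        table=table,
        classes=(positive_class, negative_class),
        prior_df=float(prior_df) if np.isfinite(prior_df) else prior_df,
        prior_var=float(prior_var) if np.isfinite(prior_var) else prior_var,
        method=method,
    )


def build_classifier(
    de: DEResult, fdr_thresh: float = 0.05, lfc_thresh: float = 1.5
) -> ClassifierGeneSet:
    """Select classifier genes: q < fdr_thresh and |log2 FC| >= lfc_thresh."""
    t = de.table
    if t.empty:
        raise DataError("empty differential-expression result")
    passed = (t["q"] < fdr_thresh) & (t["log2_fc"].abs() >= lfc_thresh)
    if not passed.any():
        near = t.assign(
            margin=np.maximum(t["q"] - fdr_thresh, 0)
            + np.maximum(lfc_thresh - t["log2_fc"].abs(), 0)
        ).nsmallest(5, "margin")
        raise DataError(
            "no gene passes the classifier thresholds; nearest misses:\n"
            + near[["log2_fc", "q"]].to_string()
        )
    sel = t[passed]
    up = sorted(sel.index[sel["log2_fc"] > 0])
    down = sorted(sel.index[sel["log2_fc"] < 0])
    return ClassifierGeneSet(up, down, sel.copy(), fdr_thresh, lfc_thresh)


def ntp_assign(
    matrix: ExpressionMatrix,
    classifier: ClassifierGeneSet,
    n_null: int = 1000,
    seed: int = 0,
    fdr_confident: float = 0.05,
    min_gene_fraction: float = 0.5,
) -> NTPResult:
    """Nearest-template prediction of the two classes in a cohort.

    Expression is log2(x+1)-transformed and standardized per gene
    across the cohort. Each class template is +1 on its own markers and
    -1 on the other class's markers (restricted to genes present in the
    cohort); a sample is assigned to the class with the smaller cosine
    distance (ties to the first class). Significance: ``n_null`` random
    gene sets of the same sizes drawn from all cohort genes build null
    templates; p = (1 + #{null min-distance <= observed}) / (1 + n_null),
    BH-adjusted across samples. Unconfident samples keep their label
    but are flagged.
    """
    if matrix.n_samples < 3:
        raise DataError("NTP needs >= 3 samples to standardize genes")
    present = set(matrix.gene_ids)
    up = [g for g in classifier.up_genes if g in present]
    down = [g for g in classifier.down_genes if g in present]
    frac = (len(up) + len(down)) / max(len(classifier.genes), 1)
    if frac < min_gene_fraction:
        raise DataError(
            f"only {frac:.0%} of classifier genes present "
            f"(minimum {min_gene_fraction:.0%})"
        )
    X = matrix.log2p1().values
    sd = X.std(axis=1, ddof=0)
    mu = X.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd[:, None] > 0, (X - mu[:, None]) / np.where(sd == 0, 1, sd)[:, None], 0.0)
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    def distances(up_idx: np.ndarray, down_idx: np.ndarray) -> np.ndarray:
        """(2, n_samples) cosine distances to the signed templates."""
        idx = np.concatenate([up_idx, down_idx])
        template = np.concatenate([np.ones(len(up_idx)), -np.ones(len(down_idx))])
        S = Z[idx, :]  # classifier genes x samples
        norm_s = np.linalg.norm(S, axis=0)
        norm_t = np.linalg.norm(template)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (template @ S) / np.where(norm_s == 0, 1, norm_s) / norm_t
        d_pos = 1 - cos  # template of the positive class
        d_neg = 1 + cos  # the opposite template is the negation
        return np.vstack([d_pos, d_neg])

    up_idx = np.array([gene_index[g] for g in up], dtype=int)
    down_idx = np.array([gene_index[g] for g in down], dtype=int)
    obs = distances(up_idx, down_idx)
    pred_idx = np.argmin(obs, axis=0)  # ties -> class 0 (Immune)
    obs_min = obs.min(axis=0)

    rng = np.random.default_rng(seed)
    null_min = np.empty((n_null, matrix.n_samples))
    all_idx = np.arange(matrix.n_genes)
    for b in range(n_null):
        pick = rng.choice(all_idx, size=len(up) + len(down), replace=False)
        null_min[b] = distances(pick[: len(up)], pick[len(up):]).min(axis=0)
    p = (1 + (null_min <= obs_min[None, :]).sum(axis=0)) / (1 + n_null)
    q = multipletests(p, method="fdr_bh")[1]

    classes = (IMMUNE, NONIMMUNE)
    table = pd.DataFrame(
        {
            "predicted_class": [classes[i] for i in pred_idx],
            f"dist_{IMMUNE}": obs[0],
            f"dist_{NONIMMUNE}": obs[1],
            "p": p,
            "q": q,
            "confident": q < fdr_confident,
        },
        index=list(matrix.sample_ids),
    )
    return NTPResult(
        table=table, classes=classes, n_null=n_null, seed=seed,
        params={"fdr_confident": fdr_confident, "genes_present": len(up) + len(down)},
    )
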