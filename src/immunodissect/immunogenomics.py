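"""Per-sample genomic burden statistics and class-association tests.

Covers tumor mutational burden (nonsynonymous mutations per megabase),
copy-number burden summaries by class, and the association statistics
used to compare subtype frequencies: chi-square (no continuity
correction), Fisher's exact test, Wilcoxon rank-sum, and Cramer's V.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError

NONSYNONYMOUS = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_ins",
        "frameshift_del",
        "inframe_ins",
        "inframe_del",
        "splice_site",
    }
)
VARIANT_CLASSES = NONSYNONYMOUS | {"silent", "other"}

#: MAF column names accepted case-insensitively when reading mutation TSVs.
MAF_COLUMNS = {
    "tumor_sample_barcode": "sample_id",
    "hugo_symbol": "gene",
    "variant_classification": "variant_class",
    "sample_id": "sample_id",
    "gene": "gene",
    "variant_class": "variant_class",
}

CNA_BURDEN_TYPES = ("arm_amp", "arm_del", "focal_amp", "focal_del")

DEFAULT_EXOME_MB = 38.0


@dataclass
class BurdenReport:
    """Per-class median/range plus rank-sum p for each burden type."""

    table: pd.DataFrame  # index burden type; median/range per class, p


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a MAF-minimal mutation TSV (columns matched case-insensitively)."""
    raw = pd.read_csv(Path(path), sep="\t")
    cols = {}
    for c in raw.columns:
        key = c.strip().lower()
        if key in MAF_COLUMNS:
            cols[c] = MAF_COLUMNS[key]
    table = raw.rename(columns=cols)
    missing = {"sample_id", "gene", "variant_class"} - set(table.columns)
    if missing:
        raise DataError(f"mutation table missing columns: {sorted(missing)}")
    table = table[["sample_id", "gene", "variant_class"]].astype(str)
    return validate_mutation_table(table)


def validate_mutation_table(table: pd.DataFrame) -> pd.DataFrame:
    unknown = sorted(set(table["variant_class"]) - VARIANT_CLASSES)
    if unknown:
        raise DataError(f"unknown variant classes: {unknown}")
    return table


def read_cna_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path), sep="\t")
    if "sample_id" not in table.columns:
        raise DataError("CNA table missing sample_id column")
    missing = set(CNA_BURDEN_TYPES) - set(table.columns)
    if missing:
        raise DataError(f"CNA table missing columns: {sorted(missing)}")
    table = table.set_index(table["sample_id"].astype(str))[list(CNA_BURDEN_TYPES)]
    if (table < 0).any().any():
        raise DataError("CNA counts must be nonnegative")
    if table.index.duplicated().any():
        raise DataError("CNA table must have one row per sample")
    return table


def tumor_mutational_burden(
    mutations: pd.DataFrame,
    exome_mb: float = DEFAULT_EXOME_MB,
    sample_ids: list[str] | None = None,
) -> pd.Series:
    """Nonsynonymous mutations per megabase, per sample.

    Silent and "other" variants are excluded. Samples listed in
    ``sample_ids`` but absent from the table get TMB 0.
    """
    if exome_mb <= 0:
        raise DataError("exome_mb must be positive")
    validate_mutation_table(mutations)
    nonsyn = mutations[mutations["variant_class"].isin(NONSYNONYMOUS)]
    counts = nonsyn.groupby("sample_id").size()
    if sample_ids is not None:
        counts = counts.reindex([str(s) for s in sample_ids], fill_value=0)
    else:
        counts = counts.reindex(sorted(mutations["sample_id"].unique()), fill_value=0)
    return (counts / exome_mb).rename("tmb")


def contingency_test(
    table: np.ndarray | pd.DataFrame, method: str = "chi-square"
) -> tuple[float, float]:
    """Association test on an r x c count table.

    "chi-square": Pearson statistic without continuity correction,
    (r-1)(c-1) df (a warning is emitted if any expected count < 5).
    "fisher": exact two-sided p by the point-probability rule (2x2
    only); the returned statistic is the odds ratio.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise DataError("contingency table must hold nonnegative integer counts")
    if method == "chi-square":
        chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
        if (expected < 5).any():
            import warnings

            warnings.warn(
                "chi-square expected count < 5; consider Fisher's exact test"
            )
        return float(chi2), float(p)
    if method == "fisher":
        if counts.shape != (2, 2):
            raise DataError("Fisher's exact test supports 2x2 tables only")
        odds, p = stats.fisher_exact(counts.astype(int), alternative="two-sided")
        return float(odds), float(p)
    raise DataError(f"unknown method {method!r}")


def rank_sum_compare(
    values: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test between two classes.

    Exact p for combined n <= 20 without ties, normal approximation
    with tie correction otherwise. Identical values everywhere give
    p = 1 by convention.
    """
    values = np.asarray(pd.Series(values), dtype=float)
    labels = np.asarray(pd.Series(labels))
    classes = np.unique(labels)
    if len(classes) != 2:
        raise DataError(f"expected 2 classes, got {list(classes)}")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) == 0 or len(b) == 0:
        raise DataError("both classes must be non-empty")
    if np.ptp(values) == 0:
        return float(len(a) * len(b) / 2), 1.0
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(values) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cramers_v(
    labels_a: pd.Series | np.ndarray, labels_b: pd.Series | np.ndarray
) -> float | None:
    """Cramer's V between two categorical labelings of the same samples.

    sqrt(chi2 / (n * min(r-1, c-1))) on the cross-tabulation; returns
    None (undefined) when either labeling has a single level.
    """
    a = pd.Series(labels_a).reset_index(drop=True)
    b = pd.Series(labels_b).reset_index(drop=True)
    if len(a) != len(b):
        raise DataError("labelings must cover the same samples")
    tab = pd.crosstab(a, b)
    r, c = tab.shape
    if min(r, c) < 2:
        return None
    chi2, _, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    n = tab.to_numpy().sum()
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


def class_burden_report(
    cna: pd.DataFrame, labels: pd.Series | dict
) -> BurdenReport:
    """Median, range and rank-sum p per CNA burden type, by class."""
    labels = pd.Series(labels)
    missing = [s for s in cna.index if s not in labels.index]
    if missing:
        raise DataError(f"labels missing for CNA samples: {missing[:5]}")
    labels = labels.loc[cna.index]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"expected 2 classes, got {classes}")
    rows = []
    for burden in CNA_BURDEN_TYPES:
        vals = cna[burden]
        row: dict = {"burden": burden}
        for c in classes:
            v = vals[labels == c]
            row[f"median_{c}"] = float(v.median())
            row[f"min_{c}"] = float(v.min())
            row[f"max_{c}"] = float(v.max())
        _, p = rank_sum_compare(vals, labels)
        row["p"] = p
        rows.append(row)
    return BurdenReport(pd.DataFrame(rows).set_index("burden"))


def gene_mutation_table(
    mutations: pd.DataFrame,
    labels: pd.Series,
    genes: list[str],
    per_gene_sample_pairs: bool = False,
) -> pd.DataFrame:
    """2x2 mutated/wild-type counts by class for a gene or gene panel.

    With ``per_gene_sample_pairs`` the unit is (gene, sample) pairs —
    the denominators are n_genes * class size — as used for pathway-
    level mutation comparisons.
    """
    labels = pd.Series(labels)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DataError(f"expected 2 classes, got {classes}")
    muts = mutations[
        mutations["gene"].isin(genes)
        & mutations["variant_class"].isin(NONSYNONYMOUS)
    ]
    rows = []
    for c in classes:
        samples = set(labels.index[labels == c])
        sub = muts[muts["sample_id"].isin(samples)]
        if per_gene_sample_pairs:
            mutated = len(sub.drop_duplicates(["sample_id", "gene"]))
            total = len(genes) * len(samples)
        else:
            mutated = sub["sample_id"].nunique()
            total = len(samples)
        rows.append({"class": c, "mutated": mutated, "wildtype": total - mutated})
    return pd.DataFrame(rows).set_index("class")
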