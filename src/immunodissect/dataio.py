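"""Tabular I/O and expression preprocessing.

The pipeline consumes nonnegative gene-by-sample expression matrices
(FPKM or microarray intensities), gene-set collections in GMT format,
and per-sample clinical / mutation / copy-number tables as plain TSV.
This module houses the containers for those inputs plus the standard
preprocessing steps: probe-to-gene collapsing, quantile normalization,
and filtering to the genes with the highest median expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of top-median-expression genes retained before factorization.
DEFAULT_TOP_GENES = 5000


class DataError(ValueError):
    """Raised when an input file or table violates its contract."""


@dataclass
class ExpressionMatrix:
    """Nonnegative gene-by-sample expression matrix.

    Parameters
    ----------
    values
        2-D float array, genes in rows, samples in columns. All entries
        must be finite and nonnegative.
    gene_ids
        Unique row identifiers (gene symbols or probe ids).
    sample_ids
        Unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise DataError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise DataError(
                f"negative value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to `genes`, in the given order; unknown genes error."""
        genes = list(genes)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows, :], genes, list(self.sample_ids))

    def log2p1(self) -> "ExpressionMatrix":
        """log2(x + 1) transform (used for clustering / DE / NTP stages)."""
        return ExpressionMatrix(
            np.log2(self.values + 1.0), list(self.gene_ids), list(self.sample_ids)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), duplicates within a set collapsed."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            uniq = list(dict.fromkeys(str(g) for g in genes))
            if not uniq:
                raise DataError(f"gene set {name!r} is empty")
            cleaned[name] = uniq
        self.sets = cleaned

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


CLINICAL_REQUIRED = ("sample_id", "time", "event")


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: unique samples, time > 0, event in {0,1}."""
    for col in CLINICAL_REQUIRED:
        if col not in table.columns:
            raise DataError(f"clinical table missing column {col!r}")
    table = table.copy()
    table["sample_id"] = table["sample_id"].astype(str)
    if table["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in clinical table")
    table["time"] = pd.to_numeric(table["time"])
    table["event"] = pd.to_numeric(table["event"])
    if (table["time"] <= 0).any():
        raise DataError("survival times must be strictly positive")
    if not table["event"].isin([0, 1]).all():
        raise DataError("event must be binary (0/1)")
    return table


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    dialect: str = "plain-tsv",
    collapse_duplicates: bool = False,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    Plain TSV: first column gene ids, remaining columns one per sample.
    GCT: two header lines, then Name/Description columns before samples.
    Duplicate gene rows raise unless ``collapse_duplicates`` requests
    mean-collapsing; missing values raise unless ``impute_missing``
    requests per-gene median imputation.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect == "plain-tsv":
        header_line = 0
        frame = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "gct":
        header_line = 2
        frame = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if frame.columns[0].lower() == "description":
            frame = frame.drop(columns=frame.columns[0])
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    # pandas mangles duplicate column names; check the raw header
    with open(path) as fh:
        for _ in range(header_line):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if dialect == "gct" and header and header[0].lower() == "description":
        header = header[1:]
    if len(set(header)) != len(header):
        raise DataError(f"duplicate sample ids in {path.name}")
    frame.index = frame.index.astype(str)
    frame.columns = [str(c) for c in header]
    frame = frame.apply(pd.to_numeric)
    if frame.isna().any().any():
        if impute_missing:
            med = frame.median(axis=1)
            frame = frame.apply(lambda col: col.fillna(med))
        else:
            gene = frame.index[frame.isna().any(axis=1)][0]
            raise DataError(
                f"missing values (first at gene {gene!r}); pass impute_missing=True "
                "for per-gene median imputation"
            )
    if frame.index.duplicated().any():
        if not collapse_duplicates:
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise DataError(
                f"duplicate gene rows {dupes[:5]}; pass collapse_duplicates=True"
            )
        frame = frame.groupby(level=0, sort=False).mean()
    return ExpressionMatrix.from_frame(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(Path(path), sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise DataError(f"duplicate gene-set name {name!r}")
        sets[name] = genes
        descriptions[name] = desc
    if not sets:
        raise DataError(f"empty GMT file: {path}")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(Path(path), sep="\t"))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def collapse_probes(
    matrix: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe rows mapping to the same gene symbol by mean expression.

    Probes absent from ``probe_map`` are dropped (count logged). An empty
    intersection between matrix rows and the map is an error.
    """
    mapped = [p for p in matrix.gene_ids if p in probe_map]
    if not mapped:
        raise DataError("no probe in the matrix appears in probe_map")
    n_dropped = matrix.n_genes - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_dropped)
    frame = matrix.to_frame().loc[mapped]
    frame.index = [probe_map[p] for p in mapped]
    collapsed = frame.groupby(level=0, sort=False).mean()
    return ExpressionMatrix.from_frame(collapsed)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples against each other.

    Every column is mapped onto the per-rank mean of the columns' order
    statistics, so all output columns share one multiset of values. Ties
    within a column receive the mean of the quantile values their ranks
    span, which keeps the map deterministic and idempotent.
    """
    if matrix.n_samples < 2:
        raise DataError("quantile normalization needs at least 2 samples")
    values = matrix.values
    # target distribution: mean across columns of each order statistic
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(col)
        ranked[order] = target
        # ties: average the target values spanned by each tied block
        sorted_col = col[order]
        i = 0
        n = len(col)
        while i < n:
            j2 = i
            while j2 + 1 < n and sorted_col[j2 + 1] == sorted_col[i]:
                j2 += 1
            if j2 > i:
                ranked[order[i : j2 + 1]] = target[i : j2 + 1].mean()
            i = j2 + 1
        out[:, j] = ranked
    return ExpressionMatrix(out, list(matrix.gene_ids), list(matrix.sample_ids))


def filter_top_genes(
    matrix: ExpressionMatrix, n: int = DEFAULT_TOP_GENES
) -> ExpressionMatrix:
    """Keep the ``n`` genes with the highest median expression across samples.

    Ties at the cutoff are broken by lexicographic gene id so the result
    is reproducible.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if n >= matrix.n_genes:
        return matrix
    medians = np.median(matrix.values, axis=1)
    order = sorted(
        range(matrix.n_genes), key=lambda i: (-medians[i], matrix.gene_ids[i])
    )
    keep = sorted(order[:n])  # preserve original row order
    return ExpressionMatrix(
        matrix.values[keep, :],
        [matrix.gene_ids[i] for i in keep],
        list(matrix.sample_ids),
    )
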