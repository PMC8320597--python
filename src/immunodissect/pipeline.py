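"""Composite discovery and validation workflows.

``run_discovery`` chains the full subtype-discovery path on one
training cohort: top-gene filtering -> NMF -> immune-factor selection
-> exemplar genes -> consensus clustering -> random-forest refinement
-> class naming -> differential expression -> classifier construction.
``run_validation`` transfers a classifier to external cohorts by
nearest-template prediction and summarizes the immune fractions.
Every stage is seeded and the configuration is serialized next to the
outputs so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import dataio, enrichment, nmf, subtyping

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryConfig:
    """Parameters of the discovery workflow (all stages seeded)."""

    seed: int
    k: int = 9
    top_genes: int = 5000
    exemplar_n: int = 50
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    consensus_k: int = 2
    n_resamples: int = 1000
    subsample_frac: float = 0.8
    n_trees: int = 500
    fdr_thresh: float = 0.05
    lfc_thresh: float = 1.5
    ssgsea_alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise dataio.DataError("discovery requires an explicit seed")


@dataclass
class DiscoveryResult:
    assignment: subtyping.SubtypeAssignment
    classifier: clf.ClassifierGeneSet
    nmf_result: nmf.NMFResult
    immune_factor: int
    factor_table: pd.DataFrame
    exemplars: list[str]
    immune_scores: pd.Series
    de: clf.DEResult
    config: DiscoveryConfig


def run_discovery(
    expression: dataio.ExpressionMatrix,
    immune_signature: list[str],
    config: DiscoveryConfig,
    out_dir: str | Path | None = None,
) -> DiscoveryResult:
    """Discover Immune/Nonimmune subtypes and build the classifier."""
    cfg = config
    logger.info("discovery: filtering to top %d genes by median", cfg.top_genes)
    filtered = dataio.filter_top_genes(expression, cfg.top_genes)

    logger.info("discovery: NMF at k=%d", cfg.k)
    res = nmf.nmf_factorize(
        filtered, cfg.k, seed=cfg.seed, max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol
    )

    immune_scores = enrichment.ssgsea_score(
        expression, immune_signature, alpha=cfg.ssgsea_alpha
    )
    factor, factor_table = subtyping.select_immune_factor(
        res.H, immune_scores, sample_ids=res.sample_ids
    )
    logger.info("discovery: immune factor = %d", factor)

    exemplars = nmf.exemplar_genes(res, factor, n=cfg.exemplar_n)
    exemplar_matrix = expression.subset_genes(exemplars)

    assignment = subtyping.assign_subtypes(
        exemplar_matrix,
        immune_scores,
        k=cfg.consensus_k,
        n_resamples=cfg.n_resamples,
        subsample_frac=cfg.subsample_frac,
        n_trees=cfg.n_trees,
        seed=cfg.seed,
        immune_factor=factor,
    )

    de = clf.differential_expression(expression, assignment.labels)
    gene_set = clf.build_classifier(de, cfg.fdr_thresh, cfg.lfc_thresh)

    result = DiscoveryResult(
        assignment=assignment,
        classifier=gene_set,
        nmf_result=res,
        immune_factor=factor,
        factor_table=factor_table,
        exemplars=exemplars,
        immune_scores=immune_scores,
        de=de,
        config=cfg,
    )
    if out_dir is not None:
        _write_discovery(result, Path(out_dir))
    return result


def _write_discovery(result: DiscoveryResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    a = result.assignment
    pd.DataFrame(
        {
            "consensus_label": a.consensus_labels,
            "refined_class": a.labels,
        }
    ).to_csv(out / "subtypes.tsv", sep="\t", index_label="sample_id")
    a.consensus_matrix.to_csv(out / "consensus_matrix.tsv", sep="\t")
    if a.confusion is not None:
        a.confusion.to_csv(out / "confusion_matrix.tsv", sep="\t")
    result.classifier.to_frame().to_csv(out / "classifier.tsv", sep="\t", index=False)
    result.de.table.to_csv(out / "differential_expression.tsv", sep="\t",
                           index_label="gene_id")
    W = pd.DataFrame(
        result.nmf_result.W,
        index=result.nmf_result.gene_ids,
        columns=[f"F{i+1}" for i in range(result.nmf_result.k)],
    )
    H = pd.DataFrame(
        result.nmf_result.H,
        index=[f"F{i+1}" for i in range(result.nmf_result.k)],
        columns=result.nmf_result.sample_ids,
    )
    W.to_csv(out / "nmf_W.tsv", sep="\t", index_label="gene_id")
    H.to_csv(out / "nmf_H.tsv", sep="\t", index_label="factor")
    result.factor_table.to_csv(out / "immune_factor_correlations.tsv", sep="\t")
    (out / "exemplar_genes.txt").write_text("\n".join(result.exemplars) + "\n")
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(result.config), indent=2) + "\n"
    )


@dataclass
class ValidationSummary:
    per_cohort: dict[str, clf.NTPResult]
    summary: pd.DataFrame  # cohort, n, n_immune, immune_fraction
    skipped: dict[str, str] = field(default_factory=dict)


def run_validation(
    gene_set: clf.ClassifierGeneSet,
    cohorts: dict[str, dataio.ExpressionMatrix],
    seed: int,
    n_null: int = 1000,
    quantile_norm: bool = False,
    out_dir: str | Path | None = None,
) -> ValidationSummary:
    """NTP-classify external cohorts; cohorts missing too many
    classifier genes are skipped with the reason logged."""
    results: dict[str, clf.NTPResult] = {}
    skipped: dict[str, str] = {}
    rows = []
    for i, (name, matrix) in enumerate(cohorts.items()):
        if quantile_norm:
            matrix = dataio.quantile_normalize(matrix)
        try:
            res = clf.ntp_assign(
                matrix, gene_set, n_null=n_null, seed=seed + i
            )
        except dataio.DataError as exc:
            logger.warning("validation: skipping cohort %s: %s", name, exc)
            skipped[name] = str(exc)
            continue
        results[name] = res
        n_immune = int((res.predicted == subtyping.IMMUNE).sum())
        rows.append(
            {
                "cohort": name,
                "n": matrix.n_samples,
                "n_immune": n_immune,
                "immune_fraction": n_immune / matrix.n_samples,
            }
        )
    summary = pd.DataFrame(rows, columns=["cohort", "n", "n_immune", "immune_fraction"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "validation_summary.tsv", sep="\t", index=False)
        for name, res in results.items():
            res.table.to_csv(out / f"ntp_{name}.tsv", sep="\t", index_label="sample_id")
    return ValidationSummary(results, summary, skipped)
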