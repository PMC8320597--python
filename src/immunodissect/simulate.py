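"""Synthetic bulk-expression cohorts with full ground truth.

The generator emulates the statistical structure the pipeline assumes:
bulk expression is a nonnegative mixture of latent expression programs
(two tumor programs, two stroma programs, one immune program) with
multiplicative lognormal noise; roughly 31% of samples are immune-high;
survival is exponential with a favorable hazard ratio for the
immune-high class (default 0.56) under independent uniform censoring;
mutation frequencies (e.g. SMAD4: 15.6% immune-high vs 32.7% otherwise)
and copy-number burdens are class-linked, as is tumor purity. Every
table shares sample ids and everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .dataio import (
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    read_expression_matrix,
    read_gmt,
    write_expression_matrix,
    write_gmt,
)

PROGRAMS = (
    "tumor_classical",
    "tumor_basal",
    "stroma_normal",
    "stroma_activated",
    "immune",
)

#: 12 WNT/beta-catenin pathway genes used for the pathway-level
#: gene-sample-pair mutation comparison.
WNT_GENES = (
    "APC", "CTNNB1", "AXIN1", "AXIN2", "TCF7L2", "WNT5A",
    "FZD1", "LRP5", "LRP6", "GSK3B", "DKK1", "RNF43",
)

NONSYN_CLASSES = (
    "missense", "nonsense", "frameshift_ins", "frameshift_del",
    "inframe_ins", "inframe_del", "splice_site",
)


def _default_mutation_probs() -> dict[str, tuple[float, float]]:
    """(immune-high, other) nonsynonymous mutation probability per gene."""
    probs: dict[str, tuple[float, float]] = {
        "SMAD4": (0.156, 0.327),
        "KRAS": (0.85, 0.85),
        "TP53": (0.60, 0.60),
        "CDKN2A": (0.20, 0.20),
    }
    for g in WNT_GENES:
        probs[g] = (3 / (45 * 12), 19 / (101 * 12))
    return probs


def _default_cna_rates() -> dict[str, tuple[float, float]]:
    """Poisson rates (immune-high, other) per burden type, chosen so the
    class medians land on 0/2/0/0 vs 3/7/0/9 events."""
    return {
        "arm_amp": (0.4, 3.2),
        "arm_del": (2.3, 7.3),
        "focal_amp": (0.4, 0.4),
        "focal_del": (0.4, 9.3),
    }


@dataclass
class GeneratorConfig:
    """Cohort-generator parameters (defaults are the study conditions)."""

    n_genes: int = 2000
    n_samples: int = 150
    markers_per_program: int = 60
    immune_fraction: float = 0.31
    noise_sd: float = 0.4  # lognormal sd on the natural-log scale
    marker_loading_shape: float = 4.0  # gamma shape of marker loadings
    background_loading: float = 0.05  # uniform ceiling for non-marker loadings
    immune_weight_mu: tuple[float, float] = (1.2, -1.2)  # lognormal mu (high, low)
    immune_weight_sd: tuple[float, float] = (0.3, 0.4)
    baseline_hazard: float = np.log(2) / 17.9  # per month; median 17.9 mo
    class_hr: float = 0.56  # hazard ratio of the immune-high class
    censoring_fraction: float = 0.35
    survival_dist: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.3
    mutation_probs: dict[str, tuple[float, float]] = field(
        default_factory=_default_mutation_probs
    )
    background_mutations: tuple[float, float] = (60.0, 40.0)  # mean counts
    cna_rates: dict[str, tuple[float, float]] = field(
        default_factory=_default_cna_rates
    )
    purity_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"immune": (2.5, 8.5), "other": (4.0, 6.0)}
    )

    def __post_init__(self) -> None:
        if not 0 < self.immune_fraction < 1:
            raise DataError("immune_fraction must lie in (0, 1)")
        if self.markers_per_program * len(PROGRAMS) > self.n_genes:
            raise DataError("markers_per_program x programs exceeds n_genes")
        if self.noise_sd < 0 or self.baseline_hazard <= 0 or self.class_hr <= 0:
            raise DataError("noise_sd >= 0, hazards > 0 required")
        for g, (p1, p2) in self.mutation_probs.items():
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise DataError(f"mutation probability out of [0,1] for {g}")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    true_W: pd.DataFrame  # genes x programs
    true_H: pd.DataFrame  # programs x samples
    true_labels: pd.Series  # bool: immune-high
    marker_gmt: GeneSetCollection
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    cna: pd.DataFrame
    config: GeneratorConfig
    seed: int


def _censoring_horizon(cfg: GeneratorConfig, p_immune: float) -> float:
    """Uniform-censoring horizon c with P(censored) = target fraction.

    For T ~ Exp(lam), C ~ U(0, c): P(C < T) = (1 - exp(-lam c))/(lam c);
    the mixture over the two classes is solved for c by bisection.
    """
    lam_imm = cfg.baseline_hazard * cfg.class_hr
    lam_non = cfg.baseline_hazard

    def censored_frac(c: float) -> float:
        def one(lam: float) -> float:
            return (1 - np.exp(-lam * c)) / (lam * c)

        return p_immune * one(lam_imm) + (1 - p_immune) * one(lam_non)

    target = cfg.censoring_fraction
    return brentq(lambda c: censored_frac(c) - target, 1e-3, 1e5)


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Draw one synthetic cohort; bit-identical under the same seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    K = len(PROGRAMS)
    n, g = cfg.n_samples, cfg.n_genes

    # --- gene names: markers per program, then background genes
    prefixes = {"tumor_classical": "TCL", "tumor_basal": "TBA",
                "stroma_normal": "SNO", "stroma_activated": "SAC",
                "immune": "IMM"}
    gene_ids: list[str] = []
    marker_sets: dict[str, list[str]] = {}
    for prog in PROGRAMS:
        names = [f"{prefixes[prog]}_{i:03d}" for i in range(cfg.markers_per_program)]
        if prog == "immune" and cfg.markers_per_program >= 2:
            names[0], names[1] = "GZMA", "PRF1"  # cytolytic-activity genes
        marker_sets[prog] = names
        gene_ids.extend(names)
    n_background = g - len(gene_ids)
    gene_ids.extend(f"BGD_{i:04d}" for i in range(n_background))

    # --- planted loadings W: exclusive gamma-high markers, low background
    W = rng.uniform(0, cfg.background_loading, size=(g, K))
    for j, prog in enumerate(PROGRAMS):
        lo = j * cfg.markers_per_program
        hi = lo + cfg.markers_per_program
        W[lo:hi, j] = rng.gamma(cfg.marker_loading_shape, 1.0, size=cfg.markers_per_program)

    # --- planted weights H; immune weights bimodal by immune-high flag
    labels = rng.random(n) < cfg.immune_fraction
    H = rng.lognormal(mean=0.0, sigma=0.5, size=(K, n))
    mu_hi, mu_lo = cfg.immune_weight_mu
    sd_hi, sd_lo = cfg.immune_weight_sd
    threshold = np.exp((mu_hi + mu_lo) / 2)
    imm = PROGRAMS.index("immune")
    w = np.where(
        labels,
        rng.lognormal(mu_hi, sd_hi, size=n),
        rng.lognormal(mu_lo, sd_lo, size=n),
    )
    # enforce: immune-high <-> immune weight above the threshold
    for _ in range(100):
        bad = np.where(labels, w <= threshold, w >= threshold)
        if not bad.any():
            break
        redraw_hi = bad & labels
        redraw_lo = bad & ~labels
        w[redraw_hi] = rng.lognormal(mu_hi, sd_hi, size=int(redraw_hi.sum()))
        w[redraw_lo] = rng.lognormal(mu_lo, sd_lo, size=int(redraw_lo.sum()))
    H[imm] = w

    sample_ids = [f"S{i:04d}" for i in range(n)]
    signal = W @ H
    noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=signal.shape)) if cfg.noise_sd > 0 else 1.0
    expression = ExpressionMatrix(signal * noise, gene_ids, sample_ids)

    # --- clinical: survival + covariates
    lam = cfg.baseline_hazard * np.where(labels, cfg.class_hr, 1.0)
    if cfg.survival_dist == "weibull":
        # proportional hazards Weibull: S(t) = exp(-lam t^shape)
        u = rng.random(n)
        T = (-np.log(u) / lam) ** (1 / cfg.weibull_shape)
    else:
        T = rng.exponential(1 / lam)
    horizon = _censoring_horizon(cfg, cfg.immune_fraction)
    C = rng.uniform(0, horizon, size=n)
    time = np.maximum(np.minimum(T, C), 1e-3)
    event = (T <= C).astype(int)
    purity = np.where(
        labels,
        rng.beta(*cfg.purity_beta["immune"], size=n),
        rng.beta(*cfg.purity_beta["other"], size=n),
    )
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": time,
            "event": event,
            "age": np.round(rng.normal(65, 10, size=n), 1),
            "sex": rng.choice(["F", "M"], size=n),
            "n_stage": rng.choice(["negative", "positive"], size=n, p=[0.35, 0.65]),
            "grade": rng.choice(["Moderate", "Poor"], size=n, p=[0.6, 0.4]),
            "purity": np.round(purity, 4),
        }
    )

    # --- mutations: driver genes by class probability + background load
    rows: list[tuple[str, str, str]] = []
    for gene, (p_imm, p_non) in cfg.mutation_probs.items():
        p = np.where(labels, p_imm, p_non)
        hit = rng.random(n) < p
        for i in np.where(hit)[0]:
            rows.append((sample_ids[i], gene, rng.choice(NONSYN_CLASSES)))
    mean_imm, mean_non = cfg.background_mutations
    bg_counts = rng.poisson(np.where(labels, mean_imm, mean_non))
    for i, count in enumerate(bg_counts):
        for _ in range(count):
            rows.append(
                (sample_ids[i], f"BGM_{rng.integers(0, 5000):04d}",
                 rng.choice(NONSYN_CLASSES))
            )
        for _ in range(rng.poisson(count * 0.25)):
            rows.append(
                (sample_ids[i], f"BGM_{rng.integers(0, 5000):04d}", "silent")
            )
    mutations = pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class"])

    # --- CNA burdens: class-specific Poisson rates
    cna = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for burden, (r_imm, r_non) in cfg.cna_rates.items():
        cna[burden] = rng.poisson(np.where(labels, r_imm, r_non))

    return SyntheticCohort(
        expression=expression,
        true_W=pd.DataFrame(W, index=gene_ids, columns=list(PROGRAMS)),
        true_H=pd.DataFrame(H, index=list(PROGRAMS), columns=sample_ids),
        true_labels=pd.Series(labels, index=sample_ids, name="immune_high"),
        marker_gmt=GeneSetCollection(
            {p: marker_sets[p] for p in PROGRAMS},
            {p: f"planted markers of the {p} program" for p in PROGRAMS},
        ),
        clinical=clinical,
        mutations=mutations,
        cna=cna,
        config=cfg,
        seed=seed,
    )


_FILES = {
    "expression": "expression.tsv",
    "markers": "markers.gmt",
    "clinical": "clinical.tsv",
    "mutations": "mutations.tsv",
    "cna": "cna.tsv",
    "true_W": "true_W.tsv",
    "true_H": "true_H.tsv",
    "true_labels": "true_labels.tsv",
    "config": "config.yaml",
}


def write_cohort(cohort: SyntheticCohort, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write every cohort table to ``directory`` in pipeline formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in _FILES.items()}
    if not overwrite:
        existing = [p.name for p in paths.values() if p.exists()]
        if existing:
            raise DataError(f"refusing to overwrite: {existing}; pass overwrite=True")
    write_expression_matrix(cohort.expression, paths["expression"])
    write_gmt(cohort.marker_gmt, paths["markers"])
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.cna.to_csv(paths["cna"], sep="\t", index=True)
    cohort.true_W.to_csv(paths["true_W"], sep="\t", index_label="gene_id")
    cohort.true_H.to_csv(paths["true_H"], sep="\t", index_label="program")
    cohort.true_labels.to_frame().assign(
        immune_high=lambda f: f["immune_high"].astype(int)
    ).to_csv(paths["true_labels"], sep="\t", index_label="sample_id")
    def plain(obj):
        # numpy scalars are not YAML-serializable
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    cfg = plain(asdict(cohort.config))
    cfg["seed"] = cohort.seed
    paths["config"].write_text(yaml.safe_dump(cfg), encoding="utf-8")
    return paths


def read_cohort_expression(directory: str | Path) -> ExpressionMatrix:
    return read_expression_matrix(Path(directory) / _FILES["expression"])


def read_cohort_markers(directory: str | Path) -> GeneSetCollection:
    return read_gmt(Path(directory) / _FILES["markers"])
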