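import numpy as np
import pandas as pd
import pytest

from immunodissect import ExpressionMatrix
from immunodissect.simulate import GeneratorConfig, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 genes x 2 samples with values 1..4."""
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0]]), ["gA", "gB"], ["s1", "s2"]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=150, 31% immune-high)."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for the cheaper statistical checks."""
    cfg = GeneratorConfig(n_genes=600, n_samples=80, markers_per_program=40)
    return generate_cohort(cfg, seed=11)


@pytest.fixture
def two_blob_matrix():
    """40 samples in two cleanly separated expression blobs (20 genes).

    Class A samples express genes 0-9 highly, class B genes 10-19; the
    planted labels are returned alongside.
    """
    rng = np.random.default_rng(5)
    n_per = 20
    X = rng.uniform(0.5, 1.5, size=(20, 2 * n_per))
    X[:10, :n_per] += 20.0
    X[10:, n_per:] += 20.0
    samples = [f"s{i:02d}" for i in range(2 * n_per)]
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=samples)
    return ExpressionMatrix(X, [f"g{i:02d}" for i in range(20)], samples), labels


def class_names(flags: pd.Series) -> pd.Series:
    """Map the generator's immune-high flags to class-name labels."""
    return flags.map({True: "Immune", False: "Nonimmune"})
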