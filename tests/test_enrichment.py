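import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunodissect import (
    DataError,
    ExpressionMatrix,
    cytolytic_activity,
    estimate_scores,
    score_panel,
    ssgsea_score,
)
from immunodissect.dataio import GeneSetCollection


def singleton_score_closed_form(n: int, position: int, alpha: float = 0.25) -> float:
    """Closed-form ssGSEA score when the set is one gene.

    With the in-set gene at descending-rank position ``position``
    (0-based), the in-set ECDF is 0 before it and 1 after; the
    out-of-set ECDF steps by 1/(n-1) at every other gene. Summing the
    difference over positions gives the score; alpha is irrelevant for
    a singleton.
    """
    total = 0.0
    ecdf_in = 0.0
    out_count = 0
    for pos in range(n):
        if pos == position:
            ecdf_in = 1.0
        else:
            out_count += 1
        total += ecdf_in - out_count / (n - 1)
    return total


def matrix_from_columns(cols: dict[str, list[float]], genes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(
        np.column_stack([cols[s] for s in cols]), genes, list(cols)
    )


class TestSsgseaScore:
    def test_three_gene_hand_example(self):
        m = matrix_from_columns({"s1": [3.0, 2.0, 1.0]}, ["top", "mid", "low"])
        score = ssgsea_score(m, ["top"], alpha=0.25)
        assert score["s1"] == pytest.approx(1.5)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 50, size=12)
        genes = [f"g{i}" for i in range(12)]
        m1 = matrix_from_columns({"s": list(x)}, genes)
        m2 = matrix_from_columns({"s": list(np.sqrt(x) + 3)}, genes)
        gene_set = ["g0", "g5", "g9"]
        assert ssgsea_score(m1, gene_set)["s"] == pytest.approx(
            ssgsea_score(m2, gene_set)["s"]
        )

    def test_top_gene_beats_bottom_gene(self):
        m = matrix_from_columns({"s": [5.0, 4.0, 3.0, 2.0, 1.0]}, list("abcde"))
        assert ssgsea_score(m, ["a"])["s"] > ssgsea_score(m, ["e"])["s"]

    @pytest.mark.parametrize("n", range(3, 11))
    def test_singleton_matches_closed_form_all_positions(self, n):
        genes = [f"g{i}" for i in range(n)]
        expr = list(float(v) for v in range(n, 0, -1))  # descending, no ties
        m = matrix_from_columns({"s": expr}, genes)
        for pos in range(n):
            score = ssgsea_score(m, [genes[pos]])["s"]
            assert score == pytest.approx(singleton_score_closed_form(n, pos))

    def test_full_coverage_and_empty_intersection_rejected(self):
        m = matrix_from_columns({"s": [1.0, 2.0]}, ["a", "b"])
        with pytest.raises(DataError):
            ssgsea_score(m, ["a", "b"])
        with pytest.raises(DataError):
            ssgsea_score(m, ["zz"])


class TestEstimateScores:
    def test_planted_immune_high_samples_score_higher(self, default_cohort):
        c = default_cohort
        scores = estimate_scores(
            c.expression, c.marker_gmt["immune"], c.marker_gmt["stroma_normal"]
        )
        imm = scores.loc[c.true_labels.values, "immune_score"]
        non = scores.loc[~c.true_labels.values, "immune_score"]
        assert imm.mean() > non.mean()

    def test_constant_expression_gives_identical_scores(self):
        m = ExpressionMatrix(
            np.full((6, 4), 2.0), [f"g{i}" for i in range(6)], list("wxyz")
        )
        s = ssgsea_score(m, ["g0", "g3"])
        assert s.nunique() == 1

    def test_equal_sets_give_equal_vectors(self, small_cohort):
        genes = small_cohort.marker_gmt["immune"][:10]
        out = estimate_scores(small_cohort.expression, genes, genes)
        pd.testing.assert_series_equal(
            out["immune_score"], out["stromal_score"], check_names=False
        )

    def test_exchangeable_noise_sets_equal_in_distribution(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(60)]
        m = ExpressionMatrix(
            rng.lognormal(0, 1, size=(60, 120)),
            genes,
            [f"s{j}" for j in range(120)],
        )
        a = ssgsea_score(m, genes[:15])
        b = ssgsea_score(m, genes[30:45])
        assert stats.ks_2samp(a, b).pvalue > 0.01


class TestCytolyticActivity:
    @pytest.mark.parametrize(
        "a,b,eps,expected", [(4, 9, 0, 6.0), (0, 0, 0.01, 0.01), (2, 8, 0, 4.0)]
    )
    def test_geometric_mean(self, a, b, eps, expected):
        m = ExpressionMatrix(
            np.array([[float(a)], [float(b)]]), ["GZMA", "PRF1"], ["s"]
        )
        assert cytolytic_activity(m, epsilon=eps)["s"] == pytest.approx(expected)

    def test_missing_gene_named_in_error(self):
        m = ExpressionMatrix(np.array([[1.0]]), ["GZMA"], ["s"])
        with pytest.raises(DataError, match="PRF1"):
            cytolytic_activity(m)


class TestScorePanel:
    def _panel(self):
        return GeneSetCollection({"sigA": ["g0", "g1"], "sigB": ["g4", "g5"]})

    def test_shape_and_labels(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(
            rng.uniform(1, 10, size=(8, 10)),
            [f"g{i}" for i in range(8)],
            [f"s{j}" for j in range(10)],
        )
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=m.sample_ids)
        out = score_panel(m, self._panel(), labels)
        assert out.scores.shape == (2, 10)
        assert set(out.pvalues.index) == {"sigA", "sigB"}

    def test_planted_separation_reaches_exact_minimal_p(self):
        # the signature genes rank near the top in class A and near the
        # bottom in class B (ssGSEA is rank-based within each sample,
        # so only rank positions matter); each sample gets distinct
        # positions so the eight scores are tie-free and completely
        # separated, making the exact two-sided rank-sum p the minimal
        # achievable for the group sizes: 2 / C(8, 4)
        n_a, n_b, n_genes = 4, 4, 10

        def sample_with_sig_at(p0: int, p1: int) -> list[float]:
            # expression vector placing g0 at descending-rank position
            # p0 and g1 at p1; higher position = lower expression
            free = [p for p in range(n_genes) if p not in (p0, p1)]
            pos = {0: p0, 1: p1}
            pos.update({g: free[i] for i, g in enumerate(range(2, n_genes))})
            return [float(n_genes - pos[g]) for g in range(n_genes)]

        genes = [f"g{i}" for i in range(n_genes)]
        cols = {}
        for j in range(n_a):
            cols[f"a{j}"] = sample_with_sig_at(0, 1 + j)
        for j in range(n_b):
            cols[f"b{j}"] = sample_with_sig_at(n_genes - 1, 5 + j)
        m = matrix_from_columns(cols, genes)
        labels = pd.Series(
            ["A"] * n_a + ["B"] * n_b, index=list(cols)
        )
        panel = GeneSetCollection({"sig": ["g0", "g1"]})
        out = score_panel(m, panel, labels)
        scores = out.scores.loc["sig"]
        assert scores.nunique() == n_a + n_b  # tie-free by construction
        assert scores[:n_a].min() > scores[n_a:].max()
        minimal_p = 2 / len(list(itertools.combinations(range(n_a + n_b), n_a)))
        assert out.pvalues["sig"] == pytest.approx(minimal_p)

    def test_identical_distributions_give_p_one(self):
        m = ExpressionMatrix(
            np.tile(np.arange(1.0, 7.0)[:, None], (1, 6)),
            [f"g{i}" for i in range(6)],
            [f"s{j}" for j in range(6)],
        )
        labels = pd.Series(["A", "B"] * 3, index=m.sample_ids)
        out = score_panel(m, self._panel().__class__({"sig": ["g0"]}), labels)
        assert out.pvalues["sig"] == pytest.approx(1.0)

    def test_tiny_class_flags_p_undefined(self):
        rng = np.random.default_rng(2)
        m = ExpressionMatrix(
            rng.uniform(1, 5, size=(6, 5)),
            [f"g{i}" for i in range(6)],
            [f"s{j}" for j in range(5)],
        )
        labels = pd.Series(["A"] + ["B"] * 4, index=m.sample_ids)
        out = score_panel(m, self._panel(), labels)
        assert out.pvalues.isna().all()
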