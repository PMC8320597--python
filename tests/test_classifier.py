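import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunodissect import (
    ClassifierGeneSet,
    DataError,
    ExpressionMatrix,
    build_classifier,
    differential_expression,
    ntp_assign,
)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Hand Benjamini-Hochberg: q_i = min over j>=rank(i) of p_(j)*m/j."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def two_class_matrix(n_genes=30, n_per=6, shift_genes=(), shift=2.0, seed=0,
                     noise=0.1):
    """Log-scale two-class cohort converted back to the raw scale."""
    rng = np.random.default_rng(seed)
    log_x = rng.normal(5, 1, size=(n_genes, 2 * n_per))
    log_x += rng.normal(0, noise, size=log_x.shape)
    for g in shift_genes:
        log_x[g, :n_per] += shift
    raw = 2.0**log_x - 1
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"a{j}" for j in range(n_per)] + [f"b{j}" for j in range(n_per)]
    labels = pd.Series(["Immune"] * n_per + ["Nonimmune"] * n_per, index=samples)
    return ExpressionMatrix(raw, genes, samples), labels


class TestDifferentialExpression:
    def test_noiseless_shift_gives_exact_log2_fc(self):
        log_x = np.tile(np.array([[3.0], [5.0]]), (1, 8))
        log_x[0, :4] += 2.0  # class Immune shifted by exactly 2 on log2 scale
        raw = 2.0**log_x - 1
        m = ExpressionMatrix(raw, ["g0", "g1"], [f"s{j}" for j in range(8)])
        labels = pd.Series(
            ["Immune"] * 4 + ["Nonimmune"] * 4, index=m.sample_ids
        )
        de = differential_expression(m, labels)
        assert de.table.loc["g0", "log2_fc"] == pytest.approx(2.0)
        assert de.table.loc["g1", "log2_fc"] == pytest.approx(0.0)

    def test_q_values_match_bh_oracle(self):
        matrix, labels = two_class_matrix(
            n_genes=40, shift_genes=(0, 1, 2), seed=3
        )
        de = differential_expression(matrix, labels)
        np.testing.assert_allclose(
            de.table["q"].to_numpy(),
            bh_oracle(de.table["p"].to_numpy()),
            atol=1e-12,
        )

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(11)
        n_genes, n = 1000, 40
        raw = 2.0 ** rng.normal(5, 1, size=(n_genes, n)) - 1
        m = ExpressionMatrix(
            raw, [f"g{i}" for i in range(n_genes)], [f"s{j}" for j in range(n)]
        )
        labels = pd.Series(
            rng.permutation(["Immune"] * 20 + ["Nonimmune"] * 20),
            index=m.sample_ids,
        )
        de = differential_expression(m, labels)
        frac = (de.table["p"] < 0.05).mean()
        # 3 binomial SDs around the nominal level
        sd = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) < 3 * sd + 0.01

    def test_zero_variance_zero_difference_gives_p_one(self):
        raw = np.vstack([np.full(8, 7.0), np.arange(1.0, 9.0)])
        m = ExpressionMatrix(raw, ["flat", "var"], [f"s{j}" for j in range(8)])
        labels = pd.Series(["Immune"] * 4 + ["Nonimmune"] * 4, index=m.sample_ids)
        de = differential_expression(m, labels)
        assert de.table.loc["flat", "p"] == pytest.approx(1.0)

    def test_welch_fallback_agrees_on_strong_signal(self):
        matrix, labels = two_class_matrix(shift_genes=(0,), shift=4.0, seed=5)
        mod = differential_expression(matrix, labels, method="moderated")
        welch = differential_expression(matrix, labels, method="welch")
        assert mod.table["q"].idxmin() == "g0"
        assert welch.table["q"].idxmin() == "g0"


class TestBuildClassifier:
    def _de_from_frame(self, frame):
        from immunodissect.classifier import DEResult

        return DEResult(frame, ("Immune", "Nonimmune"), 10.0, 1.0, "moderated")

    def test_threshold_logic(self):
        frame = pd.DataFrame(
            {
                "log2_fc": [1.6, 1.4, -1.8, 0.2],
                "t_stat": [5, 5, -6, 1],
                "p": [0.001, 0.001, 0.0005, 0.4],
                "q": [0.04, 0.04, 0.03, 0.5],
            },
            index=["up_pass", "fc_fail", "down_pass", "null"],
        )
        cls = build_classifier(self._de_from_frame(frame))
        assert cls.up_genes == ["up_pass"]
        assert cls.down_genes == ["down_pass"]

    def test_no_passing_gene_reports_near_misses(self):
        frame = pd.DataFrame(
            {
                "log2_fc": [1.0],
                "t_stat": [2.0],
                "p": [0.2],
                "q": [0.3],
            },
            index=["g"],
        )
        with pytest.raises(DataError, match="nearest miss"):
            build_classifier(self._de_from_frame(frame))


class TestNTP:
    def _classifier(self, up, down):
        return ClassifierGeneSet(up, down, pd.DataFrame(), 0.05, 1.5)

    def test_template_like_sample_gets_zero_distance(self):
        rng = np.random.default_rng(0)
        n = 20
        genes = [f"u{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
        # one sample per column; craft standardized pattern via many samples
        X = rng.lognormal(2, 0.3, size=(10, n))
        X[:5, 0] *= 50  # up genes high in sample 0
        X[5:, 0] /= 50
        m = ExpressionMatrix(X, genes, [f"s{j}" for j in range(n)])
        res = ntp_assign(
            m,
            self._classifier([f"u{i}" for i in range(5)], [f"d{i}" for i in range(5)]),
            n_null=50,
            seed=1,
        )
        assert res.predicted["s0"] == "Immune"
        assert res.table.loc["s0", "dist_Immune"] < res.table.loc["s0", "dist_Nonimmune"]

    def test_orthogonal_sample_ties_to_first_class(self):
        # cosine 0 to the template means distance 1 to both signed
        # templates; argmin ties resolve to the Immune class
        rng = np.random.default_rng(2)
        X = rng.lognormal(2, 0.5, size=(8, 10))
        m = ExpressionMatrix(X, [f"g{i}" for i in range(8)], [f"s{j}" for j in range(10)])
        res = ntp_assign(
            m, self._classifier(["g0", "g1"], ["g2", "g3"]), n_null=50, seed=0
        )
        d = res.table
        ties = d[np.isclose(d["dist_Immune"], d["dist_Nonimmune"])]
        assert (ties["predicted_class"] == "Immune").all()

    def test_invariant_to_per_gene_affine_rescaling(self, small_cohort):
        c = small_cohort
        up = c.marker_gmt["immune"][:20]
        down = c.marker_gmt["stroma_activated"][:5]
        cls = self._classifier(up, down)
        base = ntp_assign(c.expression, cls, n_null=100, seed=3)
        # per-gene affine rescale on the log2(x+1) scale: x -> (x+1)^a * b - 1
        rng = np.random.default_rng(7)
        a = rng.uniform(0.5, 2.0, size=c.expression.n_genes)
        b = rng.uniform(1.0, 2.0, size=c.expression.n_genes)  # keep x >= 0
        scaled_vals = (c.expression.values + 1) ** a[:, None] * b[:, None] - 1
        scaled = ExpressionMatrix(
            scaled_vals, list(c.expression.gene_ids), list(c.expression.sample_ids)
        )
        res = ntp_assign(scaled, cls, n_null=100, seed=3)
        pd.testing.assert_series_equal(base.predicted, res.predicted)
        np.testing.assert_allclose(
            base.table["dist_Immune"], res.table["dist_Immune"], atol=1e-9
        )

    def test_permutation_p_superuniform_under_noise(self):
        rng = np.random.default_rng(13)
        n_samples = 500
        X = rng.lognormal(3, 0.7, size=(60, n_samples))
        m = ExpressionMatrix(
            X, [f"g{i}" for i in range(60)], [f"s{j}" for j in range(n_samples)]
        )
        res = ntp_assign(
            m, self._classifier([f"g{i}" for i in range(10)],
                                [f"g{i}" for i in range(10, 15)]),
            n_null=200, seed=4,
        )
        p = res.table["p"].to_numpy()
        # super-uniform: the ECDF of p should not exceed the uniform's
        ks = stats.ks_1samp(p, stats.uniform.cdf, alternative="greater")
        assert ks.pvalue > 0.01

    def test_missing_genes_guard(self, small_cohort):
        cls = self._classifier(["absent1", "absent2"], ["absent3"])
        with pytest.raises(DataError, match="classifier genes present"):
            ntp_assign(small_cohort.expression, cls, n_null=10, seed=0)

    def test_round_trip_through_frame(self):
        cls = self._classifier(["u1", "u2"], ["d1"])
        back = ClassifierGeneSet.from_frame(cls.to_frame())
        assert back.up_genes == cls.up_genes
        assert back.down_genes == cls.down_genes
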