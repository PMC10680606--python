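"""Normalization and pairwise statistics against independent direct-formula oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import grnsup as g
from grnsup.errors import ParameterError
from grnsup.features import ROLE_TF_GENE, ROLE_TF_TF


# ----------------------------------------------------------- brute-force oracles
def cov_oracle(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / (len(x) - 1)


def pearson_oracle(x, y):
    return cov_oracle(x, y) / math.sqrt(cov_oracle(x, x) * cov_oracle(y, y))


def avg_ranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(avg_ranks(x), avg_ranks(y))


def mi_oracle(x, y, bins):
    def binof(v, vec):
        lo, hi = min(vec), max(vec)
        if hi == lo:
            return 0
        return min(int((v - lo) / (hi - lo) * bins), bins - 1)

    n = len(x)
    joint = {}
    for a, b in zip(x, y):
        key = (binof(a, x), binof(b, y))
        joint[key] = joint.get(key, 0) + 1
    px, py = {}, {}
    for (i, j), c in joint.items():
        px[i] = px.get(i, 0) + c
        py[j] = py.get(j, 0) + c
    total = 0.0
    for (i, j), c in joint.items():
        p = c / n
        total += p * math.log(p / (px[i] / n * py[j] / n))
    return total


class TestNormalize:
    def test_rows_are_zero_mean_unit_sd(self, rng):
        X = rng.gamma(2.0, 1.5, size=(8, 30))
        out = g.normalize(X)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-6)
        assert np.allclose(out.std(axis=1), 1, atol=1e-6)

    def test_strictly_positive_input_is_not_shifted(self, rng):
        # direct Box-Cox + z oracle on the unshifted rows
        X = rng.gamma(2.0, 1.5, size=(4, 25)) + 0.5
        out = g.normalize(X)
        for i in range(4):
            t, _ = sps.boxcox(X[i])
            assert np.allclose(out[i], (t - t.mean()) / t.std(), atol=1e-8)

    def test_nonpositive_input_uses_one_global_shift(self, rng):
        X = rng.gamma(2.0, 1.5, size=(4, 25))
        X[0, 0] = 0.0
        shifted = X + (1e-6 - X.min())
        expected = g.normalize(shifted)
        assert np.allclose(g.normalize(X), expected, atol=1e-10)

    def test_rank_order_preserved_per_row(self, rng):
        X = rng.gamma(2.0, 1.0, size=(5, 20))
        out = g.normalize(X)
        for i in range(5):
            assert np.array_equal(np.argsort(X[i]), np.argsort(out[i]))

    def test_constant_row_maps_to_zeros(self):
        X = np.vstack([np.full(10, 3.0), np.arange(10) + 1.0])
        out = g.normalize(X)
        assert np.allclose(out[0], 0)

    def test_too_few_conditions_error(self):
        with pytest.raises(ParameterError):
            g.normalize(np.ones((3, 2)))


@pytest.fixture(scope="module")
def small_norm():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((10, 20))
    ids = [f"TF{i}" for i in range(9)] + ["G0"]
    return g.ExpressionMatrix(X, ids, ["TF"] * 9 + ["G"]), X


class TestPairStats:
    def test_all_five_statistics_match_direct_formulas(self, small_norm):
        expr, X = small_norm
        tfs = [f"TF{i}" for i in range(9)]
        stats = g.pair_stats(expr, tfs, "G0", eps=1e-3, mi_bins=4)
        sigma = np.array([[cov_oracle(X[i], X[j]) for j in range(10)] for i in range(10)])
        from scipy.linalg import inv

        prec = inv(sigma + 1e-3 * np.eye(10))
        for i in range(10):
            for j in range(10):
                assert stats.cov[i, j] == pytest.approx(sigma[i, j], abs=1e-10)
                assert stats.precision[i, j] == pytest.approx(prec[i, j], abs=1e-8)
                assert stats.mi[i, j] == pytest.approx(mi_oracle(X[i], X[j], 4), abs=1e-6)
                if i != j:
                    assert stats.pearson[i, j] == pytest.approx(pearson_oracle(X[i], X[j]), abs=1e-10)
                    assert stats.spearman[i, j] == pytest.approx(spearman_oracle(X[i], X[j]), abs=1e-10)

    def test_symmetry_and_diagonals(self, small_norm):
        expr, _ = small_norm
        stats = g.pair_stats(expr, [f"TF{i}" for i in range(9)], "G0")
        for M in (stats.cov, stats.pearson, stats.spearman, stats.mi, stats.precision):
            assert np.allclose(M, M.T, atol=1e-10)
        assert np.allclose(np.diag(stats.pearson), 1)
        assert np.allclose(np.diag(stats.spearman), 1)
        assert (stats.mi >= -1e-12).all()

    def test_identity_covariance_precision_closed_form(self):
        # rows constructed with sample covariance exactly I -> (1+eps)^-1 * I
        rng = np.random.default_rng(0)
        m, n = 30, 6
        A = rng.standard_normal((m, n))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = (Q * np.sqrt(m - 1)).T
        ids = [f"TF{i}" for i in range(n - 1)] + ["G0"]
        expr = g.ExpressionMatrix(X, ids, ["TF"] * (n - 1) + ["G"])
        stats = g.pair_stats(expr, ids[:-1], "G0", eps=1e-3)
        assert np.allclose(stats.cov, np.eye(n), atol=1e-10)
        assert np.allclose(stats.precision, np.eye(n) / (1 + 1e-3), atol=1e-10)
        assert stats.precision[0, 0] == pytest.approx(0.999001, abs=1e-6)

    def test_monotone_nonlinear_relation(self):
        x = np.linspace(-2, 2, 20)
        X = np.vstack([x, x**3, np.random.default_rng(1).standard_normal(20)])
        expr = g.ExpressionMatrix(X, ["TF0", "TF1", "G0"], ["TF", "TF", "G"])
        stats = g.pair_stats(expr, ["TF0", "TF1"], "G0")
        assert stats.spearman[0, 1] == pytest.approx(1.0)
        assert stats.pearson[0, 1] < 1.0

    def test_per_gene_slicing_equals_direct_computation(self, rng):
        X = rng.standard_normal((8, 15))
        ids = [f"TF{i}" for i in range(5)] + [f"G{i}" for i in range(3)]
        expr = g.ExpressionMatrix(X, ids, ["TF"] * 5 + ["G"] * 3)
        tfs = ids[:5]
        batched = dict(g.pair_stats_per_gene(expr, tfs, ids[5:], eps=1e-3, mi_bins=3))
        for gene in ids[5:]:
            direct = g.pair_stats(expr, tfs, gene, eps=1e-3, mi_bins=3)
            got = batched[gene]
            for a, b in [(got.cov, direct.cov), (got.pearson, direct.pearson),
                         (got.spearman, direct.spearman), (got.mi, direct.mi),
                         (got.precision, direct.precision)]:
                assert np.allclose(a, b, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_condition_permutation_leaves_features_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((4, 12))
        ids = ["TF0", "TF1", "TF2", "G0"]
        perm = rng.permutation(12)
        a = g.pair_stats(g.ExpressionMatrix(X, ids, ["TF"] * 3 + ["G"]), ids[:3], "G0")
        b = g.pair_stats(g.ExpressionMatrix(X[:, perm], ids, ["TF"] * 3 + ["G"]), ids[:3], "G0")
        for Ma, Mb in [(a.cov, b.cov), (a.pearson, b.pearson), (a.spearman, b.spearman),
                       (a.mi, b.mi), (a.precision, b.precision)]:
            assert np.allclose(Ma, Mb, atol=1e-12)


class TestMutualInformation:
    def test_identical_distinct_vectors_reach_log_m(self):
        x = np.arange(8, dtype=float)
        assert g.mutual_information(x, x, mi_bins=8) == pytest.approx(np.log(8))

    def test_independence_limit(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(20_000), rng.random(20_000)
        assert g.mutual_information(x, y, mi_bins=4) < 0.01

    def test_symmetry(self, rng):
        x, y = rng.random(50), rng.random(50)
        assert g.mutual_information(x, y, 5) == pytest.approx(g.mutual_information(y, x, 5))

    def test_bad_bins_error(self):
        with pytest.raises(ParameterError):
            g.mutual_information(np.arange(5.0), np.arange(5.0), mi_bins=1)


@pytest.fixture(scope="module")
def stats_100():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((101, 10))
    ids = [f"TF{i}" for i in range(100)] + ["G0"]
    expr = g.ExpressionMatrix(X, ids, ["TF"] * 100 + ["G"])
    return g.pair_stats(expr, ids[:-1], "G0")


class TestAssembly:
    def test_sp_shape_and_roles(self, stats_100):
        inp = g.assemble_sp(stats_100, "TF7")
        assert inp.X.shape == (101, 5)
        assert inp.roles[0] == ROLE_TF_GENE and (inp.roles[1:] == ROLE_TF_TF).all()

    def test_sp_self_pair_row_has_unit_correlations(self, stats_100):
        inp = g.assemble_sp(stats_100, "TF7")
        self_row = inp.X[1 + 7]  # (TF7, TF7)
        assert self_row[1] == pytest.approx(1.0)  # Pearson
        assert self_row[2] == pytest.approx(1.0)  # Spearman

    def test_sp_rows_reindex_tensor_entries(self, stats_100):
        inp = g.assemble_sp(stats_100, "TF3")
        S = stats_100.stacked()
        assert np.array_equal(inp.X[0], S[3, 100])
        assert np.array_equal(inp.X[1:], S[3, :100])

    def test_ml_shape_and_row_count(self, stats_100):
        inp = g.assemble_ml(stats_100)
        assert inp.X.shape == (100 + 100 * 99 // 2, 5)  # 5050 x 5
        assert (inp.roles[:100] == ROLE_TF_GENE).all()
        assert (inp.roles[100:] == ROLE_TF_TF).all()

    def test_ml_tf_gene_rows_equal_sp_row0(self, stats_100):
        ml = g.assemble_ml(stats_100)
        for i in [0, 17, 99]:
            sp = g.assemble_sp(stats_100, f"TF{i}")
            assert np.array_equal(ml.X[i], sp.X[0])

    def test_ml_minimal_two_tfs(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((3, 8))
        expr = g.ExpressionMatrix(X, ["TF0", "TF1", "G0"], ["TF", "TF", "G"])
        inp = g.assemble_ml(g.pair_stats(expr, ["TF0", "TF1"], "G0"))
        assert inp.X.shape == (3, 5)

    def test_unknown_tf_errors(self, stats_100):
        with pytest.raises(g.ConsistencyError):
            g.assemble_sp(stats_100, "TF200")

    def test_feature_mask_zeroes_columns(self, stats_100):
        inp = g.assemble_sp(stats_100, "TF0", feature_mask=(0, 1, 0, 0, 0))
        assert (inp.X[:, [0, 2, 3, 4]] == 0).all()
        assert np.abs(inp.X[:, 1]).sum() > 0
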