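"""Geospatial baseline statistics and their permutation tests."""

import numpy as np
import pytest

from spacebf.baselines import (
    benchmark_grid,
    bivariate_moran,
    lees_l,
    make_weights,
    pearson_test,
    summarize_rejections,
)
from spacebf.simulate import grid_coords


SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestWeights:
    def test_knn_k1_square_links_each_to_one_neighbour(self):
        w = make_weights(SQUARE, "knn_binary", k=1)
        assert np.all(np.diag(w.W) == 0)
        assert set(np.unique(w.W)) <= {0.0, 1.0}
        assert np.array_equal(w.W, w.W.T)  # symmetrized by max
        assert np.all(w.W.sum(axis=1) >= 1)

    def test_delaunay_of_convex_quadrilateral_has_five_edges(self):
        # 2 triangles: 4 hull edges + 1 diagonal
        quad = np.array([[0.0, 0.0], [1.0, 0.0], [1.1, 1.0], [0.0, 1.05]])
        w = make_weights(quad, "delaunay_binary")
        assert w.W.sum() == 2 * 5  # symmetric: each edge counted twice

    def test_kernel_duplicate_points_weight_one(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        w = make_weights(coords, "exp_kernel", lengthscale=1.0)
        assert w.W[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(w.W) == 0)

    def test_delaunay_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError, match="Delaunay"):
            make_weights(pts, "delaunay_binary")


class TestBivariateMoran:
    def test_zero_weights_give_zero_statistic(self):
        w = make_weights(SQUARE, "exp_kernel", lengthscale=1.0)
        w.W[:] = 0.0
        stat, p = bivariate_moran([1, 2, 3, 4], [4, 3, 2, 1], w, n_perm=9, seed=0)
        assert stat == 0.0

    def test_matches_hand_computation_on_toy(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        y = np.array([2.0, 1.0, 3.0, 5.0])
        W = np.array(
            [
                [0, 1, 0, 1],
                [1, 0, 1, 0],
                [0, 1, 0, 1],
                [1, 0, 1, 0],
            ],
            dtype=float,
        )
        from spacebf.baselines import SpatialWeights

        w = SpatialWeights(W=W, kind="custom", params={})
        stat, _ = bivariate_moran(x, y, w, n_perm=9, seed=0)
        xs = (x - x.mean()) / x.std()
        ys = (y - y.mean()) / y.std()
        expected = sum(
            W[i, j] * xs[i] * ys[j] for i in range(4) for j in range(4)
        ) / W.sum()
        assert stat == pytest.approx(expected)

    def test_reduces_to_univariate_moran_when_inputs_equal(self):
        rng = np.random.default_rng(0)
        coords = rng.random((30, 2))
        x = rng.normal(0, 1, 30)
        w = make_weights(coords, "exp_kernel", lengthscale=0.3)
        stat, _ = bivariate_moran(x, x, w, n_perm=9, seed=0)
        xs = (x - x.mean()) / x.std()
        uni = xs @ w.W @ xs / w.W.sum()
        assert stat == pytest.approx(uni)

    def test_constant_input_raises(self):
        w = make_weights(SQUARE, "exp_kernel")
        with pytest.raises(ValueError, match="variance"):
            bivariate_moran([1, 1, 1, 1], [1, 2, 3, 4], w)


class TestLeesL:
    def test_zero_weights(self):
        w = make_weights(SQUARE, "exp_kernel")
        w.W[:] = 0.0
        stat, p = lees_l([1, 2, 3, 4], [4, 3, 2, 1], w, n_perm=9, seed=0)
        assert stat == 0.0

    def test_symmetric_in_inputs(self):
        rng = np.random.default_rng(1)
        coords = rng.random((25, 2))
        x = rng.normal(0, 1, 25)
        y = rng.normal(0, 1, 25)
        w = make_weights(coords, "knn_binary", k=2)
        a, _ = lees_l(x, y, w, n_perm=9, seed=0)
        b, _ = lees_l(y, x, w, n_perm=9, seed=0)
        assert a == pytest.approx(b)

    def test_matches_formula_oracle_and_self_smoothing_bound(self):
        rng = np.random.default_rng(2)
        coords = rng.random((20, 2))
        x = rng.normal(0, 1, 20)
        w = make_weights(coords, "knn_binary", k=3)
        stat, _ = lees_l(x, x, w, n_perm=9, seed=0)
        xs = (x - x.mean()) / x.std()
        n = 20
        oracle = (
            n
            / (w.W.sum(axis=1) ** 2).sum()
            * ((w.W @ xs) @ (w.W @ xs))
            / (np.sqrt(xs @ xs) * np.sqrt(xs @ xs))
        )
        assert stat == pytest.approx(oracle)
        assert stat >= 0.0  # self-smoothing cross product is a squared norm


class TestPearson:
    def test_identical_vectors(self):
        r, _ = pearson_test(np.arange(10.0), np.arange(10.0))
        assert r == pytest.approx(1.0)

    def test_orthogonal_pair(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        y = y - y.mean()
        r, _ = pearson_test(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        r, _ = pearson_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_test(np.ones(5), np.arange(5.0))


def test_permutation_tests_valid_on_iid_noise():
    """Without spatial structure, each baseline rejects at ~nominal rate."""
    rng = np.random.default_rng(0)
    coords = rng.random((60, 2)) * 10
    wd = make_weights(coords, "delaunay_binary")
    wk = make_weights(coords, "knn_binary", k=1)
    reps = 250
    rej = {"moran": 0, "lees": 0, "pearson": 0}
    for rep in range(reps):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0, 1, 60)
        rej["moran"] += bivariate_moran(x, y, wd, n_perm=199, seed=rep)[1] < 0.05
        rej["lees"] += lees_l(x, y, wk, n_perm=199, seed=rep)[1] < 0.05
        rej["pearson"] += pearson_test(x, y, "permutation", 199, seed=rep)[1] < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    for name, count in rej.items():
        assert abs(count / reps - 0.05) < 2.5 * se, (name, count / reps)


def test_benchmark_grid_smoke():
    coords = grid_coords(40, seed=0)
    res = benchmark_grid(
        designs=(1,),
        lengthscales=(3.6,),
        nus=(0.0, 0.5),
        n_reps=3,
        methods=("moran_delaunay", "pearson"),
        seed=1,
        coords=coords,
        n_perm=49,
    )
    assert len(res) == 2 * 3 * 2
    assert res["p"].between(0, 1).all()
    summary = summarize_rejections(res)
    assert {"rejection_rate", "binomial_se", "n_valid"} <= set(summary.columns)
    assert summary["rejection_rate"].between(0, 1).all()


def test_benchmark_grid_power_larger_se_shrinks_with_reps():
    # binomial SE halves (to within rounding) when reps quadruple
    import pandas as pd

    df = pd.DataFrame(
        {
            "design": 1,
            "lengthscale": 3.6,
            "nu": 0.0,
            "rep": range(100),
            "method": "pearson",
            "statistic": 0.0,
            "p": [0.01] * 50 + [0.5] * 50,
        }
    )
    s1 = summarize_rejections(df)
    s2 = summarize_rejections(pd.concat([df] * 4, ignore_index=True))
    assert s2["binomial_se"][0] == pytest.approx(s1["binomial_se"][0] / 2)
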