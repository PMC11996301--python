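"""SVC model fitting: Polya-Gamma weights, dispersion, sweeps, estimators."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from spacebf.graph import build_mst
from spacebf.models import (
    FitConfig,
    GaussianGibbsSVC,
    GaussianSVC,
    NBGibbsSVC,
    NegativeBinomialSVC,
    SpatialDataset,
    fit_gaussian_svc,
    fit_nb_svc,
    sample_pg_weights,
    update_dispersion,
)
from spacebf.simulate import SimulationSpec, grid_coords, simulate_design1


def pg_mean(b, z):
    return b / 4.0 if z == 0 else b * np.tanh(z / 2.0) / (2.0 * z)


class TestPolyaGamma:
    def test_mean_at_zero_tilt(self):
        rng = np.random.default_rng(0)
        om = sample_pg_weights(np.full(50000, 2), 1.0, np.zeros(50000), rng)
        assert om.mean() == pytest.approx(pg_mean(3.0, 0.0), rel=0.01)

    def test_mean_matches_closed_form(self):
        rng = np.random.default_rng(1)
        om = sample_pg_weights(np.full(50000, 2), 1.0, np.full(50000, 1.5), rng)
        assert om.mean() == pytest.approx(pg_mean(3.0, 1.5), rel=0.01)

    def test_degenerate_at_zero_shape(self):
        rng = np.random.default_rng(2)
        om = sample_pg_weights(np.zeros(100), 1e-10, np.ones(100), rng)
        assert np.all(om < 1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_pg_weights(np.array([1]), -1.0, np.array([0.0]), 0)
        with pytest.raises(ValueError):
            sample_pg_weights(np.array([-1]), 1.0, np.array([0.0]), 0)
        with pytest.raises(ValueError):
            sample_pg_weights(np.array([1]), 1.0, np.array([np.inf]), 0)


class TestDispersionUpdate:
    def test_prior_only_returns_prior_draws(self):
        rng = np.random.default_rng(0)
        draws = [
            update_dispersion(np.empty(0, dtype=int), np.empty(0), 1.0, 2.0, 3.0, rng)
            for _ in range(20000)
        ]
        assert np.mean(draws) == pytest.approx(2.0 / 3.0, rel=0.03)
        assert np.var(draws) == pytest.approx(2.0 / 9.0, rel=0.1)

    def test_zero_counts_keep_prior_shape(self):
        """With all-zero counts there are no tables: conditional is
        Gamma(prior_shape, prior_rate - n log(1 - psi))."""
        rng = np.random.default_rng(1)
        n = 50
        psi = np.full(n, 0.4)
        rate = 3.0 - n * np.log(0.6)
        draws = [
            update_dispersion(np.zeros(n, dtype=int), psi, 1.0, 2.0, 3.0, rng)
            for _ in range(20000)
        ]
        assert np.mean(draws) == pytest.approx(2.0 / rate, rel=0.05)

    def test_invalid_psi(self):
        with pytest.raises(ValueError):
            update_dispersion(np.array([1]), np.array([1.2]), 1.0)

    def test_recovers_unit_dispersion(self):
        """Posterior median of r near the generative value 1 on null data."""
        coords = grid_coords(293, seed=0)
        g = build_mst(coords)
        medians = []
        for seed in range(8):
            spec = SimulationSpec(
                design=1, lengthscale=3.6, nu=0.0, seed=seed, coords=coords
            )
            xm, xmp, _ = simulate_design1(spec)
            rng = np.random.default_rng(seed)
            s = NBGibbsSVC(xm.astype(float), np.log1p(xmp) - np.log1p(xmp).mean(), None, g, rng)
            rs = []
            for i in range(1200):
                s.step()
                if i >= 400:
                    rs.append(s.r)
            medians.append(np.median(rs))
        assert all(0.7 <= m <= 1.4 for m in medians)


class TestGaussianModel:
    def test_full_fusion_matches_ols(self):
        """Scales frozen near zero force constant surfaces: posterior means
        agree with ordinary least squares of y on x."""
        rng = np.random.default_rng(0)
        n = 60
        coords = rng.random((n, 2)) * 10
        x = rng.normal(0, 1, n)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.5, n)
        g = build_mst(coords)
        s = GaussianGibbsSVC(y, x, None, g, np.random.default_rng(1), update_scales=False)
        for sc in (s.scales0, s.scales1):
            sc.local[:] = 1e-12
            sc.global_ = 1e-12
        b0s, b1s = [], []
        for i in range(3000):
            s.step()
            if i >= 500:
                b0s.append(s.beta0.mean())
                b1s.append(s.beta1.mean())
        slope, intercept = np.polyfit(x, y, 1)
        assert np.mean(b0s) == pytest.approx(intercept, abs=1e-2)
        assert np.mean(b1s) == pytest.approx(slope, abs=1e-2)

    def test_recovers_constant_slope(self):
        rng = np.random.default_rng(3)
        n = 150
        coords = grid_coords(n, seed=3)
        x = rng.normal(0, 1, n)
        y = 0.3 + 0.5 * x + rng.normal(0, 1.0, n)
        est = GaussianSVC(
            n_iter=1500, n_burnin=500, thin=1, random_state=0,
            predictor_transform="identity",
        )
        est.fit(x, y, coords=coords)
        res = est.global_test()
        assert res.ci_lo <= 0.5 <= res.ci_hi

    def test_degenerate_predictor_raises(self):
        coords = grid_coords(20, seed=0)
        with pytest.raises(ValueError, match="zero variance"):
            GaussianSVC(n_iter=20, n_burnin=10, thin=1).fit(
                np.zeros(20), np.ones(20), coords=coords
            )

    def test_nan_input_raises(self):
        coords = grid_coords(20, seed=0)
        y = np.ones(20)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            GaussianSVC(n_iter=20, n_burnin=10, thin=1).fit(
                np.arange(20.0), y, coords=coords
            )


class TestNBModel:
    def test_non_integer_counts_raise(self):
        coords = grid_coords(20, seed=0)
        with pytest.raises(ValueError, match="integer"):
            NegativeBinomialSVC(n_iter=20, n_burnin=10, thin=1).fit(
                np.arange(20.0), np.full(20, 1.5), coords=coords
            )

    def test_all_zero_outcome_runs_and_finds_nothing(self):
        coords = grid_coords(30, seed=1)
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, 30)
        est = NegativeBinomialSVC(n_iter=400, n_burnin=200, thin=1, random_state=0)
        est.fit(x, np.zeros(30, dtype=int), coords=coords)
        res = est.global_test()
        assert not res.significant

    def test_bit_reproducible(self):
        coords = grid_coords(40, seed=2)
        spec = SimulationSpec(design=1, lengthscale=3.6, nu=0.5, seed=5, coords=coords)
        xm, xmp, _ = simulate_design1(spec)
        fits = []
        for _ in range(2):
            est = NegativeBinomialSVC(n_iter=300, n_burnin=100, thin=2, random_state=9)
            est.fit(xmp, xm, coords=coords)
            fits.append(est.samples_)
        assert np.array_equal(fits[0].beta1_draws, fits[1].beta1_draws)
        assert np.array_equal(fits[0].r_draws, fits[1].r_draws)

    def test_working_linearization_shares_gaussian_code_path(self):
        """At fixed omega the NB surface update is the Gaussian block update
        with precision omega and response kappa/omega."""
        coords = grid_coords(25, seed=4)
        g = build_mst(coords)
        rng = np.random.default_rng(0)
        x = rng.poisson(1.5, 25)
        y = rng.poisson(2.0, 25)
        t = x.astype(float)
        nb = NBGibbsSVC(y.astype(float), t, None, g, np.random.default_rng(6))
        ga = GaussianGibbsSVC(y.astype(float), t, None, g, np.random.default_rng(6))
        omega = np.full(25, 0.4)
        z = (y - 1.0) / (2 * omega)
        nb._draw_surfaces(z, omega, 1.0)
        ga.sigma2 = 1.0  # sigma enters the Gaussian prior scale; neutralize
        ga._draw_surfaces(z, omega, 1.0)
        assert np.array_equal(nb.beta0, ga.beta0)
        assert np.array_equal(nb.beta1, ga.beta1)

    def test_psi_link_identity(self):
        eta = np.linspace(-4, 4, 9)
        psi = expit(eta)
        assert np.all((psi > 0) & (psi < 1))
        assert expit(0.0) == 0.5


class TestRetention:
    def test_retained_draw_count_and_beta1_bar(self):
        coords = grid_coords(30, seed=0)
        spec = SimulationSpec(design=1, lengthscale=3.6, nu=0.0, seed=1, coords=coords)
        xm, xmp, _ = simulate_design1(spec)
        cfg = FitConfig(n_iter=200, n_burnin=100, thin=2, seed=0)
        data = SpatialDataset(coords=coords, x_m=xm, x_mprime=xmp)
        samples = fit_nb_svc(data, build_mst(coords), cfg)
        assert samples.n_draws == 50
        assert np.allclose(samples.beta1_bar_draws, samples.beta1_draws.mean(axis=1))


def _pinned_root_prior_draw(g, rng, level_sd, edge_sd):
    order, parent, parent_edge = g.elimination_order()
    beta = np.empty(g.n_nodes)
    beta[order[0]] = rng.normal(0, level_sd)
    for k in order[1:]:
        beta[k] = beta[parent[k]] + rng.normal(0, edge_sd)
    return beta


def test_simulation_based_calibration_of_the_gaussian_sampler():
    """Posterior quantiles of the true mean slope are uniform when data are
    generated from the (proper, pinned-root, fixed-scale) model itself."""
    n = 30
    coords = grid_coords(n, seed=8)
    g = build_mst(coords)
    level_sd = 2.0
    t_fixed = np.random.default_rng(99).normal(0, 1, n)
    ranks = []
    for rep in range(200):
        rng = np.random.default_rng(10_000 + rep)
        beta0 = _pinned_root_prior_draw(g, rng, level_sd, 1.0)
        beta1 = _pinned_root_prior_draw(g, rng, level_sd, 1.0)
        y = beta0 + beta1 * t_fixed + rng.normal(0, 1.0, n)
        s = GaussianGibbsSVC(
            y, t_fixed, None, g, rng,
            update_scales=False, update_sigma2=False,
            root_level_precision=1.0 / level_sd**2,
        )
        s.sigma2 = 1.0
        draws = []
        for i in range(300):
            s.step()
            if i >= 100:
                draws.append(s.beta1.mean())
        ranks.append(np.mean(np.asarray(draws) < beta1.mean()))
    stat, pval = stats.kstest(ranks, "uniform")
    assert pval > 0.05
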