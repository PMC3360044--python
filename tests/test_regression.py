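import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eivnpr.exceptions import DataError
from eivnpr.kernels import deconv_kernel
from eivnpr.regression import (BandwidthPlan, EIVDataset, bandwidth_factors,
                               cv_score, dataset_from_replicate_summaries,
                               dataset_from_summaries, fit, make_plan,
                               pilot_density, predict, select_bandwidth)
from eivnpr.array_data import MiRNASummary


def wls_oracle(x_eval, W, Y, h, sigma_u):
    """Brute-force local-linear solve from pairwise kernel evaluations."""
    out = []
    for x in np.atleast_1d(x_eval):
        z = (x - W) / h
        k0 = deconv_kernel(z, h, sigma_u, 0)
        k1 = deconv_kernel(z, h, sigma_u, 1) * h     # design in W units
        k2 = deconv_kernel(z, h, sigma_u, 2) * h * h
        S = np.array([[k0.sum(), k1.sum()], [k1.sum(), k2.sum()]])
        T = np.array([(k0 * Y).sum(), (k1 * Y).sum()])
        out.append(np.linalg.solve(S, T)[0])
    return np.array(out)


def fixed_plan(n, h):
    return BandwidthPlan(h0=h, alpha_sens=0.0, lam=np.ones(n))


class TestFit:
    def test_constant_reproduction_any_error(self):
        rng = np.random.default_rng(1)
        W = rng.normal(0, 1, 40)
        data = EIVDataset(W=W, Y=np.full(40, 3.25), sigma_u=np.full(40, 0.3))
        f = fit(data, fixed_plan(40, 0.5))
        assert np.max(np.abs(f.g_hat - 3.25)) < 1e-8

    def test_line_reproduction_error_free(self):
        rng = np.random.default_rng(2)
        W = rng.normal(0, 1, 100)
        data = EIVDataset(W=W, Y=2.0 + 3.0 * W, sigma_u=np.zeros(100))
        f = fit(data, fixed_plan(100, 0.4))
        assert np.max(np.abs(f.g_hat - (2.0 + 3.0 * f.grid))) < 1e-8

    @pytest.mark.parametrize("sigma", [0.0, 0.2])
    def test_matches_wls_oracle_on_toy_points(self, sigma):
        W = np.array([0.1, 0.5, 1.0, 1.4, 2.0])
        Y = np.array([1.0, 0.2, -0.5, 0.3, 1.1])
        su = np.full(5, sigma)
        x = np.linspace(0.1, 2.0, 33)
        ours = predict(EIVDataset(W, Y, su), fixed_plan(5, 0.8), x)
        assert np.max(np.abs(ours - wls_oracle(x, W, Y, 0.8, su))) < 1e-10

    def test_weights_reconstruct_fit_and_norm(self):
        rng = np.random.default_rng(3)
        W = rng.normal(0, 1, 60)
        Y = np.sin(W) + rng.normal(0, 0.1, 60)
        data = EIVDataset(W, Y, np.full(60, 0.1))
        f = fit(data, fixed_plan(60, 0.5))
        assert np.allclose(f.weights @ Y, f.g_hat)
        assert np.allclose(np.sqrt((f.weights ** 2).sum(axis=1)), f.l_norm)
        assert np.all(f.l_norm > 0)

    def test_grid_spans_data_range(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(2.0, 5.0, 30)
        data = EIVDataset(W, W.copy(), np.zeros(30))
        f = fit(data, fixed_plan(30, 0.6), grid_size=64)
        assert f.grid[0] == W.min() and f.grid[-1] == W.max()
        assert f.grid.size == 64


class TestPilotDensity:
    def test_error_free_equals_ordinary_kde(self):
        rng = np.random.default_rng(5)
        W = rng.normal(0, 1, 80)
        data = EIVDataset(W, np.zeros(80), np.zeros(80))
        f = pilot_density(data, 0.5)
        h = 0.5
        kde = np.array([
            deconv_kernel((w - W) / h, h, np.zeros(80), 0).sum() / (80 * h)
            for w in W
        ])
        assert np.allclose(f, np.maximum(kde, 1e-10), atol=1e-10)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(6)
        W = rng.normal(0, 1, 300)
        data = EIVDataset(W, np.zeros(300), np.full(300, 0.2))
        # evaluate on a wide grid through the same machinery
        from eivnpr.regression import _kernel_sum_matrices
        grid = np.linspace(-6, 6, 400)
        s0, _, _ = _kernel_sum_matrices(grid, W, np.full(300, 0.4),
                                        np.full(300, 0.2))
        dens = s0.mean(axis=1)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_deconvolution_beats_naive_kde(self):
        """With noisy W, the deconvolution density is closer (ISE) to the
        true predictor density than the naive KDE, on average."""
        from eivnpr.regression import _kernel_sum_matrices
        from scipy.stats import norm
        wins = 0
        n, su = 2000, 0.5
        grid = np.linspace(-3, 3, 121)
        truth = norm.pdf(grid)
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(0, 1, n)
            W = X + rng.normal(0, su, n)
            h = 0.35
            s_dec, _, _ = _kernel_sum_matrices(grid, W, np.full(n, h),
                                               np.full(n, su))
            s_nai, _, _ = _kernel_sum_matrices(grid, W, np.full(n, h),
                                               np.zeros(n))
            ise_dec = np.trapezoid((s_dec.mean(1) - truth) ** 2, grid)
            ise_nai = np.trapezoid((s_nai.mean(1) - truth) ** 2, grid)
            wins += ise_dec < ise_nai
        assert wins >= 8


class TestBandwidthFactors:
    def test_zero_sensitivity_is_fixed_bandwidth(self):
        assert np.allclose(bandwidth_factors(np.array([0.3, 1.0, 2.0]), 0.0), 1.0)

    def test_constant_density_gives_unit_factors(self):
        assert np.allclose(bandwidth_factors(np.full(5, 0.7), 0.9), 1.0)

    def test_two_point_example(self):
        lam = bandwidth_factors(np.array([1.0, 4.0]), 0.5)
        assert lam == pytest.approx([np.sqrt(2.0), 1.0 / np.sqrt(2.0)])

    @given(st.lists(st.floats(min_value=0.01, max_value=100.0),
                    min_size=2, max_size=30),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_geometric_mean_is_one(self, f, alpha):
        lam = bandwidth_factors(np.array(f), alpha)
        assert np.exp(np.mean(np.log(lam))) == pytest.approx(1.0, rel=1e-9)


class TestCV:
    def test_constant_response_scores_zero(self):
        rng = np.random.default_rng(7)
        W = rng.normal(0, 1, 50)
        data = EIVDataset(W, np.full(50, 2.0), np.full(50, 0.1))
        assert cv_score(data, 0.5, 0.5) == pytest.approx(0.0, abs=1e-18)

    def test_error_free_equals_direct_refit_oracle(self):
        """Exact leave-one-out must match brute-force per-i refits."""
        rng = np.random.default_rng(8)
        n = 30
        W = rng.normal(0, 1, n)
        Y = np.sin(2 * W) + rng.normal(0, 0.2, n)
        data = EIVDataset(W, Y, np.zeros(n))
        h = 0.45
        direct = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            g_i = wls_oracle(W[i], W[keep], Y[keep], h, np.zeros(n - 1))[0]
            direct += (Y[i] - g_i) ** 2
        assert cv_score(data, h, 0.0) == pytest.approx(direct, rel=1e-8)

    def test_cv_minimizer_beats_worst_in_rmise(self):
        """On a smooth curve the CV-chosen bandwidth outperforms the worst
        grid bandwidth in RMISE, aggregated over replicates."""
        h_grid = np.geomspace(0.05, 1.2, 8)
        g = lambda x: np.sin(2 * x)
        diffs = []
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            W = rng.normal(0, 1, 200)
            Y = g(W) + rng.normal(0, 0.3, 200)
            data = EIVDataset(W, Y, np.zeros(200))
            scores = [cv_score(data, float(h), 0.0) for h in h_grid]
            h_best = h_grid[int(np.argmin(scores))]
            h_worst = h_grid[int(np.argmax(scores))]
            grid = np.linspace(-1.5, 1.5, 50)
            rmise = {}
            for h in (h_best, h_worst):
                g_hat = predict(data, fixed_plan(200, float(h)), grid)
                rmise[h] = np.sqrt(np.mean((g_hat - g(grid)) ** 2))
            diffs.append(rmise[h_best] - rmise[h_worst])
        assert np.median(diffs) < 0


class TestSelectBandwidth:
    def test_single_grid_point_returned(self):
        rng = np.random.default_rng(9)
        W = rng.normal(0, 1, 40)
        data = EIVDataset(W, np.sin(W), np.zeros(40))
        plan = select_bandwidth(data, h0_grid=[0.33], alpha_grid=[0.5])
        assert plan.h0 == 0.33 and plan.alpha_sens == 0.5

    def test_ties_prefer_larger_h0(self):
        # constant Y makes every score exactly zero
        rng = np.random.default_rng(10)
        W = rng.normal(0, 1, 40)
        data = EIVDataset(W, np.full(40, 1.0), np.zeros(40))
        plan = select_bandwidth(data, h0_grid=[0.2, 0.4, 0.8], alpha_grid=[0.0])
        assert plan.h0 == 0.8

    def test_selection_consistent_with_cv_surface(self):
        rng = np.random.default_rng(11)
        W = rng.normal(0, 1, 60)
        Y = np.cos(W) + rng.normal(0, 0.2, 60)
        data = EIVDataset(W, Y, np.zeros(60))
        h0s, alphas = [0.3, 0.6], [0.0, 0.5]
        surface = {(h, a): cv_score(data, h, a) for h in h0s for a in alphas}
        plan = select_bandwidth(data, h0_grid=h0s, alpha_grid=alphas)
        assert surface[(plan.h0, plan.alpha_sens)] == min(surface.values())

    def test_empty_grid_rejected(self):
        data = EIVDataset(np.arange(12.0), np.arange(12.0), np.zeros(12))
        with pytest.raises(DataError):
            select_bandwidth(data, h0_grid=[], alpha_grid=[0.0])


class TestDatasetBuilders:
    def test_pair_join_on_shared_ids(self):
        ctrl = [MiRNASummary("a", 4, 1.0, 0.1), MiRNASummary("b", 4, 2.0, 0.2)]
        trt = [MiRNASummary("b", 4, 2.5, 0.3), MiRNASummary("c", 4, 3.0, 0.1)]
        d = dataset_from_summaries(ctrl, trt)
        assert d.mirna_ids == ["b"]
        assert d.W[0] == 2.0 and d.Y[0] == 2.5 and d.sigma_u[0] == 0.2

    def test_replicate_pooling_means_and_se(self):
        ctrl = [[MiRNASummary("a", 4, 1.0, 0.1)],
                [MiRNASummary("a", 4, 3.0, 0.1)]]
        trt = [[MiRNASummary("a", 4, 2.0, 0.1)],
               [MiRNASummary("a", 4, 4.0, 0.1)]]
        d = dataset_from_replicate_summaries(ctrl, trt)
        assert d.W[0] == pytest.approx(2.0)
        assert d.Y[0] == pytest.approx(3.0)
        assert d.sigma_u[0] == pytest.approx(np.std([1.0, 3.0], ddof=1) / np.sqrt(2))

    def test_no_overlap_is_an_error(self):
        with pytest.raises(DataError):
            dataset_from_summaries([MiRNASummary("a", 1, 1.0, 0.0)],
                                   [MiRNASummary("b", 1, 1.0, 0.0)])
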