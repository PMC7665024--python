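import numpy as np
import pytest

from deerflex import (
    BackgroundModel,
    DistanceDistribution,
    InversionConfig,
    build_kernel,
    correct_trace,
    fit_background,
    invert,
    mem_refine,
    mode_distance,
    select_alpha,
    tikhonov_path,
    tikhonov_solve,
)
from deerflex.errors import (
    ConvergenceWarning,
    DegenerateModulationError,
    InsufficientTailError,
    PathIntegrityError,
)
from deerflex.inversion import DipolarSignal, RegularizationPath, second_difference_operator


class TestBackground:
    def test_round_trip_recovery(self, simulated_trace):
        trace, _, _ = simulated_trace(lam=0.3, k=0.05)
        bg, _ = fit_background(trace, 0.6)
        assert bg.lam == pytest.approx(0.3, abs=0.02)
        assert bg.k == pytest.approx(0.05, rel=0.05)

    def test_pure_background_gives_zero_depth(self):
        t = np.linspace(0, 3, 128)
        trace_v = np.exp(-0.06 * t)
        from deerflex import DeerTrace

        bg, _ = fit_background(DeerTrace(t=t, v=trace_v), 0.6)
        assert bg.lam < 0.02

    def test_flat_background_recovers_zero_rate(self, simulated_trace):
        trace, _, _ = simulated_trace(lam=0.4, k=0.0)
        bg, _ = fit_background(trace, 0.6)
        assert bg.k < 1e-3

    def test_short_tail_rejected(self, simulated_trace):
        trace, _, _ = simulated_trace(n_points=64, t_max=1.0)
        from deerflex import DeerTrace

        short = DeerTrace(t=trace.t[:16], v=trace.v[:16])
        with pytest.raises(InsufficientTailError):
            fit_background(short, 0.9)


class TestCorrectTrace:
    def test_inverts_composition_exactly(self, simulated_trace, grid):
        from deerflex import form_factor

        trace, truth, bg = simulated_trace(lam=0.3, k=0.05)
        F = form_factor(build_kernel(trace.t, grid), truth)
        sig = correct_trace(trace, bg, 0.0)
        assert np.allclose(sig.s, F, atol=1e-9)

    def test_identity_when_full_depth_no_background(self, simulated_trace):
        trace, _, _ = simulated_trace(lam=1.0, k=0.0)
        sig = correct_trace(trace, BackgroundModel(k=0.0, lam=1.0), 0.0)
        assert np.allclose(sig.s, trace.v, atol=1e-12)

    def test_degenerate_depth_rejected(self, simulated_trace):
        trace, _, _ = simulated_trace()
        with pytest.raises(DegenerateModulationError):
            correct_trace(trace, BackgroundModel(k=0.05, lam=0.005))

    def test_noisy_start_value_within_propagated_error(self, simulated_trace):
        """s(0) stays within 3 sigma/lambda of 1 for nearly all noisy traces."""
        lam, sigma = 0.3, 0.01
        ok = 0
        for seed in range(50):
            trace, _, bg = simulated_trace(lam=lam, k=0.05, noise_sigma=sigma, seed=seed)
            sig = correct_trace(trace, bg, sigma)
            ok += abs(sig.s[0] - 1.0) <= 3 * sigma / lam
        assert ok >= 47  # 3-sigma events are ~0.3% per trace


class TestTikhonov:
    def test_smooth_gaussian_round_trip(self, simulated_trace, coarse_config):
        trace, truth, bg = simulated_trace(lam=0.35, k=0.04)
        sig = correct_trace(trace, bg, 0.0)
        kern = build_kernel(trace.t, coarse_config.grid())
        dist, rho, eta = tikhonov_solve(sig, kern, alpha=1e-3)
        assert abs(mode_distance(dist) - 3.5) <= 0.06
        assert rho >= 0 and eta >= 0

    def test_zero_signal_flagged_empty(self, coarse_config):
        t = np.linspace(0, 3, 64)
        sig = DipolarSignal(t=t, s=np.zeros_like(t), sigma_est=0.01)
        kern = build_kernel(t, coarse_config.grid())
        dist, rho, _ = tikhonov_solve(sig, kern, alpha=1.0)
        assert dist.is_empty
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_seminorm_antitone_in_alpha(self, simulated_trace, coarse_config):
        trace, _, bg = simulated_trace(noise_sigma=0.01, seed=4)
        sig = correct_trace(trace, bg, 0.01)
        kern = build_kernel(trace.t, coarse_config.grid())
        _, _, eta_lo = tikhonov_solve(sig, kern, alpha=1e-4)
        _, _, eta_hi = tikhonov_solve(sig, kern, alpha=1e4)
        assert eta_hi < eta_lo

    def test_path_monotonicity(self, simulated_trace, coarse_config):
        trace, _, bg = simulated_trace(noise_sigma=0.012, seed=8)
        sig = correct_trace(trace, bg, 0.012)
        kern = build_kernel(trace.t, coarse_config.grid())
        path = tikhonov_path(sig, kern, coarse_config.alphas())
        tol_r = 1e-10 * path.rho.max()
        tol_e = 1e-10 * path.eta.max()
        assert np.all(np.diff(path.rho) >= -tol_r)
        assert np.all(np.diff(path.eta) <= tol_e)

    def test_second_difference_operator_shape(self):
        L = second_difference_operator(5)
        assert np.allclose(L[0], 0) and np.allclose(L[-1], 0)
        assert np.allclose(L[2], [0, 1, -2, 1, 0])


def _path_from_arrays(alphas, rho, eta, grid):
    flat = DistanceDistribution.normalized(grid, np.ones(grid.n))
    return RegularizationPath(
        alphas=np.asarray(alphas, float),
        rho=np.asarray(rho, float),
        eta=np.asarray(eta, float),
        solutions=tuple([flat] * len(alphas)),
    )


class TestSelectAlpha:
    def test_single_entry_path(self, grid):
        path = _path_from_arrays([0.5], [1.0], [1.0], grid)
        assert select_alpha(path) == 0.5

    def test_two_identical_entries_tie_break_to_larger(self, grid):
        path = _path_from_arrays([0.5, 2.0], [1.0, 1.0], [1.0, 1.0], grid)
        assert select_alpha(path) == 2.0

    def test_non_monotone_path_rejected(self, grid):
        path = _path_from_arrays(
            [0.1, 1.0, 10.0], [1.0, 0.5, 2.0], [3.0, 2.0, 1.0], grid
        )
        with pytest.raises(PathIntegrityError):
            select_alpha(path)

    def test_corner_within_decade_of_rmse_oracle(self, simulated_trace, coarse_config):
        """On noisy traces the selected alpha is near the alpha that a
        brute-force scan against the known truth would pick."""
        hits = 0
        for seed in range(10):
            trace, truth, bg = simulated_trace(
                components=((1.0, 3.2 + 0.15 * seed, 0.35),),
                lam=0.3,
                k=0.05,
                noise_sigma=0.01,
                seed=seed,
            )
            sig = correct_trace(trace, bg, 0.01)
            kern = build_kernel(trace.t, coarse_config.grid())
            path = tikhonov_path(sig, kern, coarse_config.alphas())
            truth_c = DistanceDistribution.from_gaussian_mixture(
                coarse_config.grid(), [(1.0, 3.2 + 0.15 * seed, 0.35)]
            )
            rmse = [np.sqrt(np.mean((s.p - truth_c.p) ** 2)) for s in path.solutions]
            a_best = path.alphas[int(np.argmin(rmse))]
            a_sel = select_alpha(path)
            hits += abs(np.log10(a_sel / a_best)) <= 1.0
        assert hits >= 8


class TestMem:
    def test_uninformative_data_returns_prior(self, coarse_config, simulated_trace):
        trace, _, bg = simulated_trace()
        kern = build_kernel(trace.t, coarse_config.grid())
        prior = DistanceDistribution.from_gaussian_mixture(
            coarse_config.grid(), [(1.0, 4.0, 0.5)]
        )
        sig = DipolarSignal(t=trace.t, s=np.ones_like(trace.t), sigma_est=1e6)
        with pytest.warns(ConvergenceWarning):
            out = mem_refine(sig, kern, prior)
        tv = 0.5 * np.sum(np.abs(out.p - prior.p)) * coarse_config.grid().dr
        assert tv < 0.02

    def test_noiseless_uniform_prior_recovers_mode(self, simulated_trace, coarse_config):
        from deerflex import form_factor

        trace, truth, bg = simulated_trace(lam=1.0, k=0.0)
        g = coarse_config.grid()
        kern = build_kernel(trace.t, g)
        sig = DipolarSignal(t=trace.t, s=trace.v, sigma_est=1e-5)
        uniform = DistanceDistribution.normalized(g, np.ones(g.n))
        out = mem_refine(sig, kern, uniform)
        assert abs(mode_distance(out) - 3.5) <= 0.06

    def test_output_nonnegative_and_normalized(self, simulated_trace, coarse_config):
        g = coarse_config.grid()
        kern_cache = {}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu = rng.uniform(2.8, 4.5)
            trace, _, bg = simulated_trace(
                components=((1.0, mu, 0.3),), noise_sigma=0.01, seed=seed
            )
            sig = correct_trace(trace, bg, 0.01)
            key = len(trace.t)
            if key not in kern_cache:
                kern_cache[key] = build_kernel(trace.t, g)
            prior = DistanceDistribution.from_gaussian_mixture(g, [(1.0, mu, 0.4)])
            out = mem_refine(sig, kern_cache[key], prior)
            assert np.all(out.p >= 0)
            assert np.sum(out.p) * g.dr == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_refinement_never_worsens_fit(self, simulated_trace, coarse_config):
        trace, truth, bg = simulated_trace(lam=0.3, k=0.05)
        g = coarse_config.grid()
        sig = correct_trace(trace, bg, 0.0)
        kern = build_kernel(trace.t, g)
        path = tikhonov_path(sig, kern, coarse_config.alphas())
        alpha = select_alpha(path)
        prior = path.solutions[int(np.argmin(np.abs(path.alphas - alpha)))]
        A = kern.K * g.dr
        out = mem_refine(sig, kern, prior)
        chi_prior = np.sum((A @ prior.p - sig.s) ** 2)
        chi_mem = np.sum((A @ out.p - sig.s) ** 2)
        assert chi_mem <= chi_prior * (1 + 1e-9)


class TestInvertPipeline:
    def test_deterministic(self, simulated_trace, coarse_config):
        trace, _, _ = simulated_trace(noise_sigma=0.01, seed=3)
        r1 = invert(trace, coarse_config)
        r2 = invert(trace, coarse_config)
        assert r1.alpha_selected == r2.alpha_selected
        assert np.array_equal(r1.p_mem.p, r2.p_mem.p)
        assert r1.background == r2.background

    def test_narrow_scenario_recovered_narrow(self, coarse_config):
        from deerflex import make_scenario, simulate_trace_from_scenario
        from deerflex.distribution_stats import fwhm

        ok = 0
        for seed in range(10):
            sc = make_scenario("EEE-like", seed=100 + seed)
            trace, _ = simulate_trace_from_scenario(sc, seed=200 + seed)
            res = invert(trace, coarse_config)
            ok += fwhm(res.p_mem) < 0.8
        assert ok >= 9

    def test_broad_wider_than_narrow_in_pairs(self, coarse_config):
        from deerflex import make_scenario, simulate_trace_from_scenario
        from deerflex.distribution_stats import fwhm

        for seed in range(5):
            wt = make_scenario("WT-like", seed=300 + seed)
            ee = make_scenario("EEE-like", seed=400 + seed)
            tr_wt, _ = simulate_trace_from_scenario(wt, seed=500 + seed)
            tr_ee, _ = simulate_trace_from_scenario(ee, seed=600 + seed)
            assert fwhm(invert(tr_wt, coarse_config).p_mem) > fwhm(
                invert(tr_ee, coarse_config).p_mem
            )
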