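"""ABC sampler, Gelman-Rubin diagnostics, posterior summaries."""

import numpy as np
import pytest

from kinfit.abc_sampler import (
    AbcChainHistory,
    AbcConfig,
    abc_sample,
    chain_mean_trace,
    final_drift,
    gelman_rubin,
    summarize_posterior,
)
from kinfit.objectives import AbcTarget

FIXED_YKD_FREE = {"mu_max": 0.04, "Ks": 20.0, "b": 1.0}  # (Y, kd) free


def small_history(samples, **kw):
    samples = np.asarray(samples, dtype=float)
    nC, nG, d = samples.shape
    defaults = dict(
        fitness=np.zeros((nC, nG)),
        accepted=np.ones((nC, nG), dtype=bool),
        R_trace=np.array([[nG, 1.0]]),
        param_names=tuple(f"p{i}" for i in range(d)),
        prior_bounds=np.array([[0.0, 1.0]] * d),
        target=AbcTarget([0.0, 0.0], [0.01, 0.01]),
        seed=0,
    )
    defaults.update(kw)
    return AbcChainHistory(samples=samples, **defaults)


class TestGelmanRubin:
    def test_identical_chains_closed_form(self, rng):
        # B = 0: R = sqrt((n-1)/n) with n the retained (second-half) draws
        seq = rng.normal(size=100)
        chains = np.stack([seq] * 4)
        n = 50
        assert gelman_rubin(chains) == pytest.approx(np.sqrt((n - 1) / n))

    def test_iid_normal_chains_converge(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            assert_chains = r.normal(size=(6, 5000, 2))
            hits += gelman_rubin(assert_chains) < 1.05
        assert hits >= 19

    def test_offset_chains_flagged_nonconverged(self, rng):
        a = rng.normal(size=2000)
        b = rng.normal(size=2000) + 10.0
        assert gelman_rubin(np.stack([a, b])) > 1.2

    def test_matches_bruteforce_variance_formulas(self, rng):
        s = rng.normal(size=(5, 400, 3)) * rng.uniform(0.5, 2, size=(5, 1, 3))
        half = s[:, 200:, :]
        m, n, d = half.shape
        Rs = []
        for k in range(d):
            x = half[:, :, k]
            means = x.mean(axis=1)
            W = np.mean([np.var(x[c], ddof=1) for c in range(m)])
            B_over_n = np.var(means, ddof=1)
            Rs.append(np.sqrt((n - 1) / n + B_over_n / W))
        assert gelman_rubin(s) == pytest.approx(max(Rs))

    def test_constant_chains_degenerate(self):
        s = np.ones((3, 100, 2))
        assert np.isnan(gelman_rubin(s))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 2)))
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((3, 2, 2)))  # 1 retained draw after halving


@pytest.fixture(scope="module")
def behavioral_run(monod_spec, zero_noise_monod_ds):
    target = AbcTarget.from_compromise(0.0, 0.0)
    cfg = AbcConfig(n_chains=4, n_generations=1200, seed=3)
    return abc_sample(monod_spec, zero_noise_monod_ds, target, cfg,
                      fixed=FIXED_YKD_FREE)


class TestAbcSample:
    def test_seed_reproducibility_bit_identical(self, monod_spec, zero_noise_monod_ds):
        target = AbcTarget.from_compromise(0.0, 0.0)
        cfg = AbcConfig(n_chains=3, n_generations=600, seed=5)
        a = abc_sample(monod_spec, zero_noise_monod_ds, target, cfg, fixed=FIXED_YKD_FREE)
        b = abc_sample(monod_spec, zero_noise_monod_ds, target, cfg, fixed=FIXED_YKD_FREE)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.fitness, b.fitness)
        assert np.array_equal(a.R_trace, b.R_trace)

    def test_samples_stay_in_prior_box(self, behavioral_run):
        lo, hi = behavioral_run.prior_bounds[:, 0], behavioral_run.prior_bounds[:, 1]
        assert np.all(behavioral_run.samples >= lo)
        assert np.all(behavioral_run.samples <= hi)

    def test_fitness_nondecreasing_until_behavioral(self, behavioral_run):
        # monotone hill-climb: per chain, fitness never drops while below 0
        f = behavioral_run.fitness
        for c in range(f.shape[0]):
            pre = f[c, f[c] < 0]
            assert np.all(np.diff(pre) >= 0)

    def test_post_behavioral_samples_remain_behavioral(self, behavioral_run):
        f = behavioral_run.fitness
        for c in range(f.shape[0]):
            idx = np.flatnonzero(f[c] >= 0)
            if idx.size:
                assert np.all(f[c, idx[0]:] >= 0)

    def test_posterior_ssr_stats_within_epsilon(self, behavioral_run, monod_spec,
                                                zero_noise_monod_ds):
        # behavioral membership == per-statistic distance within epsilon
        assert behavioral_run.fitness[:, -1].min() >= 0

    def test_no_behavioral_raises_structured_error(self, monod_spec,
                                                   zero_noise_monod_ds):
        from kinfit.abc_sampler import NoBehavioralSampleError
        # epsilon far too tight to reach within a 3-generation budget
        target = AbcTarget([0.0, 0.0], [1e-15, 1e-15])
        cfg = AbcConfig(n_chains=3, n_generations=3, seed=0)
        with pytest.raises(NoBehavioralSampleError, match="Increase the epsilons"):
            abc_sample(monod_spec, zero_noise_monod_ds, target, cfg,
                       fixed=FIXED_YKD_FREE)


class TestSummaries:
    def test_degenerate_posterior_collapses_bands(self, monod_spec, zero_noise_monod_ds):
        draw = np.array([0.4, 0.005])
        samples = np.tile(draw, (3, 400, 1))
        hist = small_history(samples, param_names=("Y", "kd"),
                            prior_bounds=np.array([[0.01, 10.0], [1e-4, 1.0]]),
                            fixed=FIXED_YKD_FREE)
        s = summarize_posterior(hist, monod_spec, zero_noise_monod_ds,
                                require_converged=False)
        assert np.allclose(s.S_band[0], s.S_band[1])
        assert np.allclose(s.sd, 0.0)
        assert np.allclose(s.S_band[0], s.S_median)

    def test_predictive_band_contains_parameter_band(self, monod_spec,
                                                     zero_noise_monod_ds, rng):
        samples = np.stack([
            np.column_stack([rng.uniform(0.35, 0.45, 400), rng.uniform(0.004, 0.006, 400)])
            for _ in range(3)
        ])
        hist = small_history(samples, param_names=("Y", "kd"),
                            prior_bounds=np.array([[0.01, 10.0], [1e-4, 1.0]]),
                            fixed=FIXED_YKD_FREE)
        s = summarize_posterior(hist, monod_spec, zero_noise_monod_ds,
                                require_converged=False)
        assert np.all(s.S_predictive[0] <= s.S_band[0] + 1e-15)
        assert np.all(s.S_predictive[1] >= s.S_band[1] - 1e-15)
        assert np.all(s.C_predictive[0] <= s.C_band[0] + 1e-15)
        assert np.all(s.C_predictive[1] >= s.C_band[1] - 1e-15)
        # bands contain the median trajectory
        assert np.all((s.S_band[0] <= s.S_median) & (s.S_median <= s.S_band[1]))

    def test_too_few_draws_rejected(self, monod_spec, zero_noise_monod_ds):
        hist = small_history(np.zeros((3, 100, 2)) + 0.4, param_names=("Y", "kd"),
                            fixed=FIXED_YKD_FREE)
        with pytest.raises(ValueError, match="too few"):
            summarize_posterior(hist, monod_spec, zero_noise_monod_ds,
                                require_converged=False)

    def test_unconverged_history_refused_by_default(self, monod_spec,
                                                    zero_noise_monod_ds):
        hist = small_history(np.full((3, 400, 2), 0.4), param_names=("Y", "kd"),
                            R_trace=np.array([[400, 1.5]]), fixed=FIXED_YKD_FREE)
        with pytest.raises(RuntimeError, match="not converged"):
            summarize_posterior(hist, monod_spec, zero_noise_monod_ds)


class TestChainMeanTrace:
    def test_constant_chains_give_constant_trace(self):
        hist = small_history(np.full((3, 50, 2), 0.7))
        trace = chain_mean_trace(hist)
        assert trace.shape == (50, 2)
        assert np.allclose(trace, 0.7, rtol=0, atol=1e-15)
        assert final_drift(hist) == 0.0

    def test_trace_length_equals_generations(self, rng):
        hist = small_history(rng.random((4, 123, 3)))
        assert chain_mean_trace(hist).shape[0] == 123
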