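"""Forward integration and synthetic-experiment generation."""

import numpy as np
import pytest

import kinfit as kf
from kinfit.models import KineticParams, get_model, ode_rhs, SystemState
from kinfit.simulate import SyntheticDesign, generate_synthetic, integrate


def rk4_oracle(spec, params, S0, X0, t_end, dt=1e-3):
    """Independent fixed-step RK4 integration (brute-force oracle)."""
    y = np.array([S0, X0])

    def f(y):
        return np.array(ode_rhs(spec, SystemState(S=max(y[0], 0.0), X=max(y[1], 0.0)), params))

    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


class TestIntegrate:
    def test_closed_form_decay_when_growth_off(self):
        # mu_max=0: X(t) = b*C0*exp(-kd t), S constant
        spec = get_model("Monod")
        p = KineticParams(mu_max=0.0, Ks=1.0, Y=1.0, kd=0.05, b=2.0)
        t = np.linspace(0, 50, 11)
        pred = integrate(spec, p, S0=10.0, C0=1.0, times=t)
        assert np.allclose(pred.X_pred, 2.0 * np.exp(-0.05 * t), rtol=1e-7)
        assert np.allclose(pred.S_pred, 10.0, rtol=1e-9)
        assert np.allclose(pred.C_pred, pred.X_pred / 2.0)

    def test_mass_conservation_without_decay(self, moser_spec):
        p = KineticParams(mu_max=0.05, Ks=15.0, Y=0.4, kd=0.0, b=1.0,
                          extras={"n": 1.5})
        t = np.linspace(0, 216, 10)
        pred = integrate(moser_spec, p, S0=50.0, C0=0.05, times=t)
        X0 = p.b * 0.05
        lhs = p.Y * (50.0 - pred.S_pred)
        rhs = pred.X_pred - X0
        assert np.all(np.abs(lhs - rhs) < 1e-6 * max(X0, pred.X_pred.max()))

    def test_against_fixed_step_rk4_oracle(self):
        # frozen from the dt=1e-3 RK4 oracle below; 4 significant digits
        spec = get_model("Monod")
        p = KineticParams(mu_max=0.3, Ks=5.0, Y=0.4, kd=0.01, b=1.0)
        pred = integrate(spec, p, S0=50.0, C0=1.0, times=np.array([0.0, 24.0]))
        oracle = rk4_oracle(spec, p, 50.0, 1.0, 24.0)
        assert pred.S_pred[-1] == pytest.approx(oracle[0], rel=1e-4)
        assert pred.X_pred[-1] == pytest.approx(oracle[1], rel=1e-4)

    def test_solver_convergence_under_tolerance_halving(self, moser_spec, moser_truth):
        t = np.linspace(0, 216, 10)
        a = integrate(moser_spec, moser_truth, 50.0, 0.05, t)
        b = integrate(moser_spec, moser_truth, 50.0, 0.05, t, rtol=5e-9, atol=5e-11)
        assert np.allclose(a.S_pred, b.S_pred, rtol=1e-5)
        assert np.allclose(a.X_pred, b.X_pred, rtol=1e-5)

    def test_substrate_monotone_nonincreasing(self, moser_spec, moser_truth):
        t = np.linspace(0, 216, 200)
        pred = integrate(moser_spec, moser_truth, 50.0, 0.05, t)
        assert np.all(np.diff(pred.S_pred) <= 1e-9)

    def test_moser_unit_exponent_matches_monod_trajectory(self):
        t = np.linspace(0, 216, 10)
        core = dict(mu_max=0.04, Ks=20.0, Y=0.4, kd=0.005, b=1.0)
        monod = integrate(get_model("Monod"), KineticParams(**core), 50.0, 0.05, t)
        moser = integrate(get_model("Moser"),
                          KineticParams(**core, extras={"n": 1.0}), 50.0, 0.05, t)
        assert np.allclose(monod.S_pred, moser.S_pred, rtol=1e-6)
        assert np.allclose(monod.X_pred, moser.X_pred, rtol=1e-6)

    def test_unsorted_times_rejected(self, monod_spec, monod_truth):
        with pytest.raises(ValueError):
            integrate(monod_spec, monod_truth, 50.0, 0.05, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            integrate(monod_spec, monod_truth, 50.0, 0.05, [1.0, 2.0])


class TestGenerateSynthetic:
    def test_zero_noise_returns_exact_truth(self, moser_spec, moser_truth):
        design = SyntheticDesign(noise_sd_log10=0.0)
        ds = generate_synthetic(moser_spec, moser_truth, design, seed=1)
        truth = integrate(moser_spec, moser_truth, design.S0, design.C0, ds.times)
        assert np.array_equal(ds.S_obs, truth.S_pred)
        assert np.array_equal(ds.C_obs, truth.C_pred)
        assert np.all(ds.S_sd == 0) and np.all(ds.C_sd == 0)

    def test_same_seed_reproduces_dataset(self, moser_spec, moser_truth):
        design = SyntheticDesign(noise_sd_log10=0.05)
        a = generate_synthetic(moser_spec, moser_truth, design, seed=11)
        b = generate_synthetic(moser_spec, moser_truth, design, seed=11)
        assert np.array_equal(a.S_obs, b.S_obs)
        assert np.array_equal(a.C_obs, b.C_obs)
        c = generate_synthetic(moser_spec, moser_truth, design, seed=12)
        assert not np.array_equal(a.S_obs, c.S_obs)

    def test_log10_noise_scale_matches_request(self, monod_spec, monod_truth):
        # law of large numbers: with many replicates the per-timepoint sd of
        # log10 observations approaches the requested noise level
        design = SyntheticDesign(noise_sd_log10=0.05, n_replicates=1, n_timepoints=6,
                                 duration_h=216.0)
        obs = np.array([
            generate_synthetic(monod_spec, monod_truth, design, seed=s).S_obs
            for s in range(1000)
        ])
        sd = np.log10(obs).std(axis=0, ddof=1)
        assert np.all(np.abs(sd - 0.05) < 0.05 * 0.05)

    def test_rejects_designs_that_hit_zero(self, monod_spec):
        # fast kinetics deplete substrate below 1e-10 well inside the window
        fast = KineticParams(mu_max=1.0, Ks=1.0, Y=0.4, kd=0.0, b=1.0)
        design = SyntheticDesign(noise_sd_log10=0.01, duration_h=2000.0)
        with pytest.raises(ValueError, match="duration"):
            generate_synthetic(monod_spec, fast, design, seed=1)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SyntheticDesign(n_timepoints=3)
        with pytest.raises(ValueError):
            SyntheticDesign(noise_sd_log10=-0.1)


class TestBatchDataset:
    def test_requires_positive_observations(self):
        with pytest.raises(ValueError, match="strictly positive"):
            kf.BatchDataset(times=[0, 1, 2], S_obs=[1, 0, 1], C_obs=[1, 1, 1])

    def test_requires_time_zero_start(self):
        with pytest.raises(ValueError):
            kf.BatchDataset(times=[1, 2, 3], S_obs=[1, 1, 1], C_obs=[1, 1, 1])
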