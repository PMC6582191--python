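"""Fitting criteria: log10 residuals, joint objective, ABC fitness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinfit.objectives import (
    PENALTY_TOTAL,
    AbcTarget,
    ObjectiveValue,
    of1,
    of2_abc,
    of_mo,
    residuals,
)
from kinfit.simulate import BatchDataset, TrajectoryPrediction


def make_pair(S_obs, C_obs, S_pred, C_pred, penalized=False):
    t = np.arange(len(S_obs), dtype=float)
    ds = BatchDataset(times=t, S_obs=S_obs, C_obs=C_obs)
    S_pred = np.asarray(S_pred, dtype=float)
    C_pred = np.asarray(C_pred, dtype=float)
    pred = TrajectoryPrediction(times=t, S_pred=S_pred, X_pred=C_pred,
                                C_pred=C_pred, penalized=penalized)
    return ds, pred


class TestResiduals:
    def test_perfect_prediction_is_zero(self):
        ds, pred = make_pair([10, 5, 2], [1, 2, 3], [10, 5, 2], [1, 2, 3])
        r_s, r_c = residuals(ds, pred)
        assert np.all(r_s == 0) and np.all(r_c == 0)

    def test_decade_offset_gives_unit_residuals(self):
        ds, pred = make_pair([10, 5], [1, 2], [100, 50], [1, 2])
        r_s, _ = residuals(ds, pred)
        assert np.allclose(r_s, -1.0)

    def test_hand_arithmetic(self):
        ds, pred = make_pair([10, 1], [1, 1], [1, 10], [1, 1])
        r_s, _ = residuals(ds, pred)
        assert np.allclose(r_s, [1.0, -1.0])
        assert of1(ds, pred).ssr_subs == pytest.approx(2.0)

    def test_time_grid_mismatch_rejected(self):
        ds, _ = make_pair([10, 5], [1, 2], [10, 5], [1, 2])
        bad = TrajectoryPrediction(times=np.array([0.0, 2.0]),
                                   S_pred=np.array([10.0, 5.0]),
                                   X_pred=np.array([1.0, 2.0]),
                                   C_pred=np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="exactly the dataset's times"):
            residuals(ds, bad)

    def test_penalized_prediction_yields_large_finite_total(self):
        ds, pred = make_pair([10, 5], [1, 2], [10, 5], [1, 2], penalized=True)
        v = of1(ds, pred)
        assert v.total == pytest.approx(PENALTY_TOTAL)
        assert np.isfinite(v.total)


class TestOf1:
    def test_zero_residuals_zero_total_flagged_degenerate(self):
        ds, pred = make_pair([10, 5], [1, 2], [10, 5], [1, 2])
        v = of1(ds, pred)
        assert v.total == 0.0
        assert v.degenerate
        assert (v.pct_subs, v.pct_cells) == (50.0, 50.0)

    def test_hand_built_decomposition(self):
        # r_subs=(1,-1), r_cells=(0,0) -> (2, 0, 2, 100, 0)
        ds, pred = make_pair([10, 1], [1, 1], [1, 10], [1, 1])
        v = of1(ds, pred)
        assert (v.ssr_subs, v.ssr_cells, v.total) == (pytest.approx(2.0), 0.0, pytest.approx(2.0))
        assert (v.pct_subs, v.pct_cells) == (100.0, 0.0)

    def test_common_scaling_leaves_total_unchanged(self):
        ds1, pred1 = make_pair([10, 4], [1, 2], [8, 5], [1.5, 2.5])
        ds2, pred2 = make_pair([30, 12], [3, 6], [24, 15], [4.5, 7.5])
        assert of1(ds1, pred1).total == pytest.approx(of1(ds2, pred2).total)

    def test_total_symmetric_under_variable_exchange(self):
        ds, pred = make_pair([10, 4], [2, 7], [8, 5], [3, 6])
        sw_ds, sw_pred = make_pair([2, 7], [10, 4], [3, 6], [8, 5])
        assert of1(ds, pred).total == pytest.approx(of1(sw_ds, sw_pred).total)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(ssr_s=st.floats(0, 1e6), ssr_c=st.floats(0, 1e6))
    def test_percent_identity(self, ssr_s, ssr_c):
        v = ObjectiveValue.from_ssrs(ssr_s, ssr_c)
        assert v.total == ssr_s + ssr_c
        if v.total > 0:
            assert v.pct_subs + v.pct_cells == 100.0

    def test_sigma_weighting_recovers_weighted_form(self):
        ds, pred = make_pair([10, 1], [10, 1], [1, 10], [1, 10])
        v = of1(ds, pred, sigma_subs=2.0, sigma_cells=1.0)
        assert v.total == pytest.approx(2.0 / 4.0 + 2.0)


class TestOfMo:
    def test_vector_matches_of1_components(self):
        ds, pred = make_pair([10, 4], [2, 7], [8, 5], [3, 6])
        v = of1(ds, pred)
        assert np.allclose(of_mo(ds, pred), [v.ssr_subs, v.ssr_cells])

    def test_perfect_fit_is_origin(self):
        ds, pred = make_pair([10, 4], [2, 7], [10, 4], [2, 7])
        assert np.array_equal(of_mo(ds, pred), [0.0, 0.0])


class TestOf2Abc:
    def test_zero_distance_returns_min_epsilon(self):
        t = AbcTarget([1.0, 2.0], [0.1, 0.1])
        assert of2_abc([1.0, 2.0], t) == pytest.approx(0.1)

    def test_hand_arithmetic(self):
        t = AbcTarget([1.0, 2.0], [0.1, 0.1])
        assert of2_abc([1.05, 2.5], t) == pytest.approx(-0.4)

    def test_matches_bruteforce_min_over_statistics(self, rng):
        for _ in range(20):
            m = rng.integers(2, 6)
            obs = rng.uniform(0, 5, m)
            eps = rng.uniform(0.01, 1, m)
            sim = rng.uniform(0, 5, m)
            expected = min(eps[j] - abs(obs[j] - sim[j]) for j in range(m))
            assert of2_abc(sim, AbcTarget(obs, eps)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(bump=st.floats(0, 10), which=st.integers(0, 1))
    def test_monotone_in_epsilon(self, bump, which):
        t = AbcTarget([1.0, 2.0], [0.1, 0.1])
        eps2 = np.array([0.1, 0.1])
        eps2[which] += bump
        t2 = AbcTarget([1.0, 2.0], eps2)
        sim = [1.3, 1.8]
        assert of2_abc(sim, t2) >= of2_abc(sim, t)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            of2_abc([1.0], AbcTarget([1.0, 2.0], [0.1, 0.1]))
        with pytest.raises(ValueError):
            AbcTarget([1.0, 2.0], [0.1])

    def test_behavioral_iff_nonnegative(self):
        t = AbcTarget([1.0, 2.0], [0.1, 0.2])
        assert of2_abc([1.09, 2.19], t) >= 0
        assert of2_abc([1.11, 2.0], t) < 0
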