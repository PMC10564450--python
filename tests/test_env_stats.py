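"""Statistics stage: air speed, circular tests, LMM/AIC, categories, VIF."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from takeoffkit import (air_speed, categorize_conditions, fit_lmm_compare,
                        group_tests, relative_angle, v_test, vif)
from takeoffkit.env_stats import slope_through_origin
from takeoffkit._utils import ParameterError


class TestAirSpeed:
    def test_headwind_adds_wind(self):
        assert air_speed(6.5, 6.5, 0.0, 0.0) == pytest.approx(13.0)

    def test_no_wind_is_ground_speed(self):
        assert air_speed(6.5, 0.0, 1.0, 2.0) == pytest.approx(6.5)

    def test_crosswind_neutral(self):
        assert air_speed(6.5, 6.5, np.pi / 2, 0.0) == pytest.approx(6.5)

    def test_periodic_and_maximal_at_headwind(self, rng):
        th = rng.uniform(0, 2 * np.pi, 50)
        np.testing.assert_allclose(air_speed(5, 3, th, 1.0),
                                   air_speed(5, 3, th + 2 * np.pi, 1.0))
        grid = np.linspace(0, 2 * np.pi, 721)
        vals = air_speed(5.0, 3.0, grid, 1.0)
        assert grid[np.argmax(vals)] == pytest.approx(1.0, abs=0.01)


class TestRelativeAngle:
    @pytest.mark.parametrize("a,b,expected", [
        (350.0, 10.0, -20.0),
        (10.0, 350.0, 20.0),
        (180.0, 0.0, 180.0),  # boundary maps to +pi
    ])
    def test_wrapped_difference(self, a, b, expected):
        out = relative_angle(np.radians(a), np.radians(b))
        assert np.degrees(out) == pytest.approx(expected)


class TestVTest:
    def test_perfect_concentration(self):
        V, u, p = v_test(np.full(20, 1.3), 1.3)
        assert V == pytest.approx(1.0)
        assert p < 1e-6

    def test_uniform_grid_is_null(self):
        angles = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        V, u, p = v_test(angles, 0.0)
        assert V == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_rotation_invariance(self, rng):
        a = rng.vonmises(1.0, 2.0, 40)
        _, _, p1 = v_test(a, 1.0)
        _, _, p2 = v_test(a + 0.7, 1.7)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ParameterError):
            v_test(np.zeros(4), 0.0)


def _lmm_frame(seed, beta_wind=-0.4, beta_wave=0.0, n_birds=8,
               per_bird=8, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_birds):
        u = rng.normal(0, 0.5)
        for _ in range(per_bird):
            w = rng.weibull(2.6) * 7.3
            h = rng.lognormal(1.064, 0.262)
            y = 8.0 + beta_wind * w + beta_wave * h + u + \
                rng.normal(0, noise)
            rows.append({"bird_id": f"b{b}", "Vw": w, "Hs": h,
                         "run_duration": y})
    return pd.DataFrame(rows)


class TestLmmCompare:
    def test_wind_effect_selected(self):
        df = _lmm_frame(seed=1)
        comp = fit_lmm_compare(df, "run_duration")
        assert "wind" in comp.best
        tab = comp.table.set_index("model")
        assert tab.loc["wind", "aic"] < tab.loc["null", "aic"] - 2
        assert tab.loc["wind", "p_chisq"] < 0.01

    def test_pure_noise_prefers_null(self):
        wins = 0
        for s in range(10):
            df = _lmm_frame(seed=100 + s, beta_wind=0.0)
            comp = fit_lmm_compare(df, "run_duration")
            tab = comp.table.set_index("model")
            best_other = tab.drop("null")["aic"].min()
            wins += (best_other - tab.loc["null", "aic"]) >= -2
        assert wins >= 8

    def test_deterministic_on_identical_data(self):
        df = _lmm_frame(seed=3)
        a = fit_lmm_compare(df, "run_duration").table
        b = fit_lmm_compare(df, "run_duration").table
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_rows_rejected(self):
        df = _lmm_frame(seed=1).head(20)
        with pytest.raises(ParameterError):
            fit_lmm_compare(df, "run_duration")


class TestCategorize:
    def test_weibull_mode_closed_form(self, rng):
        wind = sps.weibull_min.rvs(2.0, scale=7.0, size=5000,
                                   random_state=1)
        wave = sps.lognorm.rvs(0.25, scale=np.e, size=5000, random_state=2)
        (wt, ht), labels = categorize_conditions(wind, wave)
        assert wt == pytest.approx(7.0 / np.sqrt(2), rel=0.05)
        assert ht == pytest.approx(np.exp(1 - 0.0625), rel=0.05)
        assert set(labels) == {"WL", "WH", "SL", "SH"}

    def test_fixed_thresholds_classification(self):
        # the published split: 6.0 m/s wind, 2.8 m wave
        _, labels = categorize_conditions([5.9], [2.9],
                                          thresholds=(6.0, 2.8))
        assert labels[0] == "WH"

    def test_counts_partition_the_sample(self, rng):
        wind = rng.weibull(2.0, 200) * 7.0
        wave = rng.lognormal(1.0, 0.25, 200)
        _, labels = categorize_conditions(wind, wave)
        assert sum((labels == c).sum()
                   for c in ("WL", "WH", "SL", "SH")) == 200


class TestVif:
    def test_orthogonal_columns_are_one(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        out = vif(X)
        np.testing.assert_allclose(out, 1.0)

    def test_duplicate_column_is_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert np.isinf(vif(X)).all()

    def test_closed_form_at_known_correlation(self, rng):
        # build exact sample correlation r = 0.27 by Gram-Schmidt
        n = 400
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        r = 0.27
        y = r * x + np.sqrt(1 - r**2) * e
        out = vif(pd.DataFrame({"x": x, "y": y}))
        np.testing.assert_allclose(out, 1.0 / (1.0 - r**2), rtol=1e-9)


def _mw_enumeration_p(x, y):
    """Two-sided Mann-Whitney p by exhaustive label enumeration."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = sps.rankdata(pooled)
    u_obs = np.sum(ranks[:n]) - n * (n + 1) / 2
    stats = []
    for idx in itertools.combinations(range(n + m), n):
        u = np.sum(ranks[list(idx)]) - n * (n + 1) / 2
        stats.append(u)
    stats = np.asarray(stats)
    mu = n * m / 2
    p = np.mean(np.abs(stats - mu) >= abs(u_obs - mu) - 1e-12)
    return p


class TestGroupTests:
    def test_identical_groups_p_one(self):
        rep = group_tests({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert rep["mannwhitney_p"] == pytest.approx(1.0)

    def test_degenerate_all_tied(self):
        rep = group_tests({"a": [2.0, 2, 2], "b": [2.0, 2, 2]})
        assert rep["degenerate"] and rep["mannwhitney_p"] == 1.0

    def test_through_origin_slope_and_r(self):
        x = np.linspace(1, 10, 30)
        y = 1.23 * x
        rep = group_tests(paired=(x, y))
        assert rep["slope_origin"] == pytest.approx(1.23)
        assert rep["pearson_r"] == pytest.approx(1.0)
        assert slope_through_origin(x, y) == pytest.approx(1.23)

    def test_small_sample_p_equals_enumeration(self, rng):
        for s in range(3):
            r = np.random.default_rng(s)
            x = r.normal(0, 1, 6)
            y = r.normal(0.8, 1, 7)
            rep = group_tests({"a": x, "b": y})
            assert rep["mannwhitney_p"] == pytest.approx(
                _mw_enumeration_p(x, y), abs=1e-12)

    def test_kruskal_three_groups(self, rng):
        rep = group_tests({"a": rng.normal(0, 1, 20),
                           "b": rng.normal(1, 1, 20),
                           "c": rng.normal(2, 1, 20)})
        assert rep["kruskal_p"] < 0.01
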