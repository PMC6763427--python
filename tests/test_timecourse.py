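"""Window fits, peak extraction, two-level bootstrap and group inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eicapvt import timecourse as tcm
from eicapvt.fir import BIN_TIMES_S


class TestWindows:
    def test_standard_sizes(self):
        seg = tcm.split_windows(np.zeros(24))
        assert len(seg.pre_times) == 8
        assert len(seg.early_times) == 9
        assert len(seg.late_times) == 7

    def test_stimulus_bin_is_post(self):
        seg = tcm.split_windows(np.arange(24.0))
        assert 0.0 in seg.early_times
        assert 0.0 not in seg.pre_times

    def test_partition_no_overlap(self):
        seg = tcm.split_windows(np.arange(24.0))
        all_t = np.concatenate([seg.pre_times, seg.early_times, seg.late_times])
        np.testing.assert_array_equal(np.sort(all_t), BIN_TIMES_S)

    def test_wrong_bin_count_raises(self):
        with pytest.raises(ValueError):
            tcm.split_windows(np.zeros(23))


class TestFits:
    def test_exact_line(self):
        t = BIN_TIMES_S[:8]
        fit = tcm.fit_pre(t, 2.0 * t + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)  # value at t = 0
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_constant_series(self):
        fit = tcm.fit_pre(BIN_TIMES_S[:8], np.full(8, 3.5))
        assert fit.slope == pytest.approx(0.0, abs=1e-14)
        assert fit.intercept == pytest.approx(3.5)

    def test_pre_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        t = BIN_TIMES_S[:8]
        y = rng.normal(size=8)
        fit = tcm.fit_pre(t, y)
        X = np.column_stack([t, np.ones(8)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_exact_cubic(self):
        t = np.linspace(0, 16, 9)
        y = t**3 - t
        fit = tcm.fit_post_cubic(t, y)
        np.testing.assert_allclose(fit.coefs, [1.0, 0.0, -1.0, 0.0],
                                   atol=1e-9)

    def test_flat_series_cubic_is_constant(self):
        fit = tcm.fit_post_cubic(np.linspace(0, 16, 9), np.full(9, 2.0))
        np.testing.assert_allclose(fit.coefs[:3], 0.0, atol=1e-12)
        assert fit.coefs[3] == pytest.approx(2.0)

    def test_cubic_matches_vandermonde_oracle(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 16, 9)
        y = rng.normal(size=9)
        fit = tcm.fit_post_cubic(t, y)
        V = np.vander(t, 4)
        beta = np.linalg.lstsq(V, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefs, beta, atol=1e-10)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            tcm.fit_pre(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            tcm.fit_post_cubic(np.arange(3.0), np.arange(3.0))


def _grid_peak_oracle(coefs, sign, window=(0.0, 16.0)):
    """Dense-grid (1-ms) argmax/argmin of the fitted cubic."""
    grid = np.arange(window[0], window[1] + 1e-9, 0.001)
    v = np.polyval(coefs, grid)
    # emulate "first interior extremum of matching curvature": scan local
    # extrema in order of time
    dv = np.diff(v)
    if sign > 0:
        turning = np.flatnonzero((dv[:-1] > 0) & (dv[1:] <= 0)) + 1
    else:
        turning = np.flatnonzero((dv[:-1] < 0) & (dv[1:] >= 0)) + 1
    if turning.size == 0:
        return v[-1], window[1], True
    i = turning[0]
    return v[i], grid[i], False


class TestFirstPeak:
    def test_known_maximum(self):
        # cubic with a max at t = 6, value 2.0:  f(t) = 2 - (t-6)^2*(t+3)/c
        # use constructed coefficients via polyfit of a shape
        t = np.linspace(0, 16, 9)
        y = 2.0 * np.exp(-0.5 * ((t - 6) / 3.0) ** 2)
        coefs = np.polyfit(t, y, 3)
        pk = tcm.extract_first_peak(coefs, response_sign=1)
        h, lat, bound = _grid_peak_oracle(coefs, 1)
        assert not bound and not pk.at_boundary
        assert pk.latency == pytest.approx(lat, abs=1e-3)
        assert pk.height == pytest.approx(h, abs=1e-6)

    def test_negative_going_trough(self):
        t = np.linspace(0, 16, 9)
        y = -1.5 * np.exp(-0.5 * ((t - 7) / 3.0) ** 2)
        coefs = np.polyfit(t, y, 3)
        pk = tcm.extract_first_peak(coefs, response_sign=-1)
        h, lat, _ = _grid_peak_oracle(coefs, -1)
        assert pk.latency == pytest.approx(lat, abs=1e-3)
        assert pk.height == pytest.approx(h, abs=1e-6)
        assert pk.height < 0

    def test_strictly_increasing_boundary_fallback(self):
        coefs = np.array([0.0, 0.0, 1.0, 0.0])  # f(t) = t
        pk = tcm.extract_first_peak(coefs, response_sign=1)
        assert pk.at_boundary
        assert pk.latency == 16.0
        assert pk.height == pytest.approx(16.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_grid_oracle_on_random_cubics(self, seed):
        rng = np.random.default_rng(seed)
        coefs = rng.normal(size=4) * np.array([0.01, 0.1, 1.0, 1.0])
        for sign in (1, -1):
            pk = tcm.extract_first_peak(coefs, response_sign=sign)
            h, lat, bound = _grid_peak_oracle(coefs, sign)
            assert pk.at_boundary == bound
            assert pk.latency == pytest.approx(lat, abs=1e-3)
            assert 0.0 <= pk.latency <= 16.0

    def test_translation_equivariance(self):
        t = np.linspace(0, 16, 9)
        y = np.sin(t / 5.0)
        c1 = tcm.fit_post_cubic(t, y).coefs
        c2 = tcm.fit_post_cubic(t, y + 5.0).coefs
        p1 = tcm.extract_first_peak(c1)
        p2 = tcm.extract_first_peak(c2)
        assert p2.latency == pytest.approx(p1.latency, abs=1e-9)
        assert p2.height == pytest.approx(p1.height + 5.0, abs=1e-9)
        # same for the pre-window line
        tp = BIN_TIMES_S[:8]
        f1 = tcm.fit_pre(tp, 0.3 * tp + 1)
        f2 = tcm.fit_pre(tp, 0.3 * tp + 1 + 5.0)
        assert f2.slope == pytest.approx(f1.slope)
        assert f2.intercept == pytest.approx(f1.intercept + 5.0)


class TestBootstrap:
    def test_zero_residuals_degenerate(self):
        t = BIN_TIMES_S[:8]
        with pytest.warns(UserWarning, match="degenerate"):
            dist = tcm.bootstrap_window_fit(t, 2 * t + 1, "pre", n_boot=50,
                                            rng=0)
        np.testing.assert_allclose(dist["slope"], 2.0, atol=1e-12)
        np.testing.assert_allclose(dist["intercept"], 1.0, atol=1e-12)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 16, 9)
        y = np.sin(t / 4) + rng.normal(scale=0.1, size=9)
        a = tcm.bootstrap_window_fit(t, y, "cubic", n_boot=100, rng=42)
        b = tcm.bootstrap_window_fit(t, y, "cubic", n_boot=100, rng=42)
        np.testing.assert_array_equal(a["peak_height"], b["peak_height"])

    def test_slope_sd_matches_analytic_ols_sd(self):
        # residual bootstrap sd of the slope vs the closed-form OLS sd
        rng = np.random.default_rng(7)
        t = BIN_TIMES_S[:8]
        sigma = 0.3
        y = 0.05 * t + rng.normal(scale=sigma, size=t.size)
        dist = tcm.bootstrap_window_fit(t, y, "pre", n_boot=1000, rng=1)
        fit = tcm.fit_pre(t, y)
        s_hat = np.sqrt((fit.residuals**2).sum() / (t.size - 2))
        analytic = s_hat / np.sqrt(((t - t.mean()) ** 2).sum())
        assert dist["slope"].std() == pytest.approx(analytic, rel=0.15)


class TestSubjectAnova:
    def test_hand_computed_contrasts(self):
        cells = {
            ("lapse", "SS"): np.array([4.0]),
            ("lapse", "HS"): np.array([4.0]),
            ("normal", "SS"): np.array([2.0]),
            ("normal", "HS"): np.array([2.0]),
        }
        out = tcm.subject_bootstrap_anova(cells, n_boot=100, rng=0)
        np.testing.assert_allclose(out["rt_class"], 1.0)
        np.testing.assert_allclose(out["sleep"], 0.0)
        np.testing.assert_allclose(out["interaction"], 0.0)

    def test_all_equal_cells_zero_coefficients(self):
        cells = {k: np.array([3.0]) for k in tcm.CELLS}
        out = tcm.subject_bootstrap_anova(cells, n_boot=10, rng=0)
        for eff in tcm.EFFECTS:
            np.testing.assert_allclose(out[eff], 0.0)

    def test_class_swap_flips_rt_sign(self):
        rng = np.random.default_rng(0)
        cells = {k: rng.normal(size=50) for k in tcm.CELLS}
        a = tcm.subject_bootstrap_anova(cells, n_boot=200, rng=5)
        swapped = {
            ("lapse", c): cells[("normal", c)] for c in ("SS", "HS")
        } | {
            ("normal", c): cells[("lapse", c)] for c in ("SS", "HS")
        }
        b = tcm.subject_bootstrap_anova(swapped, n_boot=200, rng=5)
        np.testing.assert_allclose(b["rt_class"], -a["rt_class"], atol=1e-12)
        np.testing.assert_allclose(b["sleep"], a["sleep"], atol=1e-12)

    def test_missing_cell_raises(self):
        cells = {k: np.zeros(3) for k in tcm.CELLS[:-1]}
        with pytest.raises(ValueError, match="missing"):
            tcm.subject_bootstrap_anova(cells)


class TestGroupSignRank:
    def test_all_positive_small_n_significant(self):
        x = np.linspace(0.5, 1.5, 12)
        res = tcm.group_signrank(x, direction=1)
        # exact one-sided signed-rank: all-positive at n = 12 -> 2^-12
        assert res.p == pytest.approx(2.0**-12)
        assert res.tier == "significant"

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 1.0, size=10)
        a = tcm.group_signrank(x, direction=1)
        b = tcm.group_signrank(-x, direction=-1)
        assert a.p == pytest.approx(b.p)

    def test_all_zero_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = tcm.group_signrank(np.zeros(8))
        assert res.p == 1.0

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            tcm.group_signrank(np.ones(4))

    def test_tiers(self):
        assert tcm.significance_tier(0.004) == "significant"
        assert tcm.significance_tier(0.02) == "trending"
        assert tcm.significance_tier(0.2) == "ns"


def _simulate_cohort_pvalues(rng, n_subjects, effect=0.0, n_boot=200,
                             noise=1.0):
    """Two-level bootstrap + sign-rank on directly simulated parameter cells.

    Each subject's four cells get a bootstrap distribution around a cell
    mean; under the null all means are equal, with ``effect`` the lapse
    cells sit ``effect`` units higher (in units of the within-cell sd).
    """
    coef_means = {eff: [] for eff in tcm.EFFECTS}
    for _ in range(n_subjects):
        cells = {}
        for cls, cond in tcm.CELLS:
            mu = rng.normal(0.0, 1.0) + (effect * noise if cls == "lapse"
                                         else 0.0)
            cells[(cls, cond)] = mu + rng.normal(0.0, noise, size=n_boot)
        dists = tcm.subject_bootstrap_anova(cells, n_boot=n_boot, rng=rng)
        for eff in tcm.EFFECTS:
            coef_means[eff].append(dists[eff].mean())
    return {
        eff: tcm.group_signrank(np.asarray(coef_means[eff]), direction=1).p
        for eff in tcm.EFFECTS
    }


class TestCalibrationAndPower:
    def test_null_type_one_error_at_nominal_alpha(self):
        # a-priori (fixed-direction) one-sided test under the global null
        rng = np.random.default_rng(2024)
        n_cohorts, alpha = 100, 0.05
        rejections = {eff: 0 for eff in tcm.EFFECTS}
        for _ in range(n_cohorts):
            ps = _simulate_cohort_pvalues(rng, n_subjects=12, effect=0.0)
            for eff in tcm.EFFECTS:
                rejections[eff] += ps[eff] < alpha
        bound = 3 * np.sqrt(alpha * (1 - alpha) / n_cohorts)  # ~0.065
        for eff in tcm.EFFECTS:
            assert rejections[eff] / n_cohorts <= alpha + bound

    def test_power_for_lapse_amplitude_effect(self):
        # injected lapse-cell shift of 1 within-cell sd, cohorts of 32
        rng = np.random.default_rng(7)
        n_cohorts = 50
        hits = 0
        for _ in range(n_cohorts):
            ps = _simulate_cohort_pvalues(rng, n_subjects=32, effect=1.0)
            hits += ps["rt_class"] < tcm.SIGNIFICANT_P
        assert hits / n_cohorts >= 0.8


class TestResultsTable:
    @pytest.fixture()
    def results(self):
        rows = []
        for comp in (0, 1):
            for param in ("peak_height", "peak_latency"):
                for eff, p in zip(tcm.EFFECTS, (0.001, 0.02, 0.5)):
                    rows.append({"component": comp, "parameter": param,
                                 "effect": eff, "p": p})
        return pd.DataFrame(rows)

    def test_wide_table_roundtrips_csv(self, results, tmp_path):
        table = tcm.build_results_table(results)
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col=[0, 1])
        np.testing.assert_allclose(back.values, table.values)
        assert list(back.columns) == list(table.columns)

    def test_tier_notation(self, results):
        fmt = tcm.format_results_table(results)
        row = fmt.loc[(0, "peak_height")]
        assert row["rt_class"].endswith("*")      # p = 0.001
        assert row["sleep"].startswith("(")       # p = 0.02 trending
        assert row["interaction"] == "ns"         # p = 0.5
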