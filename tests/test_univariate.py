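"""Tests of the univariate canalization estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chreodkit import (
    SimulationConfig,
    canalized_variance,
    correct_covariance_for_error,
    decompose_variance,
    estimate_measurement_error,
    estimate_theta,
    estimate_theta_lags,
    exact_canalized_variance,
    expected_theta_with_error,
    expected_variance_change,
    pacf,
    remove_group_means,
    simulate_population,
    smooth_to_grid,
    theta_bias,
)

from conftest import make_series


def long_frame(ids, ages, values, group=None):
    rows = []
    for i, ind in enumerate(ids):
        for a, v in zip(ages[i], values[i]):
            row = {"individual_id": ind, "age": a, "trait": "t", "value": v}
            if group is not None:
                row["group"] = group[i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestSmoothToGrid:
    def test_linear_data_reproduced_exactly(self):
        # a local linear fit of points on a line returns the line value
        ages = [np.array([1.0, 1.7, 2.4, 3.1, 4.0, 5.2])] * 2
        values = [2 + 3 * ages[0], -1 + 0.5 * ages[1]]
        df = long_frame(["a", "b"], ages, values)
        series = smooth_to_grid(df, grid_ages=[2.0, 3.0, 4.0], window_width=2.5)
        assert np.allclose(series.values[0], 2 + 3 * np.array([2.0, 3.0, 4.0]))
        assert np.allclose(series.values[1], -1 + 0.5 * np.array([2.0, 3.0, 4.0]))

    def test_sparse_window_flagged_missing(self):
        df = long_frame(["a"], [np.array([1.0, 5.0])], [np.array([1.0, 2.0])])
        series = smooth_to_grid(df, grid_ages=[1.0, 3.0, 5.0], window_width=2.5)
        assert np.all(np.isnan(series.values))  # never two points in one window

    def test_window_width_changes_are_qualitative_only(self):
        # smoke check: profiles from 2.5 vs 3.5 year windows correlate strongly
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(
            n_individuals=60, ages=np.arange(2.0, 18.0), theta_t=0.5,
            var_eps_t=1.0, var_mu0=1.0, baseline_growth=2.0, seed=31,
        )
        ds, _ = simulate_population(cfg)
        ds = ds.copy()
        ds["age"] = ds["age"] + rng.uniform(-0.3, 0.3, len(ds))
        grid = np.arange(3.0, 17.0)
        a = smooth_to_grid(ds, grid, window_width=2.5)
        b = smooth_to_grid(ds, grid, window_width=3.5)
        pa = decompose_variance(a).table["cross_var"].to_numpy()
        pb = decompose_variance(b).table["cross_var"].to_numpy()
        ok = np.isfinite(pa) & np.isfinite(pb)
        assert np.corrcoef(pa[ok], pb[ok])[0, 1] > 0.8


class TestRemoveGroupMeans:
    def test_constant_offset_removed(self):
        base = np.array([[1.0, 2.0], [3.0, 1.0]])
        values = np.vstack([base, base + 5.0])
        series = make_series(values, groups=["f", "f", "m", "m"])
        centred = remove_group_means(series)
        for g in ("f", "m"):
            rows = centred.group_labels == g
            assert np.allclose(centred.values[rows].mean(axis=0), 0.0)
        # within-group differences untouched
        assert np.allclose(
            np.diff(centred.values[:2], axis=0), np.diff(base, axis=0)
        )

    def test_single_group_is_per_age_centering(self):
        values = np.random.default_rng(1).normal(size=(6, 4))
        series = make_series(values)
        centred = remove_group_means(series)
        assert np.allclose(centred.values, values - values.mean(axis=0))

    def test_singleton_group_rejected(self):
        series = make_series(np.ones((3, 2)), groups=["a", "a", "b"])
        with pytest.raises(ValueError, match="singleton"):
            remove_group_means(series)

    def test_group_divergence_false_positive_removed(self):
        # diverging group means masquerade as amplification (positive
        # "canalized variance"); centring them out restores the null
        cfg = SimulationConfig(
            n_individuals=2000, ages=np.arange(8.0), theta_t=0.0,
            var_eps_t=0.01, var_mu0=0.0, n_groups=2, group_offset_t=1.0,
            seed=32,
        )
        _, truth = simulate_population(cfg)
        series = make_series(truth.x_obs, ages=truth.ages,
                             groups=truth.group.astype(str))
        raw = canalized_variance(series, 5)
        assert raw > 1.0  # divergence reads as strongly positive
        centred = remove_group_means(series)
        assert abs(canalized_variance(centred, 5)) < 0.1


class TestPacf:
    def test_white_noise_all_lags_inside_band(self):
        rng = np.random.default_rng(2)
        series = make_series(rng.normal(size=(2000, 8)))
        table = pacf(series, max_lag=4)
        assert np.all(np.abs(table["pacf"]) < table["band"])

    def test_ar1_only_lag_one_significant(self):
        cfg = SimulationConfig(
            n_individuals=3000, ages=np.arange(9.0), theta_t=0.5,
            var_eps_t=1.0, var_d0=1.0 / 0.75, seed=33,
        )
        _, truth = simulate_population(cfg)
        series = make_series(truth.x_obs, ages=truth.ages)
        table = pacf(series, max_lag=4).set_index("lag")
        assert table.loc[1, "pacf"] > 3 * table.loc[1, "band"]
        for k in (2, 3, 4):
            assert abs(table.loc[k, "pacf"]) < table.loc[k, "band"]

    def test_persistent_trait_has_unit_lag_one(self):
        rng = np.random.default_rng(3)
        const = rng.normal(size=(50, 1)) * np.ones((1, 6))
        series = make_series(const)
        table = pacf(series, max_lag=2).set_index("lag")
        assert table.loc[1, "pacf"] == pytest.approx(1.0)

    def test_matches_partial_correlation_oracle(self):
        # single age triple: pooled lag-2 value must equal the classical
        # partial correlation of (x_2, x_0) given x_1
        import pingouin as pg

        rng = np.random.default_rng(4)
        X = rng.normal(size=(400, 3))
        X[:, 1] += 0.5 * X[:, 0]
        X[:, 2] += 0.7 * X[:, 1] + 0.2 * X[:, 0]
        # pad with a missing age so only the (x0, x1, x2) triple contributes
        padded = np.column_stack([X, np.full(400, np.nan)])
        series = make_series(padded)
        ours = pacf(series, max_lag=2).set_index("lag").loc[2, "pacf"]
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        oracle = pg.partial_corr(df, x="x2", y="x0", covar="x1")["r"].iloc[0]
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_max_lag_validated(self):
        series = make_series(np.zeros((5, 4)))
        with pytest.raises(ValueError):
            pacf(series, max_lag=3)


class TestEstimateTheta:
    def test_no_change_gives_zero(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=5)
        series = make_series(np.column_stack([col, col]))
        assert estimate_theta(series, 0) == pytest.approx(0.0)

    def test_full_reversion_to_common_value_gives_one(self):
        rng = np.random.default_rng(6)
        series = make_series(np.column_stack([rng.normal(size=6), np.full(6, 2.0)]))
        assert estimate_theta(series, 0) == pytest.approx(1.0)

    def test_isogenic_parameter_recovery(self):
        cfg = SimulationConfig(
            n_individuals=5000, ages=np.arange(10.0), theta_t=0.4,
            var_eps_t=1.0, seed=34,
        )
        _, truth = simulate_population(cfg)
        series = make_series(truth.x_obs, ages=truth.ages)
        assert estimate_theta(series, 7) == pytest.approx(0.4, abs=0.06)

    def test_zero_variance_rejected(self):
        series = make_series(np.column_stack([np.ones(5), np.arange(5.0)]))
        with pytest.raises(ValueError, match="variance"):
            estimate_theta(series, 0)

    def test_missing_individuals_excluded_per_step(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(10, 3))
        values[0, 1] = np.nan
        series = make_series(values)
        full = make_series(values[1:])
        assert estimate_theta(series, 0) == pytest.approx(estimate_theta(full, 0))


class TestClosedForms:
    def test_theta_bias_limits_and_values(self):
        assert theta_bias(0.7, 0.0, 1.0, 0.0) == pytest.approx(0.7)
        assert theta_bias(0.5, 1.0, 1.0, 0.0) == pytest.approx(0.25)
        assert theta_bias(0.5, 1.0, 1.0, 0.2) == pytest.approx(0.15)
        assert theta_bias(0.5, 1.0, 0.0, 0.2) == pytest.approx(-0.2)
        with pytest.raises(ValueError):
            theta_bias(0.5, 0.0, 0.0)

    def test_exact_canalized_variance(self):
        assert exact_canalized_variance(0.0, 5.0) == 0.0
        assert exact_canalized_variance(1.0, 2.0) == -2.0
        assert exact_canalized_variance(0.5, 1.0) == pytest.approx(-0.75)
        # at theta = 0.5 the exact factor equals the 1.5x linear rule
        assert exact_canalized_variance(0.5, 1.0) == pytest.approx(-1.5 * 0.5 * 1.0)

    def test_linear_approximation_bound(self):
        theta = np.arange(0.0, 0.6 + 1e-9, 1e-4)
        err = np.abs((theta**2 - 2 * theta) + 1.5 * theta)
        assert err.max() <= 0.0625 + 1e-12

    def test_expected_variance_change_terms(self):
        assert expected_variance_change(0, 0, 0, 0, 0, 0) == 0.0
        # complete canalization exactly replaced by new perturbations
        assert expected_variance_change(0, 0, 0, 1.0, 1.0, 1.0) == pytest.approx(0.0)
        assert expected_variance_change(0.3, 0.2, 2.0, 0.5, 1.0, 0.4) == pytest.approx(
            0.3 + (0.04 + 0.4) * 2.0 + (0.25 - 1.0) * 1.0 + 0.4
        )

    def test_expected_variance_change_matches_simulation(self):
        theta, var_d, var_eps, var_mu, var_g, zeta = 0.5, 1.0, 0.4, 2.0, 0.3, 0.1
        reps, n = 100, 2000
        diffs = np.empty(reps)
        for r in range(reps):
            cfg = SimulationConfig(
                n_individuals=n, ages=[0.0, 1.0], theta_t=theta,
                var_eps_t=var_eps, var_mu0=var_mu, var_d0=var_d,
                var_g_t=var_g, zeta_t=zeta, seed=1000 + r,
            )
            _, truth = simulate_population(cfg)
            diffs[r] = (
                np.var(truth.x_obs[:, 1], ddof=1) - np.var(truth.x_obs[:, 0], ddof=1)
            )
        expected = expected_variance_change(var_g, zeta, var_mu, theta, var_d, var_eps)
        mc_se = diffs.std(ddof=1) / np.sqrt(reps)
        assert abs(diffs.mean() - expected) < 3 * mc_se


class TestCanalizedVariance:
    def test_no_change_gives_zero(self):
        col = np.random.default_rng(8).normal(size=6)
        series = make_series(np.column_stack([col, col]))
        assert canalized_variance(series, 0) == pytest.approx(0.0)

    def test_isogenic_value_matches_exact_form(self):
        # stationary AR(1) with theta=0.5, var(d)=stationary variance
        theta, var_eps = 0.5, 0.75  # stationary var = 0.75 / (1 - 0.25) = 1.0
        cfg = SimulationConfig(
            n_individuals=40000, ages=np.arange(6.0), theta_t=theta,
            var_eps_t=var_eps, var_d0=1.0, seed=35,
        )
        _, truth = simulate_population(cfg)
        series = make_series(truth.x_obs, ages=truth.ages)
        got = canalized_variance(series, 3)
        assert got == pytest.approx(exact_canalized_variance(theta, 1.0), abs=0.05)

    def test_diverging_chreods_give_positive_value(self):
        cfg = SimulationConfig(
            n_individuals=5000, ages=np.arange(4.0), theta_t=0.0,
            var_eps_t=0.01, var_mu0=1.0, zeta_t=0.3, seed=36,
        )
        _, truth = simulate_population(cfg)
        series = make_series(truth.x_obs, ages=truth.ages)
        assert canalized_variance(series, 2) > 0.1


class TestDecomposeVariance:
    def test_constant_trait_all_zero(self):
        series = make_series(np.full((5, 4), 3.0))
        table = decompose_variance(series).table
        assert np.allclose(table["cross_var"], 0.0)
        assert np.allclose(table["cv"], 0.0)

    def test_closure_is_exact(self, isogenic_series):
        table = decompose_variance(isogenic_series).table
        lhs = (table["canalized_var"] + table["new_var"]).to_numpy()[:-1]
        rhs = np.diff(table["cross_var"].to_numpy())
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_canalized_curve_tracks_exact_form(self):
        theta_sched = np.array([0.5, 0.5, 0.2, 0.2, 0.0])
        cfg = SimulationConfig(
            n_individuals=30000, ages=np.arange(6.0), theta_t=theta_sched,
            var_eps_t=0.5, var_d0=1.0, seed=37,
        )
        _, truth = simulate_population(cfg)
        series = make_series(truth.x_obs, ages=truth.ages)
        table = decompose_variance(series).table
        for t, th in enumerate(theta_sched):
            var_d = np.var(truth.d[:, t], ddof=1)
            expected = exact_canalized_variance(th, var_d)
            # 1.5x rule deviates from the exact form by theta^2 - 0.5 theta
            slack = abs(th**2 - 0.5 * th) * var_d + 0.05
            assert abs(table["canalized_var"][t] - expected) <= slack

    def test_timing_variation_resembles_targeted_growth(self):
        from chreodkit import simulate_timing_variation

        ds = simulate_timing_variation(
            dict(amplitude=10.0, mean_onset=12.0, scale=1.0),
            onset_sd=1.0, n=2000, ages=np.arange(2.0, 23.0), seed=38,
        )
        wide = ds.pivot(index="individual_id", columns="age", values="value")
        series = make_series(wide.to_numpy(), ages=wide.columns.to_numpy())
        table = decompose_variance(series).table.set_index("age")
        # variance rises into the spurt window and falls after it
        assert table.loc[12.0, "cross_var"] > 5 * table.loc[2.0, "cross_var"]
        assert table.loc[20.0, "cross_var"] < 0.1 * table.loc[12.0, "cross_var"]
        # the falling flank shows strongly negative "canalized" variance
        late = table.loc[13.0:18.0, "canalized_var"]
        assert late.min() < -0.5

    def test_zero_mean_age_flags_cv(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(20, 3))
        values[:, 1] -= values[:, 1].mean()
        series = make_series(values)
        table = decompose_variance(series).table
        assert np.isnan(table["cv"][1])
        assert np.isfinite(table["cross_var"][1])


class TestMeasurementError:
    def replicate_frame(self, rng, noise_by_age):
        rows = []
        for ind in range(4):
            for age, sd in noise_by_age.items():
                true = 100 + 5 * age + 10 * ind
                for rep in range(50):
                    rows.append({
                        "individual_id": f"i{ind}", "age": age, "replicate": rep,
                        "value": true + sd * rng.standard_normal(),
                    })
        return pd.DataFrame(rows)

    def test_identical_replicates_zero_error(self):
        df = self.replicate_frame(np.random.default_rng(10), {2.0: 0.0, 8.0: 0.0})
        model = estimate_measurement_error(df)
        assert model.var_eta_pooled == pytest.approx(0.0)

    def test_injected_noise_recovered(self):
        df = self.replicate_frame(np.random.default_rng(11), {2.0: np.sqrt(0.2)})
        model = estimate_measurement_error(df)
        assert model.var_eta_pooled == pytest.approx(0.2, rel=0.2)

    def test_per_age_estimates_and_pooling(self):
        df = self.replicate_frame(np.random.default_rng(12),
                                  {2.0: np.sqrt(0.1), 8.0: np.sqrt(0.4)})
        model = estimate_measurement_error(df)
        v2 = model.var_eta(2.0)
        v8 = model.var_eta(8.0)
        assert v2 == pytest.approx(0.1, rel=0.3)
        assert v8 == pytest.approx(0.4, rel=0.3)
        assert min(v2, v8) < model.var_eta_pooled < max(v2, v8)

    def test_single_replicates_rejected(self):
        df = pd.DataFrame({
            "individual_id": ["a", "b"], "age": [2.0, 2.0],
            "replicate": [0, 0], "value": [1.0, 2.0],
        })
        with pytest.raises(ValueError):
            estimate_measurement_error(df)

    def test_error_free_limit(self):
        assert expected_theta_with_error(0.4, 1.0, 0.0, 0.0, 0.0) == pytest.approx(0.4)

    def test_pure_error_mimics_canalization(self):
        assert expected_theta_with_error(0.0, 1.0, 0.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_error_law_matches_simulation(self):
        theta, var_d, var_eta = 0.4, 1.0, 0.5
        reps, n = 200, 2000
        covs = np.empty(reps)
        varis = np.empty(reps)
        for r in range(reps):
            cfg = SimulationConfig(
                n_individuals=n, ages=[0.0, 1.0], theta_t=theta,
                var_eps_t=0.2, var_d0=var_d, var_eta=var_eta, seed=2000 + r,
            )
            _, truth = simulate_population(cfg)
            x0, x1 = truth.x_obs[:, 0], truth.x_obs[:, 1]
            covs[r] = np.cov(x1 - x0, x0, ddof=1)[0, 1]
            varis[r] = np.var(x0, ddof=1)
        theta_star = -covs.mean() / varis.mean()
        resid = -covs - theta_star * varis
        se = resid.std(ddof=1) / (varis.mean() * np.sqrt(reps))
        expected = expected_theta_with_error(theta, var_d, 0.0, 0.0, var_eta)
        assert abs(theta_star - expected) < 3 * se

    def test_covariance_correction_round_trip(self):
        theta, var_d, var_eta = 0.4, 1.0, 0.3
        reps, n = 100, 2000
        obs = np.empty(reps)
        for r in range(reps):
            cfg = SimulationConfig(
                n_individuals=n, ages=[0.0, 1.0], theta_t=theta,
                var_eps_t=0.0, var_d0=var_d, var_eta=var_eta, seed=3000 + r,
            )
            _, truth = simulate_population(cfg)
            x0, x1 = truth.x_obs[:, 0], truth.x_obs[:, 1]
            obs[r] = np.cov(x1 - x0, x0, ddof=1)[0, 1]
        # raw lag covariance is depressed by var_eta; correction restores it
        error_free = -theta * var_d
        assert obs.mean() == pytest.approx(error_free - var_eta, abs=0.02)
        corrected = correct_covariance_for_error(obs.mean(), var_eta)
        mc_se = obs.std(ddof=1) / np.sqrt(reps)
        assert abs(corrected - error_free) < 3 * mc_se

    def test_null_theta_corrected_canalized_variance(self):
        cfg = SimulationConfig(
            n_individuals=30000, ages=[0.0, 1.0], theta_t=0.0,
            var_eps_t=0.0, var_d0=1.0, var_eta=0.3, seed=39,
        )
        _, truth = simulate_population(cfg)
        x0, x1 = truth.x_obs[:, 0], truth.x_obs[:, 1]
        cov = np.cov(x1 - x0, x0, ddof=1)[0, 1]
        assert 1.5 * cov < -0.3  # error alone mimics canalization
        assert 1.5 * correct_covariance_for_error(cov, 0.3) == pytest.approx(0.0, abs=0.05)


class TestThetaLags:
    def test_lag_one_matches_estimate_theta(self, isogenic_series):
        got = estimate_theta_lags(isogenic_series, 6, p=1)
        assert got[0] == pytest.approx(estimate_theta(isogenic_series, 6))

    def test_pure_lag_one_process_has_null_second_lag(self, isogenic_series):
        coefs = estimate_theta_lags(isogenic_series, 6, p=2)
        assert coefs[0] == pytest.approx(0.4, abs=0.08)
        assert coefs[1] == pytest.approx(0.0, abs=0.08)

    def test_planted_lag_two_reversion_recovered(self):
        rng = np.random.default_rng(13)
        n, T = 5000, 8
        th1, th2 = 0.3, 0.25
        d = np.zeros((n, T))
        d[:, 0] = rng.standard_normal(n)
        d[:, 1] = rng.standard_normal(n)
        for t in range(1, T - 1):
            d[:, t + 1] = d[:, t] - th1 * d[:, t] - th2 * d[:, t - 1] \
                + rng.standard_normal(n)
        series = make_series(d)
        coefs = estimate_theta_lags(series, 5, p=2)
        assert coefs[0] == pytest.approx(th1, abs=0.06)
        assert coefs[1] == pytest.approx(th2, abs=0.06)

    def test_insufficient_lags_rejected(self, isogenic_series):
        with pytest.raises(IndexError):
            estimate_theta_lags(isogenic_series, 0, p=2)


# ---------------------------------------------------------------------------
# invariants


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**16), shift=st.floats(-1e3, 1e3))
def test_estimate_theta_translation_invariant(seed, shift):
    """Adding a common constant to every value leaves theta unchanged."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(30, 4))
    base = make_series(values)
    shifted = make_series(values + shift)
    for t in range(3):
        assert estimate_theta(shifted, t) == pytest.approx(
            estimate_theta(base, t), rel=1e-6, abs=1e-9
        )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**16), n=st.integers(4, 40), T=st.integers(3, 9))
def test_decomposition_closure_any_dataset(seed, n, T):
    """canalized + new variance equals the cross-sectional variance change."""
    rng = np.random.default_rng(seed)
    series = make_series(rng.normal(size=(n, T)) * rng.gamma(2.0))
    table = decompose_variance(series).table
    lhs = (table["canalized_var"] + table["new_var"]).to_numpy()[:-1]
    rhs = np.diff(table["cross_var"].to_numpy())
    assert np.allclose(lhs, rhs, atol=1e-10)


@pytest.mark.parametrize("true_theta", [0.0, 0.25, 0.5, 1.0, 1.5])
def test_isogenic_unbiasedness(true_theta):
    """Mean recovered theta over replicates is within 3 MC SE of the truth."""
    reps, n = 60, 1000
    ests = np.empty(reps)
    for r in range(reps):
        cfg = SimulationConfig(
            n_individuals=n, ages=np.arange(5.0), theta_t=true_theta,
            var_eps_t=1.0, var_d0=1.0, seed=4000 + r,
        )
        _, truth = simulate_population(cfg)
        series = make_series(truth.x_obs, ages=truth.ages)
        ests[r] = estimate_theta(series, 2)
    se = ests.std(ddof=1) / np.sqrt(reps)
    assert abs(ests.mean() - true_theta) < 3 * se


@pytest.mark.parametrize("ratio", [0.25, 1.0, 4.0])
@pytest.mark.parametrize("zeta", [0.0, 0.2])
def test_bias_law_matches_simulation(ratio, zeta):
    """Empirical biased theta follows the trajectory-heterogeneity law."""
    theta, var_d = 0.5, 1.0
    var_mu = ratio * var_d
    reps, n = 60, 1500
    covs = np.empty(reps)
    varis = np.empty(reps)
    for r in range(reps):
        cfg = SimulationConfig(
            n_individuals=n, ages=[0.0, 1.0], theta_t=theta,
            var_eps_t=0.1, var_mu0=var_mu, var_d0=var_d, zeta_t=zeta,
            seed=5000 + r,
        )
        _, truth = simulate_population(cfg)
        x0, x1 = truth.x_obs[:, 0], truth.x_obs[:, 1]
        covs[r] = np.cov(x1 - x0, x0, ddof=1)[0, 1]
        varis[r] = np.var(x0, ddof=1)
    theta_tilde = -covs.mean() / varis.mean()
    resid = -covs - theta_tilde * varis
    se = resid.std(ddof=1) / (varis.mean() * np.sqrt(reps))
    expected = theta_bias(theta, var_mu, var_d, zeta)
    assert abs(theta_tilde - expected) < 3 * se
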