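import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import panelkink as pk
from panelkink.exceptions import ConfigError, JoinError
from panelkink.gmm import MomentSystem, _assemble
from panelkink.panel import first_difference
from panelkink.simulate import ThresholdParams


def _noise_free_cfg(n=400, seed=11, gamma=None):
    cfg = pk.default_bcs_config("female", n_individuals=n, seed=seed)
    truth = cfg.truth if gamma is None else dataclasses.replace(cfg.truth, gamma=gamma)
    # remove all outcome noise and endogeneity so the kinked equation holds
    # exactly, moving the fixed effect's BMI contribution into the persistent
    # component so the BMI dispersion (and hence the grid support) is unchanged
    sigma_a = np.hypot(cfg.sigma_bmi_persistent, cfg.lambda_endog * cfg.sigma_omega)
    return dataclasses.replace(cfg, truth=truth, sigma_eps=0.0, sigma_omega=0.0,
                               rho_shock=0.0, lambda_endog=0.0,
                               sigma_bmi_persistent=float(sigma_a))


def _random_system(rng, n=60, k=3, m=5):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    Z = np.column_stack([X[:, :1], rng.normal(size=(n, m - 1)) + 0.4 * X[:, 1:2]])
    y = X @ rng.normal(size=k) + rng.normal(size=n)
    return MomentSystem(X=X, Z=Z, y=y, ids=np.arange(n), q1=np.zeros(n), q2=np.zeros(n),
                        regressor_names=[f"x{j}" for j in range(k)],
                        instrument_names=[f"z{j}" for j in range(m)])


class TestBuildMomentSystem:
    def test_differenced_kink_values(self, toy_panel, toy_instruments):
        rows = first_difference(toy_panel)
        system = pk.build_moment_system(rows, toy_instruments, gamma=25.0)
        dk = dict(zip(system.ids, system.X[:, -1]))
        # a: (26.5-25)+ - (24-25)+ = 1.5 ; b: 6 - 5 = 1 ; c: q1 = q2 -> 0
        assert dk["a"] == 1.5 and dk["b"] == 1.0 and dk["c"] == 0.0

    def test_hand_assembled_arrays(self, toy_panel, toy_instruments):
        rows = first_difference(toy_panel)
        system = pk.build_moment_system(rows, toy_instruments, gamma=30.0)
        by_id = rows.set_index("id")
        for i, pid in enumerate(system.ids):
            np.testing.assert_allclose(
                system.X[i],
                [1.0, by_id.loc[pid, "d_x1"], by_id.loc[pid, "d_bmi"],
                 max(by_id.loc[pid, "bmi_2"] - 30, 0) - max(by_id.loc[pid, "bmi_1"] - 30, 0)])
            inst_row = toy_instruments.df.set_index("id").loc[pid]
            np.testing.assert_allclose(
                system.Z[i], [1.0, by_id.loc[pid, "d_x1"], *inst_row])
        assert system.y.tolist() == [by_id.loc[p, "d_hours"] for p in system.ids]

    def test_missing_individual_raises_join_error(self, toy_panel, toy_instruments):
        rows = first_difference(toy_panel)
        short = pk.InstrumentTable(toy_instruments.df.iloc[:2])
        with pytest.raises(JoinError, match="c"):
            pk.build_moment_system(rows, short, gamma=25.0)


class TestGmmLinear:
    def test_self_instruments_collapse_to_least_squares(self):
        rng = np.random.default_rng(0)
        n, k = 80, 4
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = X @ rng.normal(size=k) + rng.normal(size=n)
        system = MomentSystem(X=X, Z=X.copy(), y=y, ids=np.arange(n),
                              q1=np.zeros(n), q2=np.zeros(n),
                              regressor_names=list("abcd"), instrument_names=list("abcd"))
        Wsqrt = rng.normal(size=(k, k))
        W = Wsqrt @ Wsqrt.T + k * np.eye(k)     # arbitrary SPD weight
        theta, _ = pk.gmm_linear_at_gamma(system, W)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(theta, ols, atol=1e-10)

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(7)
        system = _random_system(rng, n=30, k=3, m=5)
        W = np.eye(5)
        theta, obj = pk.gmm_linear_at_gamma(system, W)

        def criterion(t):
            gbar = system.Z.T @ (system.y - system.X @ t) / system.n
            return system.n * gbar @ W @ gbar

        res = optimize.minimize(criterion, np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        np.testing.assert_allclose(theta, res.x, atol=1e-6)
        assert obj <= res.fun + 1e-8

    def test_noise_free_data_exact_at_true_threshold(self):
        panel, inst, truth = pk.simulate_panel(_noise_free_cfg())
        rows = first_difference(panel.balanced_view())
        system = pk.build_moment_system(rows, inst, truth.gamma)
        n = system.n
        W = np.linalg.inv(system.Z.T @ system.Z / n)
        theta, obj = pk.gmm_linear_at_gamma(system, W)
        assert obj < 1e-12
        np.testing.assert_allclose(theta[-2], truth.alpha, atol=1e-8)
        np.testing.assert_allclose(theta[-1], truth.delta, atol=1e-8)


class TestProfile:
    def test_grid_spans_trimmed_quantiles(self, toy_panel, toy_instruments):
        cfg = pk.default_bcs_config("female", n_individuals=300, seed=2)
        panel, inst, _ = pk.simulate_panel(cfg)
        rows = first_difference(panel.balanced_view())
        prof = pk.profile_gamma(rows, inst, pk.GmmSpec(trim_rate=0.3, grid_points=50))
        pooled = np.concatenate([rows["bmi_1"], rows["bmi_2"]])
        lo, hi = np.quantile(pooled, [0.15, 0.85])
        assert prof["gamma"].iloc[0] == pytest.approx(lo)
        assert prof["gamma"].iloc[-1] == pytest.approx(hi)

    def test_noise_free_minimum_at_true_threshold(self):
        panel, inst, truth = pk.simulate_panel(_noise_free_cfg())
        rows = first_difference(panel.balanced_view())
        grid = np.unique(np.concatenate([np.linspace(22, 31, 80), [truth.gamma]]))
        prof = pk.profile_gamma(rows, inst, pk.GmmSpec(grid_values=grid))
        ok = prof[~prof.skipped]
        best = ok.loc[ok.objective.idxmin()]
        assert best.gamma == truth.gamma
        assert best.objective < 1e-10

    def test_profile_is_smooth_in_gamma(self):
        cfg = pk.default_bcs_config("female", n_individuals=800, seed=760000)
        panel, inst, _ = pk.simulate_panel(cfg)
        rows = first_difference(panel.balanced_view())
        prof = pk.profile_gamma(rows, inst, pk.GmmSpec())
        obj = prof.loc[~prof.skipped, "objective"].to_numpy()
        spread = obj.max() - obj.min()
        assert np.abs(np.diff(obj)).max() < 0.15 * spread

    @pytest.mark.parametrize("seed", [740000, 740005, 740011])
    def test_no_kink_profile_is_flat(self, seed):
        # band calibrated by simulating the no-kink model: relative range stays
        # within sampling noise of the criterion, far from the kinked case
        cfg = pk.default_bcs_config("female", n_individuals=800, seed=seed)
        cfg = dataclasses.replace(cfg, truth=dataclasses.replace(cfg.truth, delta=0.0))
        panel, inst, _ = pk.simulate_panel(cfg)
        rows = first_difference(panel.balanced_view())
        prof = pk.profile_gamma(rows, inst, pk.GmmSpec(grid_points=100))
        obj = prof.loc[~prof.skipped, "objective"]
        assert (obj.max() - obj.min()) / np.median(obj) < 12.0

    def test_empty_grid_is_config_error(self, toy_panel, toy_instruments):
        rows = first_difference(toy_panel)
        with pytest.raises(ConfigError):
            pk.profile_gamma(rows, toy_instruments, pk.GmmSpec(grid_values=np.array([])))


class TestFit:
    def test_noise_free_exact_recovery_on_grid(self):
        panel, inst, truth = pk.simulate_panel(_noise_free_cfg())
        grid = np.unique(np.concatenate([np.linspace(22, 31, 120), [truth.gamma]]))
        fit = pk.fit_panel_threshold(panel, inst, pk.GmmSpec(grid_values=grid))
        assert fit.params.gamma == truth.gamma
        np.testing.assert_allclose(fit.params.alpha, truth.alpha, atol=1e-8)
        np.testing.assert_allclose(fit.params.delta, truth.delta, atol=1e-8)
        np.testing.assert_allclose(fit.params.beta[:3], [2.0, -1.5, 3.0], atol=1e-8)

    def test_dropped_period_collinear_covariates(self):
        cfg = pk.default_bcs_config("female", n_individuals=150, seed=4)
        panel, inst, _ = pk.simulate_panel(cfg)
        fit = pk.fit_panel_threshold(panel, inst, pk.GmmSpec(grid_points=60))
        assert "d_age" in fit.dropped_covariates

    def test_scale_equivariance(self):
        cfg = pk.default_bcs_config("female", n_individuals=300, seed=6)
        panel, inst, _ = pk.simulate_panel(cfg)
        spec = pk.GmmSpec(grid_points=80)
        fit1 = pk.fit_panel_threshold(panel, inst, spec)
        c = 3.7
        scaled_df = panel.df.assign(hours=panel.df["hours"] * c)
        scaled = pk.PanelDataset(scaled_df, panel.covariate_names)
        fit2 = pk.fit_panel_threshold(scaled, inst, spec)
        assert fit2.params.gamma == fit1.params.gamma
        np.testing.assert_allclose(fit2.params.alpha, c * fit1.params.alpha, rtol=1e-6)
        np.testing.assert_allclose(fit2.params.delta, c * fit1.params.delta, rtol=1e-6)
        i_alpha = fit1.param_names.index("alpha")
        i_delta = fit1.param_names.index("delta")
        np.testing.assert_allclose(fit2.se[[i_alpha, i_delta]],
                                   c * fit1.se[[i_alpha, i_delta]], rtol=1e-6)

    def test_j_statistic_contract(self):
        cfg = pk.default_bcs_config("female", n_individuals=400, seed=8)
        panel, inst, _ = pk.simulate_panel(cfg)
        fit = pk.fit_panel_threshold(panel, inst, pk.GmmSpec(grid_points=60))
        assert fit.j_statistic >= 0
        # moments: intercept + 3 kept differenced covariates + 4 instruments;
        # parameters: intercept + 3 covariates + alpha + delta + gamma
        assert fit.j_df == 8 - 7
        assert 0.0 <= fit.j_pvalue <= 1.0
        below, above = fit.regime_slopes
        assert above == pytest.approx(fit.params.alpha + fit.params.delta)

    def test_gmm_less_biased_than_naive_least_squares_under_endogeneity(self):
        # shock correlation makes differenced BMI endogenous: naive FD least
        # squares is biased, instrumented GMM is not (large-sample check)
        cfg = pk.default_bcs_config("female", n_individuals=20_000, seed=720000)
        cfg = dataclasses.replace(cfg, truth=dataclasses.replace(cfg.truth, delta=0.0))
        panel, inst, truth = pk.simulate_panel(cfg)
        rows = first_difference(panel.balanced_view())
        base = _assemble(rows, inst)
        ols_alpha = np.linalg.lstsq(base["x0"], base["y"], rcond=None)[0][-1]
        n_dx = base["x0"].shape[1] - 2
        beta, _, _ = pk.two_stage_least_squares(
            base["y"], base["x0"][:, :1 + n_dx], base["x0"][:, -1], base["z"][:, 1 + n_dx:])
        assert abs(ols_alpha - truth.alpha) > 3 * abs(beta[-1] - truth.alpha)

    def test_bootstrap_se_runs(self):
        cfg = pk.default_bcs_config("female", n_individuals=120, seed=14)
        panel, inst, _ = pk.simulate_panel(cfg)
        spec = pk.GmmSpec(grid_points=40, se_method="pairs_bootstrap",
                          bootstrap_reps=25, bootstrap_seed=3)
        fit = pk.fit_panel_threshold(panel, inst, spec)
        assert np.all(fit.se > 0)
        assert len(fit.se) == len(fit.param_names)


class TestRegimeSlopes:
    @pytest.mark.parametrize("alpha, delta, above", [
        (4.656, -7.088, -2.432),
        (0.0, 0.0, 0.0),
        (1.0, -1.0, 0.0),
    ])
    def test_values(self, alpha, delta, above):
        params = ThresholdParams(beta0=0.0, beta=np.zeros(1), alpha=alpha,
                                 delta=delta, gamma=30.0)
        below, top = pk.regime_slopes(params)
        assert below == alpha
        assert top == pytest.approx(above)
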