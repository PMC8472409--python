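"""First-difference GMM estimation of the continuous (kink) panel threshold model.

The outcome equation has slope ``alpha`` in the threshold variable ``q`` below
an unknown threshold ``gamma`` and ``alpha + delta`` above it, with the change
occurring continuously (no jump).  First-differencing removes the individual
fixed effect; the differenced kink term
``(q_2 - gamma)1{q_2 >= gamma} - (q_1 - gamma)1{q_1 >= gamma}`` must be
re-evaluated from the level BMIs at every candidate threshold, so the model is
linear in ``(beta, alpha, delta)`` only conditional on ``gamma``.  Estimation
therefore profiles a trimmed grid of candidate thresholds: at each grid value
the linear GMM problem is solved in closed form, and the threshold estimate is
the grid minimizer of the GMM criterion.

Instruments: the differenced exogenous covariates instrument themselves; the
endogenous columns (differenced BMI and differenced kink) are instrumented by
time-invariant childhood anthropometry.  Weighting is two-step by default
(first step ``(Z'Z/n)^{-1}``, second step the inverse sample covariance of the
moment contributions, with one re-profiling of the threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, JoinError, SingularityError
from .panel import InstrumentTable, PanelDataset, first_difference
from .simulate import ThresholdParams

logger = logging.getLogger(__name__)


@dataclass
class GmmSpec:
    """Estimation settings for the threshold GMM.

    ``trim_rate`` is the TOTAL fraction of the pooled threshold-variable
    distribution excluded from the grid, half from each tail (0.3 means the
    grid spans the 15th to 85th percentiles).  ``grid`` selects an even grid
    of ``grid_points`` values or the empirical sample values themselves;
    ``grid_values`` overrides both.  Grid candidates leaving fewer than
    ``min_regime_fraction`` of pooled observations in either regime are
    skipped (they make the kink column nearly collinear).
    """

    trim_rate: float = 0.3
    grid_points: int = 400
    grid: str = "even"                      # "even" | "sample"
    grid_values: np.ndarray | None = None
    weighting: str = "two_step"             # "two_step" | "identity"
    se_method: str = "analytic_sandwich"    # "analytic_sandwich" | "pairs_bootstrap"
    bootstrap_reps: int = 500
    bootstrap_seed: int = 0
    min_regime_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.trim_rate < 1.0:
            raise ConfigError("trim_rate must lie in (0, 1)")
        if self.grid_points < 1:
            raise ConfigError("grid_points must be positive")
        if not 0.0 <= self.min_regime_fraction < 0.5:
            raise ConfigError("min_regime_fraction must lie in [0, 0.5)")
        if self.weighting not in ("two_step", "identity"):
            raise ConfigError(f"unknown weighting {self.weighting!r}")
        if self.se_method not in ("analytic_sandwich", "pairs_bootstrap"):
            raise ConfigError(f"unknown se_method {self.se_method!r}")
        if self.grid not in ("even", "sample"):
            raise ConfigError(f"unknown grid type {self.grid!r}")


@dataclass
class MomentSystem:
    """Stacked arrays of one linear moment system at a fixed threshold.

    ``X`` holds (intercept, differenced covariates, differenced BMI,
    differenced kink); ``Z`` holds (intercept, differenced covariates, the
    four level instruments); ``y`` is the differenced outcome.
    """

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    ids: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    regressor_names: list[str]
    instrument_names: list[str]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class ThresholdFit:
    """Result of the threshold GMM fit.

    ``params.beta0`` is the first-difference intercept (the common time
    trend); ``params.beta`` are the differenced-covariate coefficients; the
    regime slopes are ``alpha`` below the threshold and ``alpha + delta``
    above.  ``se`` is aligned with ``param_names`` (ending alpha, delta,
    gamma).  ``objective_profile`` has columns gamma/objective/n_below/
    n_above/skipped; the reported ``params.gamma`` attains the profile
    minimum over the non-skipped grid.
    """

    params: ThresholdParams
    se: np.ndarray
    param_names: list[str]
    objective_profile: pd.DataFrame
    j_statistic: float
    j_df: int
    j_pvalue: float
    regime_slopes: tuple[float, float]
    n_used: int
    converged: bool
    dropped_covariates: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def se_for(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        estimates = np.concatenate([[self.params.beta0], self.params.beta,
                                    [self.params.alpha, self.params.delta, self.params.gamma]])
        z = np.divide(estimates, self.se, out=np.full_like(estimates, np.nan),
                      where=self.se > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"estimate": estimates, "se": self.se, "z": z, "p": p},
                            index=self.param_names)


def regime_slopes(params: ThresholdParams) -> tuple[float, float]:
    """Marginal effects of the threshold variable below and above the threshold."""
    return float(params.alpha), float(params.alpha + params.delta)


# ---------------------------------------------------------------------------
# system assembly


def _delta_kink(q1: np.ndarray, q2: np.ndarray, gamma) -> np.ndarray:
    """Differenced kink column(s); gamma may be scalar or a grid (vectorized)."""
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    out = (np.maximum(q2[:, None] - g, 0.0) - np.maximum(q1[:, None] - g, 0.0))
    return out[:, 0] if np.isscalar(gamma) or np.ndim(gamma) == 0 else out

def _assemble(rows: pd.DataFrame, instruments: InstrumentTable):
    """Join instruments and build the gamma-independent parts of the system."""
    inst = instruments.df.set_index("id")
    missing = set(rows["id"]) - set(inst.index)
    if missing:
        raise JoinError(f"individual(s) missing from instrument table: {sorted(missing)[:5]}")
    z = inst.loc[rows["id"], instruments.instrument_names].to_numpy(dtype=float)

    d_cols = [c for c in rows.columns if c.startswith("d_") and c not in ("d_hours", "d_bmi")]
    kept, dropped = [], []
    for c in d_cols:
        if np.std(rows[c].to_numpy(dtype=float)) == 0.0:
            dropped.append(c)      # period-collinear (e.g. age): absorbed by the intercept
        else:
            kept.append(c)
    if dropped:
        logger.info("dropping period-collinear differenced covariate(s) %s "
                    "(absorbed by the first-difference intercept)", dropped)

    n = len(rows)
    dx = rows[kept].to_numpy(dtype=float) if kept else np.empty((n, 0))
    ones = np.ones((n, 1))
    x0 = np.column_stack([ones, dx, rows["d_bmi"].to_numpy(dtype=float)])
    zmat = np.column_stack([ones, dx, z])
    return dict(
        x0=x0, z=zmat, y=rows["d_hours"].to_numpy(dtype=float),
        ids=rows["id"].to_numpy(),
        q1=rows["bmi_1"].to_numpy(dtype=float), q2=rows["bmi_2"].to_numpy(dtype=float),
        regressor_names=["intercept", *kept, "alpha", "delta"],
        instrument_names=["intercept", *kept, *instruments.instrument_names],
        dropped=dropped,
    )


def build_moment_system(rows: pd.DataFrame, instruments: InstrumentTable,
                        gamma: float) -> MomentSystem:
    """Stack the linear moment system at one fixed threshold value.

    ``rows`` is the output of :func:`panelkink.panel.first_difference`.
    """
    base = _assemble(rows, instruments)
    dk = _delta_kink(base["q1"], base["q2"], float(gamma))
    return MomentSystem(
        X=np.column_stack([base["x0"], dk]), Z=base["z"], y=base["y"],
        ids=base["ids"], q1=base["q1"], q2=base["q2"],
        regressor_names=base["regressor_names"],
        instrument_names=base["instrument_names"],
    )


# ---------------------------------------------------------------------------
# linear GMM at fixed threshold


def _safe_inverse(mat: np.ndarray, what: str) -> np.ndarray:
    """Invert an SPD matrix, falling back to a logged ridge-regularized inverse."""
    try:
        if np.linalg.cond(mat) > 1e12:
            raise np.linalg.LinAlgError
        return np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * np.trace(mat) / mat.shape[0]
        logger.warning("%s is ill-conditioned; using ridge-regularized inverse", what)
        return np.linalg.inv(mat + ridge * np.eye(mat.shape[0]))


def gmm_linear_at_gamma(system: MomentSystem, weight_matrix: np.ndarray):
    """Closed-form linear GMM at a fixed threshold.

    Minimizes ``n * gbar(theta)' W gbar(theta)`` with
    ``gbar = Z'(y - X theta)/n``; returns ``(theta, objective-at-optimum)``.
    """
    X, Z, y = system.X, system.Z, system.y
    n = len(y)
    if Z.shape[1] < X.shape[1]:
        raise ConfigError("need at least as many instruments as regressors")
    W = np.asarray(weight_matrix, dtype=float)
    A = Z.T @ X / n
    b = Z.T @ y / n
    M = A.T @ W @ A
    if np.linalg.cond(M) > 1e12:
        raise SingularityError(
            f"instrument cross-product is rank deficient for regressors {system.regressor_names}")
    theta = np.linalg.solve(M, A.T @ W @ b)
    gbar = b - A @ theta
    objective = float(n * gbar @ W @ gbar)
    return theta, objective


# ---------------------------------------------------------------------------
# threshold profiling


def _make_grid(q_pooled: np.ndarray, spec: GmmSpec) -> np.ndarray:
    if spec.grid_values is not None:
        grid = np.sort(np.asarray(spec.grid_values, dtype=float))
    else:
        lo, hi = np.quantile(q_pooled, [spec.trim_rate / 2.0, 1.0 - spec.trim_rate / 2.0])
        if spec.grid == "sample":
            vals = np.unique(q_pooled)
            grid = vals[(vals >= lo) & (vals <= hi)]
        else:
            grid = np.linspace(lo, hi, spec.grid_points)
    if grid.size == 0:
        raise ConfigError("threshold grid is empty after trimming")
    return grid


def _profile(base: dict, grid: np.ndarray, W: np.ndarray, spec: GmmSpec):
    """Minimized GMM objective at every admissible grid value (vectorized kink)."""
    x0, Z, y = base["x0"], base["z"], base["y"]
    q1, q2 = base["q1"], base["q2"]
    n = len(y)
    q_pooled = np.concatenate([q1, q2])
    n_below = np.array([(q_pooled < g).sum() for g in grid])
    n_above = 2 * n - n_below
    min_count = spec.min_regime_fraction * 2 * n
    skipped = (n_below < min_count) | (n_above < min_count)

    dk = _delta_kink(q1, q2, grid)              # n x G
    A0 = Z.T @ x0 / n
    b = Z.T @ y / n
    ZK = Z.T @ dk / n                           # m x G
    objectives = np.full(grid.size, np.nan)
    thetas = np.full((grid.size, x0.shape[1] + 1), np.nan)
    for j in range(grid.size):
        if skipped[j]:
            continue
        A = np.column_stack([A0, ZK[:, j]])
        M = A.T @ W @ A
        if np.linalg.cond(M) > 1e12:
            skipped[j] = True
            continue
        theta = np.linalg.solve(M, A.T @ W @ b)
        gbar = b - A @ theta
        objectives[j] = float(n * gbar @ W @ gbar)
        thetas[j] = theta
    profile = pd.DataFrame({"gamma": grid, "objective": objectives,
                            "n_below": n_below, "n_above": n_above, "skipped": skipped})
    return profile, thetas


def profile_gamma(rows: pd.DataFrame, instruments: InstrumentTable,
                  spec: GmmSpec, weight_matrix: np.ndarray | None = None) -> pd.DataFrame:
    """GMM objective profile over the trimmed threshold grid (first-step weights
    unless a weight matrix is supplied)."""
    if len(rows) == 0:
        raise ConfigError("no differenced rows to profile")
    base = _assemble(rows, instruments)
    grid = _make_grid(np.concatenate([base["q1"], base["q2"]]), spec)
    n = len(base["y"])
    if weight_matrix is None:
        weight_matrix = _safe_inverse(base["z"].T @ base["z"] / n, "Z'Z/n")
    profile, _ = _profile(base, grid, weight_matrix, spec)
    return profile


def _pick_minimum(profile: pd.DataFrame):
    ok = ~profile["skipped"] & np.isfinite(profile["objective"])
    if not ok.any():
        raise ConfigError("every grid candidate leaves a degenerate regime")
    sub = profile[ok]
    # ties broken toward the smaller threshold: idxmin returns the first minimum
    j = int(sub["objective"].idxmin())
    return j


# ---------------------------------------------------------------------------
# full fit


def _moment_contributions(base, theta, gamma):
    dk = _delta_kink(base["q1"], base["q2"], float(gamma))
    X = np.column_stack([base["x0"], dk])
    r = base["y"] - X @ theta
    return base["z"] * r[:, None], X, r


def _sandwich_se(base, theta, gamma, W):
    """Asymptotic sandwich SEs treating the criterion as smooth in the threshold.

    The moment Jacobian gets an extra column for gamma:
    d residual / d gamma = delta * (1{q2 >= gamma} - 1{q1 >= gamma}).
    """
    g_i, X, r = _moment_contributions(base, theta, gamma)
    n = len(r)
    Z = base["z"]
    delta_hat = theta[-1]
    d_gamma = delta_hat * ((base["q2"] >= gamma).astype(float)
                           - (base["q1"] >= gamma).astype(float))
    G = np.column_stack([-(Z.T @ X) / n, (Z.T @ d_gamma) / n])
    gbar = g_i.mean(axis=0)
    omega = (g_i - gbar).T @ (g_i - gbar) / n
    bread = G.T @ W @ G
    try:
        bread_inv = np.linalg.inv(bread)
    except np.linalg.LinAlgError:
        logger.warning("singular Jacobian (delta near zero?); using pseudo-inverse for SEs")
        bread_inv = np.linalg.pinv(bread)
    meat = G.T @ W @ omega @ W @ G
    V = bread_inv @ meat @ bread_inv / n
    return np.sqrt(np.maximum(np.diag(V), 0.0))


def _fit_arrays(base: dict, spec: GmmSpec) -> dict:
    grid = _make_grid(np.concatenate([base["q1"], base["q2"]]), spec)
    n = len(base["y"])
    m = base["z"].shape[1]
    if spec.weighting == "identity":
        W1 = np.eye(m)
    else:
        W1 = _safe_inverse(base["z"].T @ base["z"] / n, "Z'Z/n")
    profile, thetas = _profile(base, grid, W1, spec)
    j = _pick_minimum(profile)
    theta, gamma_hat = thetas[j], float(profile.loc[j, "gamma"])
    W = W1
    resid_scale = float(np.var(base["y"])) + 1.0
    g_i, _, r1 = _moment_contributions(base, theta, gamma_hat)
    if spec.weighting == "two_step" and np.mean(r1 ** 2) < 1e-4 * resid_scale:
        # a perfect step-1 fit has a degenerate moment covariance; reweighting
        # would amplify numerical noise, so the step-1 solution stands
        logger.info("step-1 residuals are numerically zero; skipping reweighting")
    elif spec.weighting == "two_step":
        gbar = g_i.mean(axis=0)
        omega = (g_i - gbar).T @ (g_i - gbar) / n
        W = _safe_inverse(omega, "moment covariance")
        profile, thetas = _profile(base, grid, W, spec)
        j = _pick_minimum(profile)
        theta, gamma_hat = thetas[j], float(profile.loc[j, "gamma"])
    j_stat = float(profile.loc[j, "objective"])
    p = base["x0"].shape[1] + 1 + 1        # linear params + delta + gamma
    j_df = m - p
    return dict(profile=profile, theta=theta, gamma=gamma_hat, W=W,
                j_stat=j_stat, j_df=j_df)


def fit_panel_threshold(data: PanelDataset, instruments: InstrumentTable,
                        spec: GmmSpec | None = None) -> ThresholdFit:
    """Two-step first-difference GMM fit of the kink threshold model.

    Step 1 profiles the threshold with ``(Z'Z/n)^{-1}`` weights; step 2
    re-profiles with the inverse sample covariance of the step-1 moment
    contributions.  The J statistic is ``n`` times the minimized two-step
    criterion with ``#moments - #parameters`` degrees of freedom (the
    threshold counts as a parameter).
    """
    spec = spec or GmmSpec()
    rows = first_difference(data.balanced_view())
    base = _assemble(rows, instruments)
    res = _fit_arrays(base, spec)
    theta, gamma_hat = res["theta"], res["gamma"]

    if spec.se_method == "pairs_bootstrap":
        se = _bootstrap_se(rows, instruments, spec)
    else:
        se = _sandwich_se(base, theta, gamma_hat, res["W"])

    n_dx = len(base["regressor_names"]) - 3    # minus intercept, alpha, delta
    params = ThresholdParams(
        beta0=float(theta[0]), beta=theta[1:1 + n_dx],
        alpha=float(theta[-2]), delta=float(theta[-1]), gamma=gamma_hat,
    )
    names = ["intercept", *base["regressor_names"][1:1 + n_dx], "alpha", "delta", "gamma"]
    j_pvalue = float(stats.chi2.sf(res["j_stat"], res["j_df"])) if res["j_df"] > 0 else np.nan
    return ThresholdFit(
        params=params, se=se, param_names=names,
        objective_profile=res["profile"],
        j_statistic=res["j_stat"], j_df=res["j_df"], j_pvalue=j_pvalue,
        regime_slopes=regime_slopes(params),
        n_used=len(base["y"]), converged=True,
        dropped_covariates=base["dropped"],
    )


def _bootstrap_se(rows: pd.DataFrame, instruments: InstrumentTable, spec: GmmSpec) -> np.ndarray:
    """Pairs bootstrap over individuals: resample rows of the differenced panel."""
    rng = np.random.default_rng(spec.bootstrap_seed)
    n = len(rows)
    draws = []
    for _ in range(spec.bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        resampled = rows.iloc[idx].reset_index(drop=True)
        # resampled individuals must stay joinable and uniquely identified
        resampled["id"] = np.arange(n)
        inst = instruments.df.set_index("id").loc[rows["id"].to_numpy()[idx]].reset_index(drop=True)
        inst["id"] = np.arange(n)
        try:
            base = _assemble(resampled, InstrumentTable(inst))
            res = _fit_arrays(base, spec)
        except (ConfigError, SingularityError):
            continue
        draws.append(np.concatenate([res["theta"], [res["gamma"]]]))
    if len(draws) < 2:
        raise ConfigError("bootstrap produced fewer than 2 successful replicates")
    return np.asarray(draws).std(axis=0, ddof=1)
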