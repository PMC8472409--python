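"""Synthetic two-wave panel generator with an endogenous kinked threshold variable.

The generator emulates the statistical structure the estimators assume: a
two-period panel in which the threshold variable (BMI) is driven by
time-invariant childhood instruments, an individual fixed effect shared with
the outcome equation, a persistent individual component, and period shocks
that are correlated with the outcome shocks (the source of endogeneity that
survives first-differencing).  The outcome responds to BMI through a
continuous kink: slope ``alpha`` below the threshold ``gamma`` and
``alpha + delta`` above it.

Model, per individual ``i`` and period ``t`` in {1, 2}::

    z_i        ~ N(mu_z, Sigma_z)                        (4 childhood instruments)
    omega_i    ~ N(0, sigma_omega^2)                     (fixed effect, enters y)
    a_i        ~ N(0, sigma_bmi_persistent^2)            (persistent BMI component)
    (u_it, eps_it) jointly normal, corr rho_shock        (period shocks)
    q_it = bmi_base_mean + drift*1{t=2} + pi_t'(z_i - mu_z)
           + lambda_endog*omega_i + a_i + u_it
    y_it = beta0 + x_it'beta + alpha*q_it + delta*max(q_it - gamma, 0)
           + omega_i + eps_it

with period-specific instrument loadings ``pi_1 = pi`` and
``pi_2 = (1 + pi_growth) * pi``: childhood adiposity predicts not only the
level of adult BMI but its trajectory, which is what makes the instruments
relevant in the first-differenced equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .panel import InstrumentTable, PanelDataset, kink_transform

DEFAULT_COVARIATES = ["degree", "family_size", "high_skill", "england", "age"]

#: survey moments used for the two default arms: per-arm dictionaries of the
#: marginal means/SDs the generator reproduces (instrument moments, BMI level
#: and drift, outcome mean/SD, covariate proportions).
_ARM_MOMENTS = {
    "female": dict(
        instrument_means=(3.267, 16.848, 23.248, 24.489),
        instrument_sds=(0.506, 2.160, 3.629, 2.924),
        bmi_base_mean=24.919,
        bmi_drift=25.891 - 24.919,
        bmi_sds=(4.615, 4.870),
        hours_mean_p1=31.343,
        hours_sd_p1=11.684,
        truth=(4.656, -7.088, 30.021),  # (alpha, delta, gamma)
        degree_p=(0.197, 0.287),
        family_size=(3.388, 1.006, 3.496),
        high_skill_p=(0.469, 0.551),
        england_p=0.843,
        sigma_eps=5.0,
    ),
    "male": dict(
        instrument_means=(3.401, 16.738, 23.338, 24.340),
        instrument_sds=(0.521, 1.872, 3.784, 2.710),
        bmi_base_mean=26.579,
        bmi_drift=27.334 - 26.579,
        bmi_sds=(4.140, 4.359),
        hours_mean_p1=45.285,
        hours_sd_p1=7.896,
        truth=(-3.021, 3.439, 25.658),
        degree_p=(0.222, 0.308),
        family_size=(3.151, 1.039, 3.485),
        high_skill_p=(0.533, 0.578),
        england_p=0.834,
        sigma_eps=4.0,
    ),
}

AGES = (34.0, 42.0)


@dataclass
class ThresholdParams:
    """Parameters of the kinked outcome equation.

    ``beta0`` is the intercept, ``beta`` the covariate coefficients, ``alpha``
    the below-threshold slope of the threshold variable, ``delta`` the slope
    change at the threshold ``gamma``.  The regime slopes are ``alpha`` below
    and ``alpha + delta`` above.
    """

    beta0: float
    beta: np.ndarray
    alpha: float
    delta: float
    gamma: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.isfinite(self.gamma):
            raise ConfigError("gamma must be finite")

    @property
    def slope_below(self) -> float:
        return self.alpha

    @property
    def slope_above(self) -> float:
        return self.alpha + self.delta


@dataclass
class CovariateScheme:
    """Rules for generating the time-varying covariates.

    Degree and high-skill status are Bernoulli in period 1 with one-way
    upgrades calibrated so the period-2 proportion matches; family size is a
    rounded normal with a small period drift; region is a constant Bernoulli;
    age is deterministic (the two survey ages).
    """

    degree_p: tuple[float, float] = (0.197, 0.287)
    family_size_mean: float = 3.388
    family_size_sd: float = 1.006
    family_size_mean_p2: float = 3.496
    high_skill_p: tuple[float, float] = (0.469, 0.551)
    england_p: float = 0.843
    ages: tuple[float, float] = AGES

    def expected_x(self, period: int) -> np.ndarray:
        """Population mean of the covariate vector in the given period."""
        j = period - 1
        fam = self.family_size_mean if period == 1 else self.family_size_mean_p2
        return np.array([self.degree_p[j], fam, self.high_skill_p[j],
                         self.england_p, self.ages[j]])


@dataclass
class SimulationConfig:
    """Complete description of one synthetic study arm.

    All scale parameters are in the units of the quantities they perturb
    (hours for ``sigma_omega``/``sigma_eps``, kg/m^2 for the BMI components).
    ``rho_shock`` is the within-period correlation of the BMI and outcome
    shocks and is the only channel of endogeneity that survives
    first-differencing; ``lambda_endog`` creates the levels endogeneity that
    biases pooled least squares.
    """

    n_individuals: int
    truth: ThresholdParams
    covariate_names: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    instrument_means: np.ndarray = field(default_factory=lambda: np.array(_ARM_MOMENTS["female"]["instrument_means"]))
    instrument_sds: np.ndarray = field(default_factory=lambda: np.array(_ARM_MOMENTS["female"]["instrument_sds"]))
    instrument_corr: np.ndarray | None = None
    pi: np.ndarray = field(default_factory=lambda: np.zeros(4))
    pi_growth: float = 0.5
    lambda_endog: float = 0.5
    sigma_omega: float = 5.0
    sigma_u: float = 1.5
    sigma_eps: float = 5.0
    rho_shock: float = -0.35
    sigma_bmi_persistent: float = 3.0
    bmi_base_mean: float = 24.919
    bmi_drift: float = 0.972
    measurement_error_sd: float = 0.0
    instrument_direct_effect: float = 0.0
    covariate_scheme: CovariateScheme = field(default_factory=CovariateScheme)
    gender: str = "female"
    skill_truth: dict[str, ThresholdParams] | None = None
    p_self_employed_p1: float = 0.0
    p_not_working: float = 0.0
    p_pregnant: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.instrument_means = np.asarray(self.instrument_means, dtype=float)
        self.instrument_sds = np.asarray(self.instrument_sds, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be at least 2")
        for name in ("sigma_omega", "sigma_u", "sigma_eps", "sigma_bmi_persistent",
                     "measurement_error_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if (self.instrument_sds <= 0).any():
            raise ConfigError("instrument SDs must be strictly positive")
        if not -1.0 < self.rho_shock < 1.0:
            raise ConfigError("rho_shock must lie in (-1, 1)")
        if self.gender not in ("female", "male"):
            raise ConfigError(f"unknown gender label {self.gender!r}")

    # -- closed-form moments used by the property tests ------------------
    def instrument_covariance(self) -> np.ndarray:
        d = np.diag(self.instrument_sds)
        corr = np.eye(4) if self.instrument_corr is None else np.asarray(self.instrument_corr)
        return d @ corr @ d

    def bmi_variance(self, period: int) -> float:
        """Population variance of BMI in the given period."""
        pi_t = self.pi * (1.0 + self.pi_growth if period == 2 else 1.0)
        sigma_z = self.instrument_covariance()
        return float(pi_t @ sigma_z @ pi_t
                     + self.lambda_endog ** 2 * self.sigma_omega ** 2
                     + self.sigma_bmi_persistent ** 2 + self.sigma_u ** 2)

    def instrument_share(self) -> float:
        """Instrument-explained share of BMI variance, averaged over periods."""
        sigma_z = self.instrument_covariance()
        shares = []
        for period in (1, 2):
            pi_t = self.pi * (1.0 + self.pi_growth if period == 2 else 1.0)
            shares.append(float(pi_t @ sigma_z @ pi_t) / self.bmi_variance(period))
        return float(np.mean(shares))

    def bmi_outcome_shock_covariance(self) -> float:
        """Closed-form Cov(q_it, omega_i + eps_it) (levels endogeneity)."""
        return (self.lambda_endog * self.sigma_omega ** 2
                + self.rho_shock * self.sigma_u * self.sigma_eps)


# ---------------------------------------------------------------------------


def _truth_arrays(config: SimulationConfig, skill1: np.ndarray):
    """Per-individual (alpha, delta, gamma), honoring any per-skill override."""
    n = config.n_individuals
    t = config.truth
    alpha = np.full(n, t.alpha)
    delta = np.full(n, t.delta)
    gamma = np.full(n, t.gamma)
    if config.skill_truth:
        labels = np.where(skill1 == 1, "high", "low")
        for label, params in config.skill_truth.items():
            mask = labels == label
            alpha[mask], delta[mask], gamma[mask] = params.alpha, params.delta, params.gamma
    return alpha, delta, gamma


def simulate_panel(config: SimulationConfig) -> tuple[PanelDataset, InstrumentTable, ThresholdParams]:
    """Draw one synthetic panel; identical configs (and seeds) give identical data.

    Returns the long-format panel, the per-individual instrument table and the
    generating :class:`ThresholdParams` (for recovery experiments).
    Randomness is split into named substreams derived from ``config.seed`` so
    that, e.g., changing the covariate scheme does not perturb the BMI draws.
    """
    n = config.n_individuals
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_z, rng_omega, rng_bmi, rng_cov, rng_eps, rng_labels = (
        np.random.default_rng(s) for s in streams
    )

    # instruments: one draw per individual, time-invariant
    sigma_z = config.instrument_covariance()
    z = rng_z.multivariate_normal(config.instrument_means, sigma_z, size=n, method="cholesky")
    zc = z - config.instrument_means

    omega = rng_omega.normal(0.0, config.sigma_omega, size=n)
    a_i = rng_bmi.normal(0.0, config.sigma_bmi_persistent, size=n)
    e_u = rng_bmi.normal(size=(n, 2))          # shared innovation of the period shocks
    e_eps = rng_eps.normal(size=(n, 2))
    u = config.sigma_u * e_u
    eps = config.sigma_eps * (config.rho_shock * e_u
                              + np.sqrt(1.0 - config.rho_shock ** 2) * e_eps)

    # covariates
    sch = config.covariate_scheme
    degree1 = (rng_cov.random(n) < sch.degree_p[0]).astype(float)
    up_p = 0.0 if sch.degree_p[1] <= sch.degree_p[0] else (
        (sch.degree_p[1] - sch.degree_p[0]) / (1.0 - sch.degree_p[0]))
    degree2 = np.maximum(degree1, (rng_cov.random(n) < up_p).astype(float))
    fam1 = np.maximum(1.0, np.round(rng_cov.normal(sch.family_size_mean, sch.family_size_sd, n)))
    fam2 = np.maximum(1.0, fam1 + np.round(
        rng_cov.normal(sch.family_size_mean_p2 - sch.family_size_mean, 0.6, n)))
    skill1 = (rng_cov.random(n) < sch.high_skill_p[0]).astype(float)
    up_s = 0.0 if sch.high_skill_p[1] <= sch.high_skill_p[0] else (
        (sch.high_skill_p[1] - sch.high_skill_p[0]) / (1.0 - sch.high_skill_p[0]))
    skill2 = np.maximum(skill1, (rng_cov.random(n) < up_s).astype(float))
    england = (rng_cov.random(n) < sch.england_p).astype(float)

    x_by_period = {
        1: np.column_stack([degree1, fam1, skill1, england, np.full(n, sch.ages[0])]),
        2: np.column_stack([degree2, fam2, skill2, england, np.full(n, sch.ages[1])]),
    }

    # BMI and outcome
    alpha_i, delta_i, gamma_i = _truth_arrays(config, skill1)
    truth = config.truth
    rows = []
    ids = np.arange(n)
    q_by_period = {}
    for t in (1, 2):
        pi_t = config.pi * ((1.0 + config.pi_growth) if t == 2 else 1.0)
        q = (config.bmi_base_mean + (config.bmi_drift if t == 2 else 0.0)
             + zc @ pi_t + config.lambda_endog * omega + a_i + u[:, t - 1])
        # biologically implausible left tail (prob ~5e-4 at defaults) floored
        q = np.maximum(q, 10.0)
        q_obs = q
        if config.measurement_error_sd > 0:
            q_obs = q + rng_bmi.normal(0.0, config.measurement_error_sd, size=n)
            q_obs = np.maximum(q_obs, 10.0)
        q_by_period[t] = (q, q_obs)

    for t in (1, 2):
        q, q_obs = q_by_period[t]
        x = x_by_period[t]
        y = (truth.beta0 + x @ truth.beta + alpha_i * q
             + delta_i * kink_transform(q, gamma_i) + omega + eps[:, t - 1])
        if config.instrument_direct_effect != 0.0 and t == 2:
            y = y + config.instrument_direct_effect * zc[:, 3]
        rows.append(pd.DataFrame({
            "id": ids, "period": t, "hours": y, "bmi": q_obs,
            **{name: x[:, j] for j, name in enumerate(config.covariate_names)},
        }))

    df = pd.concat(rows, ignore_index=True)
    df["gender"] = config.gender
    skill_label = {1: np.where(skill1 == 1, "high", "low"),
                   2: np.where(skill2 == 1, "high", "low")}
    df["skill"] = np.concatenate([skill_label[1], skill_label[2]])

    status = np.full((n, 2), "employee", dtype=object)
    if config.p_self_employed_p1 > 0:
        status[rng_labels.random(n) < config.p_self_employed_p1, 0] = "self_employed"
    if config.p_not_working > 0:
        status[rng_labels.random((n, 2)) < config.p_not_working] = "not_working"
    df["employment_status"] = np.concatenate([status[:, 0], status[:, 1]])
    pregnant = np.zeros((n, 2), dtype=bool)
    if config.p_pregnant > 0 and config.gender == "female":
        hit = rng_labels.random(n) < config.p_pregnant
        which = rng_labels.integers(0, 2, size=n)
        pregnant[np.arange(n)[hit], which[hit]] = True
    df["pregnant"] = np.concatenate([pregnant[:, 0], pregnant[:, 1]])

    panel = PanelDataset(df, list(config.covariate_names))
    instruments = InstrumentTable(pd.DataFrame({
        "id": ids,
        "birth_weight": z[:, 0], "bmi_age10": z[:, 1],
        "mother_bmi": z[:, 2], "father_bmi": z[:, 3],
    }))
    return panel, instruments, replace(truth)


# ---------------------------------------------------------------------------


def default_bcs_config(arm: str, n_individuals: int = 828, seed: int = 0,
                       instrument_share_target: float = 0.20) -> SimulationConfig:
    """Default study-arm configuration calibrated to the survey's marginal moments.

    ``arm`` is ``"female"`` or ``"male"``.  Instrument loadings are scaled so
    the instruments explain ``instrument_share_target`` of BMI variance
    (period average); the persistent BMI component is sized so the total BMI
    variance matches the published SDs; the outcome intercept is calibrated so
    the period-1 mean of hours matches the published mean given the kinked
    response evaluated at the (normal) BMI distribution.
    """
    if arm not in _ARM_MOMENTS:
        raise ConfigError(f"unknown arm {arm!r}; expected one of {sorted(_ARM_MOMENTS)}")
    m = _ARM_MOMENTS[arm]
    alpha, delta, gamma = m["truth"]
    sds = np.array(m["instrument_sds"])

    lambda_endog, sigma_omega, sigma_u, pi_growth = 0.5, 5.0, 1.5, 0.5
    target_var = float(np.mean(np.square(m["bmi_sds"])))
    unexplained = target_var * (1.0 - instrument_share_target)
    var_persistent = unexplained - (lambda_endog * sigma_omega) ** 2 - sigma_u ** 2
    if var_persistent <= 0:
        raise ConfigError("arm moments leave no room for a persistent BMI component")
    explained_mean = target_var * instrument_share_target
    v1 = 2.0 * explained_mean / (1.0 + (1.0 + pi_growth) ** 2)
    direction = 1.0 / sds                       # equal standardized loadings
    pi = direction * np.sqrt(v1 / float((direction * sds) @ (direction * sds)))

    scheme = CovariateScheme(
        degree_p=m["degree_p"], family_size_mean=m["family_size"][0],
        family_size_sd=m["family_size"][1], family_size_mean_p2=m["family_size"][2],
        high_skill_p=m["high_skill_p"], england_p=m["england_p"],
    )
    beta = np.array([2.0, -1.5, 3.0, 0.5, 0.05])

    # intercept calibration: E[y_1] = beta0 + E[x_1]'beta + alpha E[q_1]
    #                                 + delta E[(q_1 - gamma)+]
    sd_q1 = np.sqrt(v1 + (lambda_endog * sigma_omega) ** 2 + var_persistent + sigma_u ** 2)
    mu_q1 = m["bmi_base_mean"]
    a = (mu_q1 - gamma) / sd_q1
    expected_kink = (mu_q1 - gamma) * stats.norm.cdf(a) + sd_q1 * stats.norm.pdf(a)
    beta0 = (m["hours_mean_p1"] - scheme.expected_x(1) @ beta
             - alpha * mu_q1 - delta * expected_kink)

    truth = ThresholdParams(beta0=float(beta0), beta=beta, alpha=alpha, delta=delta, gamma=gamma)
    return SimulationConfig(
        n_individuals=n_individuals, truth=truth,
        instrument_means=np.array(m["instrument_means"]), instrument_sds=sds,
        pi=pi, pi_growth=pi_growth, lambda_endog=lambda_endog,
        sigma_omega=sigma_omega, sigma_u=sigma_u, sigma_eps=m["sigma_eps"],
        sigma_bmi_persistent=float(np.sqrt(var_persistent)),
        bmi_base_mean=m["bmi_base_mean"], bmi_drift=m["bmi_drift"],
        covariate_scheme=scheme, gender=arm, seed=seed,
    )
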