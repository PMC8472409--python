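"""Benchmark linear estimators: pooled OLS and the two-period fixed-effects (within) estimator.

Both estimate the linear restriction of the kink model (slope change fixed at
zero): hours on an intercept, the covariates and BMI.  With two periods the
within estimator's slopes coincide with least squares on first differences,
which the test-suite asserts as an exact identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import SingularityError
from .panel import PanelDataset

logger = logging.getLogger(__name__)


@dataclass
class LinearFit:
    """Coefficients, standard errors and fit statistics of a linear benchmark.

    ``r_squared`` is the overall R^2 for pooled OLS and the within R^2 for
    fixed effects.
    """

    coefficients: pd.Series
    se: pd.Series
    pvalues: pd.Series
    r_squared: float
    estimator: str
    n_obs: int
    dropped: list | None = None

    @property
    def bmi_slope(self) -> float:
        return float(self.coefficients["bmi"])


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via QR diagnostics
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        raise SingularityError(f"collinear design; dependent column(s): {bad}")


def fit_pooled_ols(data: PanelDataset, cluster_by_individual: bool = False) -> LinearFit:
    """Pooled least squares of hours on intercept, covariates and BMI.

    Conventional homoskedastic standard errors by default; pooled two-period
    observations are dependent within individual, so a cluster-by-individual
    option is provided.
    """
    df = data.df
    names = ["const"] + list(data.covariate_names) + ["bmi"]
    X = np.column_stack([np.ones(len(df)), df[data.covariate_names].to_numpy(float),
                         df["bmi"].to_numpy(float)])
    if len(df) < X.shape[1] + 2:
        raise ValueError("need at least 2 more records than parameters")
    _check_full_rank(X, names)
    if cluster_by_individual:
        res = sm.OLS(df["hours"].to_numpy(float), X).fit(
            cov_type="cluster", cov_kwds={"groups": df["id"].to_numpy()})
    else:
        res = sm.OLS(df["hours"].to_numpy(float), X).fit()
    return LinearFit(
        coefficients=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r_squared=float(res.rsquared), estimator="pooled_ols", n_obs=len(df),
    )


def fit_fixed_effects(data: PanelDataset) -> LinearFit:
    """Within (individual-demeaned) estimator on the balanced two-period panel.

    Regressors constant within every individual carry no within variation and
    are dropped with a logged note; degrees of freedom are adjusted for the
    estimated individual means (n - N - k).
    """
    balanced = data.balanced_view()
    df = balanced.df
    candidates = list(balanced.covariate_names) + ["bmi"]
    g = df.groupby("id")
    demeaned = {c: (df[c] - g[c].transform("mean")).to_numpy(float) for c in candidates}
    y = (df["hours"] - g["hours"].transform("mean")).to_numpy(float)

    kept = [c for c in candidates if np.abs(demeaned[c]).max() > 1e-12]
    dropped = [c for c in candidates if c not in kept]
    if dropped:
        logger.info("fixed effects: dropping time-invariant regressor(s) %s", dropped)
    if not kept:
        raise SingularityError("no regressor varies within individuals")

    X = np.column_stack([demeaned[c] for c in kept])
    _check_full_rank(X, kept)
    n, k = X.shape
    n_groups = df["id"].nunique()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - n_groups - k
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    from scipy import stats
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    tss = float(y @ y)
    r2_within = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return LinearFit(
        coefficients=pd.Series(beta, index=kept),
        se=pd.Series(se, index=kept),
        pvalues=pd.Series(pvals, index=kept),
        r_squared=r2_within, estimator="fixed_effects", n_obs=n, dropped=dropped,
    )
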