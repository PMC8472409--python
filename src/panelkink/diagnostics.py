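"""Instrument diagnostics: first-stage fit, Cragg–Donald statistic, Sargan test.

The named Sargan test is the classical (conditionally homoskedastic) statistic
``u'P_Z u / (u'u/n)`` on 2SLS residuals, matching the convention of reporting
it separately from the two-step GMM J statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import IdentificationError
from .gmm import _assemble
from .panel import InstrumentTable, PanelDataset, first_difference
from .stock_yogo import stock_yogo_lookup

__all__ = [
    "InstrumentDiagnostics", "cragg_donald", "sargan_test",
    "stock_yogo_lookup", "two_stage_least_squares", "compute_instrument_diagnostics",
]


@dataclass
class InstrumentDiagnostics:
    """Summary of instrument strength and validity checks."""

    first_stage_r2: float
    cragg_donald_F: float
    stock_yogo_criterion: str
    stock_yogo_critical: float
    sargan_stat: float
    sargan_df: int
    sargan_p: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "first_stage_r2": self.first_stage_r2,
            "cragg_donald_F": self.cragg_donald_F,
            "stock_yogo_criterion": self.stock_yogo_criterion,
            "stock_yogo_critical": self.stock_yogo_critical,
            "sargan_stat": self.sargan_stat,
            "sargan_df": self.sargan_df,
            "sargan_p": self.sargan_p,
            "n_obs": self.n_obs,
        }


def _annihilate(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual of each column of A after least-squares projection on X."""
    if X.size == 0:
        return A
    coef, *_ = np.linalg.lstsq(X, A, rcond=None)
    return A - X @ coef


def cragg_donald(endogenous: np.ndarray, instruments: np.ndarray,
                 exogenous: np.ndarray | None = None) -> float:
    """Cragg–Donald minimum-eigenvalue weak-instrument statistic on the F scale.

    ``endogenous`` (n,) or (n, k_e), ``instruments`` the excluded instruments
    (n, k_z), ``exogenous`` the included regressors (pass an intercept column
    explicitly).  With one endogenous regressor and one instrument the value
    equals the first-stage F statistic.  Perfect relevance (zero first-stage
    residual variance) is reported as ``inf``.
    """
    Y = np.atleast_2d(np.asarray(endogenous, dtype=float).T).T
    Z = np.atleast_2d(np.asarray(instruments, dtype=float).T).T
    X = (np.empty((len(Y), 0)) if exogenous is None
         else np.atleast_2d(np.asarray(exogenous, dtype=float).T).T)
    n, k_e = Y.shape
    k_z = Z.shape[1]
    if k_z < k_e:
        raise IdentificationError(
            f"{k_z} instrument(s) cannot identify {k_e} endogenous regressor(s)")
    Yt = _annihilate(Y, X)
    Zt = _annihilate(Z, X)
    coef, *_ = np.linalg.lstsq(Zt, Yt, rcond=None)
    fitted = Zt @ coef
    resid = Yt - fitted
    dof = n - X.shape[1] - k_z
    sigma_vv = resid.T @ resid / dof
    explained = fitted.T @ fitted
    eigvals = np.linalg.eigvalsh(sigma_vv)
    if eigvals.min() < 1e-12 * max(eigvals.max(), 1.0):
        return float("inf")
    root = np.linalg.cholesky(np.linalg.inv(sigma_vv))
    concentration = root.T @ explained @ root
    return float(np.linalg.eigvalsh(concentration).min() / k_z)


def sargan_test(residuals: np.ndarray, instrument_matrix: np.ndarray,
                n_parameters: int) -> tuple[float, int, float]:
    """Classical Sargan overidentification test.

    ``residuals`` are structural (2SLS/GMM) residuals, ``instrument_matrix``
    the full instrument set (included exogenous plus excluded instruments),
    ``n_parameters`` the number of estimated coefficients.  Returns
    ``(statistic, df, p)``; a just-identified system has no overidentifying
    restrictions and raises rather than silently reporting zero.
    """
    u = np.asarray(residuals, dtype=float)
    Z = np.atleast_2d(np.asarray(instrument_matrix, dtype=float).T).T
    df = Z.shape[1] - int(n_parameters)
    if df < 1:
        raise IdentificationError(
            "Sargan test undefined: df = #instruments - #parameters = "
            f"{df} (system is just identified or under-identified)")
    n = len(u)
    coef, *_ = np.linalg.lstsq(Z, u, rcond=None)
    proj = Z @ coef
    stat = float(proj @ proj / (u @ u / n))
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def two_stage_least_squares(y: np.ndarray, exog: np.ndarray, endog: np.ndarray,
                            excluded: np.ndarray):
    """Textbook 2SLS: returns (coefficients, structural residuals, instrument matrix).

    Coefficient order: exogenous columns then endogenous columns.
    """
    y = np.asarray(y, dtype=float)
    Xe = np.atleast_2d(np.asarray(exog, dtype=float).T).T
    Xn = np.atleast_2d(np.asarray(endog, dtype=float).T).T
    Zx = np.atleast_2d(np.asarray(excluded, dtype=float).T).T
    if Zx.shape[1] < Xn.shape[1]:
        raise IdentificationError("fewer excluded instruments than endogenous regressors")
    Z = np.column_stack([Xe, Zx])
    X = np.column_stack([Xe, Xn])
    coef_first, *_ = np.linalg.lstsq(Z, X, rcond=None)
    Xhat = Z @ coef_first
    beta, *_ = np.linalg.lstsq(Xhat, y, rcond=None)
    resid = y - X @ beta
    return beta, resid, Z


def compute_instrument_diagnostics(data: PanelDataset, instruments: InstrumentTable,
                                   sy_criterion: str = "bias_5") -> InstrumentDiagnostics:
    """Instrument report for one panel.

    The first-stage R^2 is from pooled levels (BMI on the four childhood
    instruments plus an intercept), mirroring how instrument relevance is
    usually quoted for this design; the Cragg–Donald statistic and the Sargan
    test are computed on the first-differenced system that the threshold
    estimator actually uses (differenced BMI endogenous, differenced
    covariates exogenous, the four childhood variables excluded instruments).
    """
    balanced = data.balanced_view()
    inst = instruments.df.set_index("id")
    z_levels = inst.loc[balanced.df["id"], instruments.instrument_names].to_numpy(float)
    q = balanced.df["bmi"].to_numpy(float)
    Zl = np.column_stack([np.ones(len(q)), z_levels])
    coef, *_ = np.linalg.lstsq(Zl, q, rcond=None)
    resid = q - Zl @ coef
    r2 = 1.0 - resid @ resid / ((q - q.mean()) @ (q - q.mean()))

    rows = first_difference(balanced)
    base = _assemble(rows, instruments)
    n_dx = base["x0"].shape[1] - 2          # differenced covariates kept
    exog = base["x0"][:, : 1 + n_dx]
    endog = base["x0"][:, -1]
    z = base["z"][:, 1 + n_dx:]
    cd = cragg_donald(endog, z, exog)
    beta, u, Z = two_stage_least_squares(base["y"], exog, endog, z)
    stat, df, p = sargan_test(u, Z, len(beta))
    critical = stock_yogo_lookup(1, z.shape[1], sy_criterion)
    return InstrumentDiagnostics(
        first_stage_r2=float(r2), cragg_donald_F=cd,
        stock_yogo_criterion=sy_criterion, stock_yogo_critical=critical,
        sargan_stat=stat, sargan_df=df, sargan_p=p, n_obs=base["x0"].shape[0],
    )
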