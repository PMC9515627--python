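"""Leverage estimation and dispersion diagnostics for intake tables.

The central estimator is ordinary least squares on the log-log leverage
law: log total energy regressed on log protein share (natural logs
throughout), optionally with covariate columns for confounder adjustment.
The slope is the leverage coefficient L (0 = no leverage, -1 = complete
protein leverage) and the back-transformed intercept P = exp(alpha) is
the implied protein target when leverage is complete.  A direct nonlinear
fit of the power law E = P * p**L on the natural scale is available as a
cross-check, along with index-of-dispersion and coefficient-of-variation
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .model2 import DispersionSummary
from .simulate import IntakeTable

__all__ = [
    "LeverageEstimate",
    "CVRSummary",
    "fit_leverage",
    "fit_power_law",
    "dispersion_summary",
    "cvr",
    "spearman_diagnostic",
    "ProteinLeverageRegressor",
]


@dataclass(frozen=True)
class LeverageEstimate:
    """Fitted leverage law: slope L, intercept alpha = log(P), and uncertainty."""

    L_hat: float
    alpha_hat: float
    P_hat: float
    se_L: float
    resid_var: float
    n_used: int
    covariates_adjusted: tuple[str, ...] = ()
    method: str = "loglog"

    def __post_init__(self) -> None:
        if not self.se_L > 0:
            raise ValueError(f"se_L must be positive, got {self.se_L!r}")


@dataclass(frozen=True)
class CVRSummary:
    """Coefficient-of-variation ratio between biomarker- and DAT-derived intakes."""

    cv_biomarker: float
    cv_dat: float
    cvr: float


def _design(table: IntakeTable | pd.DataFrame, covariates=None):
    df = table.df if isinstance(table, IntakeTable) else table
    bad = df.index[(df["protein_kj"] <= 0) | (df["nonprotein_kj"] <= 0)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} record(s) with non-positive intake (log undefined); "
            f"offending rows: {list(bad[:20])}"
        )
    total = df["protein_kj"] + df["nonprotein_kj"]
    p = df["protein_kj"] / total
    covariates = list(covariates or [])
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariate column(s) not in table: {missing}")
    return df, np.log(total.to_numpy()), np.log(p.to_numpy()), p.to_numpy(), covariates


def fit_leverage(table: IntakeTable | pd.DataFrame, covariates=None) -> LeverageEstimate:
    """OLS of log total energy on log protein share (the leverage regression).

    Covariates are added as extra columns of a multiple regression; the
    reported slope and standard error always refer to the log-share term.
    Rank-deficient designs are rejected naming the collinear columns.
    """
    df, y, x, _, covariates = _design(table, covariates)
    if len(df) < 3:
        raise ValueError(f"need at least 3 records, got {len(df)}")
    cols = {"log_p": x}
    for c in covariates:
        cols[c] = df[c].to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = pd.DataFrame(X).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}); "
                         f"most collinear columns: {worst}")
    res = sm.OLS(y, X).fit()
    alpha = float(res.params["const"])
    return LeverageEstimate(
        L_hat=float(res.params["log_p"]),
        alpha_hat=alpha,
        P_hat=math.exp(alpha),
        se_L=float(res.bse["log_p"]),
        resid_var=float(res.mse_resid),
        n_used=len(df),
        covariates_adjusted=tuple(covariates),
        method="loglog",
    )


def fit_power_law(table: IntakeTable | pd.DataFrame) -> LeverageEstimate:
    """Nonlinear least squares of E = P * p**L on the natural scale.

    Initialized from the log-log fit; non-convergence raises with the
    optimizer's message and final iterate.
    """
    df, _, _, p, _ = _design(table)
    E = (df["protein_kj"] + df["nonprotein_kj"]).to_numpy(dtype=float)
    start = fit_leverage(table)

    def model(prop, P, L):
        return P * prop**L

    try:
        popt, pcov = optimize.curve_fit(
            model, p, E, p0=[start.P_hat, start.L_hat], maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"power-law fit failed to converge: {exc}") from exc
    P_hat, L_hat = float(popt[0]), float(popt[1])
    resid = E - model(p, *popt)
    dof = max(len(E) - 2, 1)
    se_L = float(math.sqrt(max(pcov[1, 1], 0.0))) or np.finfo(float).tiny
    return LeverageEstimate(
        L_hat=L_hat,
        alpha_hat=math.log(P_hat),
        P_hat=P_hat,
        se_L=se_L,
        resid_var=float(resid @ resid / dof),
        n_used=len(E),
        method="powerlaw",
    )


def dispersion_summary(table: IntakeTable | pd.DataFrame) -> DispersionSummary:
    """Sample index of dispersion per nutrient (n-1 variances) and their ratio."""
    df = table.df if isinstance(table, IntakeTable) else table
    if len(df) < 2:
        raise ValueError(f"need at least 2 records, got {len(df)}")
    u = df["protein_kj"].to_numpy(dtype=float)
    v = df["nonprotein_kj"].to_numpy(dtype=float)
    id_u = u.var(ddof=1) / u.mean()
    id_v = v.var(ddof=1) / v.mean()
    return DispersionSummary(id_U=id_u, id_V=id_v, idr=id_u / id_v)


def cvr(cv_biomarker: float, cv_dat: float) -> CVRSummary:
    """Coefficient-of-variation ratio CV_biomarker / CV_DAT.

    A CVR near 1 for both protein and total energy indicates the dietary
    assessment tool measures them with similar precision to objective
    biomarkers, so differential measurement precision cannot explain a
    lower protein dispersion.
    """
    if not (cv_biomarker > 0 and cv_dat > 0):
        raise ValueError(
            f"coefficients of variation must be positive, got ({cv_biomarker!r}, {cv_dat!r})"
        )
    return CVRSummary(cv_biomarker=cv_biomarker, cv_dat=cv_dat, cvr=cv_biomarker / cv_dat)


def spearman_diagnostic(table: IntakeTable | pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of log share and log energy (non-parametric signal of
    leverage): returns (rho, p-value)."""
    _, y, x, _, _ = _design(table)
    rho, pval = stats.spearmanr(x, y)
    return float(rho), float(pval)


class ProteinLeverageRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn wrapper around the leverage regression.

    ``fit`` accepts a 2-column array ``X = [protein_kj, nonprotein_kj]``
    (``y`` is ignored: the response, log total energy, is formed from X
    itself) and exposes the fitted leverage slope, intercept and protein
    target as ``leverage_``, ``alpha_`` and ``protein_target_``.
    ``predict`` maps protein shares in (0, 1) to expected total energy via
    the fitted power law.

    Parameters
    ----------
    method : {"loglog", "powerlaw"}
        Fit by OLS on log scales or nonlinear least squares on the
        natural scale.
    """

    def __init__(self, method: str = "loglog"):
        self.method = method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must have shape (n, 2) = (protein_kj, nonprotein_kj), got {X.shape}")
        if self.method not in ("loglog", "powerlaw"):
            raise ValueError(f"method must be 'loglog' or 'powerlaw', got {self.method!r}")
        df = pd.DataFrame({"protein_kj": X[:, 0], "nonprotein_kj": X[:, 1]})
        est = fit_leverage(df) if self.method == "loglog" else fit_power_law(df)
        self.estimate_ = est
        self.leverage_ = est.L_hat
        self.alpha_ = est.alpha_hat
        self.protein_target_ = est.P_hat
        self.se_leverage_ = est.se_L
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        """Expected total energy (kJ) for protein shares X of shape (n,) or (n, 1)."""
        if not hasattr(self, "estimate_"):
            raise AttributeError("this ProteinLeverageRegressor instance is not fitted yet")
        p = np.asarray(X, dtype=float).reshape(-1)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("protein shares must lie strictly in (0, 1)")
        return self.protein_target_ * p**self.leverage_
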