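"""Robust linear regression (IRLS with Tukey's bisquare) as a Model/Results pair.

This is the workhorse behind every parcel-wise brain-behavior map: an
M-estimator with the bisquare weight function (tuning constant 4.685,
~95% Gaussian efficiency) and the MAD/0.6745 scale recomputed each
iteration, fitted by iteratively reweighted least squares via statsmodels'
RLM. Standardized betas (beta_Z) are obtained by refitting on z-scored
response and predictors, so they are directly comparable across parcels
with covariates present. Two-sided p-values use asymptotic normal theory
on the robust covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_TUNING = 4.685


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank-deficient."""


@dataclass
class RobustRegressionResults:
    """Estimates from one robust fit.

    params/bse/pvalues are on the raw scale and include the intercept;
    beta_z/beta_z_se/beta_z_ci cover the non-intercept columns on the
    z-scored scale. ``converged`` is advisory — non-convergence is flagged,
    never raised.
    """

    exog_names: list
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    scale: float
    n_iter: int
    converged: bool
    adj_r2: float
    nobs: int
    beta_z: np.ndarray = field(default=None)
    beta_z_se: np.ndarray = field(default=None)
    beta_z_ci: np.ndarray = field(default=None)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, z-scored beta, p."""
        beta_z_full = np.full(len(self.params), np.nan)
        beta_z_full[1:] = self.beta_z
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "beta_z": beta_z_full,
                "p": self.pvalues,
            },
            index=self.exog_names,
        )


class RobustLinearModel:
    """Robust linear model ``endog ~ exog`` (intercept added by default)."""

    def __init__(self, endog, exog, exog_names=None, add_intercept: bool = True):
        self.endog = np.asarray(endog, float)
        exog = np.asarray(exog, float)
        if exog.ndim == 1:
            exog = exog[:, None]
        n, k = exog.shape
        if exog_names is None:
            exog_names = [f"x{i + 1}" for i in range(k)]
        if add_intercept:
            exog = np.column_stack([np.ones(n), exog])
            exog_names = ["const"] + list(exog_names)
        self.exog = exog
        self.exog_names = list(exog_names)
        if n <= exog.shape[1] + 2:
            raise ValueError("need n > n_predictors + 2 observations")
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise SingularDesignError("design matrix is rank-deficient")
        if not (np.isfinite(self.endog).all() and np.isfinite(exog).all()):
            raise ValueError("non-finite values in model data")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors):
        predictors = list(predictors)
        sub = data[[response] + predictors].dropna()
        return cls(sub[response], sub[predictors], exog_names=predictors)

    def _rlm_fit(self, y, X, max_iter, tol):
        model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(DEFAULT_TUNING))
        return model.fit(maxiter=max_iter, tol=tol, scale_est="mad", conv="coefs")

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> RobustRegressionResults:
        y, X = self.endog, self.exog
        res = self._rlm_fit(y, X, max_iter, tol)
        n_iter = len(res.fit_history.get("params", [])) or max_iter
        converged = n_iter < max_iter

        fitted = X @ res.params
        ss_res = np.sum((y - fitted) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        k = X.shape[1] - 1
        if ss_tot > 0 and self.endog.size - k - 1 > 0:
            r2 = 1.0 - ss_res / ss_tot
            adj_r2 = 1.0 - (1.0 - r2) * (len(y) - 1) / (len(y) - k - 1)
        else:
            adj_r2 = np.nan

        # standardized betas from a z-scored refit (columns beyond intercept)
        y_sd = y.std(ddof=1)
        Xp = X[:, 1:]
        x_sd = Xp.std(axis=0, ddof=1)
        if y_sd == 0 or np.any(x_sd == 0):
            beta_z = np.zeros(k)
            beta_z_se = np.full(k, np.nan)
            beta_z_ci = np.full((k, 2), np.nan)
        else:
            yz = (y - y.mean()) / y_sd
            Xz = np.column_stack(
                [np.ones(len(y)), (Xp - Xp.mean(axis=0)) / x_sd]
            )
            resz = self._rlm_fit(yz, Xz, max_iter, tol)
            beta_z = resz.params[1:]
            beta_z_se = resz.bse[1:]
            ci = resz.conf_int()
            beta_z_ci = np.asarray(ci)[1:, :]

        return RobustRegressionResults(
            exog_names=self.exog_names,
            params=np.asarray(res.params),
            bse=np.asarray(res.bse),
            pvalues=np.asarray(res.pvalues),
            scale=float(res.scale),
            n_iter=n_iter,
            converged=converged,
            adj_r2=float(adj_r2) if np.isfinite(adj_r2) else np.nan,
            nobs=len(y),
            beta_z=np.asarray(beta_z),
            beta_z_se=np.asarray(beta_z_se),
            beta_z_ci=np.asarray(beta_z_ci),
        )


def robust_fit(y, X, max_iter: int = 50, tol: float = 1e-8, exog_names=None,
               add_intercept: bool = True) -> RobustRegressionResults:
    """Functional front door to :class:`RobustLinearModel`.

    A constant response is handled as the degenerate no-variance case:
    all slopes (raw and standardized) are zero with p = 1.
    """
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        k = X.shape[1]
        names = exog_names or [f"x{i + 1}" for i in range(k)]
        if add_intercept:
            names = ["const"] + list(names)
        kk = len(names)
        params = np.zeros(kk)
        if add_intercept:
            params[0] = y[0]
        return RobustRegressionResults(
            exog_names=list(names),
            params=params,
            bse=np.zeros(kk),
            pvalues=np.ones(kk),
            scale=0.0,
            n_iter=0,
            converged=True,
            adj_r2=np.nan,
            nobs=len(y),
            beta_z=np.zeros(kk - int(add_intercept)),
            beta_z_se=np.full(kk - int(add_intercept), np.nan),
            beta_z_ci=np.full((kk - int(add_intercept), 2), np.nan),
        )
    return RobustLinearModel(
        y, X, exog_names=exog_names, add_intercept=add_intercept
    ).fit(max_iter=max_iter, tol=tol)
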