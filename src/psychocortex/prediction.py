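"""Out-of-sample prediction of behavior from covariate-residualized cortex.

The procedure mirrors standard predictive-morphometry practice: split
subjects once into training and test sets; residualize every parcel column
on the covariates separately within each set (so no test-set statistic ever
reaches training); select the ridge penalty by k-fold cross-validated MSE
on the training set; refit on the full training set; and score the held-out
set with the out-of-sample coefficient of determination and the MSE
normalized by the instrument's maximum possible score. Significance comes
from a permutation null that permutes the training target and reruns the
entire selection pipeline, preserving selection optimism under the null.

Ridge solutions use a singular value decomposition of the (fixed) design,
shared across the penalty grid and across permutations; this is
algebraically identical to the closed form (X'X + lambda I)^-1 X'y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._utils import as_rng, check_finite, child_seed
from .robust import SingularDesignError

DEFAULT_LAMBDA_GRID = np.logspace(-3, 5, 25)
DEFAULT_K_FOLDS = 10


def split_train_test(n_subjects: int, test_fraction: float, seed: int):
    """Disjoint, exhaustive random split; test size = round(n * fraction)."""
    if not 0.0 < test_fraction < 0.5:
        raise ValueError("test_fraction must lie in (0, 0.5)")
    if n_subjects < 20:
        raise ValueError("need at least 20 subjects to split")
    n_test = int(round(n_subjects * test_fraction))
    rng = as_rng(seed)
    perm = rng.permutation(n_subjects)
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return train, test


def _residualize(X: np.ndarray, cov: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    C = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise SingularDesignError("collinear covariates in residualization")
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ beta


def residualize_covariates(train_X, test_X, train_cov, test_cov):
    """OLS-residualize each parcel column on covariates, per set independently."""
    train_X = check_finite("train_X", train_X)
    test_X = check_finite("test_X", test_X)
    train_cov = check_finite("train_cov", train_cov)
    test_cov = check_finite("test_cov", test_cov)
    return _residualize(train_X, train_cov), _residualize(test_X, test_cov)


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge coefficients (X'X + lambda I)^-1 X'y, no intercept."""
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)


class _RidgeEngine:
    """SVD factorization of a fixed design, reused across penalties and targets.

    With X = U diag(s) V', the ridge solution for penalty lam is
    V diag(s / (s^2 + lam)) U'y; validation predictions only need the
    precomputed matrix X_val V.
    """

    def __init__(self, X: np.ndarray, lambda_grid, k_folds: int, seed: int):
        self.X = X
        self.lambda_grid = np.asarray(lambda_grid, float)
        n = X.shape[0]
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**31))
        self.folds = []
        for tr, va in kf.split(X):
            U, s, Vt = np.linalg.svd(X[tr], full_matrices=False)
            self.folds.append(
                {"tr": tr, "va": va, "U": U, "s": s, "B": X[va] @ Vt.T}
            )
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        self._U, self._s, self._Vt = U, s, Vt

    def cv_mse(self, y: np.ndarray) -> np.ndarray:
        lams = self.lambda_grid
        errs = np.zeros(len(lams))
        n_total = 0
        for f in self.folds:
            y_tr = y[f["tr"]]
            ybar = y_tr.mean()
            t = f["U"].T @ (y_tr - ybar)  # (r,)
            s = f["s"]
            # shrinkage weights for the whole grid at once: (r, n_lambda)
            W = (s[:, None] / (s[:, None] ** 2 + lams[None, :])) * t[:, None]
            pred = f["B"] @ W  # (n_val, n_lambda)
            resid_true = y[f["va"]] - ybar
            errs += np.sum((pred - resid_true[:, None]) ** 2, axis=0)
            n_total += len(f["va"])
        return errs / n_total

    def fit_full(self, y: np.ndarray, lam: float):
        ybar = y.mean()
        t = self._U.T @ (y - ybar)
        coef = self._Vt.T @ ((self._s / (self._s**2 + lam)) * t)
        return coef, ybar

    def select_and_fit(self, y: np.ndarray):
        mse = self.cv_mse(y)
        i = int(np.argmin(mse))
        lam = float(self.lambda_grid[i])
        coef, intercept = self.fit_full(y, lam)
        return lam, coef, intercept, mse


@dataclass
class RidgeCVResult:
    lambda_selected: float
    coefficients: np.ndarray
    intercept: float
    beta_norm: float
    cv_mse: np.ndarray
    lambda_grid: np.ndarray


def ridge_cv(
    train_X,
    train_y,
    lambda_grid=None,
    k_folds: int = DEFAULT_K_FOLDS,
    seed: int = 0,
) -> RidgeCVResult:
    """Select the ridge penalty by k-fold CV MSE and refit on all of training.

    The target is centered on the (fold-)training mean; predictors are used
    as passed, which in this pipeline means covariate-residualized (hence
    centered) parcel columns.
    """
    train_X = check_finite("train_X", train_X)
    train_y = check_finite("train_y", train_y)
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.asarray(lambda_grid, float)
    if len(lambda_grid) < 5 or lambda_grid.max() / lambda_grid.min() < 1e4:
        raise ValueError("lambda grid needs >= 5 values spanning >= 4 orders")
    if k_folds < 5:
        raise ValueError("k_folds must be >= 5")
    engine = _RidgeEngine(train_X, lambda_grid, k_folds, seed)
    lam, coef, intercept, mse = engine.select_and_fit(train_y)
    return RidgeCVResult(
        lam, coef, intercept, float(np.linalg.norm(coef)), mse, lambda_grid
    )


def evaluate_oos(
    coefficients, test_X, test_y, score_max: float, intercept: float = 0.0,
    ss_tot_center: str = "test",
) -> dict:
    """Out-of-sample R^2 and score-normalized MSE on the held-out set.

    r2_oos = 1 - SS_res / SS_tot with SS_tot around the test-set mean by
    default (set ``ss_tot_center='train'`` and pass the training mean as
    ``intercept`` to use the alternative convention); nmse = MSE / score_max.
    """
    if score_max <= 0:
        raise ValueError("score_max must be positive")
    test_y = np.asarray(test_y, float)
    pred = np.asarray(test_X, float) @ np.asarray(coefficients, float) + intercept
    ss_res = float(np.sum((test_y - pred) ** 2))
    center = test_y.mean() if ss_tot_center == "test" else intercept
    ss_tot = float(np.sum((test_y - center) ** 2))
    if ss_tot == 0:
        raise ZeroDivisionError("zero test-set variance; R^2 undefined")
    mse = ss_res / len(test_y)
    return {
        "r2_oos": 1.0 - ss_res / ss_tot,
        "mse": mse,
        "nmse": mse / score_max,
        "predictions": pred,
    }


def permute_null_mse(
    train_X,
    train_y,
    test_X,
    test_y,
    *,
    lambda_grid=None,
    k_folds: int = DEFAULT_K_FOLDS,
    n_perm: int = 1000,
    seed: int = 0,
    cv_seed: int = 0,
):
    """Permutation null for the out-of-sample MSE.

    Each permutation shuffles the training target, reruns penalty selection
    and the full-training refit, and scores the test-set MSE. The p-value is
    (1 + #{null MSE <= observed MSE}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    train_X = check_finite("train_X", train_X)
    test_X = check_finite("test_X", test_X)
    train_y = check_finite("train_y", train_y)
    test_y = check_finite("test_y", test_y)

    engine = _RidgeEngine(train_X, lambda_grid, k_folds, cv_seed)
    _, coef, intercept, _ = engine.select_and_fit(train_y)
    obs_mse = float(np.mean((test_X @ coef + intercept - test_y) ** 2))

    rng = as_rng(seed)
    null_mse = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(train_y)
        _, coef_b, icpt_b, _ = engine.select_and_fit(y_perm)
        null_mse[b] = np.mean((test_X @ coef_b + icpt_b - test_y) ** 2)
    p_perm = (1 + int(np.sum(null_mse <= obs_mse))) / (1 + n_perm)
    return p_perm, null_mse, obs_mse


@dataclass
class PredictionResults:
    """Full out-of-sample prediction result for one (index, target) pair."""

    target: str
    index_kind: str
    lambda_selected: float
    coefficients: np.ndarray
    beta_norm: float
    r2_oos: float
    mse_oos: float
    nmse: float
    p_perm: float | None
    null_mse: np.ndarray | None
    n_train: int
    n_test: int
    seed: int

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "target": self.target,
                "index": self.index_kind,
                "n_train": self.n_train,
                "n_test": self.n_test,
                "lambda": self.lambda_selected,
                "beta_norm": self.beta_norm,
                "r2_oos": self.r2_oos,
                "nmse": self.nmse,
                "p_perm": self.p_perm,
            }
        )

    def to_dict(self) -> dict:
        s = self.summary().to_dict()
        s["seed"] = self.seed
        return s


class RidgePrediction:
    """Model object tying the whole prediction pipeline together.

    Parameters
    ----------
    features : (n, p) array or DataFrame
        Parcel-wise morphometry (raw; residualization happens inside).
    target : (n,) array or Series
        Behavioral score to predict.
    covariates : (n, c) array or DataFrame
        Covariates residualized out of the features within each split half.
    score_max : float
        Maximum possible score of the target instrument (e.g., 16 for the
        PCL-R interpersonal/affective factor, 28 for an IRI subscale);
        normalizes the reported out-of-sample MSE.
    """

    def __init__(
        self,
        features,
        target,
        covariates,
        score_max: float,
        *,
        test_fraction: float = 0.2,
        lambda_grid=None,
        k_folds: int = DEFAULT_K_FOLDS,
        seed: int = 0,
        target_name: str = "target",
        index_kind: str = "SA",
    ):
        self.features = np.asarray(features, float)
        self.target = np.asarray(target, float)
        self.covariates = np.asarray(covariates, float)
        if isinstance(target, pd.Series) and target.name:
            target_name = str(target.name)
        self.target_name = target_name
        self.index_kind = index_kind
        self.score_max = float(score_max)
        self.test_fraction = test_fraction
        self.lambda_grid = (
            DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
        )
        self.k_folds = k_folds
        self.seed = int(seed)

    def fit(self, n_perm: int = 0) -> PredictionResults:
        n = len(self.target)
        tr, te = split_train_test(
            n, self.test_fraction, child_seed(self.seed, "split")
        )
        Xtr, Xte = residualize_covariates(
            self.features[tr], self.features[te],
            self.covariates[tr], self.covariates[te],
        )
        # standardize parcels by the training-set scale so the penalty grid
        # spans the useful shrinkage range; no test-set statistic is used
        scale = Xtr.std(axis=0)
        scale[scale == 0] = 1.0
        Xtr = Xtr / scale
        Xte = Xte / scale
        ytr, yte = self.target[tr], self.target[te]
        cv_seed = child_seed(self.seed, "ridge_cv")
        sel = ridge_cv(Xtr, ytr, self.lambda_grid, self.k_folds, cv_seed)
        ev = evaluate_oos(
            sel.coefficients, Xte, yte, self.score_max, intercept=sel.intercept
        )
        p_perm, null_mse = None, None
        if n_perm:
            p_perm, null_mse, _ = permute_null_mse(
                Xtr, ytr, Xte, yte,
                lambda_grid=self.lambda_grid,
                k_folds=self.k_folds,
                n_perm=n_perm,
                seed=child_seed(self.seed, "permutation"),
                cv_seed=cv_seed,
            )
        return PredictionResults(
            target=self.target_name,
            index_kind=self.index_kind,
            lambda_selected=sel.lambda_selected,
            coefficients=sel.coefficients,
            beta_norm=sel.beta_norm,
            r2_oos=ev["r2_oos"],
            mse_oos=ev["mse"],
            nmse=ev["nmse"],
            p_perm=p_perm,
            null_mse=null_mse,
            n_train=len(tr),
            n_test=len(te),
            seed=self.seed,
        )
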