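"""Supervised comparator: partial least squares regression of items on a
residualised cognitive outcome.

The outcome is first residualised for demographic covariates (and, for the
confidence analyses, a benchmark dimension), the discovery sample is split
75/25 into training and test sets, and the number of PLS components is
chosen by 10-fold cross-validation on the training set (mean squared
prediction error in standardised-outcome units).  The fitted component's
item weights then score any dataset, so the supervised dimension can be
ranked against the unsupervised factors with the same effect-size machinery.

The PLS algorithm is the sequential-deflation (NIPALS, single-outcome)
variant: the first weight vector is proportional to X'y, components are
extracted one at a time with rank-one deflation of X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .effects import DimensionScores, code_covariates
from .exceptions import (
    CollinearityError,
    DegenerateItemError,
    InvalidArgumentError,
    MissingItemError,
)


@dataclass
class PLSModel:
    """Fitted PLS regression with the scalings needed to score new data."""

    weights: pd.DataFrame          # items x c, unit-norm weight vectors
    x_loadings: pd.DataFrame       # items x c
    scoring_weights: pd.DataFrame  # items x c, W (P'W)^{-1}: X_std @ . = scores
    y_loadings: np.ndarray         # per component
    n_components: int
    cv_rmse_per_c: list
    x_mean: pd.Series
    x_sd: pd.Series
    y_mean: float
    y_sd: float
    split_seed: int | None = None
    cv_seed: int | None = None

    @property
    def items(self):
        return list(self.weights.index)


def residualize(outcome: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of the outcome on the covariates (with intercept)."""
    coded = code_covariates(covariates)
    frame = coded.join(outcome.rename("__y__"), how="inner").dropna()
    y = frame["__y__"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(frame)),
                         frame.drop(columns="__y__").to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariates are rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=frame.index, name=outcome.name)


def split_train_test(data, train_fraction: float = 0.75, seed: int = 0):
    """Seeded uniform train/test split of rows, without replacement.

    The training set has ``ceil(train_fraction * n)`` rows.  Works on any
    pandas object (rows) or on a dataset object exposing aligned
    ``responses`` / ``covariates`` / ``outcomes`` blocks (all split
    consistently, returned as index pairs).
    """
    if not 0.0 < train_fraction < 1.0:
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    if isinstance(data, (pd.DataFrame, pd.Series)):
        index = data.index
    else:
        index = data.responses.index
    n = len(index)
    if n < 8:
        raise InvalidArgumentError(f"too few rows to split: {n}")
    n_train = int(np.ceil(train_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = index[np.sort(perm[:n_train])]
    test_idx = index[np.sort(perm[n_train:])]
    if isinstance(data, (pd.DataFrame, pd.Series)):
        return data.loc[train_idx], data.loc[test_idx]
    return train_idx, test_idx


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Sequential-deflation PLS with a single outcome.

    Returns (W, P, q) with unit-norm weight columns; X and y are assumed
    centred (typically standardised).
    """
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    Xd = X.copy()
    yd = y.copy()
    for c in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # no covariance left; keep a null component
            W[:, c] = 0.0
            continue
        w = w / norm
        t = Xd @ w
        tt = float(t @ t)
        p_c = Xd.T @ t / tt
        q_c = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p_c)
        yd = yd - t * q_c
        W[:, c], P[:, c], q[c] = w, p_c, q_c
    return W, P, q


def fit_pls(X: pd.DataFrame, y: pd.Series, n_components: int = 1,
            *, standardize: bool = True) -> PLSModel:
    """Fit a PLS regression of items on a scalar outcome.

    With ``standardize`` (default) X columns and y are z-scored internally
    and the scalings stored on the model; pass ``standardize=False`` when
    the inputs are already standardised.  Zero-variance item columns raise
    :class:`DegenerateItemError`.
    """
    if n_components < 1:
        raise InvalidArgumentError("n_components must be >= 1")
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if standardize:
        x_mean = Xv.mean(axis=0)
        x_sd = Xv.std(axis=0, ddof=0)
        if (x_sd == 0).any():
            bad = list(X.columns[x_sd == 0])
            raise DegenerateItemError(f"zero-variance items: {bad[:5]}")
        y_mean = float(yv.mean())
        y_sd = float(yv.std(ddof=0))
        if y_sd == 0:
            raise InvalidArgumentError("outcome has zero variance")
        Xs = (Xv - x_mean) / x_sd
        ys = (yv - y_mean) / y_sd
    else:
        x_mean = np.zeros(Xv.shape[1])
        x_sd = np.ones(Xv.shape[1])
        y_mean, y_sd = 0.0, 1.0
        Xs, ys = Xv, yv

    W, P, q = _nipals_pls1(Xs, ys, n_components)
    # rotation weights R = W (P'W)^{-1}: X_std @ R reproduces the internal
    # component scores exactly (R[:, 0] == W[:, 0]).
    PtW = P.T @ W
    R = W @ np.linalg.inv(PtW) if np.linalg.cond(PtW) < 1e12 else W
    items = list(X.columns)
    comp = [f"C{c + 1}" for c in range(n_components)]
    return PLSModel(
        weights=pd.DataFrame(W, index=items, columns=comp),
        x_loadings=pd.DataFrame(P, index=items, columns=comp),
        scoring_weights=pd.DataFrame(R, index=items, columns=comp),
        y_loadings=q,
        n_components=n_components,
        cv_rmse_per_c=[],
        x_mean=pd.Series(x_mean, index=items),
        x_sd=pd.Series(x_sd, index=items),
        y_mean=y_mean,
        y_sd=y_sd,
    )


def predict(model: PLSModel, X: pd.DataFrame, n_components: int | None = None) -> np.ndarray:
    """Predicted outcome in standardised-y units."""
    c = n_components or model.n_components
    Xs = (X[model.items].to_numpy(dtype=float) - model.x_mean.to_numpy()) / model.x_sd.to_numpy()
    T = Xs @ model.scoring_weights.to_numpy()[:, :c]
    return T @ model.y_loadings[:c]


def select_components_cv(X: pd.DataFrame, y: pd.Series, k_folds: int = 10,
                         max_components: int = 5, seed: int = 0) -> PLSModel:
    """Choose the component count by k-fold cross-validation and refit.

    Per fold, X and y are standardised with the fold-training moments; the
    mean squared prediction error on the left-out fold (standardised-y
    units) is averaged over folds per component count.  The winning count is
    the RMSE argmin, ties resolved toward fewer components.  The returned
    model is refitted on all supplied rows with that count.
    """
    if k_folds < 2:
        raise InvalidArgumentError("k_folds must be >= 2")
    n = len(X)
    min_train = n - int(np.ceil(n / k_folds))
    if max_components >= min_train:
        raise InvalidArgumentError("max_components too large for fold size")

    folds = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    sq_errors = np.zeros((k_folds, max_components))
    for f, (tr, te) in enumerate(folds.split(X)):
        X_tr, X_te = X.iloc[tr], X.iloc[te]
        y_tr, y_te = y.iloc[tr], y.iloc[te]
        model = fit_pls(X_tr, y_tr, n_components=max_components)
        y_te_std = (y_te.to_numpy(dtype=float) - model.y_mean) / model.y_sd
        for c in range(1, max_components + 1):
            pred = predict(model, X_te, n_components=c)
            sq_errors[f, c - 1] = float(np.mean((y_te_std - pred) ** 2))
    rmse = np.sqrt(sq_errors.mean(axis=0))
    best_c = int(np.argmin(rmse)) + 1  # argmin returns the first (smallest) c on ties

    final = fit_pls(X, y, n_components=best_c)
    final.cv_rmse_per_c = [float(v) for v in rmse]
    final.cv_seed = seed
    return final


def pls_component_scores(responses: pd.DataFrame, model: PLSModel,
                         component: int = 1) -> DimensionScores:
    """Score participants on a fitted PLS component.

    score = sum over items of standardised response x scoring weight, using
    the model's stored item scalings; on the training data this reproduces
    the internal component scores exactly.
    """
    missing = [i for i in model.items if i not in responses.columns]
    if missing:
        raise MissingItemError(missing)
    Xs = (responses[model.items].to_numpy(dtype=float)
          - model.x_mean.to_numpy()) / model.x_sd.to_numpy()
    col = model.scoring_weights.to_numpy()[:, component - 1]
    scores = pd.Series(Xs @ col, index=responses.index, name=f"PLS_C{component}")
    return DimensionScores(dimension_id=f"PLS_C{component}", scores=scores,
                           standardization="discovery_z")
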