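"""Maximum-likelihood exploratory factor analysis on a correlation matrix.

Extraction follows the profile-likelihood approach: for fixed uniquenesses
Psi the ML discrepancy

    F = log|Sigma| + tr(R Sigma^{-1}) - log|R| - p,   Sigma = Lambda Lambda' + Psi

is minimised analytically over the loadings via the eigenstructure of
Psi^{-1/2} R Psi^{-1/2}, leaving a p-dimensional bounded optimisation over
Psi.  A minres (ordinary least squares on off-diagonal residuals) fallback
keeps large solution sweeps running when ML fails to converge.  Rotation is
delegated to :mod:`factorverse.rotation`; hierarchical (Schmid-Leiman)
bifactor solutions and regression / Anderson-Rubin factor scores live here
as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import (
    InvalidArgumentError,
    RankDeficiencyError,
    SingularMatrixError,
    UndefinedFitIndexError,
)
from .polychoric import HetCorMatrix
from .rotation import canonicalize, rotate_loadings

# Heywood guard: uniquenesses are bounded below at this value and the case
# flagged rather than aborting a multiverse sweep.
UNIQUENESS_FLOOR = 0.005


@dataclass
class FactorSolution:
    """One fitted factor model: pattern loadings, factor correlations,
    uniquenesses, fit statistics and (optionally) score weights."""

    loadings: pd.DataFrame            # items x k pattern matrix
    factor_corr: np.ndarray           # k x k (identity for orthogonal)
    uniquenesses: pd.Series           # per item
    rotation: str                     # none | oblimin | varimax
    chi_square: float
    df: float
    chi_square_null: float
    df_null: float
    rmsea: float
    tli: float
    n_used: int
    converged: bool
    heywood: bool = False
    extraction: str = "ml"
    discrepancy: float = float("nan")
    score_weights: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def items(self):
        return list(self.loadings.index)

    def communalities(self) -> pd.Series:
        L = self.loadings.to_numpy()
        return pd.Series(np.diag(L @ self.factor_corr @ L.T), index=self.loadings.index)


@dataclass
class BifactorSolution:
    """Schmid-Leiman transform of an oblique solution: one general factor
    plus orthogonalised group factors, with Anderson-Rubin score weights.

    ``scoring_loadings`` is the full-rank direct-bifactor representation
    (k_group + 1 ML factors Procrustes-rotated onto the SL pattern) used for
    score estimation: the literal SL matrix [general | groups] has rank
    k_group and cannot support jointly orthogonal score estimates.
    """

    general_loadings: pd.Series
    group_loadings: pd.DataFrame
    ar_score_weights: pd.DataFrame    # items x (1 + k_group)
    higher_order_loadings: np.ndarray  # gamma, per group factor
    source: FactorSolution
    scoring_loadings: pd.DataFrame | None = None
    degenerate_hierarchy: bool = False

    def combined_loadings(self) -> pd.DataFrame:
        out = pd.concat([self.general_loadings.rename("general"), self.group_loadings], axis=1)
        return out


def _as_corr(R) -> pd.DataFrame:
    if isinstance(R, HetCorMatrix):
        return R.matrix
    if isinstance(R, pd.DataFrame):
        return R
    a = np.asarray(R, dtype=float)
    names = [f"item{i + 1}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=names, columns=names)


def identification_df(p: int, k: int) -> float:
    return ((p - k) ** 2 - (p + k)) / 2.0


# Infinitesimal preference for larger uniquenesses: when the profile
# likelihood is flat (e.g. no common variance) it selects the
# minimum-communality solution without measurably perturbing real fits.
_RIDGE = 1e-6


def _profile_objective(psi, R, k):
    sc = 1.0 / np.sqrt(psi)
    lam = np.linalg.eigvalsh(R * np.outer(sc, sc))
    tail = lam[: len(psi) - k]                    # smallest p - k eigenvalues
    return float(np.sum(tail - np.log(tail) - 1.0) - _RIDGE * np.log(psi).sum())


def _profile_gradient(psi, R, k):
    L = _loadings_from_psi(psi, R, k)
    resid = L @ L.T + np.diag(psi) - R
    return np.diag(resid) / (psi * psi) - _RIDGE / psi


def _loadings_from_psi(psi, R, k):
    sc = 1.0 / np.sqrt(psi)
    lam, vec = np.linalg.eigh(R * np.outer(sc, sc))
    lam, vec = lam[::-1], vec[:, ::-1]
    scale = np.sqrt(np.maximum(lam[:k] - 1.0, 0.0))
    return np.sqrt(psi)[:, None] * vec[:, :k] * scale[None, :]


def _minres_objective(psi, R, k):
    reduced = R - np.diag(psi)
    lam, vec = np.linalg.eigh(reduced)
    lam, vec = lam[::-1], vec[:, ::-1]
    L = vec[:, :k] * np.sqrt(np.maximum(lam[:k], 0.0))[None, :]
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return float((resid * resid).sum())


def extract_ml(R, k: int, n: int, *, extraction: str = "ml",
               n_starts: int = 1, seed: int = 0) -> FactorSolution:
    """Fit an unrotated k-factor model by maximum likelihood.

    ``n`` is the sample size behind ``R`` and scales the chi-square,
    ``chi_square = (n - 1) * F_min``.  Non-convergence of the optimiser is
    reported through ``converged=False`` (after a minres fallback), never
    raised, so multiverse sweeps survive individual cells.
    """
    frame = _as_corr(R)
    a = frame.to_numpy()
    p = a.shape[0]
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if identification_df(p, k) < 0:
        raise InvalidArgumentError(
            f"k={k} violates the identification bound for p={p} items"
        )

    try:
        inv_diag = np.diag(np.linalg.inv(a))
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "correlation matrix is singular; run ensure_psd first"
        ) from exc

    bounds = [(UNIQUENESS_FLOOR, 1.0)] * p
    start0 = np.clip((1.0 - 0.5 * k / p) / inv_diag, UNIQUENESS_FLOOR, 1.0)
    rng = np.random.default_rng(seed)
    starts = [start0] + [
        np.clip(start0 * rng.uniform(0.5, 1.5, size=p), UNIQUENESS_FLOOR, 1.0)
        for _ in range(max(0, n_starts - 1))
    ]

    best = None
    converged = False
    method_used = extraction
    if extraction == "ml":
        for s0 in starts:
            res = minimize(
                _profile_objective, s0, args=(a, k), jac=_profile_gradient,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                converged = True
        if not converged:
            method_used = "minres"
    if method_used == "minres":
        best_mr = None
        for s0 in starts:
            res = minimize(
                _minres_objective, s0, args=(a, k),
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 1000, "ftol": 1e-12},
            )
            if best_mr is None or res.fun < best_mr.fun:
                best_mr = res
            if res.success:
                converged = True
        psi = best_mr.x
    else:
        psi = best.x

    heywood = bool((psi <= UNIQUENESS_FLOOR + 1e-12).any())
    L = _loadings_from_psi(psi, a, k) if method_used == "ml" else _minres_loadings(psi, a, k)
    f_min = _profile_objective(psi, a, k) + _RIDGE * float(np.log(psi).sum())

    chi_square = (n - 1) * f_min
    df = identification_df(p, k)
    sign, logdet = np.linalg.slogdet(a)
    chi_square_null = (n - 1) * (-logdet) if sign > 0 else float("nan")
    df_null = p * (p - 1) / 2.0
    if df > 0 and df_null > 0 and np.isfinite(chi_square_null) \
            and chi_square_null / df_null > 1.0:
        rmsea, tli = fit_indices(chi_square, df, chi_square_null, df_null, n)
    else:
        rmsea, tli = float("nan"), float("nan")

    factor_names = [f"F{j + 1}" for j in range(k)]
    return FactorSolution(
        loadings=pd.DataFrame(L, index=frame.index, columns=factor_names),
        factor_corr=np.eye(k),
        uniquenesses=pd.Series(psi, index=frame.index),
        rotation="none",
        chi_square=float(chi_square), df=float(df),
        chi_square_null=float(chi_square_null), df_null=float(df_null),
        rmsea=rmsea, tli=tli, n_used=int(n),
        converged=bool(converged), heywood=heywood,
        extraction=method_used, discrepancy=float(f_min),
    )


def _minres_loadings(psi, R, k):
    reduced = R - np.diag(psi)
    lam, vec = np.linalg.eigh(reduced)
    lam, vec = lam[::-1], vec[:, ::-1]
    return vec[:, :k] * np.sqrt(np.maximum(lam[:k], 0.0))[None, :]


def rotate(sol: FactorSolution, method: str, *, n_starts: int = 8,
           seed: int = 0) -> FactorSolution:
    """Rotate a solution with oblimin (oblique) or varimax (orthogonal).

    Rotation leaves fit statistics untouched.  The returned loadings follow
    the reporting convention: dominant sign positive per factor, factors
    ordered by explained variance.
    """
    if method not in ("oblimin", "varimax"):
        raise InvalidArgumentError(f"unknown rotation method: {method!r}")
    A = sol.loadings.to_numpy()
    if sol.k == 1:
        L, Phi, _ = canonicalize(A, np.eye(1))
        return replace(sol, loadings=pd.DataFrame(L, index=sol.loadings.index,
                                                  columns=sol.loadings.columns),
                       factor_corr=Phi, rotation=method)
    L, Phi, _, conv = rotate_loadings(A, method, n_starts=n_starts, seed=seed)
    L, Phi, _ = canonicalize(L, Phi)
    factor_names = [f"F{j + 1}" for j in range(sol.k)]
    return replace(
        sol,
        loadings=pd.DataFrame(L, index=sol.loadings.index, columns=factor_names),
        factor_corr=Phi,
        rotation=method,
        converged=sol.converged and conv,
    )


def fit_indices(chi_square: float, df: float, chi_square_null: float,
                df_null: float, n: int) -> tuple[float, float]:
    """RMSEA and TLI from model and independence-baseline chi-squares.

    RMSEA = sqrt(max(chi2 - df, 0) / (df * (n - 1))); TLI compares the
    chi2/df ratios of model and null, anchored at a null ratio of 1.
    """
    if df <= 0 or df_null <= 0:
        raise InvalidArgumentError("df and df_null must be positive")
    if n <= 1:
        raise InvalidArgumentError("n must exceed 1")
    null_ratio = chi_square_null / df_null
    if null_ratio <= 1.0:
        raise UndefinedFitIndexError("TLI undefined: null chi2/df ratio <= 1")
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    tli = float((null_ratio - chi_square / df) / (null_ratio - 1.0))
    return rmsea, tli


def regression_score_weights(R, sol: FactorSolution) -> pd.DataFrame:
    """Thurstone regression score weights W = R^{-1} Lambda Phi.

    The structure matrix Lambda Phi reduces to Lambda for orthogonal
    rotations.  Weights apply to items standardised on the fitting sample.
    """
    frame = _as_corr(R)
    a = frame.to_numpy()
    S = sol.loadings.to_numpy() @ sol.factor_corr
    try:
        W = np.linalg.solve(a, S)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "singular correlation matrix; repair with ensure_psd"
        ) from exc
    return pd.DataFrame(W, index=frame.index, columns=sol.loadings.columns)


def _one_factor_gamma(Phi: np.ndarray, n: int) -> np.ndarray:
    """Higher-order loadings from a one-factor model on the factor
    correlations.  k = 2 uses the equal-loading constraint (the model is
    otherwise under-identified); k >= 3 refits with the ML routine."""
    k = Phi.shape[0]
    if k == 2:
        r = float(np.clip(Phi[0, 1], 0.0, 0.9999))
        return np.full(2, np.sqrt(r))
    sub = extract_ml(pd.DataFrame(Phi,
                                  index=[f"g{i}" for i in range(k)],
                                  columns=[f"g{i}" for i in range(k)]),
                     1, max(n, 10))
    gamma = sub.loadings.to_numpy()[:, 0]
    if gamma.sum() < 0:
        gamma = -gamma
    return np.clip(gamma, 0.0, 0.9999)


def bifactor_schmid_leiman(R, k_group: int, n: int, *,
                           rotation_seed: int = 0) -> BifactorSolution:
    """Hierarchical bifactor solution via the Schmid-Leiman transform.

    Fits the oblique ``k_group`` solution, fits a single higher-order factor
    to its factor correlations (loadings gamma), and decomposes each item's
    common variance into a general part (Lambda gamma) and orthogonal group
    residuals (Lambda diag(sqrt(1 - gamma^2))).  A near-identity factor
    correlation yields a flagged degenerate hierarchy with a null general
    factor rather than an error.
    """
    if k_group < 2:
        raise InvalidArgumentError("bifactor needs at least 2 group factors")
    frame = _as_corr(R)
    first_order = rotate(extract_ml(frame, k_group, n), "oblimin", seed=rotation_seed)
    Phi = first_order.factor_corr
    degenerate = bool(np.max(np.abs(Phi - np.eye(k_group))) < 0.05)
    gamma = np.zeros(k_group) if degenerate else _one_factor_gamma(Phi, n)

    Lam = first_order.loadings.to_numpy()
    general = Lam @ gamma
    group = Lam * np.sqrt(1.0 - gamma ** 2)[None, :]

    general_s = pd.Series(general, index=frame.index, name="general")
    group_f = pd.DataFrame(group, index=frame.index,
                           columns=[f"G{j + 1}" for j in range(k_group)])
    combined = np.column_stack([general, group])
    names = ["general"] + list(group_f.columns)

    # Full-rank scoring representation: the literal SL matrix
    # Lambda [gamma | diag(sqrt(1 - gamma^2))] has rank k_group, so a direct
    # (k_group + 1)-factor extraction is rotated onto the SL pattern by
    # orthogonal Procrustes and used for score weights.
    scoring = combined
    p = frame.shape[0]
    if identification_df(p, k_group + 1) >= 0:
        direct = extract_ml(frame, k_group + 1, n)
        A = direct.loadings.to_numpy()
        U, _, Vt = np.linalg.svd(A.T @ combined)
        scoring = A @ (U @ Vt)
    scoring_frame = pd.DataFrame(scoring, index=frame.index, columns=names)
    if np.linalg.matrix_rank(scoring, tol=1e-10) == k_group + 1:
        ar_w = _model_ar_weights(frame.to_numpy(), scoring)
    else:
        # degenerate fallback: per-column regression weights, unnormalised
        ar_w = np.linalg.solve(frame.to_numpy(), scoring)
    ar_frame = pd.DataFrame(ar_w, index=frame.index, columns=names)
    return BifactorSolution(
        general_loadings=general_s,
        group_loadings=group_f,
        ar_score_weights=ar_frame,
        higher_order_loadings=gamma,
        source=first_order,
        scoring_loadings=scoring_frame,
        degenerate_hierarchy=degenerate,
    )


def _inv_sqrt_psd(M: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    lam, vec = np.linalg.eigh((M + M.T) / 2.0)
    if lam[0] < floor:
        raise RankDeficiencyError("matrix is rank deficient")
    return (vec / np.sqrt(lam)) @ vec.T


def _model_ar_weights(R: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Anderson-Rubin weights W = R^{-1} L (L' R^{-1} L)^{-1/2}."""
    try:
        W0 = np.linalg.solve(R, loadings)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError("singular correlation matrix") from exc
    return W0 @ _inv_sqrt_psd(loadings.T @ W0)


def anderson_rubin_scores(standardized_responses, R, loadings):
    """Anderson-Rubin factor scores with exactly identity sample covariance.

    Regression-type scores ``Z R^{-1} Lambda`` are symmetrically
    orthogonalised against their own sample covariance (computed with 1/n),
    so the returned scores have identity covariance on the fitting sample to
    machine precision.  Returns ``(scores, weights)``; the weights apply to
    items standardised the same way as ``standardized_responses``.
    """
    if isinstance(standardized_responses, pd.DataFrame):
        Z = standardized_responses.to_numpy(dtype=float)
        index = standardized_responses.index
    else:
        Z = np.asarray(standardized_responses, dtype=float)
        index = pd.RangeIndex(Z.shape[0])
    frame = _as_corr(R)
    if isinstance(loadings, (pd.DataFrame, pd.Series)):
        Lam = np.asarray(loadings, dtype=float)
        names = list(loadings.columns) if isinstance(loadings, pd.DataFrame) else [loadings.name]
    else:
        Lam = np.asarray(loadings, dtype=float)
        names = [f"F{j + 1}" for j in range(Lam.shape[1])]
    if Lam.ndim == 1:
        Lam = Lam[:, None]
    if np.linalg.matrix_rank(Lam, tol=1e-10) < Lam.shape[1]:
        raise RankDeficiencyError("loading matrix is rank deficient")

    try:
        W0 = np.linalg.solve(frame.to_numpy(), Lam)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError("singular correlation matrix") from exc
    S0 = Z @ W0
    C = (S0.T @ S0) / Z.shape[0]
    C_inv_sqrt = _inv_sqrt_psd(C)
    weights = W0 @ C_inv_sqrt
    scores = pd.DataFrame(Z @ weights, index=index, columns=names)
    weights_frame = pd.DataFrame(weights, index=frame.index, columns=names)
    return scores, weights_frame
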