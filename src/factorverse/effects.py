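"""Dimension scoring and signed Cohen's f-squared effect estimation.

A candidate dimension is a vector of item weights.  Scores are linear
combinations of (optionally standardised) item responses; effects are
ordinary least-squares regressions of a cognitive outcome on the focal
dimension plus conditioning dimensions and demographic covariates, summarised
as a signed Cohen's f-squared

    f2 = (R2_full - R2_without_focal) / (1 - R2_full)

carrying the sign of the focal coefficient.  Effects from several datasets
are pooled by sample-size weighting, as in a fixed-weight meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CollinearityError, InvalidArgumentError, MissingItemError

STANDARDIZATIONS = ("raw", "discovery_z", "within_dataset_z")


@dataclass
class DimensionScores:
    """Per-participant scores on one candidate dimension."""

    dimension_id: str
    scores: pd.Series
    standardization: str

    def __post_init__(self):
        if self.standardization not in STANDARDIZATIONS:
            raise InvalidArgumentError(
                f"unknown standardization {self.standardization!r}"
            )
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise InvalidArgumentError("scores must be finite")


@dataclass
class EffectRecord:
    """One dimension's signed effect in one dataset for one outcome."""

    dataset_id: str
    n: int
    outcome_label: str
    dimension_id: str
    f2_signed: float
    beta: float
    p_value: float
    covariates: tuple
    conditioning: tuple


@dataclass
class WeightedEffect:
    """Sample-size-weighted average effect across datasets."""

    dimension_id: str
    outcome_label: str
    f2_weighted: float
    dataset_ns: tuple


def apply_weights(
    responses: pd.DataFrame,
    item_weights: pd.Series,
    standardization: str = "discovery_z",
    *,
    item_means: pd.Series | None = None,
    item_sds: pd.Series | None = None,
    dimension_id: str = "dimension",
) -> DimensionScores:
    """Score participants: sum over items of (standardised) response x weight.

    ``discovery_z`` standardises each item with the discovery-sample mean/SD
    supplied via ``item_means``/``item_sds``; ``within_dataset_z`` uses the
    current dataset's own moments; ``raw`` uses responses as given.  Items
    outside the weight vector contribute nothing.
    """
    if standardization not in STANDARDIZATIONS:
        raise InvalidArgumentError(f"unknown standardization {standardization!r}")
    items = list(item_weights.index)
    missing = [i for i in items if i not in responses.columns]
    if missing:
        raise MissingItemError(missing)
    X = responses[items].to_numpy(dtype=float)
    if standardization == "discovery_z":
        if item_means is None or item_sds is None:
            raise InvalidArgumentError("discovery_z needs item_means and item_sds")
        mu = item_means.reindex(items).to_numpy(dtype=float)
        sd = item_sds.reindex(items).to_numpy(dtype=float)
        if np.isnan(mu).any() or np.isnan(sd).any() or (sd <= 0).any():
            raise InvalidArgumentError("invalid discovery means/SDs for weighted items")
        X = (X - mu) / sd
    elif standardization == "within_dataset_z":
        sd = X.std(axis=0, ddof=0)
        if (sd <= 0).any():
            raise InvalidArgumentError("constant item under within_dataset_z")
        X = (X - X.mean(axis=0)) / sd
    scores = pd.Series(X @ item_weights.to_numpy(dtype=float),
                       index=responses.index, name=dimension_id)
    return DimensionScores(dimension_id=dimension_id, scores=scores,
                           standardization=standardization)


def questionnaire_totals(responses: pd.DataFrame, questionnaire_map: dict) -> pd.DataFrame:
    """Per-questionnaire total scores (plain sums of item responses)."""
    out = {}
    for label, items in questionnaire_map.items():
        if not items:
            raise InvalidArgumentError(f"questionnaire {label!r} has no items")
        missing = [i for i in items if i not in responses.columns]
        if missing:
            raise MissingItemError(missing)
        out[label] = responses[list(items)].sum(axis=1)
    return pd.DataFrame(out, index=responses.index)


def code_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design columns for covariates: numeric as-is, categoricals as
    indicator contrasts with the largest category as reference."""
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "ifu":
            cols[name] = col.astype(float)
        else:
            ref = col.value_counts().idxmax()
            for level in sorted(set(col.unique()) - {ref}):
                cols[f"{name}_{level}"] = (col == level).astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else 0.0


def fit_effect(
    outcome: pd.Series,
    focal: DimensionScores,
    covariates: pd.DataFrame | None = None,
    conditioning: list[DimensionScores] | None = None,
    *,
    dataset_id: str = "dataset",
) -> EffectRecord:
    """OLS effect of a focal dimension on an outcome, as signed Cohen's f2.

    The full model regresses the outcome on focal + conditioning dimensions +
    covariates; the reduced model drops the focal term.  Incomplete cases are
    dropped listwise.  Perfect collinearity of the focal score with the rest
    of the design raises :class:`CollinearityError`.
    """
    conditioning = conditioning or []
    blocks = {"__focal__": focal.scores}
    for i, cond in enumerate(conditioning):
        blocks[f"cond_{i}_{cond.dimension_id}"] = cond.scores
    design = pd.DataFrame(blocks)
    cov_names: tuple = ()
    if covariates is not None and covariates.shape[1] > 0:
        coded = code_covariates(covariates)
        cov_names = tuple(coded.columns)
        design = design.join(coded, how="inner")
    frame = design.join(outcome.rename("__y__"), how="inner").dropna()
    n = len(frame)
    p = design.shape[1]
    if n < p + 10:
        raise InvalidArgumentError(f"too few complete cases: {n} for {p} predictors")

    y = frame["__y__"].to_numpy(dtype=float)
    X_full = frame.drop(columns="__y__").to_numpy(dtype=float)
    # standardise so the focal coefficient is reported as a beta weight
    sds = X_full.std(axis=0, ddof=0)
    if sds[0] == 0:
        raise InvalidArgumentError("focal scores are constant")
    keep = sds > 0
    X_full = (X_full[:, keep] - X_full[:, keep].mean(axis=0)) / sds[keep]
    y_sd = y.std(ddof=0)
    if y_sd == 0:
        raise InvalidArgumentError("outcome is constant")
    y_std = (y - y.mean()) / y_sd

    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise CollinearityError("focal dimension is collinear with the design")

    r2_full = _r_squared(y_std, X_full)
    r2_reduced = _r_squared(y_std, X_full[:, 1:])
    f2 = (r2_full - r2_reduced) / (1.0 - r2_full)

    Xc = np.column_stack([np.ones(n), X_full])
    coef, _, _, _ = np.linalg.lstsq(Xc, y_std, rcond=None)
    resid = y_std - Xc @ coef
    dof = n - Xc.shape[1]
    sigma2 = float((resid ** 2).sum()) / dof
    cov_beta = sigma2 * np.linalg.inv(Xc.T @ Xc)
    beta_focal = float(coef[1])
    se = float(np.sqrt(cov_beta[1, 1]))
    t_stat = beta_focal / se if se > 0 else np.inf
    p_value = float(2.0 * stats.t.sf(abs(t_stat), dof))

    sign = float(np.sign(beta_focal)) if beta_focal != 0 else 0.0
    f2_signed = sign * abs(f2) if sign != 0 else 0.0
    return EffectRecord(
        dataset_id=dataset_id,
        n=n,
        outcome_label=str(outcome.name),
        dimension_id=focal.dimension_id,
        f2_signed=float(f2_signed),
        beta=beta_focal,
        p_value=p_value,
        covariates=cov_names,
        conditioning=tuple(c.dimension_id for c in conditioning),
    )


def weighted_average(effects: list[EffectRecord]) -> WeightedEffect:
    """Sample-size-weighted mean signed f2 across datasets."""
    if not effects:
        raise InvalidArgumentError("need at least one effect record")
    outcomes = {e.outcome_label for e in effects}
    dims = {e.dimension_id for e in effects}
    if len(outcomes) > 1:
        raise InvalidArgumentError(f"mixed outcomes: {sorted(outcomes)}")
    if len(dims) > 1:
        raise InvalidArgumentError(f"mixed dimensions: {sorted(dims)}")
    ns = np.array([e.n for e in effects], dtype=float)
    f2s = np.array([e.f2_signed for e in effects], dtype=float)
    return WeightedEffect(
        dimension_id=effects[0].dimension_id,
        outcome_label=effects[0].outcome_label,
        f2_weighted=float((ns * f2s).sum() / ns.sum()),
        dataset_ns=tuple(int(n) for n in ns),
    )
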