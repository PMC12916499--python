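"""Heterogeneous (polychoric / Pearson) correlation matrices for ordinal items.

Ordinal questionnaire items are modelled as discretised bivariate-normal
variables.  Each pairwise correlation is estimated in two steps: item
thresholds from the marginal cumulative proportions via the inverse normal
CDF, then the latent correlation by maximising the bivariate-normal
likelihood of the observed contingency table.  Pairwise estimation does not
guarantee a positive semi-definite matrix, so an eigenvalue-flooring repair
is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from ._bvn import cell_probabilities
from .exceptions import (
    DegenerateItemError,
    InvalidArgumentError,
    UndefinedThresholdError,
)

RHO_BOUND = 0.999
_PROB_FLOOR = 1e-12


@dataclass
class HetCorMatrix:
    """Items-by-items correlation matrix with per-pair estimation metadata.

    ``matrix`` is a symmetric unit-diagonal DataFrame; ``method_per_pair``
    holds ``"polychoric"`` or ``"pearson"`` per off-diagonal pair;
    ``clamped_pairs`` lists pairs whose estimate hit the +/-0.999 bound.
    """

    matrix: pd.DataFrame
    method_per_pair: pd.DataFrame
    psd_adjusted: bool = False
    min_eigenvalue_before: float = float("nan")
    clamped_pairs: list = field(default_factory=list)

    @property
    def items(self):
        return list(self.matrix.columns)

    @property
    def values(self):
        return self.matrix.to_numpy()

    def submatrix(self, items) -> "HetCorMatrix":
        """Restrict to a subset of items (pairwise estimates are unchanged)."""
        items = list(items)
        sub = self.matrix.loc[items, items]
        return HetCorMatrix(
            matrix=sub,
            method_per_pair=self.method_per_pair.loc[items, items],
            psd_adjusted=self.psd_adjusted,
            min_eigenvalue_before=float(np.linalg.eigvalsh(sub.to_numpy())[0]),
            clamped_pairs=[p for p in self.clamped_pairs if p[0] in items and p[1] in items],
        )

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "HetCorMatrix":
        m = pd.read_csv(path, index_col=0)
        methods = pd.DataFrame("polychoric", index=m.index, columns=m.columns)
        return cls(matrix=m, method_per_pair=methods,
                   min_eigenvalue_before=float(np.linalg.eigvalsh(m.to_numpy())[0]))


def _thresholds_from_margin(margin: np.ndarray) -> np.ndarray:
    """Interior normal thresholds from category counts of one margin."""
    total = margin.sum()
    cum = np.cumsum(margin)[:-1] / total
    return ndtri(cum)


def polychoric_nll(table: np.ndarray, row_thresholds, col_thresholds, rho: float) -> float:
    """Negative log-likelihood of a contingency table at latent correlation rho."""
    probs = np.clip(cell_probabilities(row_thresholds, col_thresholds, rho), _PROB_FLOOR, None)
    return float(-(table * np.log(probs)).sum())


def polychoric_pair(table, *, zero_cell_correction: float = 0.5, xatol: float = 1e-7):
    """Two-step polychoric correlation from a 2-D contingency table.

    Returns ``(rho, row_thresholds, col_thresholds)``.  Unoccupied rows or
    columns are dropped; if either margin then has a single category, the
    thresholds are undefined and :class:`UndefinedThresholdError` is raised.
    When any remaining cell is empty, ``zero_cell_correction`` is added to
    the empty cells only (set it to 0 to disable).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise InvalidArgumentError("table must be a 2-D array of non-negative counts")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise UndefinedThresholdError(
            "a margin has a single occupied category; thresholds undefined"
        )
    if zero_cell_correction and (table == 0).any():
        table = table + np.where(table == 0, zero_cell_correction, 0.0)

    a = _thresholds_from_margin(table.sum(axis=1))
    b = _thresholds_from_margin(table.sum(axis=0))

    res = minimize_scalar(
        lambda r: polychoric_nll(table, a, b, r),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), a, b


def _contingency(codes_i, codes_j, n_i, n_j) -> np.ndarray:
    flat = codes_i * n_j + codes_j
    return np.bincount(flat, minlength=n_i * n_j).reshape(n_i, n_j)


def heterogeneous_matrix(
    responses: pd.DataFrame,
    max_categories_for_polychoric: int = 10,
    *,
    zero_cell_correction: float = 0.5,
    xatol: float = 1e-6,
) -> HetCorMatrix:
    """Pairwise heterogeneous correlation matrix of ordinal items.

    Pairs where both items have at most ``max_categories_for_polychoric``
    observed categories are estimated polychorically; other pairs fall back
    to Pearson.  A constant item raises :class:`DegenerateItemError`.
    """
    if responses.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 participants")
    items = list(responses.columns)
    p = len(items)
    values = responses.to_numpy()

    codes, n_cats = [], []
    for idx, item in enumerate(items):
        _, coded = np.unique(values[:, idx], return_inverse=True)
        k = int(coded.max()) + 1
        if k < 2:
            raise DegenerateItemError(f"item {item!r} is constant")
        codes.append(coded)
        n_cats.append(k)

    mat = np.eye(p)
    methods = np.full((p, p), "", dtype=object)
    clamped = []
    pearson = np.corrcoef(values, rowvar=False)
    for i in range(p):
        for j in range(i + 1, p):
            if max(n_cats[i], n_cats[j]) <= max_categories_for_polychoric:
                tab = _contingency(codes[i], codes[j], n_cats[i], n_cats[j])
                rho, _, _ = polychoric_pair(
                    tab, zero_cell_correction=zero_cell_correction, xatol=xatol
                )
                method = "polychoric"
            else:
                rho = float(pearson[i, j])
                method = "pearson"
            if abs(rho) >= RHO_BOUND - 1e-6:
                rho = float(np.sign(rho)) * RHO_BOUND
                clamped.append((items[i], items[j]))
            mat[i, j] = mat[j, i] = rho
            methods[i, j] = methods[j, i] = method

    frame = pd.DataFrame(mat, index=items, columns=items)
    return HetCorMatrix(
        matrix=frame,
        method_per_pair=pd.DataFrame(methods, index=items, columns=items),
        psd_adjusted=False,
        min_eigenvalue_before=float(np.linalg.eigvalsh(mat)[0]),
        clamped_pairs=clamped,
    )


def ensure_psd(matrix, epsilon: float = 1e-8) -> HetCorMatrix:
    """Repair a symmetric correlation matrix to positive semi-definiteness.

    Eigenvalues below ``epsilon`` are floored at ``epsilon`` and the matrix is
    rescaled back to a unit diagonal.  A matrix already PSD (smallest
    eigenvalue >= epsilon) is returned unchanged with ``psd_adjusted=False``.
    """
    if isinstance(matrix, HetCorMatrix):
        frame = matrix.matrix
        methods = matrix.method_per_pair
        clamped = matrix.clamped_pairs
    else:
        frame = (matrix if isinstance(matrix, pd.DataFrame)
                 else pd.DataFrame(np.asarray(matrix, dtype=float)))
        methods = pd.DataFrame("", index=frame.index, columns=frame.columns)
        clamped = []
    a = frame.to_numpy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise InvalidArgumentError("ensure_psd requires a symmetric matrix")

    eigval, eigvec = np.linalg.eigh(a)
    min_before = float(eigval[0])
    if min_before >= epsilon:
        return HetCorMatrix(
            matrix=frame, method_per_pair=methods,
            psd_adjusted=False, min_eigenvalue_before=min_before,
            clamped_pairs=clamped,
        )
    floored = np.maximum(eigval, epsilon)
    repaired = (eigvec * floored) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2.0
    return HetCorMatrix(
        matrix=pd.DataFrame(repaired, index=frame.index, columns=frame.columns),
        method_per_pair=methods,
        psd_adjusted=True,
        min_eigenvalue_before=min_before,
        clamped_pairs=clamped,
    )
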