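"""Bivariate standard-normal rectangle probabilities via Owen's T function.

The polychoric likelihood needs P(X <= h, Y <= k) for many (h, k) pairs at a
trial correlation.  Owen's T gives a closed, vectorised route:

    Phi2(h, k, rho) = (Phi(h) + Phi(k)) / 2 - T(h, a_h) - T(k, a_k) - beta

with a_h = (k - rho*h) / (h*sqrt(1-rho^2)), a_k symmetric, and beta = 1/2
when h*k < 0 (or h*k = 0 with h + k < 0), else 0.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

# Exact zeros are nudged so the a_h, a_k ratios stay finite; Phi2 is
# continuous in h and k, so the error is O(eps).
_EPS = 1e-13


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast; entries may be +/-inf.  ``rho`` is scalar.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation out of range: {rho}")

    if rho >= 1.0 - 1e-12:
        return ndtr(np.minimum(h, k))
    if rho <= -1.0 + 1e-12:
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, 1.0)

    hf = np.where(h == 0.0, _EPS, h)
    kf = np.where(k == 0.0, _EPS, k)
    # Finite-value formula; infinities handled afterwards.
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        denom = np.sqrt(1.0 - rho * rho)
        a_h = (kf / hf - rho) / denom
        a_k = (hf / kf - rho) / denom
        hk = hf * kf
        beta = np.where((hk < 0) | ((hk == 0) & (hf + kf < 0)), 0.5, 0.0)
        finite = np.isfinite(hf) & np.isfinite(kf)
        out = np.where(
            finite,
            0.5 * (ndtr(hf) + ndtr(kf))
            - owens_t(np.where(finite, hf, 0.0), np.where(finite, a_h, 0.0))
            - owens_t(np.where(finite, kf, 0.0), np.where(finite, a_k, 0.0))
            - beta,
            0.0,
        )

    out = np.where(h == np.inf, ndtr(k), out)
    out = np.where(k == np.inf, np.where(h == np.inf, 1.0, ndtr(h)), out)
    out = np.where((h == -np.inf) | (k == -np.inf), 0.0, out)
    return np.clip(out, 0.0, 1.0)


def cell_probabilities(row_thresholds, col_thresholds, rho: float):
    """Cell probabilities of a cross-tabulated bivariate normal.

    ``row_thresholds``/``col_thresholds`` are the *interior* cut-points
    (length r-1 and c-1 for an r x c table).  Returns an (r, c) array that
    sums to 1.
    """
    a = np.concatenate(([-np.inf], np.asarray(row_thresholds, float), [np.inf]))
    b = np.concatenate(([-np.inf], np.asarray(col_thresholds, float), [np.inf]))
    cdf = bvn_cdf(a[:, None], b[None, :], rho)
    return np.diff(np.diff(cdf, axis=0), axis=1)
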