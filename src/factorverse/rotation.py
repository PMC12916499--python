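"""Analytic factor rotation by gradient projection.

Implements the gradient-projection algorithm (GPA) for orthogonal and
oblique rotation of an unrotated loading matrix, with the two criteria the
pipeline uses: direct quartimin (oblimin with gamma = 0) for oblique
solutions and the varimax criterion for orthogonal ones.  Both criteria are
expressed as minimisation problems; varimax is negated.
"""

from __future__ import annotations

import numpy as np


def quartimin_criterion(L: np.ndarray):
    """Direct quartimin: sum over item rows of cross-products of squared
    loadings between distinct factors.  Lower is simpler structure."""
    L2 = L * L
    k = L.shape[1]
    M = L2 @ (np.ones((k, k)) - np.eye(k))
    f = float((L2 * M).sum()) / 4.0
    grad = L * M
    return f, grad


def varimax_criterion(L: np.ndarray):
    """Negated varimax criterion (variance of squared loadings per factor)."""
    Q = L * L
    Qc = Q - Q.mean(axis=0, keepdims=True)
    f = -float((Q * Qc).sum()) / 4.0
    grad = -L * Qc
    return f, grad


def gpa_orthogonal(A, criterion, T=None, max_iter=2000, tol=1e-6):
    """Orthogonal GPA.  Returns (L, T, f, converged)."""
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    T = np.eye(k) if T is None else np.asarray(T, dtype=float)
    L = A @ T
    f, Gq = criterion(L)
    G = A.T @ Gq
    al = 1.0
    converged = False
    for _ in range(max_iter):
        M = T.T @ G
        S = (M + M.T) / 2.0
        Gp = G - T @ S
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            U, _, Vt = np.linalg.svd(X)
            Tt = U @ Vt
            L = A @ Tt
            ft, Gq = criterion(L)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, f = Tt, ft
        G = A.T @ Gq
    return A @ T, T, f, converged


def gpa_oblique(A, criterion, T=None, max_iter=2000, tol=1e-6):
    """Oblique GPA.  Returns (L, Phi, T, f, converged) with Phi = T'T."""
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    T = np.eye(k) if T is None else np.asarray(T, dtype=float)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = criterion(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0, keepdims=True)
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt((X * X).sum(axis=0, keepdims=True))
            Ti = np.linalg.inv(X)
            L = A @ Ti.T
            ft, Gq = criterion(L)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, f = X, ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, T, f, converged


def _random_orthonormal(k, rng):
    q, r = np.linalg.qr(rng.standard_normal((k, k)))
    return q * np.sign(np.diag(r))


def rotate_loadings(A, method: str, *, n_starts: int = 8, seed: int = 0,
                    max_iter: int = 2000, tol: float = 1e-6):
    """Rotate an unrotated loading matrix from multiple starts.

    Runs GPA from the identity plus ``n_starts`` seeded random starting
    rotations and keeps the solution with the lowest criterion value.
    Returns ``(L, Phi, f, converged)``; ``Phi`` is the identity for
    orthogonal methods.
    """
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.eye(1), 0.0, True
    rng = np.random.default_rng(seed)
    starts = [np.eye(k)] + [_random_orthonormal(k, rng) for _ in range(n_starts)]
    best = None
    for T0 in starts:
        if method == "oblimin":
            L, Phi, _, f, conv = gpa_oblique(A, quartimin_criterion, T=T0,
                                             max_iter=max_iter, tol=tol)
        elif method == "varimax":
            L, _, f, conv = gpa_orthogonal(A, varimax_criterion, T=T0,
                                           max_iter=max_iter, tol=tol)
            Phi = np.eye(k)
        else:
            raise ValueError(f"unknown rotation method: {method!r}")
        key = (not conv, f)
        if best is None or key < best[0]:
            best = (key, L, Phi, f, conv)
    _, L, Phi, f, conv = best
    return L, Phi, f, conv


def canonicalize(L, Phi):
    """Apply the reporting convention to a rotated solution.

    Each factor is sign-flipped so its largest-magnitude loading is positive,
    and factors are ordered by sum of squared loadings, descending.  ``Phi``
    is permuted and flipped consistently.
    """
    L = np.array(L, dtype=float)
    Phi = np.array(Phi, dtype=float)
    for j in range(L.shape[1]):
        col = L[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            L[:, j] = -col
            Phi[j, :] *= -1.0
            Phi[:, j] *= -1.0
    order = np.argsort(-(L * L).sum(axis=0), kind="stable")
    return L[:, order], Phi[np.ix_(order, order)], order
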