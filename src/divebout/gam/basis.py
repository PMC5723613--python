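"""Cubic regression spline and tensor-product bases with roughness penalties.

The univariate basis is the knot-value parameterization of a natural cubic
spline: coefficients are the spline's values at k knots placed at quantiles
of the covariate, and the penalty is the exact integrated squared second
derivative, whose null space is the straight lines.  Evaluation at the knots
therefore reproduces the interpolating natural cubic spline, and evaluation
beyond the boundary knots extends linearly.

Tensor-product smooths take the row-wise Kronecker product of two marginal
bases and carry one marginal roughness penalty per covariate, each with its
own smoothing parameter — the anisotropic construction appropriate when the
two covariates live on different scales (e.g. seconds and metres).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from divebout.errors import FitError

__all__ = ["CRBasis", "cr_basis", "tensor_basis", "null_space_constraint"]


class BasisError(FitError):
    """Basis construction failed (too few distinct covariate values...)."""


@dataclass
class CRBasis:
    """Evaluated cubic-regression-spline basis and its roughness penalty."""

    X: np.ndarray        # (n, k) design
    S: np.ndarray        # (k, k) PSD penalty, null space = straight lines
    knots: np.ndarray    # (k,) strictly increasing


def _cr_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F (maps knot values to knot second derivatives) and penalty S = D' B^-1 D."""
    k = knots.size
    h = np.diff(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = np.linalg.solve(B, D)
    F = np.vstack([np.zeros(k), Binv_D, np.zeros(k)])  # natural end conditions
    S = D.T @ Binv_D
    S = (S + S.T) / 2
    return F, S


def _cr_rows(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Design rows of the knot-value spline at points x (linear extrapolation)."""
    k = knots.size
    h = np.diff(knots)
    x = np.asarray(x, dtype=float)
    X = np.zeros((x.size, k))

    inside = (x >= knots[0]) & (x <= knots[-1])
    xi = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, k - 2)
    hj = h[j]
    am = (knots[j + 1] - xi) / hj
    ap = (xi - knots[j]) / hj
    cm = ((knots[j + 1] - xi) ** 3 / hj - hj * (knots[j + 1] - xi)) / 6.0
    cp = ((xi - knots[j]) ** 3 / hj - hj * (xi - knots[j])) / 6.0
    rows = np.zeros((x.size, k))
    idx = np.arange(x.size)
    rows[idx, j] += am
    rows[idx, j + 1] += ap
    rows += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
    X[:] = rows

    # linear extension beyond the boundary knots
    for boundary, sign in ((knots[0], -1), (knots[-1], +1)):
        out = (x < knots[0]) if sign < 0 else (x > knots[-1])
        if not out.any():
            continue
        jb = 0 if sign < 0 else k - 2
        hb = h[jb]
        d_row = np.zeros(k)
        if sign < 0:
            d_row[0] -= 1.0 / hb
            d_row[1] += 1.0 / hb
            d_row += (-hb / 3.0) * F[0] + (-hb / 6.0) * F[1]
        else:
            d_row[k - 2] -= 1.0 / hb
            d_row[k - 1] += 1.0 / hb
            d_row += (hb / 6.0) * F[k - 2] + (hb / 3.0) * F[k - 1]
        X[out] += (x[out] - boundary)[:, None] * d_row
    del inside
    return X


def choose_knots(x: np.ndarray, k: int) -> np.ndarray:
    """k knots at quantiles of the distinct covariate values."""
    ux = np.unique(np.asarray(x, dtype=float))
    if ux.size < k:
        raise BasisError(f"need at least k={k} distinct values, got {ux.size}")
    knots = np.quantile(ux, np.linspace(0, 1, k))
    if np.any(np.diff(knots) <= 0):  # heavy ties: fall back to even spacing
        knots = np.linspace(ux[0], ux[-1], k)
    return knots


def cr_basis(x: np.ndarray, k: int, knots: np.ndarray | None = None) -> CRBasis:
    """Cubic regression spline basis of dimension ``k`` evaluated at ``x``.

    ``knots`` may be supplied (e.g. when evaluating on new data); otherwise
    they sit at quantiles of the distinct values of ``x``.
    """
    if k < 3:
        raise BasisError(f"k must be >= 3, got {k}")
    if knots is None:
        knots = choose_knots(x, k)
    knots = np.asarray(knots, dtype=float)
    F, S = _cr_matrices(knots)
    X = _cr_rows(np.asarray(x, dtype=float), knots, F)
    return CRBasis(X=X, S=S, knots=knots)


def tensor_basis(
    x1: np.ndarray,
    x2: np.ndarray,
    k1: int,
    k2: int,
    knots1: np.ndarray | None = None,
    knots2: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Anisotropic tensor-product smooth basis.

    Returns ``(X, S1, S2, knots1, knots2)`` where X is the row-wise Kronecker
    product of the marginal bases (n, k1*k2) and S1, S2 are the two marginal
    roughness penalties expanded to the product space, each meant to carry
    its own smoothing parameter.
    """
    b1 = cr_basis(x1, k1, knots1)
    b2 = cr_basis(x2, k2, knots2)
    X = (b1.X[:, :, None] * b2.X[:, None, :]).reshape(len(b1.X), k1 * k2)
    S1 = np.kron(b1.S, np.eye(k2))
    S2 = np.kron(np.eye(k1), b2.S)
    return X, S1, S2, b1.knots, b2.knots


def null_space_constraint(col_means: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the sum-to-zero constraint {b : m'b = 0}.

    Reparameterizing a smooth as X Z absorbs the identifiability constraint
    (the fitted smooth averages to zero over the data), dropping one column.
    """
    m = np.asarray(col_means, dtype=float)
    q = m.size
    # Householder: reflect m onto e1, take remaining q-1 columns
    v = m.copy()
    v[0] += np.sign(m[0] or 1.0) * np.linalg.norm(m)
    H = np.eye(q) - 2.0 * np.outer(v, v) / (v @ v)
    return H[:, 1:]
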