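"""Tetrachoric correlations, thresholds and their asymptotic variances.

This is the summary-statistics stage of limited-information (WLSMV-style)
estimation for binary items: item thresholds come from the univariate
margins on the probit scale, and each pairwise tetrachoric correlation is
the maximum-likelihood correlation of a latent bivariate normal reproducing
the pair's 2x2 table with the thresholds held fixed (two-stage estimation).

Because the one-parameter profile fit reproduces the 2x2 table exactly,
the MLE solves ``Phi2(tau_i, tau_j; rho) = p00`` and the observed and
expected information coincide at the solution; the per-pair asymptotic
variance is the inverse of that information.

Bivariate-normal rectangle probabilities are evaluated through Owen's T
function, which is accurate to near machine precision and fully
vectorized, so all I(I-1)/2 correlations are solved simultaneously by
bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri, owens_t

from .simulate import ResponseMatrix

__all__ = [
    "TetrachoricSummary",
    "bvn_cdf",
    "bvn_pdf",
    "estimate_thresholds",
    "tetrachoric_pair",
    "summarize",
]

_RHO_BOUND = 0.99995          # search interval for rho, keeps variances finite
_MIN_EIGENVALUE = 1e-8        # PSD smoothing threshold


@dataclass
class TetrachoricSummary:
    """Thresholds, correlation matrix and per-pair asymptotic variances.

    ``asymptotic_variances`` has one entry per off-diagonal pair, ordered
    column-major over the strict lower triangle (pairs (1,0), (2,0), ...,
    (I-1,0), (2,1), ...); it is the sampling variance of each correlation
    estimate (order 1/N).  ``smoothed`` flags that the assembled matrix
    needed eigenvalue clipping to become positive semi-definite.
    """

    thresholds: np.ndarray
    correlations: np.ndarray
    asymptotic_variances: np.ndarray
    n_persons: int
    smoothed: bool = False

    @property
    def n_items(self) -> int:
        return len(self.thresholds)

    def pair_indices(self):
        """(i, k) index arrays matching the asymptotic-variance ordering."""
        j, i = np.triu_indices(self.n_items, 1)
        return i, j

    def pair_correlations(self) -> np.ndarray:
        i, j = self.pair_indices()
        return self.correlations[i, j]


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Uses the Owen's T representation; vectorized over all arguments.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, dtype=float), np.asarray(k, dtype=float),
        np.asarray(rho, dtype=float),
    )
    scalar = h.ndim == 0
    h = np.atleast_1d(h).copy()
    k = np.atleast_1d(k).copy()
    rho = np.clip(np.atleast_1d(rho), -1 + 1e-15, 1 - 1e-15)

    both_zero = (h == 0) & (k == 0)
    # the Owen's T arguments divide by h and k; nudge exact zeros upward,
    # which leaves the result unchanged to ~1e-13
    h[h == 0] = 1e-13
    k[k == 0] = 1e-13

    s = np.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * s)
    a2 = (h - rho * k) / (k * s)
    beta = np.where(h * k < 0, 0.5, 0.0)
    p = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a1) - owens_t(k, a2) - beta
    p = np.where(both_zero, 0.25 + np.arcsin(rho) / (2 * np.pi), p)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p.reshape(np.broadcast(h, k).shape)


def bvn_pdf(h, k, rho):
    """Standard bivariate normal density at (h, k) with correlation rho."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    om = 1.0 - rho * rho
    return np.exp(-(h * h - 2 * rho * h * k + k * k) / (2 * om)) / (
        2 * np.pi * np.sqrt(om)
    )


def estimate_thresholds(data) -> np.ndarray:
    """Probit thresholds ``tau_i = ndtri(P(X_i = 0))`` from the margins."""
    x = data.data if isinstance(data, ResponseMatrix) else np.asarray(data)
    p_zero = (x == 0).mean(axis=0)
    if ((p_zero == 0) | (p_zero == 1)).any():
        bad = np.flatnonzero((p_zero == 0) | (p_zero == 1))
        raise ValueError(f"items {bad.tolist()} have a single response category")
    return ndtri(p_zero)


def _solve_rho(h, k, p00, iterations: int = 52):
    """Vectorized bisection for Phi2(h, k; rho) = p00 (monotone in rho)."""
    lo = np.full_like(np.asarray(p00, dtype=float), -_RHO_BOUND)
    hi = np.full_like(lo, _RHO_BOUND)
    # clamp targets to the attainable range so the bracket always holds
    p_lo = bvn_cdf(h, k, lo)
    p_hi = bvn_cdf(h, k, hi)
    target = np.clip(p00, p_lo, p_hi)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        above = bvn_cdf(h, k, mid) > target
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    return 0.5 * (lo + hi)


def _pair_estimates(counts):
    """rho and asymptotic variance for a (K, 4) array of [n00, n01, n10, n11].

    ``n_ab`` counts persons with ``X_first = a`` and ``X_second = b``.
    Tables containing a zero cell get 0.5 added to every cell (continuity
    correction); that pair's thresholds come from the corrected margins.
    """
    counts = np.asarray(counts, dtype=float)
    needs_cc = (counts == 0).any(axis=1)
    counts = counts + 0.5 * needs_cc[:, None]
    n = counts.sum(axis=1)
    p00, p01, p10, p11 = (counts[:, c] / n for c in range(4))
    h = ndtri(p00 + p01)   # P(first item = 0)
    k = ndtri(p00 + p10)   # P(second item = 0)
    rho = _solve_rho(h, k, p00)
    dens = bvn_pdf(h, k, rho)
    info = n * dens * dens * (1 / p00 + 1 / p01 + 1 / p10 + 1 / p11)
    return rho, 1.0 / info


def tetrachoric_pair(table):
    """ML tetrachoric correlation and its asymptotic variance from a 2x2 table.

    Parameters
    ----------
    table:
        ``[[n00, n01], [n10, n11]]`` counts; rows index the first item's
        response (0/1), columns the second's.

    Returns
    -------
    (rho, asymptotic_variance)
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be a 2x2 array of non-negative counts")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("a margin of the 2x2 table is empty")
    counts = table.ravel()[None, :]
    rho, avar = _pair_estimates(counts)
    if not np.isfinite(rho[0]) or not np.isfinite(avar[0]):
        raise ArithmeticError(f"tetrachoric estimation failed for table {table}")
    return float(rho[0]), float(avar[0])


def _smooth_correlations(r: np.ndarray):
    """Clip eigenvalues below the PSD threshold and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= _MIN_EIGENVALUE:
        return r, False
    vals = np.clip(vals, _MIN_EIGENVALUE, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def summarize(data) -> TetrachoricSummary:
    """Estimate all thresholds and pairwise tetrachorics of a binary matrix.

    All I(I-1)/2 pairs are solved in one vectorized pass.  If the assembled
    correlation matrix is not positive semi-definite it is smoothed by
    eigenvalue clipping (and flagged), so downstream weighted least squares
    always receives a valid matrix.
    """
    x = data.data if isinstance(data, ResponseMatrix) else np.asarray(data)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 persons and 2 items")
    n, n_items = x.shape
    tau = estimate_thresholds(x)

    xf = x.astype(float)
    ones = xf.sum(axis=0)
    n11 = xf.T @ xf
    j_idx, i_idx = np.triu_indices(n_items, 1)   # pair k = (i_idx[k], j_idx[k])
    n11_p = n11[i_idx, j_idx]
    n10_p = ones[i_idx] - n11_p
    n01_p = ones[j_idx] - n11_p
    n00_p = n - ones[i_idx] - ones[j_idx] + n11_p
    counts = np.column_stack([n00_p, n01_p, n10_p, n11_p])
    rho, avar = _pair_estimates(counts)

    r = np.eye(n_items)
    r[i_idx, j_idx] = rho
    r[j_idx, i_idx] = rho
    r, smoothed = _smooth_correlations(r)
    return TetrachoricSummary(
        thresholds=tau,
        correlations=r,
        asymptotic_variances=avar,
        n_persons=n,
        smoothed=smoothed,
    )
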