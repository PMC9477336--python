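"""Principal component analysis of standardized Rasch residuals (PCAR).

After fitting the Rasch model there should be no structure left in the
item residuals; the largest eigenvalue V1 of their inter-item correlation
matrix is the classical screen for violations of unidimensionality.  For
pure noise V1 hovers a little above 1; shared subset traits push it up.

Residuals are the usual standardized Rasch residuals

    z_pi = (x_pi - P_pi) / sqrt(P_pi (1 - P_pi)),   P_pi = logistic(theta_hat_p - b_hat_i),

and the PCA is taken on their Pearson correlation matrix (covariance-based
PCA is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .calibration import RaschCalibration
from .simulate import ResponseMatrix

__all__ = ["PcarResult", "standardized_residuals", "first_eigenvalue", "pcar"]

_PROB_CLAMP = 1e-10


@dataclass
class PcarResult:
    """Eigenvalues of the residual correlation (or covariance) matrix."""

    first_eigenvalue: float
    eigenvalues: np.ndarray      # descending, length I
    residual_matrix: np.ndarray  # N x I


def standardized_residuals(data, calib: RaschCalibration) -> np.ndarray:
    """Standardized residuals under the calibrated Rasch model.

    Fitted probabilities are clamped away from exactly 0/1 before
    standardizing (relevant only at extreme ability estimates).
    """
    x = data.data if isinstance(data, ResponseMatrix) else np.asarray(data)
    p = expit(calib.ability_hat[:, None] - calib.difficulty_hat[None, :])
    p = np.clip(p, _PROB_CLAMP, 1.0 - _PROB_CLAMP)
    return (x - p) / np.sqrt(p * (1.0 - p))


def first_eigenvalue(residuals: np.ndarray, use_correlation: bool = True) -> PcarResult:
    """Eigen-decomposition of the inter-item residual correlation matrix.

    The eigenvalues of the I x I correlation matrix sum to I; V1 is the
    largest.  A residual column with zero variance makes the correlation
    undefined and is reported as an error naming the item.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[1] < 2:
        raise ValueError("need an N x I residual matrix with I >= 2")
    sd = residuals.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant residual column(s) for item(s) {bad.tolist()}")
    if use_correlation:
        m = np.corrcoef(residuals, rowvar=False)
    else:
        m = np.cov(residuals, rowvar=False)
    vals = np.linalg.eigvalsh(m)[::-1]
    return PcarResult(float(vals[0]), vals, residuals)


def pcar(data, calib: RaschCalibration, use_correlation: bool = True) -> PcarResult:
    """Standardized residuals followed by the eigen-decomposition."""
    return first_eigenvalue(
        standardized_residuals(data, calib), use_correlation=use_correlation
    )
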