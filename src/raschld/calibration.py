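"""Rasch parameter estimation on the logit scale and recovery RMSEs.

Item difficulties are estimated by conditional maximum likelihood (CMLE):
conditioning on each person's raw score removes the person parameters, and
the conditional likelihood involves the elementary symmetric functions
``gamma_r`` of the item easiness parameters ``eps_i = exp(-b_i)``.  The
sum-zero constraint on the difficulties identifies the scale.

Person abilities are estimated by Warm's weighted likelihood (WLE), which
keeps estimates finite at perfect and zero raw scores; under the Rasch
model the raw score is sufficient, so one root-find per observed score
suffices.

Recovery is summarized by

    RMSE_theta = sqrt( sum_p (theta_hat_p - theta_p)^2 / (N - 1) )
    RMSE_b     = sqrt( sum_i (b_hat_i - b_i)^2 / (I - 1) )

with both difficulty vectors centered to sum zero before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import expit

from .simulate import ResponseMatrix

__all__ = [
    "RaschCalibration",
    "elementary_symmetric",
    "elementary_symmetric_without",
    "estimate_difficulties",
    "estimate_abilities",
    "rmse_theta",
    "rmse_b",
    "calibrate",
]


@dataclass
class RaschCalibration:
    """CMLE difficulties, WLE abilities and (when truth is known) RMSEs."""

    difficulty_hat: np.ndarray
    ability_hat: np.ndarray
    rmse_theta: Optional[float] = None
    rmse_b: Optional[float] = None
    converged: bool = True
    method_tags: tuple = ("item: CMLE", "person: WLE")


def elementary_symmetric(eps: np.ndarray) -> np.ndarray:
    """Coefficients gamma_0..gamma_I of prod_i (1 + eps_i t).

    Computed by the summation (convolution) recursion in linear space:
    with sum-zero-centred difficulties the coefficients stay far below
    float64 overflow for any realistic test length.
    """
    eps = np.asarray(eps, dtype=float)
    g = np.zeros(len(eps) + 1)
    g[0] = 1.0
    for j, e in enumerate(eps):
        g[1 : j + 2] = g[1 : j + 2] + e * g[: j + 1]
    return g


def elementary_symmetric_without(eps: np.ndarray) -> np.ndarray:
    """gamma^(i): row i holds the ESFs of all items except item i.

    Forward prefix / backward suffix polynomials combined per item, so the
    whole table costs O(I^3) scalar multiplies via short convolutions.
    """
    eps = np.asarray(eps, dtype=float)
    n = len(eps)
    fwd = [np.array([1.0])]
    for e in eps[:-1]:
        fwd.append(np.convolve(fwd[-1], [1.0, e]))
    bwd = [np.array([1.0])]
    for e in eps[:0:-1]:
        bwd.append(np.convolve(bwd[-1], [1.0, e]))
    bwd.reverse()
    out = np.zeros((n, n))
    for i in range(n):
        out[i] = np.convolve(fwd[i], bwd[i])
    return out


def _score_data(x: np.ndarray):
    """Raw-score counts and item margins over persons with interior scores."""
    n, n_items = x.shape
    raw = x.sum(axis=1)
    interior = (raw > 0) & (raw < n_items)
    n_r = np.bincount(raw[interior], minlength=n_items + 1)[1:n_items]
    s_i = x[interior].sum(axis=0).astype(float)
    return n_r.astype(float), s_i


def _neg_cloglik_and_grad(b: np.ndarray, n_r: np.ndarray, s_i: np.ndarray):
    n_items = len(b)
    eps = np.exp(-b)
    g = elementary_symmetric(eps)
    g_wo = elementary_symmetric_without(eps)
    r = np.arange(1, n_items)
    nll = float(s_i @ b + n_r @ np.log(g[r]))
    # expected score of item i among persons with raw score r
    pi_ir = eps[:, None] * g_wo[:, r - 1] / g[r][None, :]
    grad = s_i - pi_ir @ n_r
    return nll, grad


def estimate_difficulties(data) -> np.ndarray:
    """Conditional ML item difficulties, centered to sum zero.

    Persons with zero or perfect raw scores carry no information about the
    difficulties (their conditional likelihood is constant) and drop out.
    The concave conditional log-likelihood is maximized over I-1 free
    parameters with the last difficulty set to minus their sum.
    """
    x = data.data if isinstance(data, ResponseMatrix) else np.asarray(data)
    n, n_items = x.shape
    col = x.sum(axis=0)
    if ((col == 0) | (col == n)).any():
        raise ValueError("degenerate item (single response category)")
    n_r, s_i = _score_data(x)
    if n_r.sum() == 0:
        raise ValueError("no persons with interior raw scores")

    # start from centered log-odds of failure
    p = x.mean(axis=0)
    b0 = np.log((1 - p) / p)
    b0 = b0 - b0.mean()

    def objective(free):
        b = np.append(free, -free.sum())
        nll, grad = _neg_cloglik_and_grad(b, n_r, s_i)
        return nll, grad[:-1] - grad[-1]

    res = minimize(
        objective, b0[:-1], jac=True, method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * (n_items - 1),
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
    )
    b = np.append(res.x, -res.x.sum())
    if not res.success:
        # accept a near-stationary point, otherwise flag hard failure
        _, grad = _neg_cloglik_and_grad(b, n_r, s_i)
        if np.abs(grad[:-1] - grad[-1]).max() > 1e-4 * max(1.0, n_r.sum() / 100):
            raise RuntimeError(f"CMLE did not converge: {res.message}")
    return b - b.mean()


def _wle_equation(theta: float, b: np.ndarray, raw: int) -> float:
    p = expit(theta - b)
    q = 1.0 - p
    info = np.sum(p * q)
    j = np.sum(p * q * (1.0 - 2.0 * p))
    return raw - np.sum(p) + j / (2.0 * info)


def estimate_abilities(data, b_hat: np.ndarray) -> np.ndarray:
    """Warm weighted-likelihood ability estimates given item difficulties.

    The raw score is sufficient, so the WLE equation is solved once per
    observed score and mapped back to persons; estimates are finite at
    zero and perfect scores and strictly increasing in the raw score.
    """
    x = data.data if isinstance(data, ResponseMatrix) else np.asarray(data)
    b_hat = np.asarray(b_hat, dtype=float)
    raw = x.sum(axis=1)
    theta_by_score = {}
    for r in np.unique(raw):
        theta_by_score[int(r)] = brentq(
            _wle_equation, -15.0, 15.0, args=(b_hat, int(r)), xtol=1e-10
        )
    return np.array([theta_by_score[int(r)] for r in raw])


def rmse_theta(theta_hat: np.ndarray, theta_true: np.ndarray) -> float:
    """Ability recovery error with the N-1 denominator."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_hat.shape != theta_true.shape:
        raise ValueError("ability vectors must have equal length")
    n = len(theta_hat)
    if n < 2:
        raise ValueError("need at least two persons")
    return float(np.sqrt(np.sum((theta_hat - theta_true) ** 2) / (n - 1)))


def rmse_b(b_hat: np.ndarray, b_true: np.ndarray) -> float:
    """Difficulty recovery error with the I-1 denominator.

    Both vectors are centered to sum zero first, so the comparison is free
    of the arbitrary location of the logit scale.
    """
    b_hat = np.asarray(b_hat, dtype=float)
    b_true = np.asarray(b_true, dtype=float)
    if b_hat.shape != b_true.shape:
        raise ValueError("difficulty vectors must have equal length")
    n_items = len(b_hat)
    if n_items < 2:
        raise ValueError("need at least two items")
    d = (b_hat - b_hat.mean()) - (b_true - b_true.mean())
    return float(np.sqrt(np.sum(d * d) / (n_items - 1)))


def calibrate(data: ResponseMatrix) -> RaschCalibration:
    """Full calibration: CMLE difficulties, WLE abilities, recovery RMSEs.

    RMSEs are filled in only when the matrix carries its generating
    parameters; the true ability is the primary trait ``theta_p``.
    """
    b_hat = estimate_difficulties(data)
    theta_hat = estimate_abilities(data, b_hat)
    r_theta = r_b = None
    if data.truth is not None:
        r_theta = rmse_theta(theta_hat, data.truth.theta)
        r_b = rmse_b(b_hat, data.truth.difficulties)
    return RaschCalibration(
        difficulty_hat=b_hat,
        ability_hat=theta_hat,
        rmse_theta=r_theta,
        rmse_b=r_b,
    )
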