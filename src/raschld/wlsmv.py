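"""Diagonally weighted least squares fit of the Rasch-equivalent factor model.

The dichotomous Rasch model is equivalent to a one-factor categorical CFA
with all loadings equal and fixed to 1; the single free structural
parameter is the factor variance ``psi``.  With unit residual scaling the
model-implied latent correlation is the same for every item pair,
``sigma(psi) = psi / (1 + psi)``, so the target model is fitted by
minimizing the diagonally weighted discrepancy

    F(psi) = sum_k (r_k - sigma(psi))^2 / w_k

over the sample tetrachoric correlations ``r_k``, with ``w_k`` the
asymptotic variance of ``sqrt(N) r_k``.  Thresholds are saturated (fitted
at their sample values) and contribute zero discrepancy.  The baseline
model fixes every correlation at zero.

The test statistic is the mean-and-variance adjusted chi-square: ``N F_min``
rescaled so its first two moments match a chi-square reference, with the
asymptotic covariance of the correlations approximated as diagonal; under
that approximation the rescaling is exactly neutral and the statistic is
``N F_min`` on the model degrees of freedom.  CFI, TLI and RMSEA follow
their standard definitions:

    CFI   = 1 - max(chi2_t - df_t, 0) / max(chi2_t - df_t, chi2_b - df_b, 0)
    TLI   = (chi2_b - chi2_t (df_b / df_t)) / (chi2_b - df_b)
    RMSEA = sqrt((chi2 - df) / (df (N - 1)))        (radicand floored at 0)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .tetrachoric import TetrachoricSummary

__all__ = [
    "WlsmvFitResult",
    "fit_rasch_cfa",
    "fit_baseline",
    "adjusted_chi2",
    "fit_indices",
    "fit",
]

_PSI_BOUNDS = (1e-6, 100.0)


@dataclass
class WlsmvFitResult:
    """Chi-squares, degrees of freedom and fit indices of one fitted model."""

    chi2_target: float
    df_target: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    factor_variance: float
    fitted_thresholds: np.ndarray
    converged: bool
    stat_variant: str = "mv_adjust"


@dataclass
class TargetFit:
    """Target-model side of the fit: psi-hat and the minimized discrepancy."""

    factor_variance: float
    f_min: float
    df: int
    converged: bool


def _weights(summary: TetrachoricSummary) -> np.ndarray:
    # stored variances are for r_k (order 1/N); the DWLS weights are for
    # sqrt(N) r_k so that chi2 = N * F_min
    return summary.n_persons * summary.asymptotic_variances


def _discrepancy(sigma, r, w) -> float:
    e = r - sigma
    return float(np.sum(e * e / w))


def fit_rasch_cfa(summary: TetrachoricSummary) -> TargetFit:
    """Fit the one-factor model with loadings 1 and free factor variance.

    A bounded one-dimensional minimization over ``psi`` (the problem is
    smooth with a single interior minimum for any positive weights); if the
    minimizer lands on a bound a coarse grid + polish pass is retried.
    Degrees of freedom: I(I-1)/2 sample correlations minus one free
    parameter.
    """
    r = summary.pair_correlations()
    w = _weights(summary)
    if len(r) < 2:
        raise ValueError("need at least 3 items (2+ correlations) to fit")

    def objective(psi):
        return _discrepancy(psi / (1.0 + psi), r, w)

    res = minimize_scalar(
        objective, bounds=_PSI_BOUNDS, method="bounded",
        options={"xatol": 1e-10},
    )
    psi = float(res.x)
    converged = bool(res.success)
    span = _PSI_BOUNDS[1] - _PSI_BOUNDS[0]
    if not converged or psi - _PSI_BOUNDS[0] < 1e-8 or _PSI_BOUNDS[1] - psi < 1e-6 * span:
        grid = np.geomspace(_PSI_BOUNDS[0], _PSI_BOUNDS[1], 2001)
        best = grid[np.argmin([objective(p) for p in grid])]
        lo = max(_PSI_BOUNDS[0], best / 2)
        hi = min(_PSI_BOUNDS[1], best * 2)
        res = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
        )
        psi = float(res.x)
        converged = bool(res.success)
    df = len(r) - 1
    return TargetFit(psi, float(objective(psi)), df, converged)


def fit_baseline(summary: TetrachoricSummary):
    """Discrepancy of the zero-correlation (thresholds-only) baseline model.

    Returns ``(F_b, df_b)`` with ``F_b = sum_k r_k^2 / w_k`` and
    ``df_b = I(I-1)/2``.
    """
    r = summary.pair_correlations()
    w = _weights(summary)
    return _discrepancy(0.0, r, w), len(r)


def adjusted_chi2(
    f_min: float,
    summary: TetrachoricSummary,
    model_df: int,
    factor_variance: float | None = None,
    variant: str = "mv_adjust",
    gamma_diag: np.ndarray | None = None,
):
    """Mean-and-variance adjusted chi-square for a DWLS discrepancy.

    ``N * f_min`` is asymptotically a weighted sum of chi-square(1)
    variables with weights the eigenvalues of ``U Gamma`` (``U`` the
    residual-weighting matrix of the DWLS estimator, ``Gamma`` the
    asymptotic covariance of the sqrt(N)-scaled correlations).  The
    adjustment matches the statistic's first two moments to a chi-square
    reference and reports the model degrees of freedom:

    * ``mv_adjust`` (default): Satterthwaite scaling ``T = N F d*/tr(U G)``
      with ``d* = tr(U G)^2 / tr((U G)^2)``.
    * ``scaled_shifted``: ``T = a N F + b`` with ``a = sqrt(df / tr((UG)^2))``
      and ``b = df - a tr(U G)``, floored at zero.

    ``Gamma`` is approximated as diagonal; by default its diagonal equals
    the DWLS weights, under which both variants reduce to ``T = N F`` on
    ``model_df`` degrees of freedom.  ``factor_variance`` identifies the
    target model (``None`` means the baseline model, which has no free
    structural parameter).
    """
    if f_min < 0:
        raise ValueError("discrepancy must be non-negative")
    w = _weights(summary)
    g = w if gamma_diag is None else np.asarray(gamma_diag, dtype=float)
    k = len(w)
    # U = W^-1 - W^-1 D (D' W^-1 D)^-1 D' W^-1 with D = d sigma / d psi,
    # which for the equicorrelation model is a constant vector; with
    # diagonal Gamma the traces collapse to simple sums.
    if gamma_diag is None:
        # with Gamma's diagonal equal to the weights, U Gamma is a projection:
        # both traces equal K (baseline) or K - 1 (one structural parameter)
        trace1 = trace2 = float(k if factor_variance is None else k - 1)
    elif factor_variance is None:
        trace1 = float(np.sum(g / w))
        trace2 = float(np.sum((g / w) ** 2))
    else:
        d = 1.0 / (1.0 + factor_variance) ** 2      # common to all pairs
        c = d / w
        s = float(np.sum(d * c))
        m_diag = 1.0 / w - (c * c) / s               # diag of U
        trace1 = float(np.sum(m_diag * g))
        # (U G)^2 trace with diagonal G: sum_{kl} U_kl G_l U_lk G_k
        u_off = -np.outer(c, c) / s
        np.fill_diagonal(u_off, m_diag)
        ug = u_off * g[None, :]
        trace2 = float(np.sum(ug * ug.T))
    if trace1 <= 0 or trace2 <= 0:
        raise ArithmeticError("non-positive trace in chi-square adjustment")
    t_raw = summary.n_persons * f_min
    if variant == "mv_adjust":
        d_star = trace1 * trace1 / trace2
        chi2 = t_raw * d_star / trace1
    elif variant == "scaled_shifted":
        a = np.sqrt(model_df / trace2)
        chi2 = max(a * t_raw + (model_df - a * trace1), 0.0)
    else:
        raise ValueError(f"unknown statistic variant {variant!r}")
    return float(chi2), int(model_df)


def fit_indices(chi2_t, df_t, chi2_b, df_b, n_persons):
    """CFI, TLI and RMSEA from the target and baseline chi-squares.

    CFI is bounded in [0, 1] by construction; TLI is not truncated and may
    exceed 1 (or be NaN when the baseline chi-square equals its degrees of
    freedom); the RMSEA radicand is floored at zero, so RMSEA = 0 whenever
    ``chi2_t <= df_t``.
    """
    if df_t <= 0 or df_b <= 0:
        raise ValueError("degrees of freedom must be positive")
    if n_persons <= 1:
        raise ValueError("need more than one person")
    excess_t = chi2_t - df_t
    excess_b = chi2_b - df_b
    denom = max(excess_t, excess_b, 0.0)
    numer = max(excess_t, 0.0)
    cfi = 1.0 - numer / denom if denom > 0 else 1.0
    tli_denom = chi2_b - df_b
    tli = (
        (chi2_b - chi2_t * (df_b / df_t)) / tli_denom
        if tli_denom != 0
        else float("nan")
    )
    rmsea = float(np.sqrt(max(excess_t, 0.0) / (df_t * (n_persons - 1))))
    return float(cfi), float(tli), rmsea


def fit(summary: TetrachoricSummary, variant: str = "mv_adjust") -> WlsmvFitResult:
    """Full WLSMV pipeline: target fit, baseline fit, adjusted chi-squares
    and fit indices, assembled into a :class:`WlsmvFitResult`."""
    target = fit_rasch_cfa(summary)
    f_b, df_b = fit_baseline(summary)
    chi2_t, df_t = adjusted_chi2(
        target.f_min, summary, target.df,
        factor_variance=target.factor_variance, variant=variant,
    )
    chi2_b, df_b = adjusted_chi2(f_b, summary, df_b, variant=variant)
    cfi, tli, rmsea = fit_indices(chi2_t, df_t, chi2_b, df_b, summary.n_persons)
    return WlsmvFitResult(
        chi2_target=chi2_t,
        df_target=df_t,
        chi2_baseline=chi2_b,
        df_baseline=df_b,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        factor_variance=target.factor_variance,
        fitted_thresholds=summary.thresholds.copy(),
        converged=target.converged,
        stat_variant=variant,
    )
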