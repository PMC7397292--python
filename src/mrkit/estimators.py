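"""Causal-effect estimators for two-sample Mendelian randomization.

Given allele-aligned per-variant association pairs (beta_x, se_x) with the
exposure and (beta_y, se_y) with the outcome, each estimator returns the
causal effect of the exposure on the outcome on the log-odds scale, with a
normal-quantile 95% CI, a two-sided p-value and the odds-scale equivalents.

Methods
-------
ratio_estimate
    Single-variant Wald ratio beta_y / beta_x with a first-order (default)
    or second-order delta-method standard error.
ivw_estimate
    Inverse-variance-weighted pooling of the per-variant ratios with
    first-order weights w_j = beta_x_j^2 / se_y_j^2 — algebraically the
    weighted regression of beta_y on beta_x through the origin. Fixed
    effects by default; the multiplicative random-effects variant scales
    the SE by max(1, sqrt(Q/(J-1))).
ivw_correlated
    Generalized (GLS) version for correlated variants, using the signed LD
    matrix to build the outcome covariance. Opt-in only: it is never
    applied silently by the pipeline.
weighted_median
    Weighted median of the ratios (consistent when valid instruments carry
    at least half the weight) with a seeded parametric-bootstrap SE.
egger_regression
    MR-Egger: weighted regression of beta_y on beta_x with a free
    intercept; the intercept estimates average directional pleiotropy.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats

from .exceptions import EstimationError, ParameterError
from .types import EggerResult, HarmonizedInstrument, LDMatrix, MREstimate

__all__ = [
    "ratio_estimate",
    "ivw_estimate",
    "ivw_correlated",
    "weighted_median",
    "egger_regression",
    "to_report_row",
]


def ratio_estimate(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    delta_order: str = "first",
) -> MREstimate:
    """Single-variant Wald ratio estimate beta_y / beta_x.

    The first-order delta-method SE is se_y / |beta_x|; the second-order SE
    adds the exposure-uncertainty term:
    sqrt(se_y^2/beta_x^2 + beta_y^2 se_x^2 / beta_x^4), which is never
    smaller than the first-order SE.
    """
    if delta_order not in {"first", "second"}:
        raise ParameterError(f"delta_order must be 'first' or 'second', got {delta_order!r}")
    if beta_x == 0:
        raise EstimationError("ratio undefined: variant-exposure beta is zero")
    if se_x <= 0 or se_y <= 0:
        raise ParameterError("standard errors must be > 0")
    estimate = beta_y / beta_x
    if delta_order == "first":
        se = se_y / abs(beta_x)
    else:
        se = np.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    return MREstimate.from_normal("ratio", estimate, se, n_variants=1)


def ivw_estimate(
    instrument: HarmonizedInstrument, effects_model: str = "fixed"
) -> MREstimate:
    """Inverse-variance-weighted pooled causal estimate.

    Per-variant ratios theta_j = beta_y_j / beta_x_j are pooled with
    first-order weights w_j = beta_x_j^2 / se_y_j^2. The fixed-effects SE
    is 1/sqrt(sum w_j); the multiplicative random-effects SE inflates it by
    max(1, sqrt(Q/(J-1))) where Q is Cochran's heterogeneity statistic.
    With one variant the result equals :func:`ratio_estimate` exactly.
    """
    if effects_model not in {"fixed", "random"}:
        raise ParameterError(f"effects_model must be 'fixed' or 'random', got {effects_model!r}")
    if instrument.n_variants < 1:
        raise EstimationError("empty instrument")
    bx, by, sy = instrument.beta_x, instrument.beta_y, instrument.se_y
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        raise EstimationError(
            f"variant-exposure beta is zero for {[instrument.rsids[i] for i in zero]}"
        )
    theta = by / bx
    w = bx**2 / sy**2
    estimate = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    n = instrument.n_variants
    if effects_model == "random" and n > 1:
        q = float(np.sum(w * (theta - estimate) ** 2))
        se *= max(1.0, np.sqrt(q / (n - 1)))
    return MREstimate.from_normal("ivw", estimate, se, n_variants=n)


def ivw_correlated(
    instrument: HarmonizedInstrument, ld: LDMatrix, ridge: float = 0.0
) -> MREstimate:
    """IVW generalized for correlated variants.

    Weighted regression of beta_y on beta_x through the origin with outcome
    covariance Omega_jk = r_jk * se_y_j * se_y_k:
    estimate = (bx' Omega^-1 by) / (bx' Omega^-1 bx),
    se = 1 / sqrt(bx' Omega^-1 bx).
    With identity LD this reduces to fixed-effects :func:`ivw_estimate`.

    ``ridge`` adds ``ridge * diag(Omega)`` to stabilize a near-singular
    covariance (e.g. near-duplicate variants).
    """
    if instrument.n_variants < 1:
        raise EstimationError("empty instrument")
    if ridge < 0:
        raise ParameterError("ridge must be >= 0")
    missing = [s for s in instrument.rsids if s not in ld]
    if missing:
        raise EstimationError(f"instrument rsids absent from LD matrix: {missing}")
    bx, by, sy = instrument.beta_x, instrument.beta_y, instrument.se_y
    if np.any(bx == 0):
        raise EstimationError("variant-exposure beta is zero")
    sub = ld.submatrix(instrument.rsids)
    omega = sub.r * np.outer(sy, sy)
    if ridge:
        omega = omega + ridge * np.diag(np.diag(omega))
    try:
        cho = linalg.cho_factor(omega)
    except (np.linalg.LinAlgError, linalg.LinAlgError) as exc:
        raise EstimationError(
            "outcome covariance is singular; pass a small ridge (e.g. ridge=1e-6)"
        ) from exc
    oi_by = linalg.cho_solve(cho, by)
    oi_bx = linalg.cho_solve(cho, bx)
    denom = float(bx @ oi_bx)
    if denom <= 0:
        raise EstimationError("degenerate design: bx' Omega^-1 bx is not positive")
    estimate = float(bx @ oi_by) / denom
    se = 1.0 / np.sqrt(denom)
    return MREstimate.from_normal(
        "ivw_correlated", estimate, se, n_variants=instrument.n_variants
    )


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation at cumulative midpoint 0.5.

    Weights are normalized to sum 1; with sorted ratios theta_(1..J) and
    midpoint positions s_j = sum_{k<=j} w_k - w_j/2 the estimate is the
    linear interpolation of theta at s = 0.5 (clamped to the extremes).
    """
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, th))


def weighted_median(
    instrument: HarmonizedInstrument,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratios theta_j = beta_y_j / beta_x_j receive first-order
    inverse-variance weights beta_x_j^2 / se_y_j^2. The point estimate is
    the interpolated weighted median; the SE is the standard deviation of
    the estimate over ``n_boot`` parametric-bootstrap replicates drawing
    beta_x_j ~ N(beta_x_j, se_x_j) and beta_y_j ~ N(beta_y_j, se_y_j).

    A seed is required: the bootstrap must be reproducible.
    """
    if instrument.n_variants < 3:
        raise EstimationError(
            "weighted median requires at least 3 variants "
            f"(got {instrument.n_variants})"
        )
    if n_boot < 2:
        raise ParameterError("n_boot must be at least 2")
    if seed is None:
        raise ParameterError("a seed is required for the bootstrap")
    bx, sx = instrument.beta_x, instrument.se_x
    by, sy = instrument.beta_y, instrument.se_y
    if np.any(bx == 0):
        raise EstimationError("variant-exposure beta is zero")
    theta = by / bx
    w = bx**2 / sy**2
    estimate = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, bx.size))
    by_b = rng.normal(by, sy, size=(n_boot, by.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_b = by_b / bx_b
        w_b = bx_b**2 / sy**2
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median_point(theta_b[i], w_b[i])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        # degenerate but possible for constant ratios; keep the CI honest
        se = np.finfo(float).tiny
    return MREstimate.from_normal(
        "weighted_median", estimate, se, n_variants=instrument.n_variants
    )


def egger_regression(
    instrument: HarmonizedInstrument, pvalue_reference: str = "normal"
) -> EggerResult:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Each pair is oriented so beta_x >= 0 (both signs flipped where needed),
    then beta_y is regressed on beta_x with intercept and weights
    1/se_y^2. The slope is the causal estimate; the intercept estimates the
    average directional pleiotropic effect per variant. Standard errors are
    scaled by the multiplicative overdispersion factor
    max(1, sqrt(RSS_w/(J-2))). Two-sided p-values use the standard normal
    by default (``pvalue_reference="t"`` uses a t with J-2 df).
    """
    if pvalue_reference not in {"normal", "t"}:
        raise ParameterError(
            f"pvalue_reference must be 'normal' or 't', got {pvalue_reference!r}"
        )
    n = instrument.n_variants
    if n < 3:
        raise EstimationError(f"MR-Egger requires at least 3 variants (got {n})")
    sign = np.where(instrument.beta_x < 0, -1.0, 1.0)
    bx = instrument.beta_x * sign
    by = instrument.beta_y * sign
    sy = instrument.se_y
    if np.allclose(bx, bx[0]):
        raise EstimationError(
            "degenerate design: all variant-exposure betas equal after orientation"
        )
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (n - 2))
    cov = np.linalg.inv(xtwx) * phi
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    if pvalue_reference == "t":
        ref = lambda z: 2.0 * stats.t.sf(abs(z), df=n - 2)  # noqa: E731
    else:
        ref = lambda z: 2.0 * stats.norm.sf(abs(z))  # noqa: E731
    p_slope = max(float(ref(slope / se_slope)), np.nextafter(0.0, 1.0))
    p_int = max(float(ref(intercept / se_int)), np.nextafter(0.0, 1.0))
    slope_est = MREstimate.from_normal(
        "egger_slope", slope, se_slope, n_variants=n, pvalue=p_slope
    )
    return EggerResult(
        slope=slope_est,
        intercept_estimate=intercept,
        intercept_se=se_int,
        intercept_pvalue=p_int,
    )


def _format_p(p: float, decimals: int = 3) -> str:
    """Render a p-value at fixed precision with a '<' floor below it."""
    floor = 10.0 ** (-decimals)
    if round(p, decimals) < floor:
        return f"<{floor:.{decimals}f}"
    return f"{p:.{decimals}f}"


def to_report_row(est, outcome_label: str, locus_label: str) -> dict:
    """Format an estimate as a display row (odds ratio, estimate (se), p).

    Accepts an :class:`MREstimate` or an :class:`EggerResult` (whose slope
    is reported, with the intercept carried in extra columns). ORs,
    estimates and SEs are rendered to 3 decimals; p-values to 3 decimals
    with a ``<0.001`` floor. ``significant`` flags two-sided p < 0.05.
    """
    egger_cols = {"egger_intercept": "", "egger_intercept_pvalue": ""}
    if isinstance(est, EggerResult):
        egger_cols = {
            "egger_intercept": f"{est.intercept_estimate:.3f}",
            "egger_intercept_pvalue": _format_p(est.intercept_pvalue),
        }
        est = est.slope
    if not isinstance(est, MREstimate):
        raise ParameterError(f"cannot format {type(est).__name__}")
    return {
        "locus": locus_label,
        "outcome": outcome_label,
        "method": est.method,
        "n_variants": est.n_variants,
        "odds_ratio": f"{est.odds_ratio:.3f}",
        "or_95ci": f"({est.or_ci_low:.3f}, {est.or_ci_high:.3f})",
        "estimate_se": f"{est.estimate:.3f} ({est.se:.3f})",
        "ci_95": f"({est.ci_low:.3f}, {est.ci_high:.3f})",
        "pvalue": _format_p(est.pvalue),
        "significant": est.pvalue < 0.05,
        **egger_cols,
    }
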