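"""Causal estimators: ratio, IVW, correlated IVW, weighted median, MR-Egger."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrkit.estimators import (
    _weighted_median_point,
    egger_regression,
    ivw_correlated,
    ivw_estimate,
    ratio_estimate,
    to_report_row,
    weighted_median,
)
from mrkit.exceptions import EstimationError, ParameterError
from mrkit.types import LDMatrix

from conftest import make_instrument, random_instrument


# ------------------------------------------------------------------------- ratio


def test_ratio_reproduces_published_single_variant_example():
    """rs10822184 (-0.058, 0.01) against the derived gout outcome stand-in."""
    est = ratio_estimate(-0.058, 0.01, 0.0439, 0.0128)
    assert round(est.estimate, 3) == -0.757
    assert round(est.se, 3) == 0.221
    assert round(est.odds_ratio, 3) == 0.469
    assert round(est.pvalue, 3) == 0.001
    assert round(est.ci_low, 3) == -1.189 and round(est.ci_high, 3) == -0.324


def test_ratio_identity_and_errors():
    est = ratio_estimate(0.5, 0.05, 0.5, 0.1)
    assert est.estimate == 1.0 and est.se == pytest.approx(0.2)
    with pytest.raises(EstimationError):
        ratio_estimate(0.0, 0.01, 0.1, 0.01)
    with pytest.raises(ParameterError):
        ratio_estimate(0.1, 0.01, 0.1, 0.01, delta_order="third")


def test_second_order_se_never_below_first_order(rng):
    bx = rng.uniform(-1, 1, 1000)
    bx = np.where(np.abs(bx) < 1e-3, 0.1, bx)
    sx, sy = rng.uniform(1e-3, 0.5, (2, 1000))
    by = rng.normal(0, 0.5, 1000)
    for i in range(1000):
        first = ratio_estimate(bx[i], sx[i], by[i], sy[i], "first")
        second = ratio_estimate(bx[i], sx[i], by[i], sy[i], "second")
        assert second.se >= first.se
        assert second.estimate == first.estimate


# --------------------------------------------------------------------------- IVW


def test_ivw_single_variant_equals_ratio():
    inst = make_instrument([-0.058], [0.01], [0.0439], [0.0128])
    ivw = ivw_estimate(inst)
    ratio = ratio_estimate(-0.058, 0.01, 0.0439, 0.0128)
    assert ivw.estimate == ratio.estimate
    assert ivw.se == ratio.se
    assert ivw.pvalue == ratio.pvalue


def test_ivw_two_identical_variants_pool_with_root2_se():
    one = make_instrument([0.1], [0.01], [0.03], [0.02])
    two = make_instrument([0.1, 0.1], [0.01] * 2, [0.03] * 2, [0.02] * 2)
    e1, e2 = ivw_estimate(one), ivw_estimate(two)
    assert e2.estimate == pytest.approx(e1.estimate)
    assert e2.se == pytest.approx(e1.se / np.sqrt(2))


def test_ivw_pooling_equals_regression_through_origin(rng):
    """The two algebraic forms of IVW agree to 1e-10."""
    for _ in range(1000):
        inst = random_instrument(rng, n=int(rng.integers(2, 15)))
        est = ivw_estimate(inst)
        w = 1.0 / inst.se_y**2
        slope = np.sum(w * inst.beta_x * inst.beta_y) / np.sum(w * inst.beta_x**2)
        se = 1.0 / np.sqrt(np.sum(w * inst.beta_x**2))
        assert abs(est.estimate - slope) < 1e-10
        assert abs(est.se - se) < 1e-10


def test_ivw_matches_statsmodels_wls_through_origin(rng):
    inst = random_instrument(rng, n=12)
    fit = sm.WLS(inst.beta_y, inst.beta_x, weights=1.0 / inst.se_y**2).fit()
    est = ivw_estimate(inst)
    assert est.estimate == pytest.approx(float(fit.params[0]), abs=1e-12)
    # fixed-effects SE: statsmodels' bse carries the estimated scale
    fisher_se = float(fit.bse[0]) / np.sqrt(fit.scale)
    assert est.se == pytest.approx(fisher_se, rel=1e-10)


def test_ivw_random_effects_inflates_only_under_heterogeneity():
    homogeneous = make_instrument([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2)
    assert ivw_estimate(homogeneous, "random").se == ivw_estimate(homogeneous, "fixed").se
    heterogeneous = make_instrument([0.1, 0.2], [0.01] * 2, [0.05, -0.02], [0.01] * 2)
    assert (
        ivw_estimate(heterogeneous, "random").se
        > ivw_estimate(heterogeneous, "fixed").se
    )
    assert ivw_estimate(heterogeneous, "random").estimate == pytest.approx(
        ivw_estimate(heterogeneous, "fixed").estimate
    )


def test_ivw_errors():
    inst = make_instrument([0.0, 0.1], [0.01] * 2, [0.02] * 2, [0.01] * 2)
    with pytest.raises(EstimationError, match="rs1"):
        ivw_estimate(inst)
    with pytest.raises(ParameterError):
        ivw_estimate(make_instrument([0.1], [0.01], [0.02], [0.01]), "bayes")


# --------------------------------------------------------------- correlated IVW


def test_correlated_ivw_with_identity_ld_equals_fixed_ivw(rng):
    inst = random_instrument(rng, n=8)
    ld = LDMatrix.identity(inst.rsids)
    a, b = ivw_correlated(inst, ld), ivw_estimate(inst)
    assert abs(a.estimate - b.estimate) < 1e-10
    assert abs(a.se - b.se) < 1e-10


def test_correlated_ivw_matches_brute_force_gls(rng):
    inst = random_instrument(rng, n=5)
    a = rng.normal(size=(5, 8))
    r = np.corrcoef(a)
    ld = LDMatrix(rsids=inst.rsids, r=r)
    est = ivw_correlated(inst, ld)
    omega = r * np.outer(inst.se_y, inst.se_y)
    oi = np.linalg.inv(omega)
    bx, by = inst.beta_x, inst.beta_y
    assert est.estimate == pytest.approx((bx @ oi @ by) / (bx @ oi @ bx), abs=1e-10)
    assert est.se == pytest.approx(1.0 / np.sqrt(bx @ oi @ bx), abs=1e-10)


def test_duplicate_variants_do_not_fake_precision():
    """Two copies of one variant in near-perfect LD give the single-variant
    SE, not SE/sqrt(2)."""
    single = make_instrument([0.1], [0.01], [0.03], [0.02])
    double = make_instrument([0.1, 0.1], [0.01] * 2, [0.03] * 2, [0.02] * 2)
    r = np.array([[1.0, 1.0 - 1e-9], [1.0 - 1e-9, 1.0]])
    ld = LDMatrix(rsids=double.rsids, r=r)
    est = ivw_correlated(double, ld, ridge=1e-8)
    se_single = ivw_estimate(single).se
    assert est.se == pytest.approx(se_single, rel=1e-3)
    assert est.se > se_single / np.sqrt(2) * 1.3


def test_singular_covariance_suggests_ridge():
    double = make_instrument([0.1, 0.1], [0.01] * 2, [0.03] * 2, [0.02] * 2)
    r = np.array([[1.0, 1.0], [1.0, 1.0]])
    ld = LDMatrix(rsids=double.rsids, r=r)
    with pytest.raises(EstimationError, match="ridge"):
        ivw_correlated(double, ld)
    est = ivw_correlated(double, ld, ridge=1e-6)
    assert np.isfinite(est.estimate)


def test_correlated_ivw_requires_ld_coverage(rng):
    inst = random_instrument(rng, n=3)
    ld = LDMatrix.identity(["rs1", "rs2"])
    with pytest.raises(EstimationError, match="rs3"):
        ivw_correlated(inst, ld)


# ----------------------------------------------------------------- weighted median


def brute_force_weighted_quantile(theta, weights, q):
    """Independent piecewise-linear weighted-quantile oracle."""
    order = sorted(range(len(theta)), key=lambda i: theta[i])
    th = [theta[i] for i in order]
    w = [weights[i] / sum(weights) for i in order]
    xs, acc = [], 0.0
    for wi in w:
        xs.append(acc + wi / 2.0)
        acc += wi
    if q <= xs[0]:
        return th[0]
    if q >= xs[-1]:
        return th[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= q <= xs[i + 1]:
            frac = (q - xs[i]) / (xs[i + 1] - xs[i])
            return th[i] + frac * (th[i + 1] - th[i])


def test_weighted_median_constant_ratios_returns_the_constant():
    inst = make_instrument([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12], [0.01, 0.02, 0.03])
    est = weighted_median(inst, n_boot=50, seed=1)
    assert est.estimate == pytest.approx(0.3)


def test_weighted_median_equal_weight_three_ratios():
    # ratios (0.1, 0.2, 0.9) with equal weights -> 0.2
    inst = make_instrument([0.1, 0.1, 0.1], [0.01] * 3, [0.01, 0.02, 0.09], [0.01] * 3)
    est = weighted_median(inst, n_boot=50, seed=1)
    assert est.estimate == pytest.approx(0.2)
    assert brute_force_weighted_quantile([0.1, 0.2, 0.9], [1, 1, 1], 0.5) == pytest.approx(0.2)


def test_weighted_median_point_matches_brute_force_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(3, 12))
        theta = rng.normal(0, 1, n)
        w = rng.uniform(0.1, 5, n)
        assert _weighted_median_point(theta, w) == pytest.approx(
            brute_force_weighted_quantile(list(theta), list(w), 0.5), abs=1e-12
        )


def test_weighted_median_within_ratio_range(rng):
    for _ in range(50):
        inst = random_instrument(rng, n=int(rng.integers(3, 10)))
        theta = inst.beta_y / inst.beta_x
        est = weighted_median(inst, n_boot=20, seed=7)
        assert theta.min() - 1e-12 <= est.estimate <= theta.max() + 1e-12


def test_weighted_median_bootstrap_is_seeded(rng):
    inst = random_instrument(rng, n=6)
    a = weighted_median(inst, n_boot=100, seed=11)
    b = weighted_median(inst, n_boot=100, seed=11)
    c = weighted_median(inst, n_boot=100, seed=12)
    assert a == b
    assert a.se != c.se


def test_weighted_median_errors(rng):
    small = random_instrument(rng, n=2)
    with pytest.raises(EstimationError):
        weighted_median(small, n_boot=10, seed=1)
    inst = random_instrument(rng, n=4)
    with pytest.raises(ParameterError):
        weighted_median(inst, n_boot=1, seed=1)
    with pytest.raises(ParameterError):
        weighted_median(inst, n_boot=10, seed=None)


# ----------------------------------------------------------------------- MR-Egger


def test_egger_exact_fit_recovers_line():
    bx = np.array([0.1, 0.2, 0.3])
    by = 0.5 * bx + 0.1
    inst = make_instrument(bx, [0.01] * 3, by, [0.02] * 3)
    res = egger_regression(inst)
    assert res.slope.estimate == pytest.approx(0.5, abs=1e-12)
    assert res.intercept_estimate == pytest.approx(0.1, abs=1e-12)


def test_egger_orients_exposure_betas_positive():
    bx = np.array([0.1, -0.2, 0.3])
    by = 0.5 * bx + 0.1 * np.sign(bx)  # same line after orientation
    inst = make_instrument(bx, [0.01] * 3, by, [0.02] * 3)
    res = egger_regression(inst)
    assert res.slope.estimate == pytest.approx(0.5, abs=1e-12)
    assert res.intercept_estimate == pytest.approx(0.1, abs=1e-12)


def test_egger_matches_statsmodels_wls(rng):
    inst = random_instrument(rng, n=10)
    sign = np.where(inst.beta_x < 0, -1.0, 1.0)
    bx, by = inst.beta_x * sign, inst.beta_y * sign
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / inst.se_y**2).fit()
    res = egger_regression(inst)
    assert res.intercept_estimate == pytest.approx(float(fit.params[0]), abs=1e-12)
    assert res.slope.estimate == pytest.approx(float(fit.params[1]), abs=1e-12)
    if fit.scale >= 1.0:  # overdispersed: our SE equals the WLS SE
        assert res.slope.se == pytest.approx(float(fit.bse[1]), rel=1e-10)
        assert res.intercept_se == pytest.approx(float(fit.bse[0]), rel=1e-10)
    else:  # underdispersed: we keep the Fisher SE (scale floored at 1)
        assert res.slope.se == pytest.approx(float(fit.bse[1]) / np.sqrt(fit.scale), rel=1e-10)


def test_egger_t_reference_gives_larger_p(rng):
    inst = random_instrument(rng, n=5)
    normal = egger_regression(inst, pvalue_reference="normal")
    t_ref = egger_regression(inst, pvalue_reference="t")
    assert t_ref.slope.pvalue > normal.slope.pvalue
    assert t_ref.slope.estimate == normal.slope.estimate


def test_egger_errors(rng):
    with pytest.raises(EstimationError):
        egger_regression(random_instrument(rng, n=2))
    degenerate = make_instrument([0.1, 0.1, -0.1], [0.01] * 3, [0.02, 0.03, 0.01], [0.01] * 3)
    with pytest.raises(EstimationError, match="degenerate"):
        egger_regression(degenerate)
    with pytest.raises(ParameterError):
        egger_regression(random_instrument(rng, n=5), pvalue_reference="chi2")


# -------------------------------------------------------- shared properties, report


def test_global_sign_symmetry(rng):
    """Negating every beta_y flips every estimate and preserves SE and p."""
    inst = random_instrument(rng, n=8)
    neg = make_instrument(inst.beta_x, inst.se_x, -inst.beta_y, inst.se_y)
    for fn in (
        lambda i: ivw_estimate(i),
        lambda i: ivw_estimate(i, "random"),
        lambda i: ivw_correlated(i, LDMatrix.identity(i.rsids)),
        lambda i: egger_regression(i).slope,
    ):
        a, b = fn(inst), fn(neg)
        assert b.estimate == pytest.approx(-a.estimate, abs=1e-14)
        assert b.se == pytest.approx(a.se, abs=1e-14)
        assert b.pvalue == pytest.approx(a.pvalue, rel=1e-10)
    r = ratio_estimate(0.2, 0.01, 0.06, 0.02)
    rn = ratio_estimate(0.2, 0.01, -0.06, 0.02)
    assert (rn.estimate, rn.se, rn.pvalue) == (-r.estimate, r.se, r.pvalue)
    # weighted median: the point estimate flips exactly; the bootstrap SE is
    # only distributionally invariant, so compare it statistically
    wm, wmn = (weighted_median(i, n_boot=400, seed=5) for i in (inst, neg))
    assert wmn.estimate == pytest.approx(-wm.estimate, abs=1e-14)
    assert wmn.se == pytest.approx(wm.se, rel=0.25)


def test_report_row_formatting():
    row = to_report_row(ratio_estimate(-0.058, 0.01, 0.0439, 0.0128), "gout", "JMJD1C")
    assert row["odds_ratio"] == "0.469"
    assert row["estimate_se"] == "-0.757 (0.221)"
    assert row["pvalue"] == "0.001"
    assert row["significant"] is True

    null = to_report_row(ratio_estimate(0.1, 0.01, 0.0, 0.05), "x", "L")
    assert null["odds_ratio"] == "1.000"
    assert null["significant"] is False

    from mrkit.types import MREstimate

    strong = to_report_row(MREstimate.from_normal("ivw", 0.285, 0.060, 20), "ra", "SHBG")
    assert strong["pvalue"] == "<0.001"

    inst = make_instrument([0.1, 0.2, 0.3], [0.01] * 3, [0.06, 0.11, 0.14], [0.02] * 3)
    egger_row = to_report_row(egger_regression(inst), "ra", "SHBG")
    assert egger_row["method"] == "egger_slope"
    assert egger_row["egger_intercept"] != ""
    with pytest.raises(ParameterError):
        to_report_row("not an estimate", "x", "L")
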