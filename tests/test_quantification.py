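"""Lead-curve fitting, inverse prediction and assay-level quantification."""

import math

import numpy as np
import pytest

from leadassay import kinetics
from leadassay.kinetics import GrowthFit, ROLE_LEAD_CURVE, ROLE_UNKNOWN
from leadassay.quantification import (
    LeadCurveFit,
    QuantificationError,
    SLOPE_FLOOR,
    apply_dilution,
    fit_lead_curve,
    interpolate_lead,
    quantify_assay,
)
from leadassay.synthetic import SyntheticAssaySpec, generate_timelapse


def line_points(slope=0.2, intercept=1.0, ppb=(0, 10, 20, 50, 100), sigma=0.3):
    return [(x, slope * x + intercept, sigma) for x in ppb]


# ---------------------------------------------------------------------------
# Lead-curve fit
# ---------------------------------------------------------------------------


def test_exact_line_recovered():
    fit = fit_lead_curve(line_points())
    assert fit.slope == pytest.approx(0.2, rel=1e-12)
    assert fit.intercept == pytest.approx(1.0, rel=1e-12)
    assert fit.chi2_red == pytest.approx(0.0, abs=1e-20)


def test_two_points_exact():
    fit = fit_lead_curve([(0, 2.0, 0.1), (100, 22.0, 0.1)])
    assert fit.slope == pytest.approx(0.2)
    assert fit.intercept == pytest.approx(2.0)


def test_weighted_fit_matches_normal_equation_oracle(rng):
    x = np.array([0.0, 10.0, 20.0, 50.0, 100.0])
    y = 0.2 * x + 1 + rng.normal(0, 0.5, x.size)
    s = rng.uniform(0.2, 0.8, x.size)
    fit = fit_lead_curve(list(zip(x, y, s)))
    # independent weighted-least-squares oracle
    W = np.diag(1 / s**2)
    A = np.stack([x, np.ones_like(x)], axis=1)
    cov = np.linalg.inv(A.T @ W @ A)
    beta = cov @ A.T @ W @ y
    assert fit.slope == pytest.approx(beta[0], abs=1e-10)
    assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
    np.testing.assert_allclose(fit.covariance, cov, atol=1e-12)


def test_unweighted_covariance_scaled_by_residuals(rng):
    x = np.array([0.0, 10.0, 20.0, 50.0, 100.0])
    y = 0.2 * x + 1 + rng.normal(0, 0.5, x.size)
    fit = fit_lead_curve([(xi, yi, 0.0) for xi, yi in zip(x, y)])
    A = np.stack([x, np.ones_like(x)], axis=1)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid_var = ((y - A @ beta) ** 2).sum() / (x.size - 2)
    expected = np.linalg.inv(A.T @ A) * resid_var
    np.testing.assert_allclose(fit.covariance, expected, rtol=1e-10)


def test_degenerate_inputs_rejected():
    with pytest.raises(QuantificationError):
        fit_lead_curve([(0, 2.0, 0.1)])
    with pytest.raises(QuantificationError):
        fit_lead_curve([(10, 2.0, 0.1), (10, 3.0, 0.1)])


# ---------------------------------------------------------------------------
# Inverse prediction
# ---------------------------------------------------------------------------


def _curve(slope=0.2, intercept=1.0, cov=None):
    return LeadCurveFit(slope=slope, intercept=intercept,
                        covariance=np.zeros((2, 2)) if cov is None else cov,
                        points=[])


def test_inversion_hand_value():
    # y = 10, b = 2, a = 0.4 -> x = 20
    res = interpolate_lead(10.0, 0.0, _curve(slope=0.4, intercept=2.0))
    assert res.concentration == pytest.approx(20.0)
    assert not res.clamped and not res.above_validated_range


def test_intercept_measurement_maps_to_zero():
    res = interpolate_lead(1.0, 0.0, _curve())
    assert res.concentration == pytest.approx(0.0, abs=1e-12)


def test_forward_inverse_round_trip():
    curve = _curve()
    for ppb in (0.0, 7.3, 50.0, 99.0):
        res = interpolate_lead(float(curve.predict(ppb)), 0.0, curve)
        assert res.concentration == pytest.approx(ppb, abs=1e-10)


def test_measurement_sigma_only_propagates_as_sigma_over_slope():
    res = interpolate_lead(10.0, 0.5, _curve(slope=0.25))
    assert res.sigma == pytest.approx(0.5 / 0.25)


def test_inverse_sigma_against_monte_carlo(rng):
    sds = np.array([0.004, 0.12])
    corr = np.array([[1.0, -0.6], [-0.6, 1.0]])
    cov = corr * np.outer(sds, sds)
    y0, sig_y = 12.0, 0.3
    res = interpolate_lead(y0, sig_y, _curve(cov=cov))

    n = 200_000
    ab = rng.multivariate_normal([0.2, 1.0], cov, size=n)
    ys = y0 + sig_y * rng.standard_normal(n)
    xs = (ys - ab[:, 1]) / ab[:, 0]
    mc = xs.std(ddof=1)
    assert abs(res.sigma - mc) < 3 * mc / math.sqrt(2 * (n - 1))


def test_negative_clamps_to_zero_sigma_preserved():
    cov = np.diag([1e-4, 0.04])
    res = interpolate_lead(0.2, 0.3, _curve(cov=cov))  # raw x = -4
    assert res.concentration == 0.0
    assert res.clamped
    assert res.raw_concentration == pytest.approx(-4.0)
    unclamped = interpolate_lead(1.8, 0.3, _curve(cov=cov))  # raw x = +4
    assert res.sigma == pytest.approx(unclamped.sigma, rel=0.05)
    assert res.sigma > 0


def test_above_validated_range_flagged():
    res = interpolate_lead(0.2 * 140 + 1.0, 0.1, _curve())
    assert res.above_validated_range
    assert res.concentration == pytest.approx(140.0)


def test_slope_floor_raises():
    with pytest.raises(QuantificationError, match="flat"):
        interpolate_lead(5.0, 0.1, _curve(slope=0.5 * SLOPE_FLOOR))


def test_inversion_monotone_in_saturation():
    curve = _curve()
    xs = [interpolate_lead(y, 0.1, curve).concentration
          for y in np.linspace(1.5, 21.0, 40)]
    assert (np.diff(xs) > 0).all()


def test_dilution_scales_value_and_sigma():
    base = interpolate_lead(0.2 * 66 + 1.0, 0.0, _curve())
    res = apply_dilution(
        interpolate_lead(0.2 * 66 + 1.0, 3.0, _curve()), 4.0)
    assert base.concentration == pytest.approx(66.0)
    assert res.concentration == pytest.approx(264.0)
    assert res.sigma == pytest.approx(60.0)
    assert res.dilution_factor == 4.0
    assert res.above_validated_range
    with pytest.raises(QuantificationError):
        apply_dilution(base, 0.5)


# ---------------------------------------------------------------------------
# Assay-level orchestration
# ---------------------------------------------------------------------------


def _growth_fit(final, sigma=0.3, b=480.0):
    cov = np.zeros((3, 3))
    cov[0, 0] = sigma**2  # a-variance dominates far past the half-rise
    return GrowthFit(a=final, b=b, c=0.012, covariance=cov, chi2_red=1.0,
                     t_end=1e6, final_saturation=final, final_sigma=sigma)


def _assay(slope=0.2, intercept=3.0, unknown_ppb=30.0, **kw):
    ppb = {"L0": 0.0, "L10": 10.0, "L50": 50.0, "L100": 100.0}
    fits = {lbl: _growth_fit(slope * p + intercept, **kw)
            for lbl, p in ppb.items()}
    fits["U1"] = _growth_fit(slope * unknown_ppb + intercept)
    roles = {lbl: ROLE_LEAD_CURVE for lbl in ppb}
    roles["U1"] = ROLE_UNKNOWN
    return fits, roles, ppb


def test_quantify_assay_exact_line():
    fits, roles, ppb = _assay()
    results, curve, qc = quantify_assay(fits, roles, ppb)
    assert qc.assay_status == kinetics.ASSAY_VALID
    assert curve.slope == pytest.approx(0.2, rel=1e-6)
    assert results["U1"].concentration == pytest.approx(30.0, abs=1e-6)


def test_dropped_top_point_excluded_without_biasing_others():
    fits, roles, ppb = _assay()
    # inhibit the 100 ppb well below the 50 ppb one
    fits["L100"] = _growth_fit(fits["L50"].final_saturation - 2.0)
    results, curve, qc = quantify_assay(fits, roles, ppb)
    assert qc.wells["L100"].status == kinetics.STATUS_DROPPED_TOP
    assert [p[0] for p in curve.points] == [0.0, 10.0, 50.0]
    assert curve.dropped and curve.dropped[0][0] == 100.0
    # the remaining points still sit on the exact line
    assert results["U1"].concentration == pytest.approx(30.0, abs=1e-6)


def test_disqualified_assay_returns_no_results():
    fits, roles, ppb = _assay()
    fits["L0"] = _growth_fit(1.0, b=1400.0)
    fits["L10"] = _growth_fit(3.0, b=1400.0)
    results, curve, qc = quantify_assay(fits, roles, ppb)
    assert qc.assay_status == kinetics.ASSAY_DISQUALIFIED
    assert results == {} and curve is None


def test_failed_unknown_reported_as_nan_with_status():
    fits, roles, ppb = _assay()
    fits["U1"] = _growth_fit(2.0, b=1400.0)
    results, _, _ = quantify_assay(fits, roles, ppb)
    assert math.isnan(results["U1"].concentration)
    assert results["U1"].qc_status == kinetics.STATUS_FAILED_GROWTH


def test_dilution_factor_applied_per_sample():
    fits, roles, ppb = _assay(unknown_ppb=40.0)
    results, _, _ = quantify_assay(fits, roles, ppb,
                                   dilution_factors={"U1": 5.0})
    assert results["U1"].concentration == pytest.approx(200.0, abs=1e-5)
    assert results["U1"].above_validated_range


def test_quantify_synthetic_series_within_2_sigma():
    """Full series -> fit -> curve -> inversion recovers the truth."""
    spec = SyntheticAssaySpec(seed=77)
    fits, roles, ppb, truth_ppb = {}, {}, {}, {}
    for w in spec.wells():
        series, truth = generate_timelapse(spec, w)
        fits[w.label] = kinetics.fit_timelapse(series)
        roles[w.label] = w.role
        if w.role == ROLE_LEAD_CURVE:
            ppb[w.label] = w.ppb
        else:
            truth_ppb[w.label] = w.ppb
    results, curve, qc = quantify_assay(fits, roles, ppb)
    assert qc.assay_status == kinetics.ASSAY_VALID
    assert curve.slope > SLOPE_FLOOR
    n_in = sum(
        abs(res.concentration - truth_ppb[lbl]) <= 2 * res.sigma
        or (res.clamped and truth_ppb[lbl] == 0.0)
        for lbl, res in results.items()
    )
    assert n_in >= len(results) - 1  # allow one 2-sigma outlier in 11


def test_zero_ppb_unknown_consistent_with_zero():
    spec = SyntheticAssaySpec(seed=78)
    zero_wells = [w for w in spec.wells()
                  if w.role == ROLE_UNKNOWN and w.ppb == 0.0]
    assert zero_wells
    fits, roles, ppb = {}, {}, {}
    for w in spec.wells():
        series, _ = generate_timelapse(spec, w)
        fits[w.label] = kinetics.fit_timelapse(series)
        roles[w.label] = w.role
        if w.role == ROLE_LEAD_CURVE:
            ppb[w.label] = w.ppb
    results, _, _ = quantify_assay(fits, roles, ppb)
    res = results[zero_wells[0].label]
    assert res.concentration <= 2 * res.sigma
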