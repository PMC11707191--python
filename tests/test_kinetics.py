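"""Double-sigmoid kinetics: model identities, fitting, uncertainty, QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leadassay import kinetics
from leadassay.calibration import TimelapsePoint
from leadassay.kinetics import (
    ASSAY_DISQUALIFIED,
    ASSAY_VALID,
    GrowthFit,
    KineticsError,
    ROLE_LEAD_CURVE,
    ROLE_UNKNOWN,
    STATUS_DROPPED_TOP,
    STATUS_FAILED_GROWTH,
    STATUS_PASS,
    apply_qc_cuts,
    error_band,
    eval_growth_model,
    final_saturation,
    fit_timelapse,
    growth_model_gradient,
)

TRUE = (22.0, 480.0, 0.012)
TS = np.linspace(0, 1020, 25)


def series(sats, sigmas, ts=TS):
    return [TimelapsePoint(float(t), float(s), float(e))
            for t, s, e in zip(ts, sats, np.broadcast_to(sigmas, ts.shape))]


# ---------------------------------------------------------------------------
# Model identities
# ---------------------------------------------------------------------------


@given(a=st.floats(0.1, 100), b=st.floats(0, 2000), c=st.floats(1e-4, 0.5))
@settings(max_examples=200, deadline=None)
def test_half_amplitude_at_half_rise_time(a, b, c):
    assert eval_growth_model(b, a, b, c) == pytest.approx(a / 2, rel=1e-12)


def test_limit_is_amplitude():
    assert eval_growth_model(1e7, 20.0, 400.0, 0.01) == pytest.approx(20.0)


def test_hand_evaluated_point():
    # exponent 400 * 0.01/2 = 2 at t = 0
    assert eval_growth_model(0.0, 20.0, 400.0, 0.01) == pytest.approx(
        20.0 / (1 + math.e**2), abs=5e-5)
    assert eval_growth_model(0.0, 20.0, 400.0, 0.01) == pytest.approx(2.3840, abs=5e-4)


@given(a=st.floats(0.1, 100), b=st.floats(0, 2000), c=st.floats(1e-4, 0.5))
@settings(max_examples=200, deadline=None)
def test_monotone_nondecreasing_once_gate_saturated(a, b, c):
    # The inner growth gate saturates within ~10 time constants (tau = 1 min);
    # past that the curve is a plain rising sigmoid.
    t = np.linspace(20, 2000, 400)
    y = eval_growth_model(t, a, b, c)
    assert (np.diff(y) >= -1e-9).all()


def test_overflow_safe_at_extreme_arguments():
    y = eval_growth_model(np.array([0.0, 1e6]), 100.0, 10000.0, 1.0)
    assert np.isfinite(y).all()


def test_gradient_matches_finite_differences():
    t = np.array([0.0, 200.0, 480.0, 1020.0])
    a, b, c = TRUE
    got = np.stack(growth_model_gradient(t, a, b, c), axis=1)
    eps = 1e-6
    for j, dp in enumerate(np.eye(3) * [a * eps, b * eps, max(c * eps, 1e-9)]):
        hi = eval_growth_model(t, a + dp[0], b + dp[1], c + dp[2])
        lo = eval_growth_model(t, a - dp[0], b - dp[1], c - dp[2])
        num = (hi - lo) / (2 * dp[j])
        np.testing.assert_allclose(got[:, j], num, rtol=1e-5, atol=1e-8)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def test_noiseless_self_consistency():
    fit = fit_timelapse(series(eval_growth_model(TS, *TRUE), 0.1))
    assert fit.a == pytest.approx(TRUE[0], rel=1e-6)
    assert fit.b == pytest.approx(TRUE[1], rel=1e-6)
    assert fit.c == pytest.approx(TRUE[2], rel=1e-6)
    assert fit.chi2_red == pytest.approx(0.0, abs=1e-10)


def test_fit_deterministic():
    rng = np.random.default_rng(5)
    sats = eval_growth_model(TS, *TRUE) + rng.normal(0, 0.4, TS.size)
    f1 = fit_timelapse(series(sats, 0.4))
    f2 = fit_timelapse(series(sats, 0.4))
    assert (f1.a, f1.b, f1.c) == (f2.a, f2.b, f2.c)


def test_all_zero_sigma_warns_and_fits():
    with pytest.warns(UserWarning, match="unweighted"):
        fit = fit_timelapse(series(eval_growth_model(TS, *TRUE), 0.0))
    assert fit.a == pytest.approx(TRUE[0], rel=1e-4)


def test_too_few_points_rejected():
    with pytest.raises(KineticsError):
        fit_timelapse(series(np.zeros(4), 0.1, ts=TS[:4]))


def test_flat_series_pushes_half_rise_beyond_window(rng):
    """No-growth wells end with b beyond the observation window (QC fodder)."""
    truth_b = 1400.0
    sats = eval_growth_model(TS, 20.0, truth_b, 0.012) + rng.normal(0, 0.4, TS.size)
    fit = fit_timelapse(series(sats, 0.4))
    assert fit.b > 1000.0


def test_monte_carlo_fit_calibration(rng):
    """500 noisy replicates: chi2_red ~ 1, amplitude unbiased and covered."""
    clean = eval_growth_model(TS, *TRUE)
    chi2, a_hat, b_hat, covered = [], [], [], 0
    n_rep = 500
    for _ in range(n_rep):
        sats = clean + rng.normal(0, 0.4, TS.size)
        fit = fit_timelapse(series(sats, 0.4))
        chi2.append(fit.chi2_red)
        a_hat.append(fit.a)
        b_hat.append(fit.b)
        if abs(fit.a - TRUE[0]) <= 2 * fit.sigma_a:
            covered += 1
    assert 0.8 <= np.mean(chi2) <= 1.2
    assert abs(np.mean(a_hat) - TRUE[0]) / TRUE[0] < 0.02
    assert abs(np.mean(b_hat) - TRUE[1]) < 10.0
    assert covered / n_rep >= 0.93


# ---------------------------------------------------------------------------
# Final saturation and error band
# ---------------------------------------------------------------------------


def _fit_with_cov(cov, t_end=1020.0, baseline_sigma=0.0):
    a, b, c = TRUE
    y, s = kinetics._final_saturation_at(a, b, c, cov, t_end, 1.0, baseline_sigma)
    return GrowthFit(a=a, b=b, c=c, covariance=np.asarray(cov, float),
                     chi2_red=1.0, t_end=t_end, final_saturation=y,
                     final_sigma=s, baseline_sigma=baseline_sigma)


def test_diagonal_covariance_reduces_to_quadrature():
    cov = np.diag([0.16, 25.0, 1e-6])
    fit = _fit_with_cov(cov)
    g = np.array(growth_model_gradient(1020.0, *TRUE))
    expected = math.sqrt(float(g**2 @ np.diag(cov)))
    _, got = final_saturation(fit)
    assert got == pytest.approx(expected, rel=1e-12)


def test_far_plateau_sigma_approaches_sigma_a():
    cov = np.diag([0.25, 100.0, 1e-8])
    fit = _fit_with_cov(cov, t_end=5e4)
    _, got = final_saturation(fit, t_end=5e4)
    assert got == pytest.approx(0.5, rel=1e-4)


def test_final_sigma_against_multivariate_normal_oracle(rng):
    """100 random SPD covariances: within 3 MC standard errors of 1e5 draws."""
    n = 100_000
    worst = 0.0
    for _ in range(100):
        A = rng.normal(size=(3, 3))
        spd = A @ A.T + 3 * np.eye(3)
        # scale to small relative sigmas (first-order regime)
        scale = np.array([0.004 * TRUE[0], 0.004 * TRUE[1], 0.004 * TRUE[2]])
        d = np.sqrt(np.diag(spd))
        cov = spd / np.outer(d, d) * np.outer(scale, scale)
        fit = _fit_with_cov(cov)
        _, got = final_saturation(fit)
        th = rng.multivariate_normal(TRUE, cov, size=n)
        ys = eval_growth_model(1020.0, th[:, 0], th[:, 1], th[:, 2])
        mc = ys.std(ddof=1)
        se = mc / math.sqrt(2 * (n - 1))
        worst = max(worst, abs(got - mc) / se)
    assert worst < 3.0


def test_band_at_end_equals_final_sigma():
    cov = np.diag([0.16, 25.0, 1e-6])
    fit = _fit_with_cov(cov, baseline_sigma=0.3)
    band = error_band(fit, [0.0, 500.0, 1020.0])
    assert band[-1] == pytest.approx(fit.final_sigma, rel=1e-12)


def test_band_zero_with_zero_covariance_and_continuous():
    assert (error_band(_fit_with_cov(np.zeros((3, 3))), np.linspace(0, 1020, 50)) == 0).all()
    # continuity: refining the grid 10x shrinks the largest step ~10x
    fit = _fit_with_cov(np.diag([0.2, 30.0, 1e-6]))
    coarse = np.abs(np.diff(error_band(fit, np.linspace(0, 1020, 2000)))).max()
    fine = np.abs(np.diff(error_band(fit, np.linspace(0, 1020, 20000)))).max()
    assert fine < 0.2 * coarse


def test_nonfinite_covariance_rejected():
    fit = _fit_with_cov(np.diag([0.1, 1.0, 1e-8]))
    bad = GrowthFit(a=fit.a, b=fit.b, c=fit.c,
                    covariance=np.full((3, 3), np.nan), chi2_red=1.0,
                    t_end=1020.0, final_saturation=0.0, final_sigma=0.0)
    with pytest.raises(KineticsError):
        final_saturation(bad)


# ---------------------------------------------------------------------------
# QC cuts
# ---------------------------------------------------------------------------


def qc_fixture(b_values, finals, roles, ppb):
    fits = {}
    for label in b_values:
        fits[label] = GrowthFit(
            a=finals[label], b=b_values[label], c=0.012,
            covariance=np.eye(3) * 1e-4, chi2_red=1.0, t_end=1020.0,
            final_saturation=finals[label], final_sigma=0.2)
    return fits, roles, ppb


def _five_well_assay(b100=500.0, b50=500.0, s100=22.0, s50=15.0, extra_fail=()):
    labels = ["L0", "L10", "L50", "L100", "U1"]
    b = {"L0": 450.0, "L10": 470.0, "L50": b50, "L100": b100, "U1": 480.0}
    for lbl in extra_fail:
        b[lbl] = 1200.0
    finals = {"L0": 6.0, "L10": 8.0, "L50": s50, "L100": s100, "U1": 10.0}
    roles = {lbl: (ROLE_UNKNOWN if lbl == "U1" else ROLE_LEAD_CURVE)
             for lbl in labels}
    ppb = {"L0": 0.0, "L10": 10.0, "L50": 50.0, "L100": 100.0}
    return qc_fixture(b, finals, roles, ppb)


def test_single_failed_lead_well_keeps_assay_valid():
    fits, roles, ppb = _five_well_assay(b100=1200.0)
    rep = apply_qc_cuts(fits, roles, ppb)
    assert rep.wells["L100"].status == STATUS_FAILED_GROWTH
    assert rep.assay_status == ASSAY_VALID


def test_two_failed_lead_wells_disqualify():
    fits, roles, ppb = _five_well_assay(extra_fail=("L0", "L10"))
    rep = apply_qc_cuts(fits, roles, ppb)
    assert rep.n_failed_lead_wells == 2
    assert rep.assay_status == ASSAY_DISQUALIFIED


def test_inverted_top_point_dropped_from_curve_only():
    fits, roles, ppb = _five_well_assay(s100=18.0, s50=19.5)
    rep = apply_qc_cuts(fits, roles, ppb)
    assert rep.wells["L100"].status == STATUS_DROPPED_TOP
    assert rep.assay_status == ASSAY_VALID
    assert not rep.usable_for_curve("L100")


def test_inversion_rule_skipped_without_both_anchors(caplog):
    fits, roles, ppb = _five_well_assay()
    ppb = dict(ppb)
    ppb["L100"] = 80.0  # no 100 ppb well
    rep = apply_qc_cuts(fits, roles, ppb)
    assert all(q.status == STATUS_PASS for q in rep.wells.values())


def test_flat_well_fails_on_development_floor():
    """A no-growth series fitted as a tiny already-risen amplitude (b small)
    is still flagged: the degenerate branch the b cut cannot see."""
    fits, roles, ppb = _five_well_assay()
    fits = dict(fits)
    fits["L10"] = GrowthFit(a=0.9, b=1e-9, c=0.012,
                            covariance=np.eye(3) * 1e-4, chi2_red=1.0,
                            t_end=1020.0, final_saturation=0.9,
                            final_sigma=0.2)
    rep = apply_qc_cuts(fits, roles, ppb)
    assert rep.wells["L10"].status == STATUS_FAILED_GROWTH
    assert "development" in rep.wells["L10"].reason


def test_failed_unknown_excluded_individually():
    fits, roles, ppb = _five_well_assay(extra_fail=("U1",))
    rep = apply_qc_cuts(fits, roles, ppb)
    assert rep.wells["U1"].status == STATUS_FAILED_GROWTH
    assert rep.assay_status == ASSAY_VALID
    assert not rep.usable_sample("U1")
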