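"""Timelapse kinetics: double-sigmoid model, fitting, and quality cuts.

As the biosensor grows and expresses the reporter, well saturation rises
along an S-shaped trajectory.  The model couples two sigmoids — one for the
lead-induced gene expression, one for the continuing bacterial growth that
gates it:

    y(t) = a / (1 + exp( (b - t) * c / (1 + exp(-t / tau)) ))

* a   : amplitude, the maximum saturation (percent);
* b   : half-rise time, the t (minutes) at which y = a/2 exactly;
* c   : slope (per minute);
* tau : optional time-scale divisor of the inner growth sigmoid, default 1
        (with t in minutes the inner factor saturates within minutes, so by
        default the growth gate is effectively constant; tau lets the gate
        act on a slower scale if wanted).

The final saturation reported for a well is y(t_end) with a 1-sigma
uncertainty from first-order propagation of the full fitted parameter
covariance (all three variances and all three off-diagonal terms).

Data-quality cuts: a well whose fitted half-rise time exceeds 1000 minutes
failed to grow; if the 100 ppb calibration well ends below the 50 ppb well
(growth inhibition at high lead), the 100 ppb point is dropped from the lead
curve; more than one failed calibration well disqualifies the whole assay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Half-rise-time cut (minutes): beyond this the biosensor did not grow.
B_CUT_MINUTES = 1000.0

#: Minimum end-of-assay colour development (saturation points).  A well that
#: never grows produces a flat series; the fit can explain that either with a
#: huge half-rise time or, degenerately, with a negligible amplitude already
#: risen — the two have identical cost.  The b cut catches the first branch;
#: this floor catches the second.  Growing wells develop >= ~6 points (the
#: basal 0 ppb response), no-growth wells < 0.1.
MIN_DEVELOPMENT = 2.0

# exponent clamp making the model and its gradient overflow-safe
# (exp(350)^2 still fits in a float64)
_EXP_CLAMP = 350.0

STATUS_PASS = "pass"
STATUS_FAILED_GROWTH = "failed_growth"
STATUS_DROPPED_TOP = "dropped_top_point"

ASSAY_VALID = "valid"
ASSAY_DISQUALIFIED = "disqualified"

ROLE_LEAD_CURVE = "lead_curve"
ROLE_UNKNOWN = "unknown"


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthFit:
    """Fitted double-sigmoid parameters with covariance and fit quality."""

    a: float
    b: float
    c: float
    covariance: np.ndarray  # 3x3, order (a, b, c)
    chi2_red: float
    t_end: float
    final_saturation: float
    final_sigma: float
    tau: float = 1.0
    n_points: int = 0
    #: coherent first-frame (baseline-subtraction) sigma; the first frame's
    #: measurement error shifts every subtracted point together, so fitting
    #: cannot average it away — it adds in quadrature to the curve sigma.
    baseline_sigma: float = 0.0

    @property
    def sigma_a(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def sigma_b(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    @property
    def sigma_c(self) -> float:
        return float(np.sqrt(self.covariance[2, 2]))


@dataclass
class WellQC:
    label: str
    role: str
    status: str
    reason: str = ""
    nominal_ppb: float | None = None


@dataclass
class QCReport:
    wells: dict[str, WellQC]
    assay_status: str
    n_failed_lead_wells: int

    def usable_for_curve(self, label: str) -> bool:
        qc = self.wells[label]
        return qc.role == ROLE_LEAD_CURVE and qc.status == STATUS_PASS

    def usable_sample(self, label: str) -> bool:
        qc = self.wells[label]
        return qc.role == ROLE_UNKNOWN and qc.status == STATUS_PASS


# ---------------------------------------------------------------------------
# Model evaluation and analytic gradient
# ---------------------------------------------------------------------------


def eval_growth_model(t, a: float, b: float, c: float, tau: float = 1.0):
    """Saturation at time t (minutes); overflow-safe, total on all inputs."""
    t = np.asarray(t, dtype=float)
    gate = c / (1.0 + np.exp(-np.clip(t / tau, -_EXP_CLAMP, _EXP_CLAMP)))
    z = np.clip((b - t) * gate, -_EXP_CLAMP, _EXP_CLAMP)
    y = a / (1.0 + np.exp(z))
    return y if y.ndim else float(y)


def growth_model_gradient(t, a: float, b: float, c: float, tau: float = 1.0):
    """Partial derivatives (dy/da, dy/db, dy/dc) at time t.

    With E = exp(gate*(b-t)) and gate = c/(1+exp(-t/tau)):
        dy/da = 1/(1+E)
        dy/db = -a*c*E / ((1+E)^2 * (1+exp(-t/tau)))
        dy/dc = -a*E*(b-t) / ((1+E)^2 * (1+exp(-t/tau)))
    """
    t = np.asarray(t, dtype=float)
    denom_inner = 1.0 + np.exp(-np.clip(t / tau, -_EXP_CLAMP, _EXP_CLAMP))
    gate = c / denom_inner
    z = np.clip((b - t) * gate, -_EXP_CLAMP, _EXP_CLAMP)
    e = np.exp(z)
    d2 = (1.0 + e) ** 2
    dy_da = 1.0 / (1.0 + e)
    dy_db = -a * c * e / (d2 * denom_inner)
    dy_dc = -a * e * (b - t) / (d2 * denom_inner)
    return dy_da, dy_db, dy_dc


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _default_init(ts: np.ndarray, sats: np.ndarray) -> tuple[float, float, float]:
    a0 = max(float(sats.max()), 1e-3)
    half = a0 / 2.0
    above = np.nonzero(sats >= half)[0]
    b0 = float(ts[above[0]]) if above.size else float(ts[-1])
    t_range = max(float(ts[-1] - ts[0]), 1.0)
    c0 = 4.0 / t_range
    return a0, b0, c0


def fit_timelapse(series, init=None, tau: float = 1.0,
                  baseline_sigma: float = 0.0) -> GrowthFit:
    """Weighted nonlinear least-squares fit of the double-sigmoid model.

    ``series`` is a sequence of TimelapsePoint (or any objects with
    t/saturation/sigma attributes).  Requires >= 6 timepoints.  The fit is a
    deterministic bounded trust-region least squares: a in [0, 120] percent,
    b in [0, 10*t_end] minutes, c in [0, 1] per minute — the physically
    meaningful branch.  Covariance comes from the weighted Jacobian at the
    solution; chi2_red uses n - 3 degrees of freedom.

    If every sigma is zero the fit proceeds unweighted with a warning.

    ``baseline_sigma`` is the measurement sigma of the first (subtracted)
    frame: it offsets the whole series coherently and is added in quadrature
    to the final-saturation uncertainty and the error band.
    """
    ts = np.array([p.t for p in series], dtype=float)
    sats = np.array([p.saturation for p in series], dtype=float)
    sigmas = np.array([p.sigma for p in series], dtype=float)
    n = ts.size
    if n < 6:
        raise KineticsError("timelapse fit requires >= 6 timepoints")
    if (sigmas < 0).any():
        raise KineticsError("negative measurement sigma")
    if not (sigmas > 0).any():
        warnings.warn("all sigmas are zero: performing unweighted fit",
                      stacklevel=2)
        w = np.ones(n)
        weighted = False
    else:
        # zero-sigma points get the smallest positive sigma (conservative)
        floor = sigmas[sigmas > 0].min()
        w = np.where(sigmas > 0, sigmas, floor)
        weighted = True

    t_end = float(ts[-1])
    p0 = np.asarray(init if init is not None else _default_init(ts, sats),
                    dtype=float)
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([120.0, 10.0 * max(t_end, 1.0), 1.0])
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)

    def resid(p):
        return (eval_growth_model(ts, *p, tau=tau) - sats) / w

    def jac(p):
        g = growth_model_gradient(ts, *p, tau=tau)
        return np.stack(g, axis=1) / w[:, None]

    # Deterministic multi-start: failed-growth wells have their half-rise
    # beyond the observation window, where a single in-window start can strand
    # the optimiser in a flat local minimum.
    starts = [p0]
    if init is None:
        a0, _, c0 = p0
        for b_alt in (t_end, 2.0 * t_end):
            starts.append(np.clip(np.array([a0, b_alt, c0]),
                                  lo + 1e-9, hi - 1e-9))
    best = last = None
    for start in starts:
        cand = least_squares(resid, start, jac=jac, bounds=(lo, hi),
                             method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                             max_nfev=5000)
        last = cand
        if cand.success and (best is None or cand.cost < best.cost):
            best = cand
    res = best if best is not None else last
    if not res.success:
        raise KineticsError(
            f"timelapse fit did not converge: {res.message} "
            f"(last iterate a={res.x[0]:.4g}, b={res.x[1]:.4g}, c={res.x[2]:.4g})"
        )
    a, b, c = (float(v) for v in res.x)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    chi2 = float(2.0 * res.cost)
    dof = max(n - 3, 1)
    chi2_red = chi2 / dof
    if not weighted:
        # unweighted: scale covariance by the residual variance estimate
        cov = cov * chi2_red

    final, final_sigma = _final_saturation_at(a, b, c, cov, t_end, tau,
                                              baseline_sigma)
    return GrowthFit(a=a, b=b, c=c, covariance=cov, chi2_red=chi2_red,
                     t_end=t_end, final_saturation=final,
                     final_sigma=final_sigma, tau=tau, n_points=n,
                     baseline_sigma=baseline_sigma)


def _final_saturation_at(a, b, c, cov, t_end, tau,
                         baseline_sigma: float = 0.0) -> tuple[float, float]:
    y = eval_growth_model(t_end, a, b, c, tau=tau)
    g = np.array(growth_model_gradient(t_end, a, b, c, tau=tau), dtype=float)
    var = float(g @ np.asarray(cov, dtype=float) @ g) + baseline_sigma**2
    return float(y), float(np.sqrt(max(var, 0.0)))


def final_saturation(fit: GrowthFit, t_end: float | None = None) -> tuple[float, float]:
    """Best-fit saturation at the assay end time with 1-sigma uncertainty.

    The variance is the quadratic form g' C g of the model gradient with the
    parameter covariance — the three diagonal terms plus all three
    off-diagonal (covariance) cross terms.
    """
    if not np.isfinite(np.asarray(fit.covariance)).all():
        raise KineticsError("fit covariance is not finite")
    te = fit.t_end if t_end is None else float(t_end)
    return _final_saturation_at(fit.a, fit.b, fit.c, fit.covariance, te,
                                fit.tau, fit.baseline_sigma)


def error_band(fit: GrowthFit, t_grid) -> np.ndarray:
    """1-sigma uncertainty of the fitted curve at each grid time."""
    if not np.isfinite(np.asarray(fit.covariance)).all():
        raise KineticsError("fit covariance is not finite")
    t_grid = np.asarray(t_grid, dtype=float)
    g = np.stack(growth_model_gradient(t_grid, fit.a, fit.b, fit.c, tau=fit.tau),
                 axis=-1)
    var = np.einsum("...i,ij,...j->...", g, np.asarray(fit.covariance), g)
    return np.sqrt(np.clip(var + fit.baseline_sigma**2, 0.0, None))


# ---------------------------------------------------------------------------
# Data-quality cuts
# ---------------------------------------------------------------------------


def apply_qc_cuts(
    fits: dict[str, GrowthFit],
    roles: dict[str, str],
    nominal_ppb: dict[str, float],
    b_cut: float = B_CUT_MINUTES,
    min_development: float = MIN_DEVELOPMENT,
) -> QCReport:
    """Growth-based quality cuts over the fitted wells of one assay.

    1. half-rise time b > ``b_cut``, or end-of-assay development below
       ``min_development`` saturation points -> well failed_growth;
    2. if the 100 ppb calibration well ends below the 50 ppb one, the
       100 ppb point is dropped from the lead-curve fit only;
    3. more than one failed_growth calibration well -> assay disqualified.
    """
    wells: dict[str, WellQC] = {}
    for label, fit in fits.items():
        role = roles[label]
        ppb = nominal_ppb.get(label)
        if fit.b > b_cut:
            wells[label] = WellQC(
                label, role, STATUS_FAILED_GROWTH,
                reason=f"half-rise time b={fit.b:.0f} min exceeds {b_cut:.0f} min",
                nominal_ppb=ppb,
            )
        elif fit.final_saturation < min_development:
            wells[label] = WellQC(
                label, role, STATUS_FAILED_GROWTH,
                reason=(f"colour development {fit.final_saturation:.2f} below "
                        f"{min_development:.2f} saturation points"),
                nominal_ppb=ppb,
            )
        else:
            wells[label] = WellQC(label, role, STATUS_PASS, nominal_ppb=ppb)

    passing_lead = {
        label: fits[label] for label, qc in wells.items()
        if qc.role == ROLE_LEAD_CURVE and qc.status == STATUS_PASS
    }
    by_ppb = {wells[lbl].nominal_ppb: lbl for lbl in passing_lead}
    if 100.0 in by_ppb and 50.0 in by_ppb:
        top = by_ppb[100.0]
        mid = by_ppb[50.0]
        if fits[top].final_saturation < fits[mid].final_saturation:
            wells[top].status = STATUS_DROPPED_TOP
            wells[top].reason = (
                "final saturation at 100 ppb below 50 ppb (growth inhibition); "
                "excluded from the lead-curve fit"
            )
    else:
        logger.info(
            "50/100 ppb inversion rule skipped: both concentrations not "
            "present among passing calibration wells"
        )

    n_failed = sum(
        1 for qc in wells.values()
        if qc.role == ROLE_LEAD_CURVE and qc.status == STATUS_FAILED_GROWTH
    )
    status = ASSAY_DISQUALIFIED if n_failed > 1 else ASSAY_VALID
    if status == ASSAY_DISQUALIFIED:
        logger.warning("assay disqualified: %d calibration wells failed growth",
                       n_failed)
    return QCReport(wells=wells, assay_status=status,
                    n_failed_lead_wells=n_failed)
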