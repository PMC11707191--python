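"""Lead-curve construction and inverse prediction of sample concentrations.

Calibration wells of known concentration are co-measured with every assay to
absorb batch and temperature variability in bacterial growth.  Their final
saturations y versus concentration x (ppb) are fit with a first-order
polynomial y = a*x + b (weighted by the per-point sigma); an unknown sample's
saturation is then inverted,

    x = (y - b) / a,

with the uncertainty from first-order propagation of sigma_y and the full
2x2 parameter covariance (including the slope-intercept cross term).
Negative interpolations clamp to 0 ppb (the raw value is retained), results
above 100 ppb are flagged as beyond the validated range, and dilution
bookkeeping scales concentration and uncertainty together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kinetics
from .calibration import WaterMatrixCorrection, tap_water_correction

#: Below this |slope| (percent saturation per ppb) the full 0-100 ppb span
#: changes saturation by < 1 point — under the noise floor, the assay failed.
SLOPE_FLOOR = 0.01

#: Upper edge of the validated measurement range (ppb).
VALIDATED_RANGE_PPB = 100.0


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class LeadCurveFit:
    """Weighted linear fit of final saturation versus lead concentration."""

    slope: float  # percent per ppb
    intercept: float  # percent
    covariance: np.ndarray  # 2x2, order (slope, intercept)
    points: list[tuple[float, float, float]]  # (ppb, saturation, sigma) used
    dropped: list[tuple[float, str]] = field(default_factory=list)  # (ppb, reason)
    chi2_red: float = float("nan")

    def predict(self, ppb) -> np.ndarray | float:
        return self.slope * np.asarray(ppb, dtype=float) + self.intercept


@dataclass(frozen=True)
class LeadResult:
    sample_id: str
    concentration: float  # ppb, >= 0, dilution-adjusted
    sigma: float  # ppb
    clamped: bool
    dilution_factor: float = 1.0
    qc_status: str = kinetics.STATUS_PASS
    raw_concentration: float = float("nan")  # pre-clamp, pre-dilution
    above_validated_range: bool = False


# ---------------------------------------------------------------------------
# Lead-curve fit
# ---------------------------------------------------------------------------


def fit_lead_curve(points, weighted: bool = True) -> LeadCurveFit:
    """Weighted linear least squares of (ppb, saturation, sigma) points.

    Weights are 1/sigma^2 when every sigma is positive and ``weighted`` is
    true; otherwise the fit is unweighted (weights 1) and the covariance is
    scaled by the residual variance.
    """
    pts = [(float(x), float(y), float(s)) for x, y, s in points]
    if len(pts) < 2:
        raise QuantificationError(
            "assay unquantifiable: fewer than 2 usable lead-curve points"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    s = np.array([p[2] for p in pts])
    if np.unique(x).size < 2:
        raise QuantificationError(
            "lead-curve fit rank deficient: all concentrations identical"
        )
    use_weights = weighted and (s > 0).all()
    w = 1.0 / s**2 if use_weights else np.ones_like(x)

    # weighted normal equations for y = slope*x + intercept
    design = np.stack([x, np.ones_like(x)], axis=1)
    jtw = design.T * w
    normal = jtw @ design
    cov = np.linalg.inv(normal)
    beta = cov @ (jtw @ y)
    slope, intercept = (float(v) for v in beta)

    resid = y - design @ beta
    dof = max(len(pts) - 2, 1)
    if use_weights:
        chi2_red = float((w * resid**2).sum()) / dof
    else:
        var = float((resid**2).sum()) / dof
        cov = cov * var
        chi2_red = float("nan")
    return LeadCurveFit(slope=slope, intercept=intercept,
                        covariance=np.asarray(cov), points=pts,
                        chi2_red=chi2_red)


# ---------------------------------------------------------------------------
# Inverse prediction
# ---------------------------------------------------------------------------


def interpolate_lead(
    saturation: float,
    sigma: float,
    curve: LeadCurveFit,
    sample_id: str = "",
) -> LeadResult:
    """Invert the lead curve for one sample: x = (y - b) / a.

    sigma_x combines the measurement sigma with the curve parameter
    covariance (cross term included).  A negative concentration clamps to 0
    ppb with the raw value retained; the sigma is never altered by clamping.
    """
    a, b = curve.slope, curve.intercept
    if abs(a) <= SLOPE_FLOOR:
        raise QuantificationError(
            f"lead curve slope {a:.4g} %/ppb below floor {SLOPE_FLOOR}: "
            "assay unquantifiable (flat response)"
        )
    y = float(saturation)
    x = (y - b) / a
    # gradient of x w.r.t. (a, b) and y
    g = np.array([-(y - b) / a**2, -1.0 / a])
    var = float(g @ np.asarray(curve.covariance) @ g) + (float(sigma) / a) ** 2
    sig = math.sqrt(max(var, 0.0))
    clamped = x < 0
    return LeadResult(
        sample_id=sample_id,
        concentration=max(x, 0.0),
        sigma=sig,
        clamped=clamped,
        raw_concentration=x,
        above_validated_range=x > VALIDATED_RANGE_PPB,
    )


def apply_dilution(result: LeadResult, factor: float) -> LeadResult:
    """Scale a result back to the undiluted sample: both value and sigma."""
    if factor < 1:
        raise QuantificationError("dilution factor must be >= 1")
    conc = result.concentration * factor
    return LeadResult(
        sample_id=result.sample_id,
        concentration=conc,
        sigma=result.sigma * factor,
        clamped=result.clamped,
        dilution_factor=result.dilution_factor * factor,
        qc_status=result.qc_status,
        raw_concentration=result.raw_concentration * factor,
        above_validated_range=conc > VALIDATED_RANGE_PPB,
    )


# ---------------------------------------------------------------------------
# Assay-level orchestration
# ---------------------------------------------------------------------------


def quantify_assay(
    fits: dict[str, kinetics.GrowthFit],
    roles: dict[str, str],
    nominal_ppb: dict[str, float],
    qc: kinetics.QCReport | None = None,
    matrix: WaterMatrixCorrection | None = None,
    dilution_factors: dict[str, float] | None = None,
    weighted: bool = True,
) -> tuple[dict[str, LeadResult], LeadCurveFit | None, kinetics.QCReport]:
    """Full quantification of one QC'd assay.

    Final saturations of the calibration wells (optionally matrix-corrected)
    build the lead curve; each passing unknown well is inverted, clamped and
    dilution-adjusted.  A disqualified assay returns no results, only the QC
    report.
    """
    if qc is None:
        qc = kinetics.apply_qc_cuts(fits, roles, nominal_ppb)
    if qc.assay_status == kinetics.ASSAY_DISQUALIFIED:
        return {}, None, qc

    def corrected(label: str) -> tuple[float, float]:
        f = fits[label]
        s, e = f.final_saturation, f.final_sigma
        if matrix is not None:
            s, e = tap_water_correction(s, e, matrix)
        return s, e

    curve_points = []
    dropped = []
    for label, well in qc.wells.items():
        if well.role != kinetics.ROLE_LEAD_CURVE:
            continue
        if well.status == kinetics.STATUS_PASS:
            s, e = corrected(label)
            curve_points.append((well.nominal_ppb, s, e))
        else:
            dropped.append((well.nominal_ppb, well.reason))
    curve = fit_lead_curve(curve_points, weighted=weighted)
    curve = LeadCurveFit(slope=curve.slope, intercept=curve.intercept,
                         covariance=curve.covariance, points=curve.points,
                         dropped=dropped, chi2_red=curve.chi2_red)

    results: dict[str, LeadResult] = {}
    factors = dilution_factors or {}
    for label, well in qc.wells.items():
        if well.role != kinetics.ROLE_UNKNOWN:
            continue
        if well.status != kinetics.STATUS_PASS:
            results[label] = LeadResult(
                sample_id=label, concentration=float("nan"),
                sigma=float("nan"), clamped=False,
                qc_status=well.status,
            )
            continue
        s, e = corrected(label)
        res = interpolate_lead(s, e, curve, sample_id=label)
        factor = float(factors.get(label, 1.0))
        if factor > 1.0:
            res = apply_dilution(res, factor)
        results[label] = res
    return results, curve, qc
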