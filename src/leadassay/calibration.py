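"""Absolute saturation calibration, baseline subtraction, matrix correction.

Measured HSV saturation depends on the unit's optics and illumination.  To
make end-of-assay saturations comparable between devices, each unit can be
calibrated against a printed wheel of digitally defined colours: measured
saturation y versus digital saturation x follows a saturating exponential

    y = a * exp(-b * x) + c

(a < 0 gives the usual rising response that plateaus at c; a > 0 a falling
one) which is fitted per device and inverted, x = -ln((y - c)/a) / b, to map
measured saturations onto the digital scale.

Two further per-assay corrections live here: subtraction of the first
timelapse frame (so every assay starts at zero saturation, removing
between-assay offsets) and the de-ionised -> tap water matrix correction
(bacterial growth is slightly impeded in tap water; the lead curve measured
in de-ionised water is divided by a fixed ratio, ~1.08, preserving relative
uncertainty).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

#: Default de-ionised -> tap water saturation ratio.
DEFAULT_MATRIX_RATIO = 1.08


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class SaturationCalibration:
    """Fitted y = a*exp(-b*x) + c with parameter covariance and fit domain."""

    a: float
    b: float
    c: float
    covariance: np.ndarray  # 3x3, order (a, b, c)
    domain: tuple[float, float]  # [min, max] digital saturation fitted
    device_id: str = ""

    def forward(self, x) -> np.ndarray | float:
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float)) + self.c

    def to_json(self, path: str | Path) -> None:
        payload = {
            "a": self.a, "b": self.b, "c": self.c,
            "covariance": np.asarray(self.covariance).tolist(),
            "domain": list(self.domain),
            "device_id": self.device_id,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SaturationCalibration":
        d = json.loads(Path(path).read_text())
        return cls(a=d["a"], b=d["b"], c=d["c"],
                   covariance=np.asarray(d["covariance"], dtype=float),
                   domain=tuple(d["domain"]), device_id=d.get("device_id", ""))


@dataclass(frozen=True)
class TimelapsePoint:
    """One baseline-subtracted saturation sample of a well."""

    t: float  # minutes
    saturation: float  # percent
    sigma: float  # percent


@dataclass(frozen=True)
class WaterMatrixCorrection:
    ratio: float = DEFAULT_MATRIX_RATIO
    provenance: str = "de-ionised->tap"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ratio) and self.ratio > 0):
            raise CalibrationError("matrix ratio must be positive and finite")


# ---------------------------------------------------------------------------
# Digital saturation calibration
# ---------------------------------------------------------------------------


def _exp_model(x, a, b, c):
    return a * np.exp(-b * x) + c


def fit_saturation_calibration(
    digital_sats,
    measured_sats,
    sigmas=None,
    device_id: str = "",
) -> SaturationCalibration:
    """Weighted least-squares fit of the device saturation response.

    ``sigmas`` weights the fit when given (1/sigma^2); otherwise the fit is
    unweighted.  Initialisation orients the amplitude by the observed trend:
    rising data start at a0 = -(measured range), c0 = measured maximum;
    falling data at a0 = +(measured range), c0 = measured minimum; in both
    cases b0 = 1/(digital range).
    """
    x = np.asarray(digital_sats, dtype=float)
    y = np.asarray(measured_sats, dtype=float)
    if x.size < 4:
        raise CalibrationError("need at least 4 calibration points")
    if np.unique(x).size != x.size:
        raise CalibrationError("digital saturations must be distinct")
    if np.ptp(y) == 0:
        raise CalibrationError(
            "all measured saturations identical: decay rate unidentifiable"
        )
    sigma = None
    absolute = False
    if sigmas is not None:
        sigma = np.asarray(sigmas, dtype=float)
        if (sigma > 0).all():
            absolute = True
        else:
            sigma = None
    rising = y[np.argmax(x)] > y[np.argmin(x)]
    if rising:
        a0 = -max(np.ptp(y), 1e-3)
        c0 = float(y.max())
    else:
        a0 = max(np.ptp(y), 1e-3)
        c0 = float(y.min())
    b0 = 1.0 / max(np.ptp(x), 1e-6)
    try:
        popt, pcov = curve_fit(
            _exp_model, x, y, p0=(a0, b0, c0), sigma=sigma,
            absolute_sigma=absolute, maxfev=20000,
        )
    except RuntimeError as exc:
        raise CalibrationError(f"saturation calibration fit failed: {exc}") from exc
    a, b, c = (float(v) for v in popt)
    if b <= 0 or a == 0:
        raise CalibrationError(
            f"fitted curve is not monotone (a={a:.4g}, b={b:.4g}): "
            "calibration unusable"
        )
    return SaturationCalibration(
        a=a, b=b, c=c, covariance=np.asarray(pcov, dtype=float),
        domain=(float(x.min()), float(x.max())), device_id=device_id,
    )


def apply_saturation_calibration(
    measured_sat: float,
    sigma: float,
    cal: SaturationCalibration,
) -> tuple[float, float]:
    """Invert the device response: digital saturation for a measured value.

        x = -ln((y - c) / a) / b

    with sigma_x from first-order propagation of sigma_y and the parameter
    covariance.  Values outside the open interval between the plateau c and
    the intercept a + c are out of range (both curve orientations handled).
    """
    y = float(measured_sat)
    a, b, c = cal.a, cal.b, cal.c
    u = (y - c) / a
    if u <= 0:
        raise CalibrationError(
            f"measured saturation {y:.4g} at or beyond the calibration "
            f"plateau c={c:.4g}"
        )
    if u > 1:
        raise CalibrationError(
            f"measured saturation {y:.4g} beyond the calibration intercept "
            f"a+c={a + c:.4g}"
        )
    x = -math.log(u) / b
    # gradient w.r.t. (a, b, c) and y
    dx_da = 1.0 / (a * b)
    dx_db = math.log(u) / b**2  # = -x / b
    dx_dc = 1.0 / (b * (y - c))
    dx_dy = -1.0 / (b * (y - c))
    g = np.array([dx_da, dx_db, dx_dc])
    var = float(g @ np.asarray(cal.covariance) @ g) + (dx_dy * float(sigma)) ** 2
    return x, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# First-image subtraction
# ---------------------------------------------------------------------------


def subtract_baseline(ts, sats, sigmas) -> list[TimelapsePoint]:
    """Subtract the first frame so every assay starts at zero saturation.

    sigma_sub = sqrt(sigma_first^2 + sigma_N^2); the first point becomes
    exactly 0 with sigma = sqrt(2) * sigma_first.
    """
    ts = np.asarray(ts, dtype=float)
    sats = np.asarray(sats, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if ts.size < 2:
        raise CalibrationError("baseline subtraction needs >= 2 timepoints")
    if not (np.diff(ts) > 0).all():
        raise CalibrationError("timepoints must be strictly increasing")
    sub = sats - sats[0]
    sig = np.sqrt(sigmas**2 + sigmas[0] ** 2)
    return [TimelapsePoint(float(t), float(s), float(e))
            for t, s, e in zip(ts, sub, sig)]


# ---------------------------------------------------------------------------
# Water matrix correction
# ---------------------------------------------------------------------------


def tap_water_correction(
    sat_deionised: float,
    sigma: float,
    corr: WaterMatrixCorrection = WaterMatrixCorrection(),
) -> tuple[float, float]:
    """De-ionised -> tap water saturation: S_tap = S / ratio.

    The uncertainty keeps the relative error: sigma_tap = S_tap * sigma / S.
    """
    s = float(sat_deionised)
    if s == 0.0:
        warnings.warn(
            "zero de-ionised saturation: relative-error propagation undefined, "
            "returning 0 +/- 0",
            stacklevel=2,
        )
        return 0.0, 0.0
    s_tap = s / corr.ratio
    return s_tap, abs(s_tap) * float(sigma) / abs(s)


def estimate_matrix_ratio(
    curve_a,
    domain_a: tuple[float, float],
    curve_b,
    domain_b: tuple[float, float],
    n_grid: int = 201,
) -> dict:
    """Mean pointwise ratio curve_a(x)/curve_b(x) over the overlapping domain.

    Returns the ratio together with the grid actually used, so a
    concentration-dependent variant can be reconstructed later.
    """
    lo = max(domain_a[0], domain_b[0])
    hi = min(domain_a[1], domain_b[1])
    if hi <= lo:
        raise CalibrationError("curve domains do not overlap")
    grid = np.linspace(lo, hi, n_grid)
    ya = np.asarray(curve_a(grid), dtype=float)
    yb = np.asarray(curve_b(grid), dtype=float)
    if (yb == 0).any():
        raise CalibrationError("denominator curve crosses zero on the overlap")
    ratios = ya / yb
    return {
        "ratio": float(ratios.mean()),
        "grid": grid,
        "ratios": ratios,
        "rule": "arithmetic mean of pointwise ratio on a uniform grid",
    }
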