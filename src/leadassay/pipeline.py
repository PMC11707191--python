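"""End-to-end analysis: image stacks in, per-sample lead concentrations out.

The processing order mirrors the acquisition chain: white-balance exposure
calibration from the white-reference frames, channel merging, flat fielding,
fiducial-anchored ROI placement, per-ROI HSV decomposition with propagated
uncertainties, optional per-device absolute saturation calibration,
first-frame baseline subtraction, the double-sigmoid timelapse fit per well,
growth quality cuts, lead-curve fit, and inverse prediction of the unknown
samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, imaging, kinetics, quantification
from .calibration import SaturationCalibration, WaterMatrixCorrection
from .config import AssayConfig, load_frames_from_manifest, read_manifest
from .imaging import RGBImage

logger = logging.getLogger(__name__)


@dataclass
class AssayResult:
    qc: kinetics.QCReport
    fits: dict[str, kinetics.GrowthFit]
    curve: quantification.LeadCurveFit | None
    results: dict[str, quantification.LeadResult]
    colour_table: pd.DataFrame  # final-frame per-ROI colour decomposition
    series: dict[str, list[calibration.TimelapsePoint]]
    metadata_payload: str | None = None

    @property
    def disqualified(self) -> bool:
        return self.qc.assay_status == kinetics.ASSAY_DISQUALIFIED


def _central_mean(plane: np.ndarray) -> float:
    """Mean over the central half-width/half-height window."""
    h, w = plane.shape
    return float(plane[h // 4: h - h // 4, w // 4: w - w // 4].mean())


def colour_table(image: RGBImage, boxes) -> pd.DataFrame:
    """Per-ROI colour decomposition table (RGB, HSV and their sigmas)."""
    rows = []
    for box in boxes:
        rgb = imaging.roi_color_stats(image, box)
        hsv = imaging.propagate_hsv_uncertainty(rgb)
        rows.append({
            "ROI": box.label,
            "R": rgb.mean_r, "G": rgb.mean_g, "B": rgb.mean_b,
            "sigma_R": rgb.se_r, "sigma_G": rgb.se_g, "sigma_B": rgb.se_b,
            "H": hsv.hue, "S": hsv.saturation, "V": hsv.value,
            "sigma_H": hsv.sigma_h, "sigma_S": hsv.sigma_s,
            "sigma_V": hsv.sigma_v,
        })
    return pd.DataFrame(rows)


def analyze_assay(
    white_frames: dict[str, np.ndarray],
    sample_frames: dict[tuple[float, str], np.ndarray],
    config: AssayConfig,
    saturation_cal: SaturationCalibration | None = None,
) -> AssayResult:
    """Analyse one assay held in memory as raw channel planes.

    ``white_frames`` maps channel -> plane (the white-reference LED set);
    ``sample_frames`` maps (timepoint_min, channel) -> plane.
    """
    # --- LED exposure calibration from the white-reference centre ---------
    white_img = RGBImage(white_frames["R"], white_frames["G"], white_frames["B"])
    led_cal = imaging.compute_led_calibration(
        {ch: _central_mean(white_img.plane(ch)) for ch in imaging.CHANNELS},
        reference_aec=config.reference_aec,
        target_mean=config.target_mean,
    )
    flat = imaging.apply_led_calibration(white_img, led_cal)

    timepoints = sorted({t for (t, _ch) in sample_frames})
    if len(timepoints) < 2:
        raise imaging.ImagingError("an assay needs at least 2 timepoints")

    def corrected_image(t: float) -> RGBImage:
        merged = imaging.merge_channel_frames([
            imaging.ChannelImage(sample_frames[(t, ch)], ch)
            for ch in imaging.CHANNELS
        ])
        merged = imaging.apply_led_calibration(merged, led_cal)
        if config.flat_fielding:
            return imaging.flat_field(merged, flat, config.target_mean)
        return merged

    first = corrected_image(timepoints[0])
    boxes, payload = imaging.locate_rois(first, config.layout)

    # --- per-well saturation series ---------------------------------------
    raw_series: dict[str, list[tuple[float, float, float]]] = {
        b.label: [] for b in boxes
    }
    last_image = first
    for i, t in enumerate(timepoints):
        img = first if i == 0 else corrected_image(t)
        last_image = img
        for box in boxes:
            rgb = imaging.roi_color_stats(img, box)
            hsv = imaging.propagate_hsv_uncertainty(rgb)
            s, sig = hsv.saturation, hsv.sigma_s
            if saturation_cal is not None:
                s, sig = calibration.apply_saturation_calibration(
                    s, sig, saturation_cal)
            raw_series[box.label].append((t, s, sig))

    series = {
        label: calibration.subtract_baseline(
            [p[0] for p in pts], [p[1] for p in pts], [p[2] for p in pts])
        for label, pts in raw_series.items()
    }

    # --- kinetics, QC, quantification --------------------------------------
    # the first frame's own measurement sigma offsets the whole subtracted
    # series coherently; carried into the final-saturation uncertainty
    fits = {
        label: kinetics.fit_timelapse(
            pts, tau=config.tau, baseline_sigma=raw_series[label][0][2])
        for label, pts in series.items()
    }
    roles = config.layout.roles()
    nominal = config.layout.nominal_ppb()
    qc = kinetics.apply_qc_cuts(fits, roles, nominal, b_cut=config.b_cut,
                                min_development=config.min_development)
    matrix = (WaterMatrixCorrection(config.matrix_ratio)
              if config.matrix_ratio else None)
    results, curve, qc = quantification.quantify_assay(
        fits, roles, nominal, qc=qc, matrix=matrix,
        dilution_factors=config.layout.dilution_factors(),
        weighted=config.weighted_lead_curve,
    )
    return AssayResult(
        qc=qc, fits=fits, curve=curve, results=results,
        colour_table=colour_table(last_image, boxes),
        series=series, metadata_payload=payload,
    )


def analyze_directory(
    manifest_path: str | Path,
    config: AssayConfig,
    saturation_cal: SaturationCalibration | None = None,
) -> AssayResult:
    """Analyse an assay from a frame manifest CSV on disk."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    white, frames = load_frames_from_manifest(manifest, manifest_path.parent)
    missing = [ch for ch in imaging.CHANNELS if ch not in white]
    if missing:
        raise imaging.ImagingError(
            f"manifest has no white-reference frame for channel(s) {missing}")
    return analyze_assay(white, frames, config, saturation_cal)


# ---------------------------------------------------------------------------
# Serialisation of results
# ---------------------------------------------------------------------------


def results_table(result: AssayResult) -> pd.DataFrame:
    curve = result.curve
    rows = []
    for label, res in sorted(result.results.items()):
        rows.append({
            "sample_id": label,
            "lead_ppb": res.concentration,
            "sigma_ppb": res.sigma,
            "clamped": res.clamped,
            "dilution_factor": res.dilution_factor,
            "qc_status": res.qc_status,
            "above_validated_range": res.above_validated_range,
            "curve_slope": curve.slope if curve else float("nan"),
            "curve_intercept": curve.intercept if curve else float("nan"),
            "chi2_red": (result.fits[label].chi2_red
                         if label in result.fits else float("nan")),
        })
    return pd.DataFrame(rows)


def fits_record(result: AssayResult) -> dict:
    rec = {
        "assay_status": result.qc.assay_status,
        "metadata_payload": result.metadata_payload,
        "wells": {},
    }
    for label, fit in result.fits.items():
        qc = result.qc.wells[label]
        rec["wells"][label] = {
            "a": fit.a, "b": fit.b, "c": fit.c,
            "covariance": np.asarray(fit.covariance).tolist(),
            "chi2_red": fit.chi2_red,
            "t_end": fit.t_end,
            "final_saturation": fit.final_saturation,
            "final_sigma": fit.final_sigma,
            "qc_status": qc.status,
            "qc_reason": qc.reason,
        }
    if result.curve is not None:
        rec["lead_curve"] = {
            "slope": result.curve.slope,
            "intercept": result.curve.intercept,
            "covariance": np.asarray(result.curve.covariance).tolist(),
            "points": result.curve.points,
            "dropped": result.curve.dropped,
            "chi2_red": result.curve.chi2_red,
        }
    return rec


def write_outputs(result: AssayResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.colour_table.to_csv(outdir / "colour_table.csv", index=False)
    (outdir / "fits.json").write_text(json.dumps(fits_record(result), indent=2))
    qc_rows = [
        {"well": qc.label, "role": qc.role, "status": qc.status,
         "reason": qc.reason, "nominal_ppb": qc.nominal_ppb}
        for qc in result.qc.wells.values()
    ]
    pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.csv", index=False)
    if not result.disqualified:
        results_table(result).to_csv(outdir / "lead_results.csv", index=False)
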