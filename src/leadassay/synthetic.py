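"""Synthetic assay generator: timelapse series and rendered image stacks.

Everything the hardware produces is emulated here with known ground truth,
so the whole pipeline — LED calibration, flat fielding, fiducial-anchored ROI
placement, HSV decomposition, kinetic fitting and lead quantification — is
testable without a device or a wet lab.

What is emulated, and the defaults chosen:

* acquisition cadence: a frame triplet every 40 minutes over 17 hours;
* per-well saturation trajectories following the double-sigmoid growth model
  with half-rise time ~480 min and slope 0.012 per min (blue colour visible
  from roughly 5-6 h, as observed at 37 C), plus Gaussian measurement noise
  of sd 0.4 saturation points per timepoint;
* a monotone, saturating concentration -> amplitude response
  a(ppb) = a_base + a_max * ppb / (K + ppb) with a_base = 6, a_max = 256,
  K = 1500: ~22 points of final saturation at 100 ppb (the scale seen on
  real assays), a basal (0 ppb) response of ~6 points of reporter leak, and
  only mild curvature across the validated 0-100 ppb range — matching the
  observed behaviour that a first-order polynomial fits real lead curves
  well (the half-saturation constant sits far above the assay range);
* heterogeneous illumination: an independent linear gradient per LED channel
  (the three LEDs sit at different positions), default 30 percent edge
  falloff, plus a fixed per-LED exposure imbalance for the white-balance
  step to correct;
* a fiducial marker carrying the assay metadata payload;
* failed-growth wells (half-rise time pushed beyond the observation window).

Noise enters the rendered images per pixel, with the per-pixel saturation sd
scaled by sqrt(n_roi_pixels) so that the standard error of the ROI mean
matches the series-level noise sd.  All randomness flows from the single
spec seed through named child streams; renders are byte-identical per seed.

The concentration -> amplitude mapping is a property of the generator only:
the analysis pipeline never sees it, it sees rendered pixels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import fiducial
from .calibration import TimelapsePoint
from .config import AssayConfig, WellLayout, WellSpec, write_manifest
from .kinetics import ROLE_LEAD_CURVE, ROLE_UNKNOWN, eval_growth_model

DEFAULT_LEAD_CURVE_PPB = (0.0, 10.0, 20.0, 50.0, 100.0)
DEFAULT_UNKNOWN_PPB = (5.0, 8.0, 10.0, 15.0, 25.0, 30.0, 40.0, 60.0, 75.0, 90.0, 0.0)


@dataclass(frozen=True)
class WellTruth:
    label: str
    role: str
    ppb: float
    a: float
    b: float
    c: float
    failed: bool
    cx: int  # well centre, pixels
    cy: int


@dataclass(frozen=True)
class SyntheticAssaySpec:
    seed: int
    lead_curve_ppb: tuple[float, ...] = DEFAULT_LEAD_CURVE_PPB
    unknown_ppb: tuple[float, ...] = DEFAULT_UNKNOWN_PPB
    failed_wells: tuple[str, ...] = ()
    # growth kinetics
    half_rise_min: float = 480.0
    half_rise_sd: float = 20.0  # well-to-well growth variability
    slope_per_min: float = 0.012
    failed_half_rise_min: float = 1400.0
    # concentration -> amplitude response
    amp_base: float = 6.0
    amp_max: float = 256.0
    amp_k_ppb: float = 1500.0
    # acquisition
    noise_sd: float = 0.4  # saturation points, per timepoint
    cadence_min: float = 40.0
    duration_min: float = 1020.0
    # scene
    base_saturation: float = 20.0  # starting tint of every well, percent
    hue_deg: float = 200.0  # blue-cyan, as the developed wells show
    value_pct: float = 68.0
    illumination_gradient: float = 0.3  # edge falloff fraction, per channel
    led_imbalance: tuple[float, float, float] = (0.95, 1.05, 1.0)
    white_level: float = 200.0  # white reference at balanced exposure
    background_gray: float = 180.0
    width: int = 360
    height: int = 280
    marker_xy: tuple[int, int] = (10, 10)
    marker_module_px: int = 3
    well_radius: int = 20
    roi_px: int = 16
    payload: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.illumination_gradient < 1):
            raise ValueError("illumination gradient must be in [0, 1)")
        if len(self.lead_curve_ppb) + len(self.unknown_ppb) > 16:
            raise ValueError("at most 16 wells fit the sample holder")

    # -- derived geometry -------------------------------------------------

    def timepoints(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + 0.5 * self.cadence_min,
                         self.cadence_min)

    @property
    def marker_edge(self) -> int:
        return fiducial.GRID * self.marker_module_px

    def _rng(self, *key) -> np.random.Generator:
        # stable across processes (Python's str hash is salted; crc32 is not)
        parts = [int(self.seed) % (2**31)]
        for k in key:
            if isinstance(k, (int, np.integer)):
                parts.append(int(k) % (2**31))
            else:
                parts.append(zlib.crc32(str(k).encode()) % (2**31))
        return np.random.default_rng(parts)

    def amplitude(self, ppb: float) -> float:
        return self.amp_base + self.amp_max * ppb / (self.amp_k_ppb + ppb)

    def wells(self) -> list[WellTruth]:
        """Ground truth for every well, with deterministic geometry."""
        out = []
        concs = ([(ROLE_LEAD_CURVE, p) for p in self.lead_curve_ppb]
                 + [(ROLE_UNKNOWN, p) for p in self.unknown_ppb])
        rng = self._rng("kinetics")
        for i, (role, ppb) in enumerate(concs):
            label = f"W{i:02d}"
            row, col = divmod(i, 4)
            cx = 120 + col * 60
            cy = 35 + row * 70
            failed = label in self.failed_wells
            b = (self.failed_half_rise_min if failed
                 else self.half_rise_min + self.half_rise_sd * rng.standard_normal())
            out.append(WellTruth(label=label, role=role, ppb=float(ppb),
                                 a=self.amplitude(ppb), b=float(b),
                                 c=self.slope_per_min, failed=failed,
                                 cx=cx, cy=cy))
        return out

    def metadata_payload(self) -> str:
        return self.payload or f"assay-seed={self.seed};device=synthetic"


# ---------------------------------------------------------------------------
# Timelapse series (no imaging)
# ---------------------------------------------------------------------------


def generate_timelapse(
    spec: SyntheticAssaySpec,
    well: str | WellTruth,
) -> tuple[list[TimelapsePoint], WellTruth]:
    """Noisy saturation series for one well, plus its ground truth.

    saturation_i = y(t_i; a, b, c) + eps_i with eps ~ N(0, noise_sd^2) and
    sigma_i = noise_sd.  Deterministic per (seed, well).
    """
    truth = _resolve_well(spec, well)
    ts = spec.timepoints()
    y = eval_growth_model(ts, truth.a, truth.b, truth.c)
    rng = spec._rng("series", truth.label)
    noise = rng.normal(0.0, spec.noise_sd, size=ts.size) if spec.noise_sd > 0 \
        else np.zeros(ts.size)
    return (
        [TimelapsePoint(float(t), float(v + e), spec.noise_sd)
         for t, v, e in zip(ts, y, noise)],
        truth,
    )


def _resolve_well(spec: SyntheticAssaySpec, well) -> WellTruth:
    if isinstance(well, WellTruth):
        return well
    for w in spec.wells():
        if w.label == well:
            return w
    raise KeyError(f"no such well {well!r}")


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def hsv_to_rgb_array(h_deg, s_pct, v_pct) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised hexcone inverse: degrees/percent in, 0-255 float planes out."""
    h = (np.asarray(h_deg, dtype=float) % 360.0) / 60.0
    s = np.clip(np.asarray(s_pct, dtype=float), 0, 100) / 100.0
    v = np.clip(np.asarray(v_pct, dtype=float), 0, 100) / 100.0 * 255.0
    c = v * s
    x = c * (1.0 - np.abs(h % 2.0 - 1.0))
    m = v - c
    zeros = np.zeros_like(c)
    sector = np.floor(h).astype(int) % 6
    r = np.choose(sector, [c, x, zeros, zeros, x, c])
    g = np.choose(sector, [x, c, c, x, zeros, zeros])
    b = np.choose(sector, [zeros, zeros, x, c, c, x])
    return r + m, g + m, b + m


def illumination_field(spec: SyntheticAssaySpec, channel: str) -> np.ndarray:
    """Per-channel linear illumination gradient, in (0, 1].

    The three LEDs sit at different positions, so each channel has its own
    gradient orientation; this is what makes flat fielding consequential for
    the saturation observable.
    """
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    u = {
        "R": xx / max(spec.width - 1, 1),
        "G": yy / max(spec.height - 1, 1),
        "B": (xx / max(spec.width - 1, 1) + yy / max(spec.height - 1, 1)) / 2.0,
    }[channel]
    return 1.0 - spec.illumination_gradient * u


def render_white_frames(spec: SyntheticAssaySpec) -> dict[str, np.ndarray]:
    """White-reference frame per channel: exposure imbalance x illumination."""
    out = {}
    for ch, imb in zip(("R", "G", "B"), spec.led_imbalance):
        field_ = illumination_field(spec, ch)
        out[ch] = _quantise(spec.white_level * imb * field_)
    return out


def render_assay_images(
    spec: SyntheticAssaySpec,
    t: float,
    t_index: int | None = None,
) -> dict[str, np.ndarray]:
    """Three single-LED channel frames of the sample holder at time t.

    Well disks are flat colours at the spec hue/value whose saturation is
    base_saturation + y(t) plus per-pixel noise; the fiducial marker and a
    grey background complete the scene; each channel is multiplied by its
    illumination field and LED imbalance and quantised to 8 bits.
    """
    if t_index is None:
        ts = spec.timepoints()
        matches = np.nonzero(np.isclose(ts, t))[0]
        t_index = int(matches[0]) if matches.size else int(round(t))

    planes = {ch: np.full((spec.height, spec.width), spec.background_gray)
              for ch in ("R", "G", "B")}

    marker = fiducial.render(spec.metadata_payload(), spec.marker_module_px)
    mx, my = spec.marker_xy
    e = marker.shape[0]
    for ch in planes:
        planes[ch][my:my + e, mx:mx + e] = marker

    sigma_pix = spec.noise_sd * spec.roi_px  # se of ROI mean == noise_sd
    rng = spec._rng("image", t_index)
    for truth in spec.wells():
        s_mean = spec.base_saturation + float(
            eval_growth_model(t, truth.a, truth.b, truth.c))
        r = spec.well_radius
        y0, y1 = truth.cy - r, truth.cy + r + 1
        x0, x1 = truth.cx - r, truth.cx + r + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - truth.cy) ** 2 + (xx - truth.cx) ** 2 <= r * r
        s_field = np.clip(
            s_mean + sigma_pix * rng.standard_normal(disk.shape), 0.0, 100.0)
        rp, gp, bp = hsv_to_rgb_array(spec.hue_deg, s_field, spec.value_pct)
        for ch, plane_vals in zip(("R", "G", "B"), (rp, gp, bp)):
            patch = planes[ch][y0:y1, x0:x1]
            patch[disk] = plane_vals[disk]

    out = {}
    for ch, imb in zip(("R", "G", "B"), spec.led_imbalance):
        out[ch] = _quantise(planes[ch] * imb * illumination_field(spec, ch))
    return out


def _quantise(plane: np.ndarray) -> np.ndarray:
    """8-bit quantisation, returned as float64 (mimics camera output)."""
    return np.clip(np.round(plane), 0, 255).astype(np.float64)


# ---------------------------------------------------------------------------
# Layout / configuration matching the rendered geometry
# ---------------------------------------------------------------------------


def layout_for_spec(spec: SyntheticAssaySpec,
                    with_absolute: bool = False) -> AssayConfig:
    """AssayConfig whose ROI geometry matches the rendered scene.

    Offsets are expressed relative to the marker, exactly as a field layout
    would be; nothing about the ground truth leaks into the configuration.
    """
    edge = float(spec.marker_edge)
    mx, my = spec.marker_xy
    half = spec.roi_px // 2
    wells = []
    for truth in spec.wells():
        x0 = truth.cx - half
        y0 = truth.cy - half
        wells.append(WellSpec(
            label=truth.label, role=truth.role,
            nominal_ppb=truth.ppb if truth.role == ROLE_LEAD_CURVE else None,
            dx=(x0 - mx) / edge, dy=(y0 - my) / edge,
            box_w=spec.roi_px / edge, box_h=spec.roi_px / edge,
            abs_x0=x0 if with_absolute else None,
            abs_y0=y0 if with_absolute else None,
            abs_w=spec.roi_px if with_absolute else None,
            abs_h=spec.roi_px if with_absolute else None,
        ))
    return AssayConfig(
        layout=WellLayout(tuple(wells)),
        cadence_min=spec.cadence_min,
        duration_min=spec.duration_min,
    )


def ground_truth_table(spec: SyntheticAssaySpec) -> pd.DataFrame:
    return pd.DataFrame(
        [{"well": w.label, "role": w.role, "true_ppb": w.ppb,
          "a": w.a, "b": w.b, "c": w.c, "failed": w.failed}
         for w in spec.wells()]
    )


def assay_frames(
    spec: SyntheticAssaySpec,
) -> tuple[dict[str, np.ndarray], dict[tuple[float, str], np.ndarray]]:
    """All frames of one assay, in the structure the pipeline consumes."""
    white = render_white_frames(spec)
    frames = {}
    for i, t in enumerate(spec.timepoints()):
        for ch, plane in render_assay_images(spec, t, t_index=i).items():
            frames[(float(t), ch)] = plane
    return white, frames


def write_assay(spec: SyntheticAssaySpec, outdir: str | Path) -> Path:
    """Write a complete synthetic assay directory: frames (PNG), manifest,
    configuration and ground truth.  Deterministic per seed."""
    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    white, frames = assay_frames(spec)
    for ch, plane in white.items():
        name = f"frames/white_{ch}.png"
        _save_png(plane, outdir / name)
        rows.append({"timepoint_min": 0, "channel": ch, "path": name,
                     "is_white": 1})
    for (t, ch), plane in frames.items():
        name = f"frames/t{int(t):05d}_{ch}.png"
        _save_png(plane, outdir / name)
        rows.append({"timepoint_min": t, "channel": ch, "path": name,
                     "is_white": 0})
    write_manifest(rows, outdir / "manifest.csv")
    from .config import config_to_yaml

    config_to_yaml(layout_for_spec(spec), outdir / "config.yaml")
    ground_truth_table(spec).to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "seed.txt").write_text(f"{spec.seed}\n")
    return outdir


def _save_png(plane: np.ndarray, path: Path) -> None:
    Image.fromarray(plane.astype(np.uint8), mode="L").save(path)
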