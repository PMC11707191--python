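"""Assay configuration, well layout, frame manifests and image loading.

The configuration is one plain-text YAML file holding the acquisition
parameters and a per-well table.  Well ROI geometry is stored relative to
the fiducial marker: offsets and box sizes in units of the marker edge
length, measured from its top-left corner, so the same layout works at any
camera distance.  Wells may additionally carry absolute pixel coordinates as
a fallback for frames in which the marker cannot be decoded.

Frames are listed in a manifest CSV with columns
``timepoint_min, channel, path, is_white`` — one row per single-LED frame,
white-reference frames flagged with ``is_white = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import imaging
from .imaging import ROIBox
from .kinetics import (
    B_CUT_MINUTES,
    MIN_DEVELOPMENT,
    ROLE_LEAD_CURVE,
    ROLE_UNKNOWN,
)

MANIFEST_COLUMNS = ("timepoint_min", "channel", "path", "is_white")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class WellSpec:
    label: str
    role: str  # lead_curve | unknown
    nominal_ppb: float | None = None  # required for lead_curve wells
    # geometry relative to the fiducial marker, in marker-edge units
    dx: float = 0.0
    dy: float = 0.0
    box_w: float = 0.2
    box_h: float = 0.2
    # absolute-pixel fallback (used when the marker is not decodable)
    abs_x0: int | None = None
    abs_y0: int | None = None
    abs_w: int | None = None
    abs_h: int | None = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in (ROLE_LEAD_CURVE, ROLE_UNKNOWN):
            raise ConfigError(f"well {self.label!r}: unknown role {self.role!r}")
        if self.role == ROLE_LEAD_CURVE:
            if self.nominal_ppb is None or self.nominal_ppb < 0:
                raise ConfigError(
                    f"lead-curve well {self.label!r} needs a nominal ppb >= 0"
                )
        if self.dilution_factor < 1:
            raise ConfigError(f"well {self.label!r}: dilution factor < 1")


@dataclass(frozen=True)
class WellLayout:
    wells: tuple[WellSpec, ...]

    def __post_init__(self) -> None:
        labels = [w.label for w in self.wells]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate well labels in layout")
        n_lead = sum(1 for w in self.wells if w.role == ROLE_LEAD_CURVE)
        if len(self.wells) == 16 and not 4 <= n_lead <= 6:
            raise ConfigError(
                f"a 16-well holder uses 4-6 calibration wells, got {n_lead}"
            )
        if n_lead < 2:
            raise ConfigError("layout needs >= 2 lead-curve wells")

    def absolute_boxes(self) -> list[ROIBox] | None:
        """Fallback ROI boxes from absolute coordinates, or None if absent."""
        boxes = []
        for w in self.wells:
            if None in (w.abs_x0, w.abs_y0, w.abs_w, w.abs_h):
                return None
            boxes.append(ROIBox(w.label, w.abs_x0, w.abs_y0, w.abs_w, w.abs_h))
        return boxes

    def roles(self) -> dict[str, str]:
        return {w.label: w.role for w in self.wells}

    def nominal_ppb(self) -> dict[str, float]:
        return {w.label: w.nominal_ppb for w in self.wells
                if w.nominal_ppb is not None}

    def dilution_factors(self) -> dict[str, float]:
        return {w.label: w.dilution_factor for w in self.wells}


@dataclass(frozen=True)
class AssayConfig:
    layout: WellLayout
    cadence_min: float = 40.0  # imaging every 40 min
    duration_min: float = 1020.0  # over 17 h
    matrix_ratio: float | None = None  # de-ionised -> tap, e.g. 1.08
    confidence: float = 0.95
    t_end: float | None = None  # defaults to duration_min
    tau: float = 1.0
    target_mean: float = imaging.DEFAULT_TARGET_MEAN
    reference_aec: float = imaging.DEFAULT_REFERENCE_AEC
    b_cut: float = B_CUT_MINUTES
    min_development: float = MIN_DEVELOPMENT
    weighted_lead_curve: bool = True
    flat_fielding: bool = True

    @property
    def end_time(self) -> float:
        return self.duration_min if self.t_end is None else self.t_end

    def timepoints(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + 0.5 * self.cadence_min,
                         self.cadence_min)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------


def config_to_yaml(config: AssayConfig, path: str | Path) -> None:
    doc = {
        "cadence_min": config.cadence_min,
        "duration_min": config.duration_min,
        "matrix_ratio": config.matrix_ratio,
        "confidence": config.confidence,
        "t_end": config.t_end,
        "tau": config.tau,
        "target_mean": config.target_mean,
        "reference_aec": config.reference_aec,
        "b_cut": config.b_cut,
        "min_development": config.min_development,
        "weighted_lead_curve": config.weighted_lead_curve,
        "flat_fielding": config.flat_fielding,
        "wells": [
            {
                "label": w.label, "role": w.role, "ppb": w.nominal_ppb,
                "dx": w.dx, "dy": w.dy, "box_w": w.box_w, "box_h": w.box_h,
                "abs_x0": w.abs_x0, "abs_y0": w.abs_y0,
                "abs_w": w.abs_w, "abs_h": w.abs_h,
                "dilution": w.dilution_factor,
            }
            for w in config.layout.wells
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> AssayConfig:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        wells = tuple(
            WellSpec(
                label=str(w["label"]), role=w["role"],
                nominal_ppb=w.get("ppb"),
                dx=float(w.get("dx", 0.0)), dy=float(w.get("dy", 0.0)),
                box_w=float(w.get("box_w", 0.2)),
                box_h=float(w.get("box_h", 0.2)),
                abs_x0=w.get("abs_x0"), abs_y0=w.get("abs_y0"),
                abs_w=w.get("abs_w"), abs_h=w.get("abs_h"),
                dilution_factor=float(w.get("dilution", 1.0)),
            )
            for w in doc["wells"]
        )
    except KeyError as exc:
        raise ConfigError(f"malformed well entry: missing {exc}") from exc
    return AssayConfig(
        layout=WellLayout(wells),
        cadence_min=float(doc.get("cadence_min", 40.0)),
        duration_min=float(doc.get("duration_min", 1020.0)),
        matrix_ratio=doc.get("matrix_ratio"),
        confidence=float(doc.get("confidence", 0.95)),
        t_end=doc.get("t_end"),
        tau=float(doc.get("tau", 1.0)),
        target_mean=float(doc.get("target_mean", imaging.DEFAULT_TARGET_MEAN)),
        reference_aec=float(doc.get("reference_aec",
                                    imaging.DEFAULT_REFERENCE_AEC)),
        b_cut=float(doc.get("b_cut", B_CUT_MINUTES)),
        min_development=float(doc.get("min_development", MIN_DEVELOPMENT)),
        weighted_lead_curve=bool(doc.get("weighted_lead_curve", True)),
        flat_fielding=bool(doc.get("flat_fielding", True)),
    )


# ---------------------------------------------------------------------------
# Frame manifests and image files
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"manifest missing columns: {missing}")
    df["channel"] = df["channel"].astype(str).str.upper()
    bad = ~df["channel"].isin(imaging.CHANNELS)
    if bad.any():
        raise ConfigError(f"manifest has unknown channels: "
                          f"{sorted(df.loc[bad, 'channel'].unique())}")
    return df


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)


def load_channel_frame(path: str | Path, channel: str) -> np.ndarray:
    """Decode one single-LED frame (PNG or JPEG) to a float intensity plane.

    Grayscale files are used as-is; colour files contribute the plane of the
    LED that lit the frame.
    """
    with Image.open(path) as im:
        if im.mode in ("L", "I", "I;16"):
            arr = np.asarray(im.convert("L"), dtype=np.float64)
        else:
            rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
            arr = rgb[:, :, imaging.CHANNELS.index(channel)]
    return arr


def load_frames_from_manifest(
    manifest: pd.DataFrame,
    root: str | Path,
) -> tuple[dict[str, np.ndarray], dict[tuple[float, str], np.ndarray]]:
    """(white frames by channel, sample frames by (timepoint, channel))."""
    root = Path(root)
    white: dict[str, np.ndarray] = {}
    frames: dict[tuple[float, str], np.ndarray] = {}
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        arr = load_channel_frame(p, row.channel)
        if int(row.is_white):
            white[row.channel] = arr
        else:
            frames[(float(row.timepoint_min), row.channel)] = arr
    return white, frames
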