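"""Per-LED channel images to per-ROI colour measurements with uncertainties.

The device images the 16-well sample holder three times per timepoint, once
under each colour LED at full power with a per-LED exposure.  This module
covers the software side of that acquisition chain: the white-balance
exposure calibration, merging the single-LED frames into one RGB image,
flat-field correction of heterogeneous illumination, ROI placement relative
to the fiducial marker, per-ROI RGB statistics, and the HSV decomposition
with first-order (delta-method) uncertainty propagation.

All pixel intensities are 8-bit scale (0-255) but held as float64 after
decode; statistics are never computed on quantised integers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("R", "G", "B")

#: Reference automatic-exposure-control setting used for the white frame.
DEFAULT_REFERENCE_AEC = 100.0
#: Expected mean intensity of a white reference under balanced exposure.
DEFAULT_TARGET_MEAN = 200.0

#: Sentinel reported for the hue uncertainty when chroma is zero and the
#: hue derivative is singular.
SIGMA_H_UNDEFINED = float("nan")


class ImagingError(ValueError):
    """Raised for malformed acquisitions and invalid calibration inputs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelImage:
    """A single-LED frame: one colour channel of the sample-holder scene."""

    pixels: np.ndarray  # 2-D float array, intensities in [0, 255]
    channel: str  # one of "R", "G", "B"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ImagingError("channel image must be a non-empty 2-D array")
        if self.channel not in CHANNELS:
            raise ImagingError(f"unknown channel {self.channel!r}")
        if px.min() < 0 or px.max() > 255:
            raise ImagingError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RGBImage:
    """Three aligned channel planes forming one composite colour image."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        planes = {}
        for name in ("r", "g", "b"):
            p = np.asarray(getattr(self, name), dtype=np.float64)
            if p.ndim != 2:
                raise ImagingError("channel planes must be 2-D")
            planes[name] = p
        if not (planes["r"].shape == planes["g"].shape == planes["b"].shape):
            raise ImagingError("channel planes must have identical dimensions")
        for name, p in planes.items():
            object.__setattr__(self, name, p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    @property
    def height(self) -> int:
        return self.r.shape[0]

    @property
    def width(self) -> int:
        return self.r.shape[1]

    def plane(self, channel: str) -> np.ndarray:
        return {"R": self.r, "G": self.g, "B": self.b}[channel]

    def stacked(self) -> np.ndarray:
        """(H, W, 3) view of the image, useful for grey-level operations."""
        return np.stack([self.r, self.g, self.b], axis=-1)

    def grayscale(self) -> np.ndarray:
        return (self.r + self.g + self.b) / 3.0


@dataclass(frozen=True)
class LEDCalibration:
    """Per-LED exposure scales establishing white balance.

    ``exposure_scale[c] = reference_aec * target_mean / measured_white_mean[c]``
    is the exposure setting that would render the white reference at
    ``target_mean`` in channel ``c``.
    """

    exposure_scale: dict[str, float]
    measured_white_mean: dict[str, float]
    reference_aec: float = DEFAULT_REFERENCE_AEC
    target_mean: float = DEFAULT_TARGET_MEAN

    def gain(self, channel: str) -> float:
        """Software gain equivalent to re-exposing at the calibrated AEC."""
        return self.exposure_scale[channel] / self.reference_aec


@dataclass(frozen=True)
class ROIBox:
    """Half-open pixel box [x0, x0+w) x [y0, y0+h), 0-based."""

    label: str
    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.width * self.height < 4:
            raise ImagingError(f"ROI {self.label!r} smaller than 4 pixels")
        if self.x0 < 0 or self.y0 < 0:
            raise ImagingError(f"ROI {self.label!r} has negative origin")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height),
                slice(self.x0, self.x0 + self.width))

    def inside(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return self.x0 + self.width <= w and self.y0 + self.height <= h

    def shifted(self, dx: int, dy: int) -> "ROIBox":
        return ROIBox(self.label, self.x0 + dx, self.y0 + dy,
                      self.width, self.height)


@dataclass(frozen=True)
class RGBMeasurement:
    """Per-ROI channel means with standard errors of the mean."""

    mean_r: float
    mean_g: float
    mean_b: float
    se_r: float
    se_g: float
    se_b: float
    n_pixels: int

    @property
    def means(self) -> tuple[float, float, float]:
        return (self.mean_r, self.mean_g, self.mean_b)

    @property
    def ses(self) -> tuple[float, float, float]:
        return (self.se_r, self.se_g, self.se_b)


@dataclass(frozen=True)
class HSVMeasurement:
    """Hue (deg), saturation and value (percent) with propagated sigmas."""

    hue: float
    saturation: float
    value: float
    sigma_h: float = 0.0
    sigma_s: float = 0.0
    sigma_v: float = 0.0
    chroma: float = 0.0
    sigma_chroma: float = 0.0


# ---------------------------------------------------------------------------
# LED exposure calibration
# ---------------------------------------------------------------------------


def compute_led_calibration(
    white_image_means: dict[str, float],
    reference_aec: float = DEFAULT_REFERENCE_AEC,
    target_mean: float = DEFAULT_TARGET_MEAN,
) -> LEDCalibration:
    """White-balance exposure calibration from a white-reference frame set.

    Each LED is operated at full power and only its exposure is adjusted,
    so the calibrated exposure for channel c is the reference exposure
    scaled by target_mean / measured_mean_c.

    Raises :class:`ImagingError` if any channel mean is not positive
    (an unlit or saturated-to-zero white frame) or outside the 8-bit range.
    """
    if not 0 < target_mean <= 255:
        raise ImagingError("target_mean must be in (0, 255]")
    if reference_aec <= 0:
        raise ImagingError("reference_aec must be positive")
    scales = {}
    means = {}
    for ch in CHANNELS:
        try:
            m = float(white_image_means[ch])
        except KeyError as exc:
            raise ImagingError(f"missing white mean for channel {ch}") from exc
        if not math.isfinite(m) or m <= 0:
            raise ImagingError(
                f"invalid white-frame mean {m!r} for channel {ch}: "
                "white reference appears unlit"
            )
        means[ch] = m
        scales[ch] = reference_aec * target_mean / m
    return LEDCalibration(
        exposure_scale=scales,
        measured_white_mean=means,
        reference_aec=reference_aec,
        target_mean=target_mean,
    )


def apply_led_calibration(image: RGBImage, cal: LEDCalibration) -> RGBImage:
    """Rescale each channel by its calibrated exposure gain, clipped to 8-bit.

    Equivalent in software to re-acquiring the frame at the calibrated
    exposure: a frame whose channel mean equals the measured white mean maps
    to the target mean.
    """
    planes = []
    for ch in CHANNELS:
        planes.append(np.clip(image.plane(ch) * cal.gain(ch), 0.0, 255.0))
    return RGBImage(*planes)


# ---------------------------------------------------------------------------
# Channel merging and flat fielding
# ---------------------------------------------------------------------------


def merge_channel_frames(frames: list[ChannelImage]) -> RGBImage:
    """Compose the three single-LED frames into one RGB image.

    Requires exactly one frame per channel with identical dimensions.
    """
    by_channel: dict[str, ChannelImage] = {}
    for f in frames:
        if f.channel in by_channel:
            raise ImagingError(f"duplicate frame for channel {f.channel}")
        by_channel[f.channel] = f
    missing = [c for c in CHANNELS if c not in by_channel]
    if missing:
        raise ImagingError(f"missing channel frame(s): {missing}")
    shapes = {by_channel[c].pixels.shape for c in CHANNELS}
    if len(shapes) != 1:
        raise ImagingError("channel frames have mismatched dimensions")
    return RGBImage(by_channel["R"].pixels, by_channel["G"].pixels,
                    by_channel["B"].pixels)


def split_channels(image: RGBImage) -> list[ChannelImage]:
    """Inverse of :func:`merge_channel_frames`."""
    return [ChannelImage(image.plane(c), c) for c in CHANNELS]


def flat_field(
    raw: RGBImage,
    flat: RGBImage,
    target_mean: float = DEFAULT_TARGET_MEAN,
) -> RGBImage:
    """Divide out the illumination field measured on the white reference.

    corrected = raw * target_mean / flat, per pixel and channel, clipped to
    [0, 255].  Zero pixels in the flat (dust, shadow) are substituted by the
    flat's channel mean and reported via a warning.
    """
    if raw.shape != flat.shape:
        raise ImagingError("raw and flat images have mismatched dimensions")
    planes = []
    n_zero = 0
    for ch in CHANNELS:
        f = flat.plane(ch)
        zeros = f == 0
        if zeros.any():
            n_zero += int(zeros.sum())
            fmean = f[~zeros].mean() if (~zeros).any() else target_mean
            f = np.where(zeros, fmean, f)
        corrected = raw.plane(ch) * target_mean / f
        n_clipped = int((corrected > 255).sum())
        if n_clipped:
            warnings.warn(
                f"flat fielding clipped {n_clipped} pixels in channel {ch}",
                stacklevel=2,
            )
        planes.append(np.clip(corrected, 0.0, 255.0))
    if n_zero:
        warnings.warn(
            f"flat image contained {n_zero} zero pixels; substituted channel means",
            stacklevel=2,
        )
    return RGBImage(*planes)


# ---------------------------------------------------------------------------
# ROI location
# ---------------------------------------------------------------------------


def locate_rois(image: RGBImage, layout) -> tuple[list[ROIBox], str | None]:
    """Place the per-well ROI boxes using the fiducial marker.

    ``layout`` is an :class:`~leadassay.config.WellLayout`.  Well offsets and
    box sizes are stored in units of the fiducial edge length relative to its
    top-left corner, which makes the geometry robust to camera distance.
    Returns the boxes and the fiducial payload string (assay metadata), or
    ``None`` for the payload if the fallback absolute coordinates were used.
    """
    from . import fiducial

    detection = fiducial.detect(image.grayscale())
    if detection is None:
        boxes = layout.absolute_boxes()
        if boxes is None:
            raise ImagingError(
                "fiducial marker not decodable and layout has no absolute "
                "ROI coordinates"
            )
        payload = None
    else:
        edge = detection.edge
        boxes = []
        for well in layout.wells:
            x0 = detection.x0 + int(round(well.dx * edge))
            y0 = detection.y0 + int(round(well.dy * edge))
            w = max(2, int(round(well.box_w * edge)))
            h = max(2, int(round(well.box_h * edge)))
            boxes.append(ROIBox(well.label, x0, y0, w, h))
        payload = detection.payload
    for box in boxes:
        if not box.inside(image.shape):
            raise ImagingError(f"ROI for well {box.label!r} lies outside image")
    return boxes, payload


# ---------------------------------------------------------------------------
# ROI statistics
# ---------------------------------------------------------------------------


def roi_color_stats(image: RGBImage, roi: ROIBox) -> RGBMeasurement:
    """Channel means over the ROI with standard errors of the mean.

    se_j = sd_j / sqrt(n_p) with the sample (ddof=1) standard deviation.
    ROIs smaller than 4 pixels are rejected: the variance estimate is
    unreliable.
    """
    if not roi.inside(image.shape):
        raise ImagingError(f"ROI {roi.label!r} lies outside the image")
    ys, xs = roi.slices()
    stats = {}
    n_p = roi.width * roi.height
    if n_p < 4:
        raise ImagingError(f"ROI {roi.label!r} has fewer than 4 pixels")
    for ch in CHANNELS:
        patch = image.plane(ch)[ys, xs].ravel()
        stats[ch] = (float(patch.mean()),
                     float(patch.std(ddof=1) / math.sqrt(n_p)))
    return RGBMeasurement(
        mean_r=stats["R"][0], mean_g=stats["G"][0], mean_b=stats["B"][0],
        se_r=stats["R"][1], se_g=stats["G"][1], se_b=stats["B"][1],
        n_pixels=n_p,
    )


# ---------------------------------------------------------------------------
# HSV decomposition
# ---------------------------------------------------------------------------


def _hsv_components(r: float, g: float, b: float) -> tuple[float, float, float, float]:
    """Hexcone conversion: hue in degrees [0,360), S and V in percent."""
    mx = max(r, g, b)
    mn = min(r, g, b)
    c = mx - mn
    v = 100.0 * mx / 255.0
    if mx == 0.0:
        return 0.0, 0.0, 0.0, 0.0
    s = 100.0 * c / mx
    if c == 0.0:
        return 0.0, s, v, c
    if mx == r:
        h = 60.0 * (((g - b) / c) % 6.0)
    elif mx == g:
        h = 60.0 * ((b - r) / c + 2.0)
    else:
        h = 60.0 * ((r - g) / c + 4.0)
    return h % 360.0, s, v, c


def rgb_to_hsv(mean_rgb: tuple[float, float, float]) -> HSVMeasurement:
    """HSV decomposition of an average ROI colour (values only, no sigmas).

    Saturation provides the largest measurable change as the biosensor's
    blue colour develops, and is the pipeline's working observable.
    """
    r, g, b = (float(x) for x in mean_rgb)
    for x in (r, g, b):
        if not (0.0 <= x <= 255.0):
            raise ImagingError(f"RGB component {x} outside [0, 255]")
    h, s, v, c = _hsv_components(r, g, b)
    return HSVMeasurement(hue=h, saturation=s, value=v, chroma=c)


def propagate_hsv_uncertainty(rgb: RGBMeasurement) -> HSVMeasurement:
    """HSV decomposition with first-order propagated uncertainties.

    Channel errors are treated as independent; the Jacobian of the hexcone
    conversion is evaluated numerically at the measured mean, on the branch
    active there.  When chroma is zero the hue derivative is singular and
    sigma_h is reported as NaN with a warning.
    """
    r, g, b = rgb.means
    if max(r, g, b) <= 0:
        raise ImagingError("HSV propagation requires a non-black mean colour")
    h, s, v, c = _hsv_components(r, g, b)

    ses = np.asarray(rgb.ses, dtype=np.float64)
    means = np.asarray(rgb.means, dtype=np.float64)

    # Central-difference Jacobian of (H, S, V, Ch) w.r.t. (R, G, B).  The
    # step is tiny relative to the 0-255 scale so branch crossings only occur
    # in genuinely degenerate configurations, handled below.
    step = 1e-5 * 255.0
    jac = np.zeros((4, 3))
    for j in range(3):
        lo = means.copy()
        hi = means.copy()
        lo[j] = max(0.0, lo[j] - step)
        hi[j] = min(255.0, hi[j] + step)
        d = hi[j] - lo[j]
        f_hi = np.array(_hsv_components(*hi))
        f_lo = np.array(_hsv_components(*lo))
        diff = f_hi - f_lo
        # hue wrap-around at 0/360
        if abs(diff[0]) > 180.0:
            diff[0] -= math.copysign(360.0, diff[0])
        jac[:, j] = diff / d

    var = jac**2 @ ses**2
    sigma_h, sigma_s, sigma_v, sigma_c = np.sqrt(var)
    if c == 0.0:
        warnings.warn(
            "chroma is zero: hue is undefined and sigma_h is reported as NaN",
            stacklevel=2,
        )
        sigma_h = SIGMA_H_UNDEFINED
    return HSVMeasurement(
        hue=h, saturation=s, value=v,
        sigma_h=float(sigma_h), sigma_s=float(sigma_s), sigma_v=float(sigma_v),
        chroma=c, sigma_chroma=float(sigma_c),
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Presentation rounding: half away from zero, as in printed tables."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)
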