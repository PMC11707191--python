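"""Square matrix fiducial marker: renderer and detector.

The sample holder carries a printed fiducial that serves two purposes: its
bounding box anchors the well ROI geometry (robust to camera placement), and
it carries a short free-text payload — assay date, device identifier, sample
origin, test configuration — recorded verbatim into the results metadata.

The marker is a GRID x GRID module square:

* ring 0 (outermost module ring): all black — detection target;
* ring 1: all white — quiet zone separating border from data;
* inner (GRID-4)^2 modules: payload bits, row-major, MSB-first, encoded as a
  2-byte big-endian length followed by UTF-8 payload bytes, zero padded.

Detection thresholds the grayscale image, finds connected dark components
(the border ring is one connected component whose bounding box is the marker
bounds), and validates the border/quiet-zone signature before decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

GRID = 25
_DATA_SIDE = GRID - 4
_CAPACITY_BYTES = (_DATA_SIDE * _DATA_SIDE) // 8  # 55 bytes incl. 2-byte length

#: Grey level separating "black" marker modules from the scene after
#: flat fielding (black modules render near 0, white near 200).
DARK_THRESHOLD = 100.0


class FiducialError(ValueError):
    """Raised for payloads that do not fit the marker capacity."""


@dataclass(frozen=True)
class FiducialDetection:
    x0: int
    y0: int
    edge: int  # side length in pixels
    payload: str


def _payload_bits(payload: str) -> np.ndarray:
    data = payload.encode("utf-8")
    if len(data) > _CAPACITY_BYTES - 2:
        raise FiducialError(
            f"payload of {len(data)} bytes exceeds marker capacity "
            f"({_CAPACITY_BYTES - 2} bytes)"
        )
    framed = len(data).to_bytes(2, "big") + data
    framed += bytes(_CAPACITY_BYTES - len(framed))
    bits = np.unpackbits(np.frombuffer(framed, dtype=np.uint8))
    return np.pad(bits, (0, _DATA_SIDE * _DATA_SIDE - bits.size))


def render(payload: str, module_px: int = 3) -> np.ndarray:
    """Render the marker as a (GRID*module_px)^2 float image, 0=black 255=white."""
    if module_px < 1:
        raise FiducialError("module_px must be >= 1")
    modules = np.full((GRID, GRID), 255.0)
    modules[0, :] = modules[-1, :] = modules[:, 0] = modules[:, -1] = 0.0
    bits = _payload_bits(payload).reshape(_DATA_SIDE, _DATA_SIDE)
    inner = np.where(bits == 1, 0.0, 255.0)
    modules[2:-2, 2:-2] = inner
    return np.kron(modules, np.ones((module_px, module_px)))


def _sample_modules(gray: np.ndarray, x0: int, y0: int, edge: int) -> np.ndarray:
    """Boolean GRID x GRID grid of 'module is dark', sampled at module centres."""
    centres = (np.arange(GRID) + 0.5) * edge / GRID
    ys = np.clip(np.round(y0 + centres - 0.5).astype(int), 0, gray.shape[0] - 1)
    xs = np.clip(np.round(x0 + centres - 0.5).astype(int), 0, gray.shape[1] - 1)
    return gray[np.ix_(ys, xs)] < DARK_THRESHOLD


def _decode_grid(dark: np.ndarray) -> str | None:
    ring0 = np.concatenate([dark[0, :], dark[-1, :], dark[1:-1, 0], dark[1:-1, -1]])
    ring1 = np.concatenate([dark[1, 1:-1], dark[-2, 1:-1],
                            dark[2:-2, 1], dark[2:-2, -2]])
    if ring0.mean() < 0.95 or ring1.mean() > 0.05:
        return None
    bits = dark[2:-2, 2:-2].ravel().astype(np.uint8)
    data = np.packbits(bits).tobytes()[:_CAPACITY_BYTES]
    length = int.from_bytes(data[:2], "big")
    if length > _CAPACITY_BYTES - 2:
        return None
    try:
        return data[2:2 + length].decode("utf-8")
    except UnicodeDecodeError:
        return None


def detect(gray: np.ndarray) -> FiducialDetection | None:
    """Find and decode the marker in a grayscale image, or return None.

    Candidate components are connected dark regions whose bounding box is
    approximately square and at least GRID pixels on a side; the largest
    candidate whose border/quiet-zone signature validates wins.
    """
    gray = np.asarray(gray, dtype=np.float64)
    labels, n = ndimage.label(gray < DARK_THRESHOLD)
    if n == 0:
        return None
    objects = ndimage.find_objects(labels)
    candidates = []
    for sl in objects:
        if sl is None:
            continue
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if min(h, w) < GRID or abs(h - w) > 0.15 * max(h, w):
            continue
        candidates.append((h * w, sl))
    for _, sl in sorted(candidates, reverse=True, key=lambda t: t[0]):
        y0, x0 = sl[0].start, sl[1].start
        edge = max(sl[0].stop - y0, sl[1].stop - x0)
        dark = _sample_modules(gray, x0, y0, edge)
        payload = _decode_grid(dark)
        if payload is not None:
            return FiducialDetection(x0=x0, y0=y0, edge=edge, payload=payload)
    return None
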