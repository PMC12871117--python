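"""Corridor frame classification: the camera half of the double ID system.

A lightweight pixel-threshold pipeline: each grayscale frame is binarized at
a fixed luminance threshold (dark animals on a light corridor by default,
polarity invertible for light-coated animals), and animal-pixel counts inside
predefined rectangular regions of interest classify each corridor zone as
empty, occupied by a single animal, or occupied by multiple animals.  The
"multiple" label is triggered by pixel count alone; connected-component
counting exists only as a test oracle.

Also included: a centroid tracker over the largest connected component and a
synthetic frame generator that records its ground truth, used for fixtures
and calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .records import ConfigError, ValidationError


@dataclass
class Frame:
    """An 8-bit grayscale frame; origin top-left, x rightward, y downward."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("frame pixels must be a non-empty 2-D array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RoiSpec:
    """A corridor zone: rectangle [x0, x1) x [y0, y1) with count thresholds.

    ``t_single`` and ``t_multi`` are animal-pixel counts: below ``t_single``
    the zone is empty, in ``[t_single, t_multi)`` a single animal, at or
    above ``t_multi`` multiple animals.
    """

    zone_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    t_single: int
    t_multi: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValidationError(f"zone {self.zone_id}: empty rectangle")
        area = (self.x1 - self.x0) * (self.y1 - self.y0)
        if not 0 < self.t_single < self.t_multi <= area:
            raise ValidationError(
                f"zone {self.zone_id}: need 0 < t_single < t_multi <= area ({area})"
            )

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class ZoneState:
    zone_id: str
    count: int
    label: str  # empty | single | multiple


def binarize(frame: Frame | np.ndarray, threshold: float, polarity: str = "dark") -> np.ndarray:
    """Return a boolean mask of animal pixels.

    ``polarity="dark"`` classifies pixels strictly below the threshold as
    animal; ``"bright"`` inverts the comparison (animal iff above threshold).
    """
    if not 0 <= threshold <= 255:
        raise ConfigError("threshold must be in [0, 255]")
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if polarity == "dark":
        return pixels < threshold
    if polarity == "bright":
        return pixels > threshold
    raise ConfigError(f"unknown polarity {polarity!r}")


def classify_zones(mask: np.ndarray, rois: list[RoiSpec]) -> list[ZoneState]:
    """Classify each ROI from its animal-pixel count."""
    _warn_on_overlap(rois)
    h, w = mask.shape
    out: list[ZoneState] = []
    for roi in rois:
        if roi.x1 > w or roi.y1 > h:
            raise ValidationError(f"zone {roi.zone_id} lies outside the frame")
        count = int(mask[roi.y0 : roi.y1, roi.x0 : roi.x1].sum())
        if count < roi.t_single:
            label = "empty"
        elif count < roi.t_multi:
            label = "single"
        else:
            label = "multiple"
        out.append(ZoneState(zone_id=roi.zone_id, count=count, label=label))
    return out


def _warn_on_overlap(rois: list[RoiSpec]) -> None:
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            if a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1:
                warnings.warn(f"ROIs {a.zone_id} and {b.zone_id} overlap", stacklevel=3)
                return


def default_rois(width: int = 640, height: int = 480, animal_area: int = 1200) -> list[RoiSpec]:
    """Three corridor zones (home side, inter-door gap, box side).

    Thresholds are calibrated from the nominal single-animal pixel area:
    ``t_single = 0.3 x`` and ``t_multi = 1.7 x`` that area.
    """
    thirds = [0, width // 3, 2 * width // 3, width]
    names = ["home_side", "door_gap", "box_side"]
    t_single = max(1, int(0.3 * animal_area))
    t_multi = int(1.7 * animal_area)
    return [
        RoiSpec(names[i], thirds[i], 0, thirds[i + 1], height, t_single, t_multi)
        for i in range(3)
    ]


def count_components(mask: np.ndarray, min_area: int = 1) -> int:
    """Connected-component count (8-connectivity); test oracle, not the classifier."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if min_area <= 1:
        return int(n)
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=int), labels, range(1, n + 1))
    return int(np.sum(np.asarray(areas) >= min_area))


def track_centroid(
    frames: list[Frame] | list[np.ndarray], threshold: float, polarity: str = "dark"
) -> list[tuple[float, float] | None]:
    """Per frame, the (x, y) centroid of the largest connected animal blob.

    Returns ``None`` for frames with no animal pixels.  All frames must share
    dimensions.
    """
    shapes = {(_as_array(f).shape) for f in frames}
    if len(shapes) > 1:
        raise ValidationError("all frames must share dimensions")
    out: list[tuple[float, float] | None] = []
    for f in frames:
        mask = binarize(_as_array(f), threshold, polarity)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            out.append(None)
            continue
        areas = ndimage.sum_labels(np.ones_like(mask, dtype=int), labels, range(1, n + 1))
        biggest = int(np.argmax(areas)) + 1
        cy, cx = ndimage.center_of_mass(mask, labels, biggest)
        out.append((float(cx), float(cy)))
    return out


def _as_array(f: Frame | np.ndarray) -> np.ndarray:
    return f.pixels if isinstance(f, Frame) else np.asarray(f)


@dataclass(frozen=True)
class Blob:
    """Ground-truth ellipse: center (cx, cy), radii (rx, ry), fill intensity."""

    cx: float
    cy: float
    rx: float
    ry: float
    intensity: int


@dataclass
class SynthFrame:
    frame: Frame
    blobs: list[Blob] = field(default_factory=list)

    def zone_blob_counts(self, rois: list[RoiSpec]) -> dict[str, int]:
        """Ground-truth number of blob centers falling inside each ROI."""
        counts = {roi.zone_id: 0 for roi in rois}
        for blob in self.blobs:
            for roi in rois:
                if roi.x0 <= blob.cx < roi.x1 and roi.y0 <= blob.cy < roi.y1:
                    counts[roi.zone_id] += 1
        return counts


def synth_frame(
    width: int,
    height: int,
    blobs: list[tuple[float, float, float, float, int]],
    background: int = 220,
    noise_sd: float = 3.0,
    seed: int | np.random.Generator = 0,
) -> SynthFrame:
    """Render a grayscale frame of elliptical blobs on a noisy background.

    Reproducible given the seed; the returned :class:`SynthFrame` carries the
    ground-truth blob list for oracle checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.full((height, width), float(background))
    yy, xx = np.mgrid[0:height, 0:width]
    blob_records: list[Blob] = []
    for cx, cy, rx, ry, intensity in blobs:
        if not (0 <= cx < width and 0 <= cy < height):
            raise ValidationError("blob center must lie inside the frame")
        inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        img[inside] = intensity
        blob_records.append(Blob(cx, cy, rx, ry, int(intensity)))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SynthFrame(frame=Frame(img), blobs=blob_records)


def write_png(frame: Frame, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(frame.pixels, mode="L").save(path, format="PNG")
    return path


def read_png(path: str | Path) -> Frame:
    with Image.open(path) as img:
        return Frame(np.asarray(img.convert("L"), dtype=np.uint8))
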