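"""Projected canopy size from top-view chlorophyll-fluorescence images.

Chlorophyll-fluorescence imaging excites the crop with blue actinic light
and records the emission through a long-pass filter, so the canopy is the
only bright structure in the frame.  Canopy area is therefore measured by
plain intensity thresholding: every pixel brighter than the threshold —
outside the reserved scale-marker region — contributes its full
``(cm/px)**2`` to the projected canopy size (PCS, cm**2).  No sub-pixel
weighting and, by default, no morphological cleanup is applied; an
optional small-object filter is available for speckled images.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImageGeometry",
    "FluorescenceImage",
    "CanopyMask",
    "PCSRecord",
    "MissingScaleError",
    "threshold_mask",
    "calibrate_scale",
    "measure_pcs",
    "read_image",
    "segment_directory",
]

#: columns of a PCS series table, one row per (plant, imaging day)
PCS_SERIES_COLUMNS = [
    "plant_id",
    "day",
    "pcs_cm2",
    "pixel_count",
    "cm_per_pixel",
    "threshold",
]

_FILENAME_RE = re.compile(r"plant(?P<plant>\d+)_day(?P<day>\d+)\.(png|tif|tiff)$")


class MissingScaleError(ValueError):
    """No scale marker found in the image's reserved marker region."""


@dataclass(frozen=True)
class ImageGeometry:
    """Layout of a fluorescence frame: resolution, scale and marker position.

    The scale marker is a high-intensity horizontal bar of known physical
    length drawn in a reserved strip at the bottom of the frame; the strip
    is always excluded from canopy measurement.
    """

    height: int = 896
    width: int = 896
    cm_per_pixel: float = 0.06
    marker_length_cm: float = 3.0
    marker_rows: tuple[int, int] = (878, 888)  # [start, stop) pixel rows
    marker_col_start: int = 10
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("image must be at least 64x64 pixels")
        if self.cm_per_pixel <= 0:
            raise ValueError("cm_per_pixel must be positive")
        if not (0 <= self.marker_rows[0] < self.marker_rows[1] <= self.height):
            raise ValueError("marker rows outside image")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def marker_length_px(self) -> int:
        return int(round(self.marker_length_cm / self.cm_per_pixel))

    def marker_mask(self) -> np.ndarray:
        """Boolean mask of the reserved marker strip (True inside)."""
        m = np.zeros((self.height, self.width), dtype=bool)
        m[self.marker_rows[0] : self.marker_rows[1], :] = True
        return m


@dataclass
class FluorescenceImage:
    """A single-channel fluorescence frame plus the metadata needed to
    convert pixel counts to physical area."""

    pixels: np.ndarray
    plant_id: int | None = None
    day: int | None = None
    geometry: ImageGeometry | None = None
    cm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("fluorescence image must be 2-D and >= 64x64")
        if px.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.pixels = px

    @property
    def scale(self) -> float:
        """cm per pixel, from the explicit field or the geometry."""
        if self.cm_per_pixel is not None:
            return self.cm_per_pixel
        if self.geometry is not None:
            return self.geometry.cm_per_pixel
        raise MissingScaleError(
            "no cm_per_pixel available; calibrate from the scale marker first"
        )


@dataclass(frozen=True)
class CanopyMask:
    """Binary canopy mask congruent with its source image."""

    mask: np.ndarray
    pixel_count: int
    threshold: float

    def __post_init__(self) -> None:
        if int(self.mask.sum()) != self.pixel_count:
            raise ValueError("pixel_count inconsistent with mask")


@dataclass(frozen=True)
class PCSRecord:
    plant_id: int | None
    day: int | None
    pcs_cm2: float
    pixel_count: int
    cm_per_pixel: float
    threshold: float

    def __post_init__(self) -> None:
        if self.pcs_cm2 < 0:
            raise ValueError("pcs_cm2 must be >= 0")


def _auto_threshold(pixels: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(pixels))


def threshold_mask(
    image: FluorescenceImage,
    threshold: float | None,
    min_object_px: int = 0,
) -> CanopyMask:
    """Threshold a fluorescence frame into a canopy mask.

    A pixel is canopy when its intensity is strictly greater than
    ``threshold`` and it lies outside the reserved marker strip.
    ``threshold=None`` selects Otsu's method on the whole frame.
    ``min_object_px`` optionally removes connected components smaller
    than the given pixel count (speckle removal; off by default).
    """
    px = image.pixels
    max_ok = image.geometry.max_intensity if image.geometry else np.iinfo(px.dtype).max if px.dtype.kind == "u" else px.max()
    if threshold is None:
        threshold = _auto_threshold(px)
    if threshold < 0 or threshold > max_ok:
        raise ValueError(f"threshold {threshold} outside representable range [0, {max_ok}]")
    mask = px > threshold
    if image.geometry is not None:
        mask &= ~image.geometry.marker_mask()
    if min_object_px > 0:
        from skimage import measure

        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_object_px
        keep[0] = False
        mask = keep[labels]
    return CanopyMask(mask=mask, pixel_count=int(mask.sum()), threshold=float(threshold))


def calibrate_scale(
    image: FluorescenceImage,
    marker_length_cm: float | None = None,
    threshold: float | None = None,
) -> float:
    """cm-per-pixel from the scale marker drawn in the reserved strip.

    The marker is located as the longest above-threshold horizontal run
    within the strip; its pixel extent divides the known physical length.
    Raises :class:`MissingScaleError` when no run is found.
    """
    if image.geometry is None:
        raise MissingScaleError("image carries no geometry; marker region unknown")
    geom = image.geometry
    if marker_length_cm is None:
        marker_length_cm = geom.marker_length_cm
    if threshold is None:
        threshold = geom.max_intensity / 2
    strip = image.pixels[geom.marker_rows[0] : geom.marker_rows[1], :]
    profile = (strip > threshold).any(axis=0)
    if not profile.any():
        raise MissingScaleError("no above-threshold run in the marker region")
    # longest run of consecutive True values
    padded = np.concatenate(([0], profile.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    run_lengths = edges[1::2] - edges[::2]
    extent = int(run_lengths.max())
    return marker_length_cm / extent


def measure_pcs(
    image: FluorescenceImage,
    threshold: float | None,
    min_object_px: int = 0,
) -> PCSRecord:
    """Measure projected canopy size: mask pixel count times (cm/px)**2."""
    mask = threshold_mask(image, threshold, min_object_px=min_object_px)
    scale = image.scale
    return PCSRecord(
        plant_id=image.plant_id,
        day=image.day,
        pcs_cm2=mask.pixel_count * scale**2,
        pixel_count=mask.pixel_count,
        cm_per_pixel=scale,
        threshold=mask.threshold,
    )


def read_image(path: str | Path, geometry: ImageGeometry | None = None) -> FluorescenceImage:
    """Read one ``plant{ID}_day{D}.png`` (or .tif) frame with metadata."""
    path = Path(path)
    m = _FILENAME_RE.search(path.name)
    plant_id = int(m.group("plant")) if m else None
    day = int(m.group("day")) if m else None
    return FluorescenceImage(
        pixels=np.asarray(iio.imread(path)),
        plant_id=plant_id,
        day=day,
        geometry=geometry,
    )


def segment_directory(
    images_dir: str | Path,
    threshold: float | None,
    geometry: ImageGeometry | None = None,
    min_object_px: int = 0,
    calibrate: bool = False,
) -> pd.DataFrame:
    """Segment every ``plant*_day*`` image in a directory into a PCS table.

    With ``calibrate=True`` the cm/px scale is measured from each frame's
    marker instead of taken from the geometry.
    """
    rows = []
    paths = sorted(Path(images_dir).iterdir())
    for path in paths:
        if not _FILENAME_RE.search(path.name):
            continue
        img = read_image(path, geometry=geometry)
        if calibrate:
            img.cm_per_pixel = calibrate_scale(img)
        rec = measure_pcs(img, threshold, min_object_px=min_object_px)
        rows.append(
            (rec.plant_id, rec.day, rec.pcs_cm2, rec.pixel_count, rec.cm_per_pixel, rec.threshold)
        )
    if not rows:
        warnings.warn(f"no plant*_day* images found in {images_dir}")
    df = pd.DataFrame(rows, columns=PCS_SERIES_COLUMNS)
    return df.sort_values(["plant_id", "day"], ignore_index=True)
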