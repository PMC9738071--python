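"""Radiograph raster, ROI-specification and feature-table input/output.

Images are single-channel 8- or 16-bit PNG/TIFF rasters. ROI specifications
travel in JSON sidecar files next to each frame; feature tables are plain
UTF-8 CSV with a ``.`` decimal separator. Coordinates are 0-based and
row-major, rectangles are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon as _sk_polygon

from .errors import (
    EmptyRoiError,
    PeriocortError,
    RoiBoundsError,
    RoiSizeWarning,
    UnsupportedImageError,
)

#: ROI pixel count mandated by the acquisition protocol.
PROTOCOL_ROI_PIXELS = 1500

ROI_LABELS = ("peri_implant", "reference")
TIMEPOINTS = ("initial", "y5", "y10")


@dataclass
class RadiographImage:
    """A 2-D integer gray-level raster with acquisition metadata.

    Parameters
    ----------
    pixels
        Non-negative integer gray levels, shape ``(rows, cols)``.
    bit_depth
        8 or 16; every pixel must be below ``2**bit_depth``.
    pixel_spacing_mm
        Physical pixel pitch. Stored as metadata only: every texture
        feature in this package is a pixel-lattice quantity.
    image_id
        Free-form identifier, usually the file stem.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_spacing_mm: float = 0.07
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise UnsupportedImageError("pixels must form a non-empty 2-D matrix")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise UnsupportedImageError(
                f"pixels must be integer-typed, got {self.pixels.dtype}"
            )
        if self.bit_depth not in (8, 16):
            raise UnsupportedImageError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.min() < 0 or self.pixels.max() >= 2**self.bit_depth:
            raise UnsupportedImageError(
                f"pixel values out of range for {self.bit_depth}-bit image"
            )
        if not self.pixel_spacing_mm > 0:
            raise UnsupportedImageError("pixel_spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class RoiSpec:
    """Region-of-interest specification.

    Exactly one of ``rect``, ``polygon_vertices`` or ``mask`` must be set.
    ``rect`` is ``(r0, c0, r1, c1)`` with half-open row/column ranges;
    ``polygon_vertices`` is an ``(n, 2)`` array of (row, col) vertices;
    ``mask`` is a boolean array of the full image shape.
    """

    roi_id: str
    label: str = "peri_implant"
    timepoint: str = "initial"
    rect: tuple[int, int, int, int] | None = None
    polygon_vertices: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise PeriocortError(f"unknown ROI label {self.label!r}; use one of {ROI_LABELS}")
        if self.timepoint not in TIMEPOINTS:
            raise PeriocortError(
                f"unknown timepoint {self.timepoint!r}; use one of {TIMEPOINTS}"
            )
        n_geoms = sum(g is not None for g in (self.rect, self.polygon_vertices, self.mask))
        if n_geoms != 1:
            raise PeriocortError("exactly one of rect/polygon_vertices/mask must be given")
        if self.polygon_vertices is not None:
            self.polygon_vertices = np.asarray(self.polygon_vertices, dtype=float)
            if self.polygon_vertices.ndim != 2 or self.polygon_vertices.shape[1] != 2:
                raise PeriocortError("polygon_vertices must be an (n, 2) array")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)


def read_image(path: str | Path) -> RadiographImage:
    """Read a single-channel 8/16-bit PNG or TIFF raster.

    No rescaling is applied: pixel values arrive exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedImageError(
            f"{path.name}: unsupported pixel dtype {arr.dtype}; need uint8 or uint16"
        )
    return RadiographImage(pixels=arr, bit_depth=depth, image_id=path.stem)


def write_image(image: RadiographImage, path: str | Path) -> None:
    """Write a radiograph as PNG or TIFF, preserving bit depth."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), image.pixels.astype(dtype))


def resolve_roi(image: RadiographImage, spec: RoiSpec) -> np.ndarray:
    """Resolve an ROI specification to an ordered (row, col) pixel array.

    Returns an ``(n, 2)`` int64 array in row-major order. A
    :class:`~periocort.errors.RoiSizeWarning` is emitted when the pixel
    count differs from the 1500-pixel acquisition protocol; this is a
    protocol check, not a hard constraint.
    """
    n_rows, n_cols = image.shape
    if spec.rect is not None:
        r0, c0, r1, c1 = spec.rect
        if not (0 <= r0 < r1 <= n_rows and 0 <= c0 < c1 <= n_cols):
            raise RoiBoundsError(
                f"ROI {spec.roi_id!r}: rectangle {spec.rect} outside image {image.shape}"
            )
        rr, cc = np.mgrid[r0:r1, c0:c1]
        pixels = np.column_stack([rr.ravel(), cc.ravel()])
    elif spec.polygon_vertices is not None:
        verts = spec.polygon_vertices
        if (
            verts[:, 0].min() < 0
            or verts[:, 1].min() < 0
            or verts[:, 0].max() > n_rows - 1
            or verts[:, 1].max() > n_cols - 1
        ):
            raise RoiBoundsError(f"ROI {spec.roi_id!r}: polygon outside image {image.shape}")
        rr, cc = _sk_polygon(verts[:, 0], verts[:, 1], shape=image.shape)
        pixels = np.column_stack([rr, cc])
        order = np.lexsort((pixels[:, 1], pixels[:, 0]))
        pixels = pixels[order]
    else:
        mask = spec.mask
        assert mask is not None
        if mask.shape != image.shape:
            raise RoiBoundsError(
                f"ROI {spec.roi_id!r}: mask shape {mask.shape} != image shape {image.shape}"
            )
        rr, cc = np.nonzero(mask)
        pixels = np.column_stack([rr, cc])
    if len(pixels) == 0:
        raise EmptyRoiError(f"ROI {spec.roi_id!r} resolves to zero pixels")
    if len(pixels) != PROTOCOL_ROI_PIXELS:
        warnings.warn(
            f"ROI {spec.roi_id!r} has {len(pixels)} pixels, protocol expects "
            f"{PROTOCOL_ROI_PIXELS}",
            RoiSizeWarning,
            stacklevel=2,
        )
    return pixels.astype(np.int64)


# ---------------------------------------------------------------------------
# ROI JSON sidecars


def write_roi_specs(specs: Sequence[RoiSpec], path: str | Path) -> None:
    """Write ROI specifications to a JSON sidecar (rectangles/polygons only)."""
    entries = []
    for s in specs:
        entry: dict = {"roi_id": s.roi_id, "label": s.label, "timepoint": s.timepoint}
        if s.rect is not None:
            entry["rect"] = [int(v) for v in s.rect]
        elif s.polygon_vertices is not None:
            entry["polygon"] = [[float(r), float(c)] for r, c in s.polygon_vertices]
        else:
            raise PeriocortError("mask ROIs cannot be serialized to a JSON sidecar")
        entries.append(entry)
    Path(path).write_text(json.dumps(entries, indent=1) + "\n")


def read_roi_specs(path: str | Path) -> list[RoiSpec]:
    """Read ROI specifications from a JSON sidecar."""
    path = Path(path)
    entries = json.loads(path.read_text())
    specs = []
    for entry in entries:
        kwargs: dict = {
            "roi_id": entry["roi_id"],
            "label": entry.get("label", "peri_implant"),
            "timepoint": entry.get("timepoint", "initial"),
        }
        if "rect" in entry:
            kwargs["rect"] = tuple(int(v) for v in entry["rect"])
        elif "polygon" in entry:
            kwargs["polygon_vertices"] = np.asarray(entry["polygon"], dtype=float)
        elif "mask" in entry:
            mask_img = iio.imread(path.parent / entry["mask"])
            kwargs["mask"] = np.asarray(mask_img) > 0
        else:
            raise PeriocortError(f"ROI entry {entry.get('roi_id')!r} lacks a geometry")
        specs.append(RoiSpec(**kwargs))
    return specs


# ---------------------------------------------------------------------------
# Feature tables

FEATURE_COLUMNS = (
    "roi_id",
    "label",
    "timepoint",
    "mean_od",
    "difentr_avg",
    "lngremph_avg",
    "ci",
)


def write_feature_table(rows: Iterable[tuple], path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write (RoiSpec-or-id, TextureFeatures) pairs as a CSV feature table.

    Column order is fixed (:data:`FEATURE_COLUMNS`); floats are printed with
    12 significant digits so a write/read round-trip is lossless at that
    precision. ``header_lines`` are prepended as ``#``-prefixed comments.
    """
    rows = list(rows)
    if not rows:
        raise PeriocortError("refusing to write an empty feature table")
    lines = [f"# {h}" for h in header_lines]
    lines.append(",".join(FEATURE_COLUMNS))
    for meta, feats in rows:
        if isinstance(meta, RoiSpec):
            roi_id, label, timepoint = meta.roi_id, meta.label, meta.timepoint
        else:
            roi_id, label, timepoint = meta
        values = [feats.mean_od, feats.difentr_avg, feats.lngremph_avg, feats.ci]
        cells = [roi_id, label, timepoint] + [
            "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.12g}"
            for v in values
        ]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path):
    """Read a feature table back into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, comment="#")
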