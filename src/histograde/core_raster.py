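"""Raster carriers and per-region descriptors.

Every pipeline stage works on plain ``numpy`` arrays:

* ``GrayImage``  -- 2-D ``uint8`` array, intensities in [0, 255]
* ``RGBImage``   -- 3-D ``uint8`` array of shape (H, W, 3)
* ``BinaryMask`` -- 2-D ``bool`` array
* ``LabelMap``   -- 2-D non-negative ``int`` array, 0 = background,
  labels contiguous 1..L

Geometry conventions used throughout the package: coordinates are
0-based ``(row, col)``; areas and perimeters are pixel counts; ellipse
angles are degrees measured counter-clockwise from the image x-axis
(columns increasing rightwards, rows increasing downwards, i.e. the
mathematical angle of the displayed image), normalised to [-90, 90).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "RegionRecord",
    "read_rgb",
    "write_mask",
    "write_labels",
    "write_region_csv",
    "red_channel",
    "label_components",
    "region_properties",
    "inner_boundary",
    "perimeter_pixels",
    "ellipse_from_moments",
]

# 4- and 8-connectivity structuring elements for component labelling.
_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class RegionRecord:
    """Geometric/intensity descriptor of one labelled component.

    ``ellipse_major``/``ellipse_minor`` are the full axis lengths (px) of
    the ellipse with the same second-order central moments as the region;
    ``circularity`` is the MOR metric, filled in by the circularity
    module (``nan`` until computed).
    """

    label: int
    area: int
    centroid: tuple[float, float]
    perimeter: int
    mean_intensity: float
    intensity_mode: int
    ellipse_center: tuple[float, float]
    ellipse_major: float
    ellipse_minor: float
    ellipse_angle: float
    circularity: float = field(default=float("nan"))

    @property
    def diameter(self) -> float:
        """Nucleus diameter: mean of the two ellipse axis lengths."""
        return 0.5 * (self.ellipse_major + self.ellipse_minor)


def read_rgb(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an 8-bit RGB array (H, W, 3).

    Grayscale inputs are replicated across channels, alpha is dropped,
    16-bit inputs are rescaled onto [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - decoding failures vary by plugin
        raise ValueError(f"cannot decode image file: {path}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"not an RGB-convertible image: shape {arr.shape}")
    arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) / 65535.0 * 255.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as PNG; 16-bit when more than 255 labels."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 255:
        iio.imwrite(Path(path), labels.astype(np.uint16))
    else:
        iio.imwrite(Path(path), labels.astype(np.uint8))


_CSV_HEADER = [
    "label", "area", "centroid_row", "centroid_col", "perimeter",
    "mean_intensity", "intensity_mode", "ellipse_center_row",
    "ellipse_center_col", "ellipse_major", "ellipse_minor",
    "ellipse_angle", "circularity",
]


def write_region_csv(path: str | Path, records: list[RegionRecord]) -> None:
    """Write one CSV row per region (documented header, fixed precision)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for r in records:
            writer.writerow([
                r.label, r.area,
                f"{r.centroid[0]:.4f}", f"{r.centroid[1]:.4f}",
                r.perimeter, f"{r.mean_intensity:.4f}", r.intensity_mode,
                f"{r.ellipse_center[0]:.4f}", f"{r.ellipse_center[1]:.4f}",
                f"{r.ellipse_major:.4f}", f"{r.ellipse_minor:.4f}",
                f"{r.ellipse_angle:.4f}", f"{r.circularity:.6f}",
            ])


def red_channel(img: np.ndarray) -> np.ndarray:
    """Return the R plane of an RGB image unchanged."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return img[:, :, 0]


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected foreground components (labels 1..L, background 0)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, _ = ndimage.label(np.asarray(mask, bool), structure=struct)
    return labels


def inner_boundary(mask: np.ndarray) -> np.ndarray:
    """8-connected inner boundary: foreground pixels with a 4-neighbour
    in the background (or on the image edge)."""
    mask = np.asarray(mask, bool)
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT4, border_value=0)
    return mask & ~eroded


def perimeter_pixels(mask: np.ndarray) -> int:
    """Perimeter as the count of inner-boundary pixels."""
    return int(inner_boundary(mask).sum())


def ellipse_from_moments(
    rows: np.ndarray, cols: np.ndarray
) -> tuple[tuple[float, float], float, float, float]:
    """Equivalent-ellipse of a pixel set from second-order central moments.

    Returns ``(center(row, col), major, minor, angle_deg)`` with full axis
    lengths (4 * sqrt(eigenvalue), the same normalisation scikit-image
    uses) and the angle convention of this module.  Angles of regions
    whose moment matrix is isotropic are reported as 0.0 (orientation is
    undefined by symmetry).
    """
    rows = np.asarray(rows, np.float64)
    cols = np.asarray(cols, np.float64)
    n = rows.size
    cr, cc = rows.mean(), cols.mean()
    # y measured upwards so the angle is counter-clockwise on screen
    x = cols - cc
    y = -(rows - cr)
    mxx = float(x @ x) / n
    myy = float(y @ y) / n
    mxy = float(x @ y) / n
    common = np.sqrt(max((mxx - myy) ** 2 + 4.0 * mxy * mxy, 0.0))
    l1 = 0.5 * (mxx + myy + common)
    l2 = 0.5 * (mxx + myy - common)
    major = 4.0 * np.sqrt(max(l1, 0.0))
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    if common < 1e-12:
        angle = 0.0
    else:
        angle = float(np.degrees(0.5 * np.arctan2(2.0 * mxy, mxx - myy)))
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return (float(cr), float(cc)), float(major), float(minor), float(angle)


def _intensity_mode(values: np.ndarray) -> int:
    counts = np.bincount(values.ravel(), minlength=256)
    return int(counts.argmax())  # argmax ties break to the smallest value


def region_properties(labels: np.ndarray, intensity: np.ndarray) -> list[RegionRecord]:
    """One :class:`RegionRecord` per label, in increasing label order.

    The equivalent ellipse comes from second-order central moments, the
    intensity mode is the most frequent 8-bit value (ties to the smallest
    value) and the perimeter counts inner-boundary pixels.
    """
    labels = np.asarray(labels)
    intensity = np.asarray(intensity)
    if labels.shape != intensity.shape:
        raise ValueError("labels and intensity must share dimensions")
    n_labels = int(labels.max(initial=0))
    if n_labels == 0:
        return []
    records: list[RegionRecord] = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n_labels + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        sub = labels[sl] == lab
        rows, cols = np.nonzero(sub)
        rows_g = rows + sl[0].start
        cols_g = cols + sl[1].start
        vals = intensity[sl][sub]
        center, major, minor, angle = ellipse_from_moments(rows_g, cols_g)
        records.append(RegionRecord(
            label=lab,
            area=int(rows.size),
            centroid=(float(rows_g.mean()), float(cols_g.mean())),
            perimeter=perimeter_pixels(sub),
            mean_intensity=float(vals.mean()),
            intensity_mode=_intensity_mode(vals),
            ellipse_center=center,
            ellipse_major=major,
            ellipse_minor=minor,
            ellipse_angle=angle,
        ))
    return records
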