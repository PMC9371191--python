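"""Nuclei extraction: size partition, watershed clump splitting, filtering.

The binarized foreground is partitioned by size against the dominant
nucleus scale ``lambda_n``: specks far below nucleus area are noise,
components far above it are clumps of touching nuclei.  Clumps are split
by a marker-controlled watershed on the negated Euclidean distance
transform (distance peaks = nucleus cores), the split pieces are fused
with the single-nucleus components, and the candidates are filtered by

* a size window ``T_lambda = [round(lambda_n / 2), lambda_2]`` on the
  inscribed-disk radius (``lambda_2`` is the secondary granulometric
  scale; fallback ``2 * lambda_n`` when none exists), and
* a circularity threshold ``T_c = mu_c - sigma_c`` over the MOR values
  of the size-filtered candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from . import morphology
from .circularity import mor
from .contrast import binarize_nuclei
from .core_raster import RegionRecord, label_components, red_channel, region_properties

__all__ = [
    "SizePartition",
    "WatershedResult",
    "NucleiFilter",
    "component_scale",
    "partition_by_size",
    "split_clumps",
    "segment_nuclei",
]

# h-maxima suppression depth for watershed markers, as a fraction of
# lambda_n.  Touching nuclei of radius ~lambda_n meet at a distance-
# transform saddle only ~1-1.5 px below their peaks; a quarter-scale
# depth keeps those splits while still merging raster noise peaks.
H_MAXIMA_FRACTION = 0.25
# A secondary granulometric peak is only trusted as the upper size bound
# when it carries a meaningful fraction of the main peak's mass;
# otherwise the argmax over the tail is pure noise and would collapse
# the size window.  Fallback: 2 * lambda_n.
LAMBDA2_RELEVANCE = 0.05


@dataclass
class SizePartition:
    """Foreground split into noise / single nuclei / clumps label maps."""

    small: np.ndarray
    medium: np.ndarray
    clumps: np.ndarray


@dataclass
class WatershedResult:
    labels: np.ndarray
    basin_counts: dict[int, int]


@dataclass
class NucleiFilter:
    """The size window and circularity threshold actually applied."""

    t_lambda: tuple[int, int]
    t_c: float
    mu_c: float
    sigma_c: float


def component_scale(component_mask: np.ndarray) -> int:
    """Size of a component as its largest inscribed-disk radius.

    Computed as the maximum of the Euclidean distance transform inside
    the component, rounded to the nearest integer.
    """
    mask = np.asarray(component_mask, bool)
    if not mask.any():
        raise ValueError("empty component")
    dist = ndimage.distance_transform_edt(np.pad(mask, 1))
    return int(np.floor(dist.max() + 0.5))


def partition_by_size(mask: np.ndarray, lambda_n: int) -> SizePartition:
    """Partition foreground components by area against the nucleus scale.

    A component is *small* (noise) when its area is below that of the
    disk of radius ``lambda_n / 2``, a *clump* when above 1.5x the area
    of the disk of radius ``lambda_n``, *medium* (single nucleus)
    otherwise.  The area reading catches fused same-radius nuclei whose
    inscribed radius alone would still look like one nucleus; the union
    of two overlapping nucleus-sized disks always stays below twice a
    single disk's area, so the clump bound must sit below 2x.  Routing a
    large single nucleus to the watershed is harmless (one basin).
    """
    if lambda_n < 1:
        raise ValueError("lambda_n must be >= 1")
    labels = label_components(mask, connectivity=8)
    n = int(labels.max(initial=0))
    small = np.zeros_like(labels)
    medium = np.zeros_like(labels)
    clumps = np.zeros_like(labels)
    if n == 0:
        return SizePartition(small, medium, clumps)
    lo = morphology.disk_area(lambda_n / 2.0)
    hi = 1.5 * morphology.disk_area(float(lambda_n))
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    for lab, area in zip(range(1, n + 1), areas):
        sel = labels == lab
        if area < lo:
            small[sel] = lab
        elif area > hi:
            clumps[sel] = lab
        else:
            medium[sel] = lab
    return SizePartition(small, medium, clumps)


def split_clumps(clumps: np.ndarray, lambda_n: int) -> WatershedResult:
    """Split clumped nuclei by marker-controlled watershed.

    Markers are the regional maxima of the in-clump Euclidean distance
    transform after h-maxima suppression with depth
    ``max(1, lambda_n * H_MAXIMA_FRACTION)``; flooding runs on the
    negated distance transform, restricted to the clump.  Every clump
    yields at least one basin.
    """
    clumps = np.asarray(clumps)
    mask = clumps > 0
    out = np.zeros(clumps.shape, dtype=np.int32)
    basin_counts: dict[int, int] = {}
    if not mask.any():
        return WatershedResult(out, basin_counts)
    h = max(1.0, lambda_n * H_MAXIMA_FRACTION)
    next_label = 1
    objects = ndimage.find_objects(clumps)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = clumps[sl] == lab
        padded = np.pad(sub, 1)
        dist = ndimage.distance_transform_edt(padded)
        peaks = h_maxima(dist, h)
        markers, n_markers = ndimage.label(peaks, structure=np.ones((3, 3), int))
        if n_markers == 0:
            markers = padded.astype(np.int32)
            n_markers = 1
        basins = watershed(-dist, markers=markers, mask=padded)
        basins = basins[1:-1, 1:-1]
        seen = np.unique(basins[basins > 0])
        remap = {int(b): next_label + i for i, b in enumerate(seen)}
        next_label += len(seen)
        view = out[sl]
        for b, new in remap.items():
            view[basins == b] = new
        basin_counts[lab] = len(seen)
    return WatershedResult(out, basin_counts)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Make the label set contiguous 1..L preserving order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1)
    return lut[labels]


def segment_nuclei(
    img: np.ndarray,
    max_scale: int = 20,
    split: bool = True,
    lambda_n: int | None = None,
) -> tuple[np.ndarray, list[RegionRecord], NucleiFilter]:
    """Full nuclei segmentation of an RGB histopathology image.

    Runs the red channel through granulometric scale estimation,
    tile-local binarization, size partitioning, watershed clump
    splitting (disable with ``split=False``), and the ``T_lambda`` /
    ``T_c`` filters.  Returns the final contiguous label map, the
    per-nucleus records (with MOR circularity filled in) and the filter
    actually applied.
    """
    red = red_channel(img)
    if lambda_n is None:
        lambda_n, spectrum = morphology.nucleus_scale(red, max_scale=max_scale)
    else:
        _, spectrum = morphology.nucleus_scale(red, max_scale=max_scale)
    lambda_2 = 2 * lambda_n
    if spectrum.lambda_2 is not None:
        peak = float(spectrum.values.max())
        second = float(spectrum.values[spectrum.scales == spectrum.lambda_2][0])
        if second >= LAMBDA2_RELEVANCE * peak:
            lambda_2 = spectrum.lambda_2

    mask = binarize_nuclei(red, lambda_n)
    empty_filter = NucleiFilter(
        t_lambda=(max(1, round(lambda_n / 2)), lambda_2),
        t_c=float("nan"), mu_c=float("nan"), sigma_c=float("nan"),
    )
    if not mask.any():
        warnings.warn("no foreground after binarization; empty segmentation")
        return np.zeros(mask.shape, np.int32), [], empty_filter

    part = partition_by_size(mask, lambda_n)
    candidates = np.zeros(mask.shape, dtype=np.int32)
    medium_labels = np.unique(part.medium)
    medium_labels = medium_labels[medium_labels > 0]
    next_label = 1
    for lab in medium_labels:
        candidates[part.medium == lab] = next_label
        next_label += 1
    if split:
        ws = split_clumps(part.clumps, lambda_n)
        sel = ws.labels > 0
        candidates[sel] = ws.labels[sel] + (next_label - 1)
    else:
        clump_labels = np.unique(part.clumps)
        for lab in clump_labels[clump_labels > 0]:
            candidates[part.clumps == lab] = next_label
            next_label += 1
    candidates = _relabel(candidates)

    # size window on inscribed-disk radius
    lo = max(1, round(lambda_n / 2))
    t_lambda = (lo, int(lambda_2))
    objects = ndimage.find_objects(candidates)
    keep_size: list[int] = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        scale = component_scale(candidates[sl] == lab)
        if lo <= scale <= lambda_2:
            keep_size.append(lab)
    if not keep_size:
        warnings.warn("no candidates inside the size window; empty segmentation")
        return np.zeros(mask.shape, np.int32), [], empty_filter

    # circularity threshold from the size-filtered candidate set
    mors = {}
    for lab in keep_size:
        sl = objects[lab - 1]
        mors[lab] = mor(candidates[sl] == lab)
    values = np.array(list(mors.values()))
    mu_c = float(values.mean())
    sigma_c = float(values.std())
    t_c = mu_c - sigma_c
    kept = [lab for lab in keep_size if mors[lab] >= t_c]

    final = np.zeros(mask.shape, dtype=np.int32)
    for new, lab in enumerate(kept, start=1):
        sl = objects[lab - 1]
        view = final[sl]
        view[candidates[sl] == lab] = new
    records = region_properties(final, red)
    mor_by_new = {new: mors[lab] for new, lab in enumerate(kept, start=1)}
    for rec in records:
        rec.circularity = mor_by_new[rec.label]
    nfilter = NucleiFilter(t_lambda=t_lambda, t_c=t_c, mu_c=mu_c, sigma_c=sigma_c)
    return final, records, nfilter
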