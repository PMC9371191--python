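"""Flat morphology with Euclidean-disk structuring elements and granulometry.

The structuring element of scale ``lam`` is the rasterised disk
``{(dr, dc) : dr^2 + dc^2 <= lam^2}``.  Erosion is the windowed minimum
over that support with the outside of the image treated as white (255);
dilation is the windowed maximum with the outside treated as black (0).
Opening and closing are the usual compositions.

For speed the disk operators are decomposed into per-row 1-D running
min/max filters (the disk is the union of its horizontal chords), which
is exact: results are pixel-identical to a direct windowed min/max over
the disk support.

The pattern spectrum PS(lam) measures, per scale, the fraction of the
image's accumulated gray mass removed between the openings at ``lam``
and ``lam + step``:

    PS(lam) = (mes(opening(I, lam)) - mes(opening(I, lam + step))) / mes(I)

where ``mes`` is the sum of gray levels.  Bright structure of radius r
is removed by openings of scale just above r, so PS peaks at the
dominant grain radius.  Nuclei are *dark* in the red channel, so
:func:`nucleus_scale` inverts the image before the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "disk",
    "erode",
    "dilate",
    "opening",
    "closing",
    "PatternSpectrum",
    "pattern_spectrum",
    "nucleus_scale",
]


def disk(radius: float) -> np.ndarray:
    """Boolean footprint of the Euclidean disk of the given radius."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    return (dr * dr + dc * dc) <= radius * radius


def disk_area(radius: float) -> int:
    """Pixel count of the rasterised disk of the given radius."""
    return int(disk(radius).sum())


def _chord_halfwidths(radius: int) -> np.ndarray:
    dy = np.arange(-radius, radius + 1)
    return np.floor(np.sqrt(radius * radius - dy * dy)).astype(int)


def _disk_rank_filter(img: np.ndarray, radius: int, maximum: bool) -> np.ndarray:
    """Exact disk min/max filter via per-chord 1-D running filters."""
    pad = np.uint8(0) if maximum else np.uint8(255)
    filt = ndimage.maximum_filter1d if maximum else ndimage.minimum_filter1d
    reduce_ = np.maximum if maximum else np.minimum
    h = img.shape[0]
    out = None
    halfwidths = _chord_halfwidths(radius)
    # cache row filters per distinct chord width
    by_width: dict[int, np.ndarray] = {}
    for dy, hw in zip(range(-radius, radius + 1), halfwidths):
        w = 2 * int(hw) + 1
        if w not in by_width:
            by_width[w] = filt(img, size=w, axis=1, mode="constant", cval=pad)
        rowf = by_width[w]
        # out[i, j] op= rowf[i + dy, j]; rows shifted outside the image
        # contribute the padding value and can be skipped.
        if dy >= 0:
            src = rowf[dy:, :]
            dst_rows = slice(0, h - dy)
        else:
            src = rowf[:h + dy, :]
            dst_rows = slice(-dy, h)
        if out is None:
            out = np.full_like(img, pad)
        out[dst_rows] = reduce_(out[dst_rows], src)
    assert out is not None
    return out


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return img.astype(np.uint8, copy=False)


def erode(img: np.ndarray, lam: int) -> np.ndarray:
    """Grayscale erosion by the disk of radius ``lam`` (border = white)."""
    img = _check_image(img)
    if lam < 1:
        raise ValueError("scale must be >= 1")
    return _disk_rank_filter(img, int(lam), maximum=False)


def dilate(img: np.ndarray, lam: int) -> np.ndarray:
    """Grayscale dilation by the disk of radius ``lam`` (border = black)."""
    img = _check_image(img)
    if lam < 1:
        raise ValueError("scale must be >= 1")
    return _disk_rank_filter(img, int(lam), maximum=True)


def opening(img: np.ndarray, lam: int) -> np.ndarray:
    """Morphological opening: dilation after erosion."""
    return dilate(erode(img, lam), lam)


def closing(img: np.ndarray, lam: int) -> np.ndarray:
    """Morphological closing: erosion after dilation."""
    return erode(dilate(img, lam), lam)


@dataclass
class PatternSpectrum:
    """Granulometric response over scales 1..max_scale.

    ``lambda_n`` is the dominant grain scale (argmax, ties to the
    smallest scale); ``lambda_2`` is the secondary scale, the argmax of
    PS restricted to scales above ``lambda_n`` (``None`` when no
    positive mass remains there).
    """

    scales: np.ndarray
    values: np.ndarray
    lambda_n: int
    lambda_2: int | None

    def as_rows(self) -> list[tuple[int, float]]:
        return [(int(s), float(v)) for s, v in zip(self.scales, self.values)]


def pattern_spectrum(img: np.ndarray, max_scale: int = 20, step: int = 1) -> PatternSpectrum:
    """Pattern spectrum of a grains-bright image.

    Requires ``max_scale >= 2`` and a non-empty image (``mes(I) > 0``).
    """
    img = _check_image(img)
    if max_scale < 2:
        raise ValueError("max_scale must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    total = float(img.sum(dtype=np.float64))
    if total <= 0.0:
        raise ValueError("pattern spectrum undefined for an all-zero image (mes(I) = 0)")
    scales = np.arange(1, max_scale + 1, step)
    mes = np.empty(scales.size + 1, dtype=np.float64)
    # Rasterised Euclidean disks do not form an exact sieve (an opening at
    # scale lam+1 can retain corner pixels the opening at lam removed), so
    # each opening is applied to the previous scale's result.  The cascade
    # makes mes non-increasing in lam, hence PS >= 0, at the cost of at
    # most one scale step of bias in the peak location.
    current = img
    for i, lam in enumerate([*scales, scales[-1] + step]):
        current = opening(current, int(lam))
        mes[i] = current.sum(dtype=np.float64)
    values = (mes[:-1] - mes[1:]) / total
    lambda_n = int(scales[int(np.argmax(values))])
    above = scales > lambda_n
    lambda_2: int | None = None
    if above.any() and values[above].max() > 0.0:
        lambda_2 = int(scales[above][int(np.argmax(values[above]))])
    return PatternSpectrum(scales=scales, values=values, lambda_n=lambda_n, lambda_2=lambda_2)


def nucleus_scale(img_red: np.ndarray, max_scale: int = 20, step: int = 1) -> tuple[int, PatternSpectrum]:
    """Dominant nucleus radius from granulometry of the inverted red channel.

    Nuclei are dark in R; the granulometric grains must be bright, so the
    analysis runs on ``255 - I``.  Returns ``(lambda_n, spectrum)``.
    """
    img_red = _check_image(img_red)
    inverted = (255 - img_red.astype(np.int16)).astype(np.uint8)
    ps = pattern_spectrum(inverted, max_scale=max_scale, step=step)
    if float(ps.values.max(initial=0.0)) <= 0.0:
        raise ValueError("degenerate pattern spectrum: no positive granulometric mass")
    return ps.lambda_n, ps
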