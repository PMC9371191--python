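"""Tubule detection: lumina candidates, gland retrieval, and the Cs score.

A tubule is a bright lumen ringed by nuclei.  Detection proceeds in
three stages:

1. *Lumina candidates* — bright components of the connective tissue
   (image minus nuclei), thresholded at the connective-tissue mean
   intensity, then filtered by area (``U_a = 2 * mean nucleus area``),
   by the mode-below-mean intensity criterion, and by border contact.
2. *Gland retrieval* — each candidate is grown by unit-disk dilations;
   the coefficient of variation ``CV = sigma/mu`` of the intensities
   inside the grown region rises while dark nuclei are being absorbed
   and falls once only tissue is added, so growth stops at the first CV
   decrease after a rise (cap ``3 * lambda_n`` steps).  A candidate is
   kept when ``CV > d``, where ``d = mu_gamma - mu_l`` compares the
   normalised mean of the added annulus with the lumen mean.
3. *Scoring* — the convex hull of the gland's nucleus centroids plus
   the lumen centroid is fitted with a moment ellipse and compared with
   the lumen's own ellipse.  The tubule-likelihood score is

       Cs = T_nuclei + l_cdis + l_theta + l_A

   (nucleus-count penalty, centroid distance in px, orientation
   difference in degrees, asymmetry percent); candidates with
   ``Cs <= 60`` are called tubules.  The score deliberately mixes units,
   as calibrated at 200x magnification; ``scale`` rescales ``l_cdis``
   for other magnifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as draw_polygon

from .core_raster import (
    RegionRecord, ellipse_from_moments, label_components, perimeter_pixels,
    red_channel, region_properties,
)
from .segmentation import NucleiFilter, segment_nuclei

__all__ = [
    "LuminaCandidate",
    "GlandRegion",
    "TubuleAssessment",
    "lumina_candidates",
    "retrieve_gland",
    "assess_tubule",
    "detect_tubules",
]

CS_THRESHOLD = 60.0
T_NUCLEI_PENALTY = 10.0
DILATION_CAP_FACTOR = 3       # cap = 3 * lambda_n unit dilations
ON_AXIS_TOLERANCE = 0.5       # px; nuclei this close to the axis are excluded
# minor/major above this ratio means the moment ellipse is effectively a
# circle: its orientation is undefined by symmetry and reported as 0
CIRCULAR_AXIS_RATIO = 0.9

# gland growth structuring elements: alternating cross / square dilations
# approximate Euclidean (octagonal) growth; pure cross steps would grow an
# L1 ball and under-reach nuclei along diagonals
_CROSS = ndimage.generate_binary_structure(2, 1)
_SQUARE = ndimage.generate_binary_structure(2, 2)


@dataclass
class LuminaCandidate:
    label: int
    mask: np.ndarray
    area: int
    perimeter: int
    centroid: tuple[float, float]
    mean_intensity: float
    intensity_mode: int
    touches_border: bool
    status: str = "active"     # active / rejected_area / rejected_mode /
                               # rejected_border / rejected_cv


@dataclass
class GlandRegion:
    region: np.ndarray
    cv_history: list[float]
    final_cv: float
    mu_gamma: float            # normalised mean of the added annulus
    mu_l: float                # normalised lumen mean
    d: float
    nuclei_inside: list[int]
    d_n: float                 # mean nucleus diameter in the gland
    d_min: float               # min pairwise centroid distance
    t_n: float                 # minimum nucleus count for a full ring


@dataclass
class TubuleAssessment:
    candidate: LuminaCandidate
    gland: GlandRegion | None
    l_cdis: float = float("nan")
    l_theta: float = float("nan")
    n_upper: int = 0
    n_lower: int = 0
    symmetry: float = 0.0
    l_a: float = 100.0
    penalty: float = T_NUCLEI_PENALTY
    cs: float = float("inf")
    is_tubule: bool = False
    lumina_in_hull: bool = False


def lumina_candidates(
    img_red: np.ndarray,
    nuclei_labels: np.ndarray,
    nuclei_records: list[RegionRecord],
) -> list[LuminaCandidate]:
    """Bright connective-tissue components as lumina candidates.

    Components failing the area criterion ``U_a = 2 * mean nucleus
    area``, the mode-below-mean criterion, or touching the image border
    keep a rejected status instead of being dropped, so the CSV report
    can account for every candidate.
    """
    if not nuclei_records:
        raise ValueError("no nuclei records: mean nucleus area (Arean) undefined")
    img_red = np.asarray(img_red)
    connective = nuclei_labels == 0
    threshold = float(img_red[connective].mean())
    cand_mask = connective & (img_red > threshold)
    labels = label_components(cand_mask, connectivity=8)
    u_a = 2.0 * float(np.mean([r.area for r in nuclei_records]))
    out: list[LuminaCandidate] = []
    for rec in region_properties(labels, img_red):
        sel = labels == rec.label
        rows, cols = np.nonzero(sel)
        touches = bool(
            rows.min() == 0 or cols.min() == 0
            or rows.max() == sel.shape[0] - 1 or cols.max() == sel.shape[1] - 1
        )
        cand = LuminaCandidate(
            label=rec.label, mask=sel, area=rec.area,
            perimeter=rec.perimeter, centroid=rec.centroid,
            mean_intensity=rec.mean_intensity,
            intensity_mode=rec.intensity_mode, touches_border=touches,
        )
        if rec.area < u_a:
            cand.status = "rejected_area"
        elif rec.intensity_mode < rec.mean_intensity:
            cand.status = "rejected_mode"
        elif touches:
            cand.status = "rejected_border"
        out.append(cand)
    return out


def retrieve_gland(
    candidate: LuminaCandidate,
    img_red: np.ndarray,
    nuclei_labels: np.ndarray,
    nuclei_records: list[RegionRecord],
    lambda_n: int,
) -> GlandRegion | None:
    """Grow a lumina candidate into its gland by CV-stopped dilation.

    Returns the gland, or ``None`` (and marks the candidate
    ``rejected_cv``) when the CV test ``CV > d`` fails.
    """
    img_red = np.asarray(img_red)
    lumen = candidate.mask

    def cv_of(region: np.ndarray) -> float:
        vals = img_red[region].astype(np.float64)
        m = vals.mean()
        return float(vals.std() / m) if m > 0 else 0.0

    region = lumen
    cv_history = [cv_of(region)]
    cap = DILATION_CAP_FACTOR * lambda_n
    risen = False
    for step in range(cap):
        grown = ndimage.binary_dilation(
            region, structure=_CROSS if step % 2 else _SQUARE)
        cv = cv_of(grown)
        if cv > cv_history[-1]:
            risen = True
        elif risen:
            break  # first decrease after a rise: gland complete
        region = grown
        cv_history.append(cv)
    final_cv = cv_history[-1]

    annulus = region & ~lumen
    mu_gamma = float(img_red[annulus].mean()) / 255.0 if annulus.any() else 0.0
    mu_l = float(img_red[lumen].mean()) / 255.0
    d = mu_gamma - mu_l
    if not final_cv > d:
        candidate.status = "rejected_cv"
        return None

    inside: list[int] = []
    for rec in nuclei_records:
        r, c = int(round(rec.centroid[0])), int(round(rec.centroid[1]))
        if 0 <= r < region.shape[0] and 0 <= c < region.shape[1] and region[r, c]:
            inside.append(rec.label)
    by_label = {rec.label: rec for rec in nuclei_records}
    if inside:
        d_n = float(np.mean([by_label[lab].diameter for lab in inside]))
    else:
        d_n = float(np.mean([rec.diameter for rec in nuclei_records]))
    if len(inside) >= 2:
        pts = np.array([by_label[lab].centroid for lab in inside])
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        d_min = float(dist[np.triu_indices(len(inside), k=1)].min())
    else:
        d_min = d_n  # degenerate glands: avoid a blow-up in T_n
    t_n = (candidate.perimeter / 2.0) / (d_n + d_min)
    return GlandRegion(
        region=region, cv_history=cv_history, final_cv=final_cv,
        mu_gamma=mu_gamma, mu_l=mu_l, d=d, nuclei_inside=inside,
        d_n=d_n, d_min=d_min, t_n=t_n,
    )


def _angle_difference(a: float, b: float) -> float:
    diff = abs(a - b) % 180.0
    return min(diff, 180.0 - diff)


def _hull_ellipse(points_rc: np.ndarray, shape: tuple[int, int]):
    """Moment ellipse of the filled convex hull of (row, col) points."""
    try:
        hull = ConvexHull(points_rc[:, ::-1])  # (x, y) for qhull
    except QhullError:
        return None
    verts = points_rc[hull.vertices]
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    if rr.size < 3:
        return None
    return ellipse_from_moments(rr, cc), (rr, cc)


def assess_tubule(
    gland: GlandRegion,
    candidate: LuminaCandidate,
    nuclei_records: list[RegionRecord],
    scale: float = 1.0,
) -> TubuleAssessment:
    """Score a retrieved gland with the Cs metric.

    With fewer than 3 nucleus centroids the hull is degenerate: the
    assessment is still returned, with ``S = 0`` and the nucleus-count
    penalty applied.
    """
    by_label = {rec.label: rec for rec in nuclei_records}
    pts = np.array([by_label[lab].centroid for lab in gland.nuclei_inside],
                   dtype=np.float64).reshape(-1, 2)
    penalty = T_NUCLEI_PENALTY if len(gland.nuclei_inside) < gland.t_n else 0.0
    assessment = TubuleAssessment(candidate=candidate, gland=gland, penalty=penalty)

    lum_center, lum_major, lum_minor, lum_angle = _ellipse_of_mask(candidate.mask)
    if lum_major > 0 and lum_minor / lum_major > CIRCULAR_AXIS_RATIO:
        lum_angle = 0.0

    hull_input = np.vstack([pts, [candidate.centroid]])
    hull = _hull_ellipse(hull_input, candidate.mask.shape) if len(pts) >= 3 else None
    if hull is None:
        assessment.l_cdis = 0.0
        assessment.l_theta = 0.0
        assessment.symmetry = 0.0
        assessment.l_a = 100.0
        assessment.penalty = T_NUCLEI_PENALTY
    else:
        (ec_center, ec_major, ec_minor, ec_angle), (hr, hc) = hull
        if ec_major > 0 and ec_minor / ec_major > CIRCULAR_AXIS_RATIO:
            ec_angle = 0.0
        assessment.l_cdis = scale * float(np.hypot(
            ec_center[0] - lum_center[0], ec_center[1] - lum_center[1]))
        assessment.l_theta = _angle_difference(ec_angle, lum_angle)
        # split nucleus centroids by signed distance to the EC major axis
        theta = np.radians(ec_angle)
        # axis direction in (col, row-up) space; normal likewise
        nx, ny = -np.sin(theta), np.cos(theta)
        dx = pts[:, 1] - ec_center[1]
        dy = -(pts[:, 0] - ec_center[0])
        signed = dx * nx + dy * ny
        n_u = int((signed > ON_AXIS_TOLERANCE).sum())
        n_l = int((signed < -ON_AXIS_TOLERANCE).sum())
        assessment.n_upper, assessment.n_lower = n_u, n_l
        s = min(n_u, n_l) / max(n_u, n_l) if max(n_u, n_l) > 0 else 0.0
        assessment.symmetry = s
        assessment.l_a = (1.0 - s) * 100.0
        hull_mask = np.zeros(candidate.mask.shape, bool)
        hull_mask[hr, hc] = True
        assessment.lumina_in_hull = bool(candidate.mask[~hull_mask].sum() == 0)
    assessment.cs = (assessment.penalty + assessment.l_cdis
                     + assessment.l_theta + assessment.l_a)
    assessment.is_tubule = assessment.cs <= CS_THRESHOLD
    return assessment


def _ellipse_of_mask(mask: np.ndarray):
    rows, cols = np.nonzero(mask)
    return ellipse_from_moments(rows, cols)


def detect_tubules(
    img: np.ndarray,
    cs_threshold: float = CS_THRESHOLD,
    scale: float = 1.0,
    max_scale: int = 20,
) -> tuple[list[TubuleAssessment], int, "_PipelineState"]:
    """Full tubule detection on an RGB image.

    Returns the assessments of all glands that survived retrieval, the
    tubule count at the Cs threshold, and the intermediate pipeline
    state (nuclei labels/records/filter and candidate list) for
    reporting.
    """
    from . import morphology

    red = red_channel(img)
    labels, records, nfilter = segment_nuclei(img, max_scale=max_scale)
    lambda_n, _ = morphology.nucleus_scale(red, max_scale=max_scale)
    assessments: list[TubuleAssessment] = []
    candidates: list[LuminaCandidate] = []
    if records:
        candidates = lumina_candidates(red, labels, records)
        for cand in candidates:
            if cand.status != "active":
                continue
            gland = retrieve_gland(cand, red, labels, records, lambda_n)
            if gland is None:
                continue
            a = assess_tubule(gland, cand, records, scale=scale)
            a.is_tubule = a.cs <= cs_threshold
            assessments.append(a)
    count = sum(a.is_tubule for a in assessments)
    state = _PipelineState(labels, records, nfilter, candidates, lambda_n)
    return assessments, count, state


@dataclass
class _PipelineState:
    nuclei_labels: np.ndarray
    nuclei_records: list[RegionRecord]
    nuclei_filter: NucleiFilter
    candidates: list[LuminaCandidate]
    lambda_n: int
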