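"""Synthetic H&E-like phantoms with exact ground truth.

The generator emulates the red-channel appearance the pipeline relies
on: dark elliptical nuclei on brighter stroma, bright lumina ellipses
ringed by nuclei (tubules), bright bare gaps with no ring (tubule
negatives), per-image stain shift and additive Gaussian noise.  Green
and blue channels are derived from red for visual plausibility only.

Grade presets follow the histological trends of the Nottingham system:
from healthy tissue to grade 3, nuclear size and pleomorphism (radius
spread, eccentricity) increase, nuclei become darker (hyperchromasia
proxy), and tubule density falls to zero.

Lumina are drawn as moderately elongated ellipses (aspect ratio sampled
in [1.25, 1.6]) with the nucleus ring on a concentric ellipse: real
duct cross-sections are rarely perfect circles, and an elongated lumen
gives the gland envelope a well-defined orientation.

Everything is deterministic given ``spec.seed``: identical specs yield
bit-identical images and truth structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

__all__ = ["PhantomSpec", "PhantomImage", "TubuleTruth", "generate_phantom", "grade_preset", "GRADES"]

GRADES = ("healthy", "G1", "G2", "G3")

PLACEMENT_RETRIES = 1000
NUCLEUS_SEPARATION = 2        # min clearance between non-clumped nuclei, px
RING_GAP = 2                  # clearance between lumen edge and ring nuclei, px
RIM_WIDTH = 2                 # epithelial rim around lumina/gaps, px
RIM_DARKENING = 20.0          # rim intensity drop below stroma


@dataclass
class PhantomSpec:
    """Study conditions for one phantom image."""

    width: int = 384
    height: int = 384
    n_nuclei: int = 120                   # scattered nuclei (ring nuclei extra)
    nucleus_radius_mean: float = 4.0
    nucleus_radius_std: float = 0.4
    nucleus_eccentricity_max: float = 1.2  # max major/minor axis ratio
    clump_fraction: float = 0.0
    n_tubules: int = 0
    tubule_lumina_radius: float = 14.0    # geometric-mean lumen semi-axis
    ring_count: int = 10
    ring_symmetry_noise: float = 0.15     # angular jitter, fraction of spacing
    n_bare_gaps: int = 0
    nucleus_r_mean: float = 95.0          # red-channel means
    stroma_r_mean: float = 200.0
    lumina_r_mean: float = 252.0   # near-saturated, as empty slide space
    stain_shift_sigma: float = 6.0        # per-image shift of all means
    noise_sigma: float = 5.0
    grade: str | None = None
    seed: int = 0


@dataclass
class TubuleTruth:
    lumina_mask: np.ndarray
    ring_labels: list[int]
    center: tuple[float, float]


@dataclass
class PhantomImage:
    rgb: np.ndarray
    nuclei_truth: np.ndarray
    tubule_truth: list[TubuleTruth]
    gap_truth: list[np.ndarray] = field(default_factory=list)
    grade: str | None = None
    spec: PhantomSpec | None = None


def grade_preset(grade: str, seed: int = 0) -> PhantomSpec:
    """Phantom conditions for one differentiation grade.

    Healthy tissue: uniform round nuclei, many tubules.  G1 to G3:
    nuclear size/spread and eccentricity increase, nuclei darken, and
    tubule count decreases to zero (replaced by bare bright gaps).
    """
    presets = {
        "healthy": dict(n_nuclei=110, nucleus_radius_mean=4.0, nucleus_radius_std=0.4,
                        nucleus_eccentricity_max=1.2, n_tubules=6, n_bare_gaps=0,
                        nucleus_r_mean=95.0),
        "G1": dict(n_nuclei=110, nucleus_radius_mean=4.5, nucleus_radius_std=0.8,
                   nucleus_eccentricity_max=1.4, n_tubules=6, n_bare_gaps=2,
                   nucleus_r_mean=90.0),
        "G2": dict(n_nuclei=120, nucleus_radius_mean=5.5, nucleus_radius_std=1.5,
                   nucleus_eccentricity_max=1.8, n_tubules=3, n_bare_gaps=4,
                   nucleus_r_mean=80.0),
        "G3": dict(n_nuclei=130, nucleus_radius_mean=7.0, nucleus_radius_std=2.2,
                   nucleus_eccentricity_max=2.0, n_tubules=0, n_bare_gaps=6,
                   nucleus_r_mean=70.0),
    }
    if grade not in presets:
        raise ValueError(f"unknown grade {grade!r}; expected one of {GRADES}")
    return PhantomSpec(grade=grade, seed=seed, **presets[grade])


class _Placer:
    """Dart-throwing placement with an occupancy mask."""

    def __init__(self, shape: tuple[int, int], rng: np.random.Generator):
        self.shape = shape
        self.rng = rng
        self.occupied = np.zeros(shape, dtype=bool)

    def footprint(self, r0, c0, a, b, rot, margin=0.0):
        rr, cc = draw_ellipse(r0, c0, b + margin, a + margin,
                              shape=self.shape, rotation=rot)
        return rr, cc

    def try_place(self, a, b, rot, margin, border):
        h, w = self.shape
        for _ in range(PLACEMENT_RETRIES):
            r0 = self.rng.uniform(border, h - border)
            c0 = self.rng.uniform(border, w - border)
            rr, cc = self.footprint(r0, c0, a, b, rot, margin)
            if rr.size and not self.occupied[rr, cc].any():
                return r0, c0
        return None

    def stamp(self, r0, c0, a, b, rot, margin=0.0):
        rr, cc = self.footprint(r0, c0, a, b, rot, margin)
        self.occupied[rr, cc] = True
        return rr, cc


def _sample_nucleus(spec: PhantomSpec, rng: np.random.Generator):
    rho = max(2.0, rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_std))
    ecc = rng.uniform(1.0, spec.nucleus_eccentricity_max)
    a = rho * np.sqrt(ecc)   # semi-major
    b = rho / np.sqrt(ecc)   # semi-minor
    rot = rng.uniform(0.0, np.pi)
    return a, b, rot


def generate_phantom(spec: PhantomSpec) -> PhantomImage:
    """Render one phantom and its exact ground truth.

    Raises ``RuntimeError`` when dart-throwing cannot place the requested
    structure counts (reporting the counts achieved).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    shift = rng.normal(0.0, spec.stain_shift_sigma)
    base = np.full((h, w), spec.stroma_r_mean + shift, dtype=np.float64)

    placer = _Placer((h, w), rng)
    nuclei_truth = np.zeros((h, w), dtype=np.int32)
    tubule_truth: list[TubuleTruth] = []
    gap_truth: list[np.ndarray] = []
    next_label = 1

    def stamp_nucleus(r0, c0, a, b, rot, *, margin=NUCLEUS_SEPARATION):
        nonlocal next_label
        rr, cc = placer.footprint(r0, c0, a, b, rot)
        jitter = rng.normal(0.0, 4.0)
        base[rr, cc] = spec.nucleus_r_mean + shift + jitter
        nuclei_truth[rr, cc] = next_label
        placer.stamp(r0, c0, a, b, rot, margin=margin)
        next_label += 1
        return next_label - 1

    # lumen-bearing structures first (they claim the most room)
    ring_radius_pad = (RING_GAP + 2.0 * spec.nucleus_radius_mean
                       + NUCLEUS_SEPARATION)

    def place_lumen(with_ring: bool):
        aspect = rng.uniform(1.25, 1.6)
        la = spec.tubule_lumina_radius * np.sqrt(aspect)
        lb = spec.tubule_lumina_radius / np.sqrt(aspect)
        rot = rng.uniform(0.0, np.pi)
        pad = ring_radius_pad if with_ring else RING_GAP + NUCLEUS_SEPARATION
        border = la + pad + 4
        pos = placer.try_place(la, lb, rot, pad, border)
        if pos is None:
            return None
        r0, c0 = pos
        # slightly darker epithelial rim around the lumen: separates the
        # bright interior from stroma speckle and mimics the cell layer
        # bounding real ducts
        rim_rr, rim_cc = placer.footprint(r0, c0, la + RIM_WIDTH, lb + RIM_WIDTH, rot)
        base[rim_rr, rim_cc] = spec.stroma_r_mean + shift - RIM_DARKENING
        rr, cc = placer.footprint(r0, c0, la, lb, rot)
        # lumina are empty space: near-saturated and unaffected by the
        # per-image stain shift
        base[rr, cc] = spec.lumina_r_mean
        lmask = np.zeros((h, w), dtype=bool)
        lmask[rr, cc] = True
        placer.stamp(r0, c0, la, lb, rot, margin=pad if not with_ring else RING_GAP)
        return r0, c0, la, lb, rot, lmask

    for _ in range(spec.n_tubules):
        placed = place_lumen(with_ring=True)
        if placed is None:
            raise RuntimeError(
                f"could not place tubule {len(tubule_truth) + 1} of {spec.n_tubules}")
        r0, c0, la, lb, rot, lmask = placed
        ring_labels = []
        spacing = 2.0 * np.pi / spec.ring_count
        cos_r, sin_r = np.cos(rot), np.sin(rot)
        for k in range(spec.ring_count):
            ang = k * spacing + rng.uniform(-1, 1) * spec.ring_symmetry_noise * spacing
            na, nb, nrot = _sample_nucleus(spec, rng)
            ra = la + RING_GAP + (na + nb) / 2.0
            rb = lb + RING_GAP + (na + nb) / 2.0
            # parametric point on the concentric ellipse, rotated
            ex, ey = ra * np.cos(ang), rb * np.sin(ang)
            nr = r0 + ey * cos_r - ex * sin_r
            nc = c0 + ex * cos_r + ey * sin_r
            lab = stamp_nucleus(nr, nc, na, nb, nrot)
            ring_labels.append(lab)
        # reserve the whole gland disc so scattered nuclei stay outside
        placer.stamp(r0, c0, la, lb, rot, margin=ring_radius_pad)
        tubule_truth.append(TubuleTruth(lmask, ring_labels, (r0, c0)))

    for i in range(spec.n_bare_gaps):
        placed = place_lumen(with_ring=False)
        if placed is None:
            raise RuntimeError(f"could not place gap {i + 1} of {spec.n_bare_gaps}")
        gap_truth.append(placed[5])

    # scattered nuclei (with optional intentional clumps)
    placed_count = 0
    while placed_count < spec.n_nuclei:
        na, nb, nrot = _sample_nucleus(spec, rng)
        pos = placer.try_place(na, nb, nrot, NUCLEUS_SEPARATION, max(na, nb) + 2)
        if pos is None:
            raise RuntimeError(
                f"could not place nucleus {placed_count + 1} of {spec.n_nuclei}")
        r0, c0 = pos
        # remember this nucleus' claimed zone: a clump partner may overlap it
        own_rr, own_cc = placer.footprint(r0, c0, na, nb, nrot, NUCLEUS_SEPARATION)
        stamp_nucleus(r0, c0, na, nb, nrot)
        placed_count += 1
        if placed_count < spec.n_nuclei and rng.uniform() < spec.clump_fraction:
            # partner overlapping its neighbour: centres ~1.5 mean radii apart
            pa, pb, prot = _sample_nucleus(spec, rng)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            d = 0.75 * ((na + nb) / 2.0 + (pa + pb) / 2.0)
            pr, pc = r0 + d * np.sin(ang), c0 + d * np.cos(ang)
            rr, cc = placer.footprint(pr, pc, pa, pb, prot, NUCLEUS_SEPARATION)
            free = ~placer.occupied
            free[own_rr, own_cc] = True
            m = max(pa, pb) + 2
            if rr.size and free[rr, cc].all() and m < pr < h - m and m < pc < w - m:
                stamp_nucleus(pr, pc, pa, pb, prot)
                placed_count += 1

    noisy = base + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    red = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)
    green = np.clip(red.astype(np.float64) * 0.55 + 15.0, 0, 255).astype(np.uint8)
    blue = np.clip(red.astype(np.float64) * 0.75 + 40.0, 0, 255).astype(np.uint8)
    rgb = np.stack([red, green, blue], axis=-1)
    return PhantomImage(rgb=rgb, nuclei_truth=nuclei_truth,
                        tubule_truth=tubule_truth, gap_truth=gap_truth,
                        grade=spec.grade, spec=spec)


def truth_feature_pool(phantom: PhantomImage) -> "pd.DataFrame":
    """Per-nucleus ground-truth features of a phantom.

    Returns a DataFrame with columns ``area``, ``mean_intensity`` and
    ``circularity`` (MOR), one row per planted nucleus, computed from
    the truth label map and the rendered red channel.  This is the
    sampling pool for grade-level subset analyses.
    """
    import pandas as pd
    from scipy import ndimage

    from .circularity import mor

    labels = phantom.nuclei_truth
    red = phantom.rgb[:, :, 0]
    rows = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        rows.append({
            "label": lab,
            "area": int(sub.sum()),
            "mean_intensity": float(red[sl][sub].mean()),
            "circularity": mor(sub),
        })
    return pd.DataFrame(rows)
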