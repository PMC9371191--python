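"""Lumina candidates, gland retrieval and the Cs tubule score."""

import numpy as np
import pytest

from histograde.core_raster import perimeter_pixels, region_properties
from histograde.segmentation import segment_nuclei
from histograde.tubules import (
    GlandRegion,
    LuminaCandidate,
    assess_tubule,
    detect_tubules,
    lumina_candidates,
    retrieve_gland,
)

from conftest import corpus_confusion, disk_mask


def ring_scene(n_ring=10, lumen_radius=14, nucleus_radius=4, one_sided=False,
               shape=(160, 160), rotate=0):
    """Synthetic gland geometry: lumen mask + ring nucleus labels/records.

    Returns (lumina_candidate, gland, records) built directly from the
    geometry, bypassing image rendering, to probe assess_tubule alone.
    """
    h, w = shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[:h, :w]
    lumen = (yy - cy) ** 2 + (xx - cx) ** 2 <= lumen_radius ** 2
    labels = np.zeros(shape, np.int32)
    ring_r = lumen_radius + 2 + nucleus_radius
    angles = np.linspace(0, 2 * np.pi, n_ring, endpoint=False) + np.radians(rotate)
    if one_sided:
        # all nuclei in a horizontal row above the lumen: the hull's major
        # axis runs along the row, leaving every nucleus on one side
        xs = np.linspace(cx - 2.2 * ring_r, cx + 2.2 * ring_r, n_ring)
        for i, nx in enumerate(xs, start=1):
            ny = cy - ring_r - nucleus_radius
            labels[(yy - ny) ** 2 + (xx - nx) ** 2 <= nucleus_radius ** 2] = i
    else:
        for i, ang in enumerate(angles, start=1):
            ny = cy + ring_r * np.sin(ang)
            nx = cx + ring_r * np.cos(ang)
            labels[(yy - ny) ** 2 + (xx - nx) ** 2 <= nucleus_radius ** 2] = i
    intensity = np.full(shape, 200, np.uint8)
    intensity[lumen] = 250
    intensity[labels > 0] = 90
    records = region_properties(labels, intensity)
    cand = LuminaCandidate(
        label=1, mask=lumen, area=int(lumen.sum()),
        perimeter=perimeter_pixels(lumen), centroid=(float(cy), float(cx)),
        mean_intensity=250.0, intensity_mode=250, touches_border=False,
    )
    gland_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (ring_r + nucleus_radius + 2) ** 2
    pts = np.array([r.centroid for r in records])
    diffs = pts[:, None, :] - pts[None, :, :]
    dists = np.sqrt((diffs ** 2).sum(-1))
    d_min = float(dists[np.triu_indices(len(pts), 1)].min()) if len(pts) > 1 else 8.0
    d_n = float(np.mean([r.diameter for r in records]))
    gland = GlandRegion(
        region=gland_mask, cv_history=[0.1, 0.3], final_cv=0.3,
        mu_gamma=0.6, mu_l=0.98, d=-0.38,
        nuclei_inside=[r.label for r in records],
        d_n=d_n, d_min=d_min,
        t_n=(cand.perimeter / 2.0) / (d_n + d_min),
    )
    return cand, gland, records


class TestLuminaCandidates:
    def test_phantom_tubule_becomes_active(self, tubule_corpus):
        ph, _, _, state = tubule_corpus[("G1", 0)]
        active = [c for c in state.candidates if c.status in ("active", "rejected_cv")]
        for t in ph.tubule_truth:
            r, c = int(t.center[0]), int(t.center[1])
            assert any(cand.mask[r, c] for cand in active)

    def test_small_bright_speck_rejected_by_area(self, tubule_corpus):
        _, _, _, state = tubule_corpus[("G1", 0)]
        small = [c for c in state.candidates if c.status == "rejected_area"]
        assert small, "noise specks should be present and area-rejected"

    def test_mottled_region_rejected_by_mode(self):
        """A component whose most frequent value sits below its mean
        (bright speckle over a darker base) is not lumen-like."""
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(150, 4, (120, 120)), 0, 255).astype(np.uint8)
        # mottled patch: 2/3 of pixels at 180, 1/3 at 250 -> mean ~203 > mode 180
        yy, xx = np.mgrid[:120, :120]
        patch = (yy - 60) ** 2 + (xx - 60) ** 2 <= 20 ** 2
        vals = np.where(rng.uniform(size=(120, 120)) < 1 / 3, 250, 180)
        img[patch] = vals[patch]
        labels = np.zeros((120, 120), np.int32)
        labels[5:12, 5:12] = 1  # one fake nucleus for Arean
        recs = region_properties(labels, img)
        cands = lumina_candidates(img, labels, recs)
        big = max(cands, key=lambda c: c.area)
        assert big.status == "rejected_mode"

    def test_border_touching_rejected(self):
        img = np.full((100, 100), 150, np.uint8)
        img[0:30, 40:70] = 250  # bright region on the border
        labels = np.zeros((100, 100), np.int32)
        labels[80:88, 80:88] = 1
        recs = region_properties(labels, img)
        cands = lumina_candidates(img, labels, recs)
        big = max(cands, key=lambda c: c.area)
        assert big.status == "rejected_border"

    def test_no_nuclei_errors(self):
        with pytest.raises(ValueError):
            lumina_candidates(np.zeros((10, 10), np.uint8),
                              np.zeros((10, 10), np.int32), [])


class TestRetrieveGland:
    def test_cv_rises_while_absorbing_nuclei(self, tubule_corpus):
        ph, assessments, _, _ = tubule_corpus[("G1", 0)]
        ringed = [a for a in assessments if len(a.gland.nuclei_inside) >= 5]
        assert ringed
        for a in ringed:
            cv = a.gland.cv_history
            assert cv[-1] > cv[0]  # net rise while nuclei are absorbed
            assert len(a.gland.nuclei_inside) >= 5

    def test_bare_gap_has_low_cv_and_no_nuclei(self, tubule_corpus):
        ph, assessments, _, _ = tubule_corpus[("G3", 0)]
        gaps = [a for a in assessments if len(a.gland.nuclei_inside) == 0]
        ringed_cv = [a.gland.final_cv for a in tubule_corpus[("G1", 0)][1]
                     if len(a.gland.nuclei_inside) >= 5]
        for a in gaps:
            assert a.gland.final_cv < min(ringed_cv)


class TestAssessTubule:
    def test_ideal_ring_scores_as_tubule(self):
        cand, gland, records = ring_scene()
        a = assess_tubule(gland, cand, records)
        assert a.symmetry == 1.0
        assert a.l_a == 0.0
        assert a.l_cdis <= 2.0
        assert a.cs <= 60
        assert a.is_tubule
        assert a.lumina_in_hull

    def test_one_sided_ring_fails(self):
        cand, gland, records = ring_scene(one_sided=True)
        a = assess_tubule(gland, cand, records)
        assert a.symmetry == 0.0
        assert a.l_a == 100.0
        assert a.cs > 60
        assert not a.is_tubule

    def test_symmetry_arithmetic(self):
        """S follows min/max of the axis split: 3/3 -> 1, 2/4 -> 0.5."""
        cand, gland, records = ring_scene(n_ring=6)
        a = assess_tubule(gland, cand, records)
        n_u, n_l = a.n_upper, a.n_lower
        expected = min(n_u, n_l) / max(n_u, n_l)
        assert a.symmetry == expected
        assert a.l_a == (1 - expected) * 100.0

    def test_score_decomposition_exact(self, tubule_corpus):
        for (_, _), (_, assessments, _, _) in tubule_corpus.items():
            for a in assessments:
                assert a.cs == a.penalty + a.l_cdis + a.l_theta + a.l_a

    def test_penalty_applied_when_ring_sparse(self):
        cand, gland, records = ring_scene(n_ring=10)
        gland.nuclei_inside = gland.nuclei_inside[:1]
        a = assess_tubule(gland, cand, records[:1])
        assert a.penalty == 10.0
        assert not a.is_tubule

    def test_rotation_robustness(self):
        cand0, gland0, recs0 = ring_scene(rotate=0)
        cand90, gland90, recs90 = ring_scene(rotate=90)
        a0 = assess_tubule(gland0, cand0, recs0)
        a90 = assess_tubule(gland90, cand90, recs90)
        assert abs(a0.cs - a90.cs) <= 5.0

    def test_symmetry_monotonicity(self):
        """Lower S never lowers Cs, all else fixed."""
        cand, gland, records = ring_scene()
        a = assess_tubule(gland, cand, records)
        for s in (1.0, 0.6, 0.2, 0.0):
            cs = a.penalty + a.l_cdis + a.l_theta + (1 - s) * 100.0
            assert cs >= a.penalty + a.l_cdis + a.l_theta


class TestDetectTubules:
    def test_g1_counts_near_planted(self, tubule_corpus):
        diffs = []
        for seed in range(10):
            ph, _, count, _ = tubule_corpus[("G1", seed)]
            diffs.append(abs(count - len(ph.tubule_truth)))
        assert np.mean(diffs) <= 1.0

    def test_g3_counts_near_zero(self, tubule_corpus):
        for seed in range(10):
            _, _, count, _ = tubule_corpus[("G3", seed)]
            assert count <= 1

    def test_classification_accuracy(self, tubule_corpus):
        c = corpus_confusion(tubule_corpus)
        total = sum(c.values())
        assert total >= 100
        accuracy = (c["tp"] + c["tn"]) / total
        assert accuracy >= 0.90
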