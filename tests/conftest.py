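"""Shared fixtures: geometric masks and pre-computed phantom pipelines.

The expensive pipeline runs (segmentation / tubule detection over seed
sweeps) are session-scoped so the unit, property and acceptance tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from histograde.phantoms import generate_phantom, grade_preset, truth_feature_pool
from histograde.segmentation import segment_nuclei
from histograde.tubules import detect_tubules


def disk_mask(radius: float, pad: int = 3) -> np.ndarray:
    """Rasterised disk: pixels with Euclidean distance <= radius."""
    n = 2 * int(radius) + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n] - (n // 2)
    return yy * yy + xx * xx <= radius * radius


def ellipse_mask(a: float, b: float, theta: float = 0.0, pad: int = 3) -> np.ndarray:
    """Rasterised ellipse with semi-axes a (x) and b (y), rotated by theta."""
    n = 2 * int(max(a, b)) + 2 * pad + 1
    yy, xx = np.mgrid[:n, :n] - (n // 2)
    c, s = np.cos(theta), np.sin(theta)
    u = c * xx + s * yy
    v = -s * xx + c * yy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def fused_disks(k: int, radius: int = 5, overlap: int = 3) -> np.ndarray:
    """Chain of k disks, adjacent centres 2*radius - overlap apart."""
    step = 2 * radius - overlap
    w = step * (k - 1) + 2 * radius + 7
    h = 2 * radius + 7
    yy, xx = np.mgrid[:h, :w]
    mask = np.zeros((h, w), bool)
    for i in range(k):
        cx = radius + 3 + i * step
        cy = h // 2
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    return mask


def dice(ss: np.ndarray, st: np.ndarray) -> float:
    ss, st = np.asarray(ss, bool), np.asarray(st, bool)
    return 2.0 * (ss & st).sum() / (ss.sum() + st.sum())


@pytest.fixture(scope="session")
def healthy_runs():
    """10 seeded healthy-preset phantoms with their nuclei segmentations."""
    runs = []
    for seed in range(10):
        ph = generate_phantom(grade_preset("healthy", seed=seed))
        labels, records, nfilter = segment_nuclei(ph.rgb)
        runs.append((ph, labels, records, nfilter))
    return runs


@pytest.fixture(scope="session")
def clump_ablation():
    """Count errors with/without watershed splitting on clumped phantoms."""
    from dataclasses import replace

    errors = {"split": [], "nosplit": []}
    for seed in range(6):
        spec = replace(grade_preset("healthy", seed=seed), clump_fraction=0.2)
        ph = generate_phantom(spec)
        n_true = int(ph.nuclei_truth.max())
        for key, split in (("split", True), ("nosplit", False)):
            _, records, _ = segment_nuclei(ph.rgb, split=split)
            errors[key].append(abs(len(records) - n_true) / n_true)
    return errors


@pytest.fixture(scope="session")
def tubule_corpus():
    """Tubule detection on G1/G2/G3 phantoms over seed sweeps.

    Returns {(grade, seed): (phantom, assessments, count, state)} with
    10 seeds for G1 and G3 (the classification corpus: 60 planted
    tubules, 80 planted non-tubule bright regions) and 4 seeds for G2
    (grade-trend check).
    """
    corpus = {}
    for grade, seeds in (("G1", range(10)), ("G3", range(10)), ("G2", range(4))):
        for seed in seeds:
            ph = generate_phantom(grade_preset(grade, seed=seed))
            assessments, count, state = detect_tubules(ph.rgb)
            corpus[(grade, seed)] = (ph, assessments, count, state)
    return corpus


def corpus_confusion(corpus) -> dict[str, int]:
    """Planted-structure confusion counts from a tubule corpus."""
    tp = fn = fp = tn = 0
    for ph, assessments, _, _ in corpus.values():
        centers = [(int(a.candidate.centroid[0]), int(a.candidate.centroid[1]), a)
                   for a in assessments]
        for t in ph.tubule_truth:
            hit = [a for (r, c, a) in centers if t.lumina_mask[r, c]]
            if hit and hit[0].is_tubule:
                tp += 1
            else:
                fn += 1
        for g in ph.gap_truth:
            hit = [a for (r, c, a) in centers if g[r, c]]
            if hit and hit[0].is_tubule:
                fp += 1
            else:
                tn += 1
    return {"tp": tp, "fn": fn, "fp": fp, "tn": tn}


@pytest.fixture(scope="session")
def grade_pools():
    """Per-grade ground-truth nucleus feature pools (>= 2000 nuclei each)."""
    pools = {}
    for grade in ("healthy", "G1", "G2", "G3"):
        dfs = [truth_feature_pool(generate_phantom(grade_preset(grade, seed=s)))
               for s in range(16)]
        pools[grade] = pd.concat(dfs, ignore_index=True)
    return pools
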