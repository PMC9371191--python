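# Methods

This note records the models, parameter choices and numerical
conventions behind `histograde`, and what the synthetic tests do and do
not establish.

## Scope and model

The pipeline characterises H&E breast-tissue images along two
Nottingham criteria, nuclear pleomorphism and tubule formation; the
third criterion (mitotic count) is out of scope.  All image analysis
runs on the red channel, where hematoxylin-stained nuclei are darkest.
The method is deliberately feature-based: every intermediate quantity
(scale, circularity, symmetry, score) has a direct histological
reading.

## Granulometry

Openings use flat, rasterised Euclidean disks (pixels at distance
≤ λ from the centre).  Erosion treats the outside of the image as
white, dilation as black, so border-touching structures are not
penalised.  The disk operators are computed by per-chord 1-D running
min/max filters — an exact decomposition, verified pixel-for-pixel
against brute-force structuring-element translation in the tests.

Rasterised disks do not form an exact sieve: an opening at λ+1 can
retain corner pixels the opening at λ removed, which would produce
negative pattern-spectrum values.  The spectrum is therefore computed
as a *cascade* (each scale's opening applied to the previous scale's
result), which restores monotonicity of the gray mass and hence
PS(λ) ≥ 0.  The cost is a bias of at most one scale step in the peak
location (a radius-4 disk typically peaks at λ = 3); every scale
comparison in the pipeline carries a ±1 tolerance for this reason.

Parameters: step Δ = 1 px, scan range X = 20 (configurable).  Argmax
ties break to the smallest scale.  The secondary peak λ₂ (argmax of PS
above λₙ) is trusted as the upper size bound only when it carries at
least 5% of the main peak's mass; otherwise the argmax over the tail is
noise and the bound falls back to 2λₙ.

## Tile-local binarization

Tile side 25·λₙ makes the tiling magnification-invariant.  Each tile is
stretched linearly from [μ−2σ, μ] (clipped at 0) to [0, 255], rounded
half-up, then thresholded with Otsu; nuclei are the class below the
threshold.  Two guards suppress structure-free tiles: near-flat tiles
(σ < 1), and tiles whose raw Otsu classes are separated by fewer than
15 gray levels.  The second guard exists because Otsu applied to pure
sensor noise happily splits it in half; noise class means sit ~1.6σ
apart (< 10 gray levels for any plausible noise), while genuine nuclei
lie tens of levels below tissue.  A separability-*ratio* criterion was
rejected: tiles containing a bright lumen have three intensity modes
and legitimately score a low ratio despite abundant nuclei.

Border tiles keep their natural smaller size and their own statistics;
tiles are disjoint, with no blending.  Known limitation: a tile
containing stroma and lumen but *no* nuclei would binarize the stroma
as foreground; in practice nuclei-free tiles of that kind are rare and
the downstream size/circularity filters absorb most of the residue.

## MOR circularity

The boundary is the 8-connected inner boundary (foreground pixels with
a 4-neighbour background); distances are measured from the area
centroid; the histogram uses 1-px bins.  Mode and window detection run
on a 3-bin centre-weighted (¼, ½, ¼) smoothing of the histogram — a
flat 3-bin mean creates exactly tied peaks around 1–2-bin modes and
would truncate the window.  The integration window [k1, k2] is the
maximal strict descent from the mode: a stop at a rise is precisely the
nearest flanking local minimum; stopping at a plateau extends that rule
to exactly flat histograms (an idealised bar has a uniform radius
histogram with no strict minima at all).  The MOR value is the
*unsmoothed* histogram mass inside the window, so an ideal disk scores
exactly 1.  Regions with fewer than 8 boundary pixels are degenerate
and score 0.

## Nuclei segmentation

Components are partitioned by area: noise below area(disk(λₙ/2)),
clumps above 1.5·area(disk(λₙ)).  The clump bound sits below 2× a
nucleus disk because the union of two overlapping nucleus-sized disks
is always smaller than two disks; routing an unusually large single
nucleus to the watershed is harmless (it yields one basin).

Clump splitting is a marker-controlled watershed on the negated
Euclidean distance transform.  Markers are the distance maxima after
h-maxima suppression with h = max(1, λₙ/4): touching nuclei of radius
~λₙ meet at a saddle only ~1–1.5 px below their distance peaks, so a
deeper suppression would merge genuine pairs, while h ≥ 1 still removes
rasterisation peaks.

The final filters use the inscribed-disk radius (rounded distance-
transform maximum) against T_λ = [max(1, round(λₙ/2)), λ₂], then the
MOR threshold T_c = μ_c − σ_c computed over the size-filtered candidate
set (computing the statistics after size filtering keeps watershed
fragments out of them).  Border-touching nuclei are retained; only
lumina candidates are border-filtered.

## Tubule detection

The lumina threshold is the mean red intensity of the connective tissue
(everything outside segmented nuclei).  Candidate filters: area
≥ U_a = 2 × mean nucleus area; intensity mode ≥ candidate mean (a
mottled bright-ish region has its mode below its mean); no border
contact.

Gland growth dilates the candidate with alternating cross/3×3
structuring elements — octagonal, near-Euclidean growth; pure cross
steps would grow an L1 ball and under-reach ring nuclei on diagonals.
The coefficient of variation of the red intensities inside the grown
region rises while dark nuclei are being absorbed; growth stops at the
first CV decrease after at least one rise, capped at 3·λₙ steps.  The
candidate is kept when final CV > d = μ_γ − μ_l (annulus mean minus
lumen mean, both normalised by 255).

Scoring: the gland's nucleus centroids (centroid-inside membership)
plus the lumen centroid form a convex hull; moment ellipses of the
filled hull and of the lumen mask give the centroid distance l_cdis
(px) and orientation difference l_θ (degrees, folded to [0, 90]).
Moment ellipses with axis ratio above 0.9 are treated as circles and
report orientation 0 — for a circle the orientation is undefined by
symmetry, and comparing two raster-noise angles would add a uniform
[0, 90] term to the score.  Nuclei within 0.5 px of the hull's major
axis are excluded from the symmetry split.  T_n uses the per-gland
minimum pairwise centroid distance (falling back to the mean diameter
when fewer than two nuclei are present).  Cs mixes pixels, degrees and
percent by design; the decision threshold 60 was calibrated at 200×
magnification, and the `scale` parameter rescales l_cdis for other
magnifications.

## Grading

Dispersion: covariance of (area, circularity) with the n−1 denominator
after z-scoring; Λ is the eigenvalue sum.  Z-scoring each table by its
own statistics would make Λ identically 2, so comparisons across pools
share one standardisation reference computed from the pooled data
(`compare_dispersion`); `dispersion` also accepts explicit references.
Subsets draw without replacement within a subset (with replacement,
flagged, when the pool is too small) and independently across subsets.
KNN uses Euclidean distance on features standardised with training
statistics, K = 5, majority vote, macro-F1, and stratified 10-fold
cross-validation.  Segmentation evaluation uses the standard confusion
definitions (FN = St∖Ss, TN = E∖(Ss∪St)) — the only reading consistent
with the precision/sensitivity/Dice formulas — with zero-denominator
metrics reported as undefined.

## Synthetic phantoms

The generator renders what the pipeline measures: dark elliptical
nuclei (radius ~N(μ_r, σ_r) clipped at 2 px, axis ratio uniform up to a
preset maximum) on noisy stroma, bright lumina ringed by nuclei, and
bare bright gaps as tubule negatives.  Default study conditions:
384×384 px, ~110–130 scattered nuclei plus 10 ring nuclei per tubule,
stroma ≈ 200, nuclei ≈ 70–95, lumina ≈ 252 in R, per-image stain shift
σ = 6, additive Gaussian noise σ = 5.  Three deliberate realism
choices matter to the method:

* **Epithelial rim.** Each lumen is bounded by a 2-px rim ~20 gray
  levels below stroma, mimicking the cell layer around real ducts.
  Without it, the connective-mean threshold sits so close to the stroma
  mode that above-threshold noise percolates into one giant component
  that swallows the lumina — an artifact of idealised iid noise, not of
  tissue.
* **Near-saturated, unshifted lumina.** Lumina are empty slide space:
  unaffected by the stain shift and close to the sensor ceiling, which
  pins their intensity mode at 255 as in real slides.
* **Elliptical lumina** (aspect 1.25–1.6) give the gland a defined
  orientation, as real duct cross-sections do.

Grade presets move along the Nottingham trends: nucleus radius mean/std
4.0/0.4 (healthy) → 7.0/2.2 (G3), eccentricity cap 1.2 → 2.0, nucleus
intensity 95 → 70 (hyperchromasia proxy), tubules 6 → 0 with bare gaps
rising 0 → 6.

What the phantoms do **not** model: stain-colour variation beyond a
scalar shift, texture inside nuclei and stroma, overlapping tissue
layers, mitotic figures, fat, and the full morphological diversity of
real carcinoma.  Passing tests therefore establish that the
implementation realises the method faithfully and that the method's
internal logic (scale recovery, clump splitting, Cs separation, grade
trends) is sound under clean conditions — not that the real-data
accuracies reported for expert-labelled datasets are reproduced.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on
384×384 phantoms: 10 seeds for segmentation closure, 10+10 seeds
(G1/G3) for tubule classification (≥ 100 planted structures), 16
phantoms per grade (≥ 2000 nuclei) for the subset/KNN protocol — sizes
chosen so each sweep completes in a few minutes on one CPU while
keeping every statistical margin wide.  All randomness flows through
explicit seeds: phantom generation is bit-deterministic given its spec,
and a pipeline rerun from a manifest reproduces artifacts
byte-identically.
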