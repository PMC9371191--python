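# histograde

Quantitative analysis of H&E-stained breast-histopathology images along
two of the Nottingham Grading System's criteria: **nuclear pleomorphism**
and **tubule formation**.  The package segments cell nuclei, scores how
likely each bright lumen is to belong to a glandular tubule, and
classifies the differentiation grade from nucleus shape and intensity
features.  A synthetic phantom generator with exact ground truth makes
every stage testable without external datasets.

## Who is this for

Researchers in computational pathology who want a transparent,
feature-based (non-deep-learning) reference pipeline whose intermediate
quantities — granulometric scales, circularities, tubule scores — map
directly onto what a pathologist assesses, and who need a fully
synthetic, ground-truthed test bed for such methods.

## Method

All processing runs on the red channel *I* of the RGB image (hematoxylin
makes nuclei dark in R).

1. **Dominant nucleus scale** λₙ by granulometry: the pattern spectrum
   PS(λ) = [mes(γ_λ(I)) − mes(γ_{λ+Δ}(I))] / mes(I), with γ_λ the
   opening by a disk of radius λ and mes the accumulated gray mass,
   peaks at the radius of the most frequent grains — the nuclei
   (computed on 255 − I, since the grains must be bright).
2. **Binarization**: the image is tiled at side 25·λₙ; each tile is
   linearly stretched from [μ−2σ, μ] onto [0, 255] and thresholded with
   Otsu; the dark class is the nuclei foreground.
3. **Nuclei segmentation**: components are partitioned by area against
   λₙ (noise / single nuclei / clumps); clumps are split by
   marker-controlled watershed on the negated distance transform; the
   fused candidates are filtered by the size window
   T_λ = [λₙ/2, λ₂] (λ₂ = secondary spectrum peak) and by MOR
   circularity ≥ T_c = μ_c − σ_c.  MOR is the probability mass of the
   boundary-radius distribution between the local minima flanking its
   mode — near 1 for disks, low for elongated artifacts.
4. **Tubule detection**: bright connective-tissue components above the
   connective mean are lumina candidates (area ≥ U_a = 2·Area_n, mode ≥
   mean, not touching the border); each is grown by dilations with the
   coefficient of variation CV = σ/μ as stop signal, and scored with

       Cs = T_nuclei + l_cdis + l_θ + l_A

   the sum of a nucleus-count penalty (10 when fewer than
   T_n = (p_l/2)/(d_n + d_min) nuclei ring the lumen), the centroid
   distance and orientation difference between the lumen ellipse and the
   ellipse of the convex hull of the gland's nuclei, and the asymmetry
   l_A = (1 − S)·100 with S = min(N_u, N_l)/max(N_u, N_l) the axis-split
   symmetry.  Candidates with **Cs ≤ 60** are counted as tubules.
5. **Grading**: per-grade pools of nucleus features are resampled into
   subsets (n ∈ {100, 500, 2000}); each subset's mean (area, intensity)
   is one sample for a K-nearest-neighbour classifier (K = 5, stratified
   10-fold CV).  The covariance dispersion Λ = Λ_A + Λ_C of
   (area, circularity) separates healthy from cancerous tissue.

## Worked example

```bash
histograde synth --preset G1 --seed 7 --out-dir ph
histograde run ph/image.png --out-dir out
histograde eval-seg out/nuclei_labels.png ph/nuclei_truth.png
```

prints

```
G1 phantom seed=7 -> ph/
nuclei=159 tubules=6 -> out/ (config d491d8e3219108b0)
precision=1.0000 sensitivity=0.9114 sdc=0.9536
```

The grade-1 phantom plants 6 tubules and 170 nuclei; the pipeline
recovers 159 nuclei (the size/circularity filters deliberately drop
atypical elements) and finds all 6 tubules.  The evaluation line
compares the final nuclei mask with the phantom's exact truth:
precision 1.0 (no false nucleus pixels), sensitivity 0.91, Sørensen–Dice
0.95.  `out/tubules.csv` lists every lumina candidate with its status
and the Cs decomposition; `out/manifest.json` records the full
configuration and its hash, from which `histograde run` reproduces the
outputs byte-identically.

Other subcommands: `granulo` (pattern spectrum), `binarize`,
`segment-nuclei`, `detect-tubules`, `grade` (KNN protocol on a feature
CSV).

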