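# Methods

This note documents the models behind `arthromri`, the parameters that
matter, the numerical conventions, and what the synthetic data can and
cannot show. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## 1. The edge-detection chain

The chain is classical Canny on a 2-D grayscale raster, with every stage
pinned down explicitly:

1. **Smoothing.** Discrete convolution with a normalised isotropic Gaussian,
   standard deviation `delta` (pixels), kernel radius `ceil(3·delta)` by
   default (≥ 99.7 % of the mass). Borders are replicate-padded; constant
   images are exact fixed points because the kernel sums to 1.
2. **Gradients.** 3×3 Sobel templates: `gx` weighs the column to the right
   of a pixel (1, 2, 1) against the column to its left; `gy` the row above
   against the row below. Magnitude is `hypot(gx, gy)`; direction is the
   four-quadrant angle `atan2(gy, gx)`, defined as 0 where both components
   vanish. Because `gy` responds to intensity increasing *upward*, the
   angle lives in a y-up frame; the non-maximum-suppression neighbour
   table accounts for this (sector 45° points to `(row−1, col+1)`). An
   axis-swapped `arctan(gx/gy)` variant is available behind
   `literal_direction` for auditing; suppression always uses the
   conventional angle, since only the sector assignment matters.
3. **Non-maximum suppression.** Directions are quantised to four sectors
   (0°, 45°, 90°, 135°); a pixel survives only if its magnitude is
   *strictly* greater than both neighbours along its sector, out-of-bounds
   neighbours counting as 0. Strictness means plateaus of constant
   magnitude vanish entirely — a documented, deliberate reading of the
   suppression rule. No sub-pixel interpolation is performed.
4. **Double-threshold hysteresis.** Nonzero suppressed magnitudes ≥ `t_high`
   are strong; those in `[t_low, t_high)` are weak; a weak pixel becomes an
   edge iff it is transitively connected (4- or 8-connectivity, default 8)
   through weak pixels to a strong one. Zero-magnitude pixels are never
   candidates: without this clause a zero `t_low` would promote the entire
   background of a blank image, which is clearly not intended. Per-pixel
   provenance (none / weak-suppressed / strong / weak-linked) is retained.
5. **Thresholds.** Absolute thresholds may be given; otherwise `t_high` is
   the nearest-rank 0.90 quantile of the nonzero suppressed magnitudes and
   `t_low = 0.4·t_high`. Per-image quantiles are the default because a
   fixed absolute pair is meaningless across rasters of different contrast;
   both knobs are exposed.

`approximation_degree` is the discrete L2 distance
`sqrt(Σ (f−g)²)` between two rasters — the closeness measure for a
processed image against its original. Contour extraction takes the largest
8-connected edge component (ties broken by the lexicographically smallest
first pixel in raster order) and flags it closed when it encloses interior
pixels under flood fill from the border.

Correctness is established two ways: hand-derived values at every stage,
and pixel-for-pixel equality of the full chain with an independent
straight-line reference (pure-Python loops, BFS hysteresis) on 100 seeded
random rasters. On a noiseless filled disk of radius 20 the chain yields a
single closed ring within 0.8 px of the analytic boundary.

## 2. Quality metrics

MSE, PSNR (`10·log10((2^B−1)²/MSE)` dB) and SSIM are implemented exactly as
defined for the comparison of a processed raster against a clean reference.
SSIM uses **uniform** (unweighted) H×H windows, H = 8 by default, sliding
with stride 1 over every position fully inside the raster; the overall
value is the arithmetic mean of the per-window `l·c·s` products. Window
statistics use sample (n−1) normalisation. This departs from the common
Gaussian-weighted implementation on purpose — the plain boxed window is the
definition adopted here — but agrees with `skimage.metrics.
structural_similarity(gaussian_weights=False, use_sample_covariance=True)`
to 1e-7 in the cross-check test (odd window, since skimage requires one).

Two textual defects in the source definitions were resolved as follows:
the dynamic range is taken as `L = 255` for 8-bit data (the printed "225"
is inconsistent with `MAX = 2^B − 1`), and the covariance is the
cross-product form `Σ(M−μM)(N−μN)/(HW−1)` (the printed formula repeats the
variance); a `literal_covariance` audit mode reproduces the printed text.
PSNR of identical images is signalled with `IdenticalImagesError` rather
than a number; report layers render it as `"inf"`.

## 3. IPSG scoring

The score card holds three soft-tissue grades (effusion/bleeding, synovial
hyperplasia, hemosiderin deposition; each 0–3) and eight binary
osteochondral items (two erosion, two cyst, four cartilage). Subtotals are
9 + 8, total 17; the bound is verified exhaustively over all 16 384 valid
cards.

The clinical "small / medium / large" bands are operationalised as area
fractions of the joint region with half-open cut points (default
floor 0.01, cuts 0.05 and 0.15). These are **package conventions for
phantom work**, not IPSG definitions — the clinical atlas grades lesions
qualitatively, and any monotone mapping supports the pipeline's purpose of
comparing measurement arms against a known truth. Osteochondral items are
derived from mask overlap: erosion touching the one-pixel cortical
boundary of a bone (any-surface item) or covering ≥ 50 % of a bone;
any cyst component (single-capsule item), cysts reaching more than two
bones or more than 1/3 of a single bone (extensive item — the fraction
follows the scoring table's wording); cartilage damage present, ≥ 50 % of
a bone's cartilage, full-thickness (a component bridging from the bone
side to the exterior of the cartilage band), and full-thickness over
≥ 50 % of the cartilage.

Two scoring pathways are kept distinct: grading ground-truth masks
(`score_from_masks`) and grading a raster by intensity-band segmentation
(`measure_grades_from_raster`). They agree exactly on clean phantoms and
diverge under noise, which is what lets method-vs-pathology disagreement
be simulated mechanistically.

## 4. Synthetic phantoms

A phantom is one 2-D slice: background soft tissue (intensity 60), bright
bone-marrow ellipses (200), a mid-gray closed synovial annulus (110), an
optional bright effusion pocket (230) whose disk is sized to a requested
area fraction of the joint region, and small near-zero hemosiderin foci
(2) — hemosiderin gives markedly low MRI signal. Later layers overwrite
earlier ones and masks record final pixel ownership, so stored true grades
always equal a re-scoring of the masks. The default slice is 64×64 with a
ring of inner radius 18 and thickness 4, effusion fraction 0.10 (grade 2),
three hemosiderin foci of radius 2, and Rician noise σ = 12: Rician
(magnitude-MRI) statistics are the default noise model, with Gaussian
retained because it has clean closed-form checks; σ = 12 on a 0–255 scale
gives a visibly noisy but readable image (contrast-to-noise ≈ 4 between
adjacent tissue bands), which we consider a realistic mid-field acquisition.
Noise is seeded and clipped to the dynamic range.

What the phantom does **not** emulate: partial-volume averaging, coil
inhomogeneity, anatomically realistic shapes, 3-D structure, or any pulse
sequence physics. Passing tests therefore show algorithmic correctness and
direction-of-effect under controlled conditions, not clinical performance.

## 5. Synthetic cohort

The cohort reproduces the emulated study's structure: 60 patients, 146
joints (84 knee / 38 ankle / 10 elbow / 14 hip), a 42-joint treated
subgroup, and per-lesion pathology grade tables — effusion (14, 59, 37) at
levels (0, 1, 2), where level 2 stands for the combined 2–3 band;
synovial hyperplasia (15, 50, 27, 54); hemosiderin (36, 46, 22, 44).
Grades are allocated by **seeded permutation of the exact multiset**, not
sampling, so these tables are reproduced verbatim. Two of the printed
tables do not reconcile with the 146-joint roster (they sum to 110 and
148); the generator models each lesion class as an *assessment table* — 36
joints simply lack an effusion assessment, and two joints carry a repeat
hemosiderin assessment (flagged `repeat`) — rather than silently editing
the counts. The spec-level sum check exists and must be explicitly relaxed
per lesion class to permit this.

The three study groups are modelled as three **measurement arms over the
same joints** (pathology, conventional MRI, Canny MRI), because the
per-level comparisons involve all joints under each method; a
`disjoint_patients` flag partitions patients instead, for sensitivity
analysis. Method arms derive from pathology via a per-assessment model:
`exact` (copy), `confusion` (misread with probability `error_rate`, one
level down, grade 0 overcalled to 1; defaults 0.25 conventional / 0.05
Canny, encoding the premise that the conventional reading blurs adjacent
severity bands while the Canny-based reading is nearly faithful), or
`independent` (i.i.d. from the pathology grade distribution — the
no-association null used to calibrate the chi-square; in that mode the
pathology grades themselves are drawn multinomially so that both raters are
genuinely i.i.d. samples from the same distribution).

Volumes are lognormal: pre-surgery mean 45 000 mm³ with 20 % coefficient of
variation; post = pre × 0.7 × lognormal noise (mean 1, cv 20 %). The
reduction is multiplicative because only the direction and significance of
the post-surgery decrease are on record, and 0.7/20 % are the conditions
under which the power analysis is run. Bleed counts per six months are
negative binomial (pre mean 4.0, post mean 1.5, size 5): inclusion required
more than one bleed in six months, and mild overdispersion is the norm for
bleed counts.

## 6. Statistics

* Paired t: `t = mean(d)/(sd(d)/√n)`, df `n−1`, two-sided.
* One-way ANOVA: `F = (SSB/(k−1))/(SSW/(N−k))`. Applying ANOVA to count
  data follows the emulated analysis plan as stated; it is anticonservative
  for skewed counts and a chi-square alternative exists in the module.
* Detection-rate comparison: for a score level ℓ, the 2×2 table is
  (rater arm) × (grade = ℓ / ≠ ℓ) over the jointly graded assessments, and
  the statistic is `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` with df 1 — the
  standard two-proportion chi-square; Yates correction is off by default
  and available by flag. A level absent from both raters raises a
  degenerate-data signal instead of returning a bogus p.
* Tail probabilities come from the package's own special functions:
  regularized incomplete beta by modified-Lentz continued fraction
  (relative tolerance 1e-12, with the `I_x(a,b) = 1 − I_{1−x}(b,a)`
  symmetry for convergence), `erfc` for the df-1 chi-square. They match
  scipy and direct quadrature to ≤ 1e-6 in tests but keep the inferential
  core free of a statistics-package dependency.

All tests are two-sided at α = 0.05 with **no multiple-testing
correction**, mirroring the emulated analysis plan; with three lesions ×
four levels × two arms this inflates the family-wise error rate, and any
per-level significance should be read accordingly.

Calibration and power are verified by simulation in the acceptance suite:
under the no-effect null the level-1 chi-square rejects in 4–5 % of 2 000
seeded cohorts, and under the 0.7 volume reduction at n = 42 the paired t
rejects in > 99 % of 1 000 replicates. The replicate counts are the sizes
at which these rates are stable to within the stated bands.

## 7. Study orchestration

`run_study` derives every stage seed from the master seed by hashing
`(seed, stage, record)` (SHA-256, reduced below 2³¹), so a single joint or
phantom can be replayed in isolation and the whole report regenerates
bit-for-bit. The image-quality sub-study renders `n_phantoms` (default 20)
seeded phantoms and processes each under two arms: the conventional arm is
the raw noisy raster; the Canny arm is a Gaussian-smoothed reconstruction
plus Canny contour extraction. The reconstruction smoother has its own
width, `recon_delta = 0.5`, distinct from the edge-detection
`delta = 1.4`: a denoising characterisation on the default phantom showed
that PSNR gain over the raw raster requires a kernel narrow enough to
preserve the piecewise-constant tissue steps, while gradient estimation
for edge detection benefits from stronger smoothing. Neither width is
prescribed by the source method description; both are config fields.

## 8. Known limitations

* Phantoms are 2-D and geometric; no claim of anatomical realism.
* The IPSG area-fraction cuts are package conventions, so absolute grades
  on real images would depend on that mapping.
* The confusion model for method arms is adjacent-level and one-sided;
  real reader error is richer.
* The per-image quantile thresholds make the edge chain contrast-invariant
  but mean that a nearly featureless image still yields some edges; use
  absolute thresholds where that matters.
* ANOVA on counts and uncorrected multiplicity are retained by design (see
  §6) and should not be copied into a fresh analysis plan.
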