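# Methods

## Problem setting

TILs scoring on H&E images requires each observer to (1) outline stromal
tissue and (2) mark lymphocyte centers; the score itself is the fraction of
stromal area occupied by lymphocytes. Agreement between observers can
therefore be measured at the segmentation level, the detection level, and
the final score level. This package implements one statistic per level,
plus the sensitivity analyses that characterise them.

## Pixel-wise Fleiss' kappa and boundary weighting

Masks are compared as N raters assigning M pixels to K = 2 categories
(stroma / non-stroma). The observed agreement is the standard Fleiss form
averaged over the M pixels,

P̄ = (Σ_i Σ_j n_ij² − MN) / (MN(N−1)),  P̄e = Σ_j p_j²,  p_j = Σ_i n_ij/(MN),

and κ = (P̄ − P̄e)/(1 − P̄e). BWFK inserts per-pixel weights w′_i:

1. **Boundary extraction.** A boundary pixel is a stroma pixel with at
   least one non-stroma 4-neighbour; neighbours are taken with edge
   replication, so the image border never creates boundary. A mask with no
   boundary at all (all-stroma / all-background) contributes a constant
   distance image equal to DT, with a warning.
2. **Distance transform.** Exact Euclidean distance of every pixel to the
   observer's nearest boundary pixel (`scipy.ndimage.distance_transform_edt`).
3. **Averaging and flattening.** The N distance images are averaged
   pixel-wise, then clipped at DT (default 100 px). Clipping *after*
   averaging is the default (mean map first, then flatten); clip-before is
   available via `clip_before_average=True`. Near-boundary pixels thus get
   weight ≈ 0 — boundary disagreement is down-weighted — and pixels beyond
   DT contribute equally.
4. **Normalisation.** w′_i = M·w_i/Σw, so Σ w′_i = M and uniform raw
   distances give w′_i = 1 for every pixel, collapsing BWFK to plain FK
   exactly. Pixels on a boundary keep weight 0; no floor is added.

Degenerate universes (a single category everywhere, P̄e = 1) return κ = 1
with a `degenerate` flag rather than NaN: identical constant masks are
operationally perfect agreement. A weighted observed agreement within
1e-12 of 1 is snapped to exactly 1 to absorb weight-normalisation rounding,
so unanimous stacks score exactly κ = 1 at any DT.

Pixels labelled "other" (necrosis, fat, debris…) are excluded from the
pixel universe by default, mirroring their exclusion from TILs scoring;
`CategoryMap(exclude_other=False)` folds them into non-stroma instead.
Neither treatment is asserted as the clinically reported one — the choice
is exposed because the original analysis does not state it.

## Distance-based cell agreement (DBCAA)

For each point P of observer i, a_k^i counts the observers j ≠ i whose
nearest point to P lies strictly within D_L (ties at exactly D_L are
configurable). Matching is one-to-many by design: no exclusivity
constraint is imposed, so several points of one observer may match the
same point of another. The score divides Σa by a normalising constant:

* `max_match` (default): (N−1)·Σm_i — the maximum attainable total, so
  identical annotations score 1.0;
* `paper`: N·Σm_i — the literal printed form, under which perfect
  agreement scores (N−1)/N.

The published worked example (55/84 ≅ 0.65 for four observers) is
consistent with the (N−1)·Σm_i denominator at Σm_i = 28, which motivated
the default; both remain available because the original point count is not
published.

D_L defaults to the accepted 8 μm lymphocyte diameter divided by the pixel
size; there is no universally correct pixel value because the annotation
working resolution varies between datasets.

Nearest-point queries use a k-d tree (`scipy.spatial.cKDTree`); tests
verify bit-identical results against an all-pairs brute force up to 2,000
points.

## TILs score

T = L·a_lymph / (stroma pixels · pixel_size²), with a_lymph = π(8/2)² ≈
50.3 μm². A lymphocyte is "in stroma" iff its rounded center pixel is
stroma — only centers are annotated, so the fixed-area, center-membership
rule is the only computable reading. T is not capped at 1 (a warning is
raised above 1). The default calibration 0.23 μm/px derives from a
3000×3000 px field covering ≈ 0.476 mm²: √(0.476·10⁶/9·10⁶) ≈ 0.23.

## Concordance statistics

* **ICC** defaults to the two-way random-effects, absolute-agreement,
  single-rater form ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC−MSE)/n),
  computed directly from the two-way ANOVA mean squares; the variant is
  recorded in the result. Absolute agreement is the natural choice when
  the question is whether observers' scores are interchangeable. A
  consistency variant is selectable. `pingouin` serves as an independent
  cross-check in the tests, never as the implementation.
* **Bland-Altman LOAM** for multiple observers: per (image, observer), the
  difference from that image's observer mean; limits are the mean
  difference ± 1.96·SD of all differences. The caption-level reading
  (limits of agreement with the mean across all observers, not pairwise
  plots) is implemented.
* **Correlation test**: images are repeatedly (default 50×) sampled into
  subgroups (default 10, without replacement within a repeat); per
  subgroup M_S = mean per-image BWFK, M_L = mean per-image DBCAA, M_T =
  ICC of the subgroup score matrix; the 3×3 Pearson matrix is taken across
  repeats. Mean-of-per-image aggregation is the default; pooled
  recomputation was considered and left out of the default path because
  the subgroup definition in the source analysis is per-image.

## Sensitivity analyses

* **Mask shift test**: each observer's mask (or a single observer's, via
  `shift_all=False`) is displaced by a uniformly random direction at the
  given magnitude; vacated pixels are filled with non-stroma (no stroma is
  fabricated; wrap-around is available but off by default). FK, BWFK and
  gain % = 100·(BWFK−FK)/FK are recorded per level.
* **Point shift test**: every point is displaced by an offset drawn
  uniformly from the disk of radius r. Bounding the displacement *norm*
  (rather than each axis) pins the geometry: coincident matched points
  cannot drift beyond 2r apart, so for well-separated perfect-agreement
  sets the score stays exactly 1 while r < D_L/2 and degrades beyond —
  the inflection at about half the match diameter that characterises the
  statistic.
* **Point lost test**: ⌊f·m_i⌋ points are removed uniformly per observer.
  For a perfect-agreement configuration with well-separated cells, each
  surviving point is matched by every other observer independently with
  probability 1−f, so E[Σa] = m·N(N−1)(1−f)² against a denominator of
  (N−1)·N·m(1−f): the expected max-match score is **1−f**. (Evaluating
  E[S(S−1)] as E[S]·(E[S]−1) for the binomial survivor count S would give
  (N(1−f)−1)/(N−1) instead; that neglects the variance of S and is
  incorrect — the package's tests assert the correct 1−f form, verified
  by simulation.)

All sensitivity curves are pure functions of (input, seed).

## Synthetic data: what it emulates, what it does not

`synthetic_data` stands in for a clinical multi-observer dataset
(25 fields of 3000² px at 0.23 μm/px, 4 pathologists, ~50,000 annotated
lymphocytes in total → a latent density of ≈ 1050 cells/mm²):

* **Truth**: stroma = thresholded low-pass Gaussian random field at the
  quantile matching the target stroma fraction (default 0.45, a typical
  stromal share of tumor-bulk fields); lymphocytes = random sequential
  adsorption inside stroma with hard-core spacing of one lymphocyte
  diameter. Infeasible density/spacing combinations fail fast with an
  explanation (the guard is 50% disk packing of the stromal area).
* **Observers**: masks are perturbed by adding a smooth signed radius
  field (bounded by the amplitude) to the truth's signed distance and
  re-thresholding — every changed pixel lies within the amplitude of the
  true boundary, reproducing the boundary-concentrated disagreement
  regime that boundary weighting targets. Independent pixel noise would
  not produce that regime and is deliberately not used. Points get
  Bernoulli misses (default 10%), Gaussian jitter (default SD 2 px) and
  uniform in-frame false positives (default 5% of the truth count);
  defaults are plausible magnitudes for trained observers, chosen once.
* **Datasets**: per-image parameter draws (stroma fraction ±0.08,
  amplitude ×U(0.5,1.5), density ×U(0.7,1.3)) so images differ in true
  agreement; byte-reproducible from the seed.

Not emulated: staining/texture appearance, spatial clustering of
lymphocytes beyond the hard-core process, observer-specific bias (one
consistently generous rater), and correlated errors between observers. A
green test on synthetic data therefore establishes the *statistical
machinery* (formulas, invariances, sensitivity shapes), not clinical
agreement levels.

The shift-test shape check runs on a scaled-down clinical regime: 512²
fields with coarse structure (length scale 90 px ≈ the proportional
structure scale of 3000² clinical fields) and boundary amplitude 12 px
(baseline FK well below 1, as observed clinically), one observer shifted
per trial, averaged over 20 replicate fields. Test-scale fixtures
elsewhere use 96²–256² fields, often at 1 μm/px so the 8 μm hard-core
spacing stays compatible with small images.

## Numerical choices and edge cases

* Coordinates are 0-based, x = column, y = row, pixel centers at integer
  coordinates; distances in pixels unless μm is explicit.
* Weight normalisation tolerance: Σw′ = M within 1e-9·M (validated on
  construction).
* If every universe pixel lies on a boundary (Σw = 0), weights fall back
  to uniform with a warning.
* Empty point files load as empty sets with a warning; an observer with
  zero points never matches and contributes nothing to Σm.
* `point_lost_test` refuses a fraction that removes every point.
* Masks are accepted as 8-bit grayscale (>0 → stroma) or indexed labels
  via `CategoryMap`; an optional declared label universe makes unknown
  codes fatal.

## Known limitations

* K is fixed at 2; multi-category weighted kappa is out of scope.
* DBCAA's one-to-many matching means duplicated points inflate Σa; inputs
  are only warned about, not deduplicated.
* The LOAM limits use the plain 1.96·SD of observer-minus-mean
  differences without the small-sample variance-component correction for
  the number of observers.
* ICC assumes a complete images × observers design; missing cells must be
  resolved by the caller.
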