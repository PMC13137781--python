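# Methods

## The measurement model

CT-osteoabsorptiometry treats subchondral CT attenuation as a surrogate of
the long-term mechanical loading history of a joint surface.  For each
patella the package computes an anterior–posterior maximum-intensity
projection (MIP) of the segmented bone, so each projection pixel holds the
densest voxel along its projection column — in practice the subchondral
plate when the projection axis is roughly orthogonal to the articular
surface.  The projection is windowed to 200–1200 HU: the floor excludes
soft tissue, the ceiling spans the mineralization range of subchondral
bone.  Projection columns containing no bone receive a sentinel of
`window.lo − 1` HU (renders to gray 0, can never be counted as bone).

Regional quantification is proportional, not anatomical: the tight bounding
box of the projected bone is cut into four equally wide vertical stripes
labelled medial→lateral MF, CR, MLF, LLF.  The high-density area (HDA)
fraction of a region at threshold T is the count of its pixels **strictly**
above T divided by the count of supra-threshold pixels in all four regions
combined.  Pixels exactly at T are excluded; thresholds are applied in the
HU domain on the lossless MIP rather than on the quantized 8-bit rendering,
which keeps the statistic independent of display quantization.  Counts are
integers and fractions exact rationals, so defined fractions sum to exactly
1.  When no pixel exceeds T the fractions are undefined and flagged — never
silently reported as zeros.

## Orientation conventions

2D images are indexed (row = superior→inferior, column = image-left→
image-right); all intervals are 0-based and half-open.  Left patellae are
mirrored along the medial–lateral axis into a *standardized-right* frame in
which medial is at the low-column side.  **Stripe boundaries and pixel
counts are computed in this frame**, for a reason worth recording: the
equal-width boundary rule `col_lo + round(k·W/4)` (round half up) is not
reflection-symmetric (W = 10 gives widths 3,2,3,2, whose mirror is
2,3,2,3), so partitioning mirrored anatomy directly would shift a stripe
boundary by one pixel between paired knees.  Measuring in the standardized
frame makes left and right knees geometrically congruent and the left-flip
convention exactly self-consistent; region labels are anatomical in either
frame, and the exported MIP is flipped back to anatomical orientation
afterwards.  `partition_stripes` still supports anatomical-orientation
labelling (image-space order reversed for left patellae) for working
directly with flipped images.

Other numerical conventions: 8-bit rendering maps the window linearly onto
0–255 with round-half-up (1000 HU ↦ 204, 700 HU ↦ 127.5 ↦ 128);
segmentation keeps the largest 26-connected component above 200 HU;
maximum/quadrant localization declares "indeterminate" when the top two
fractions differ by ≤ 0.05 (absolute) or the top two quadrant counts by
≤ 5% of the supra-threshold total — localization calls in comparable
studies are visual, so an explicit margin is this package's
reproducibility device; the quadrant split is at the bounding-box midpoints
with the extra row/column of odd boxes assigned to the inferior/lateral
half.

## Statistical battery

The design is paired within patients (operated vs. contralateral knee) and
repeated across regions, so the battery is entirely nonparametric:

- **Side comparison.**  Per region, a two-sided Wilcoxon signed-rank test
  on the paired fractions.  Zero differences are dropped (classic
  convention; the effective n is reported), absolute differences receive
  midranks under ties, and for n ≤ 12 the p value is exact: all 2^n sign
  assignments are enumerated and assignments with |W′ − S/2| ≥ |W − S/2|
  counted (S the total rank sum; the null distribution is symmetric about
  S/2 even under midranks).  The exact-with-ties route is why the test is
  implemented in-package; common exact implementations fall back to
  approximations under ties.  Above n = 12 a normal approximation with tie
  and continuity corrections is used.  The four regional p values are
  Holm-adjusted; effect sizes are matched-pairs rank-biserial correlations
  r = (R⁺ − R⁻)/(R⁺ + R⁻) with sign retained.
- **Interregional comparison.**  Per patient, fractions are averaged over
  both knees (row sums stay 1 by linearity); the four regions are compared
  by a Friedman test with within-patient midranks and tie correction,
  χ² = (k−1)·Σ(Rⱼ − n(k+1)/2)² / (Σrᵢⱼ² − nk(k+1)²/4), df = 3; fully tied
  data give χ² = 0.  Post-hoc: the six pairwise exact Wilcoxon tests,
  Bonferroni-corrected (min(1, 6p)).  At n = 9 the exact-test floor is
  p = 2/512, so the smallest attainable adjusted p is ≈ 0.0234.
- **Screening.**  Shapiro–Wilk is computed per series and reported, but the
  pipeline never switches to parametric tests — the analysis path is fixed.
- Quartiles (for median [IQR] summaries) use linear interpolation between
  order statistics; α = 0.05 two-sided throughout.

## The synthetic cohort generator

No patient CT data ship with the package, so every downstream stage is
validated against a phantom with analytic ground truth.  The phantom is a
stylized half-ellipsoid (semi-axes 0.42× the volume shape, flat posterior
articular face at half the anterior–posterior semi-axis): background
0 HU (soft tissue), trabecular interior 400 HU, cortical shell (outer 8% of
the normalized radius) 700 HU, and a one-voxel subchondral plate on the
articular face carrying the signal.  Plate HU per stripe = regional mean
(+ operated-side shift) + i.i.d. Gaussian noise per pixel.  Defaults:

| parameter | default | rationale |
|---|---|---|
| region mean HU (MF, CR, MLF, LLF) | 700, 850, 1150, 1050 | encodes the physiological lateral-dominant gradient MLF > LLF > CR > MF; chosen analytically so the expected supra-threshold mass preserves that ordering at all of 900/1000/1100 HU given the stripe geometry |
| noise SD | 80 HU | plausible subchondral attenuation variability at the fidelity the HDA count statistic needs |
| cortical shell | 700 HU | deliberately below the lowest HDA threshold so supra-threshold pixels are exclusively plate pixels, making regional counts analytic |
| operated shift | (0,0,0,0) | the null of no side-to-side difference |
| n patients | 9 | study-scale paired cohort |
| volume shape / spacing | 48×36×64 voxels, 0.7×0.4×0.4 mm | desk-scale volume with ≈1300 plate pixels (≈190 in the narrow edge stripes) |

The operated side is a seeded Bernoulli(1/2) per patient.  Every knee has
its own RNG stream derived from (seed, patient, side, status), noise is
drawn before mirroring, and left knees are exact mirrors of their own
right-sided construction — so seeded runs are bit-reproducible and the
left-flip convention can be tested for exact equality.  With the noise off,
pipeline-measured fractions equal the closed-form truth exactly.

`simulate_cohort_table` is an analytic fast path: it draws the identical
plate noise and counts supra-threshold pixels directly, skipping 3D volume
assembly.  A test asserts count-identity with the full volume→MIP→HDA
route, so Monte-Carlo results obtained through it are results of the
pipeline.  Calibration at study scale (one CPU, seconds): over 500 null
replicates the familywise rate of any Holm-adjusted side-to-side p < 0.05
is ≈ 0.02–0.03, within the nominal 0.05; over 200 gradient replicates the
combined-fraction rank order MLF > LLF > CR > MF is recovered at all three
thresholds and the Friedman test is significant in ≈ 100% of replicates.

What the phantom does **not** emulate: real patellar anatomy (facets,
ridge curvature, cartilage), trabecular microstructure, beam hardening or
scanner-specific noise, and inter-subject registration (the stripe scheme
is per-patella and proportional, so none is needed).  Passing tests
demonstrate correctness of the measurement and inference machinery under a
known generating model — not clinical validity on real CT, where
segmentation quality and projection-axis choice would dominate.  A further
honest caveat: the default phantom yields perfect interregional agreement
(Friedman χ² at its ceiling of 27 for n = 9, k = 4), cleaner than
real-cohort heterogeneity would be.

## Known limitations

- Segmentation is threshold + largest-component; manual or model-based
  segmentation of clinical data is out of scope.
- The projection axis is the anterior–posterior voxel axis; no
  reference-patient registration is implemented.
- DICOM export rounds HU to integers (16-bit stored values); NIfTI export
  is lossless float64.
- The normality screen is reported but cannot alter the analysis path by
  design.
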