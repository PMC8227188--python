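# Methods

`foveapit` implements a quantitative analysis pipeline for foveal pit
morphology from macular OCT scans: total retinal thickness (TRT) map
construction, foveal center location, radial resampling, parametric pit
modelling, geometric parameter extraction, and the agreement statistics
used to compare centering strategies and models between paired raster and
star acquisitions of the same eye. This note documents the models, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Thickness maps and resampling

TRT is the per-A-scan difference between the inner limiting membrane (ILM)
and Bruch's membrane (BM) heights, `TRT = ILM − BM`, equivalent to
flattening the volume with BM as the reference. Heights are in µm; lateral
coordinates in mm with x running temporal→nasal and y inferior→superior.
Left eyes are mirrored in x onto the right-eye convention.

Scattered TRT samples are interpolated with triangulation-based C1
piecewise-cubic (Clough–Tocher) interpolation onto

* a square grid of 3 × 3 mm² at 0.02 mm spacing (151 × 151), centered on
  the located foveal center, for alignment comparisons; the extent is the
  total side length, x, y ∈ [−1.5, 1.5] mm;
* a radial pattern of 24 directions × 101 radii (0–2 mm, 0.02 mm steps)
  for morphometry and model fitting. Direction 0 points along +x (nasal)
  and angles increase counter-clockwise.

Cells or samples outside the convex hull of the data stay undefined (NaN);
nothing is extrapolated. Pairwise metrics (Dalign, RMSE) skip undefined
cells and renormalize by the number of cells actually compared. Radial
resampling fails if more than 5% of samples are undefined (scan too
decentered); smaller out-of-hull tails — which arise when the estimated
center of a noisy star scan sits a tenth of a millimetre from the scan
center — are tolerated and skipped sample-wise by fits, smoothers, and
morphometry. Interior gaps are rejected. Note that Clough–Tocher
interpolation reproduces affine fields exactly but not curved ones; on a
square sampling lattice the directional interpolation error is of order
0.01–0.05 µm on smooth surfaces and considerably larger (a few µm) across
the 0.3125 mm B-scan gaps of a raster acquisition. This raster resampling
error is a real feature of sparse acquisitions and is what makes raw
raster slope estimates wiggly even without measurement noise.

## Foveal center location

Four strategies of increasing robustness:

| method       | definition |
|--------------|------------|
| `none`       | trust fixation; use the scan center (0, 0) |
| `min`        | raw A-scan of minimum TRT within the central **0.85 mm radius** circle |
| `interp_min` | resample the central **0.85 × 0.85 mm square** to a 0.02 mm grid (cubic) and take the minimum node |
| `smooth_min` | as `interp_min`, after a 0.05 mm-radius circular-support mean filter (21 pixels on the 0.02 mm grid) |

The circle-vs-square asymmetry follows each method's original wording.
The filter kernel is truncated at the window border and renormalized by
the in-window pixel count, avoiding the downward bias of zero padding.
Ties (within 1e-9 µm, far below the 3.87 µm axial resolution) are broken
by distance to the scan center, then by (B-scan, A-scan) or row-major grid
index, making degenerate inputs reproducible.

## Pit models

Six parametric families are implemented. The source publications are
identified by first author; parameter counts, fitted regions, and
fixed-point behaviour follow the published descriptions, but the concrete
equations are **reconstructions** — the package does not claim numerical
equivalence with the original implementations.

* **dubis** (6, diametric profile): z₀ + A₁ exp(−(x−x₀)²/2σ₁²) −
  A₂ exp(−(x−x₀)²/2σ₂²). The parameterization has a two-fold gauge freedom
  ((A₁,σ₁,A₂,σ₂) ↔ (−A₂,σ₂,−A₁,σ₁)); fits are canonicalized so σ₁ ≥ σ₂.
* **ding** (8, whole 2-D map, single fit): second-order polynomial surface
  minus an axis-aligned Gaussian.
* **scheibe** (4, per direction, center-anchored): the rise above the
  center D(r) = μσ² r^γ e^(−μ r^γ) + α(1 − e^(−μ r^γ)), with D(0) = 0, so
  the fitted center value equals the raw one bit-for-bit.
* **liu** (6, pit region only): flat bottom of half-width w with linear
  tilt s around x₀, C1 Gaussian walls of amplitude A and width σ outside;
  fitted only between the two detected rims but evaluated (and scored by
  the fitting RMSE) over the whole profile, which is why its map-wide
  RMSE is large.
* **yadav** (2+3, per direction): two cubic Bézier segments with control
  abscissae at thirds (so the lateral coordinate is linear in the Bézier
  parameter and the problem is linear least squares, solved exactly);
  the inner segment pins both endpoints to the raw center and rim, the
  outer segment pins its start to the rim. CFT, rim height and rim radius
  are therefore identical to the raw estimates.
* **breher** (9, diametric profile): sum of three Gaussians, canonicalized
  by ascending center.

Fitting is nonlinear least squares (trust-region reflective) with at most
1000 residual evaluations and 1e-6 tolerances on residual and coefficient
updates. Initial values are data driven (offsets from the profile edge
mean, pit amplitude from rim−center, widths from the detected rim radius);
up to 5 seeded, jittered restarts are attempted on non-convergence and the
lowest-SSE solution kept. Non-convergence is always reported
(`converged=False`, per-unit flags), never silent. Width-like coefficients
are bounded positive. Two additional bounds cut off degenerate ridges
found during development: the liu pit center is confined to ±1 mm with a
flat-bottom half-width ≤ 1.5 mm (otherwise the walls disengage and the
model collapses onto a line), and scheibe's decay rate is bounded μ ≥ 0.05
with γ ∈ [0.5, 10] (μ → 0 linearizes the exponential and lets α diverge
along a pure power-law ridge; μ = 0.05 still admits rim radii beyond the
2 mm analysis region).

Because the radial profile set has 24 directions, "B-scan"-region models
are fitted on 12 *diametric* pseudo-B-scans formed by joining direction k
with direction k+12 (mirrored radii, 201 samples), preserving the models'
two-sided shape assumptions. LOESS is likewise applied per diametric
profile.

Two smoothers complement the parametric models: LOESS (local
second-degree polynomial with tricube weights over the nearest span·n
samples, span ∈ [1%, 50%], at least 5 points) and a centered moving
average (5–60 samples, shrinking windows at the edges; even windows take
one extra trailing sample). The LOESS smoother is implemented in-package
because the widely used `statsmodels` lowess is local-linear only. Both
smoothers are linear operators and reproduce constants; LOESS reproduces
global quadratics exactly.

## Geometric parameters

Per direction: CFT (TRT at r = 0, shared across directions), rim height
(maximum TRT excluding r = 0), rim radius (radius of that maximum; a rim
on the 2 mm boundary is flagged but included in averages), and maximum
slope (largest radial derivative between center and rim, µm/mm, with a
degrees helper atan(slope/1000)). Parameters are averaged over the 24
directions.

The slope derivative uses a fourth-order central stencil on the 0.02 mm
lattice (second-order/one-sided near the ends) with parabolic vertex
refinement of the discrete maximum. A plain 3-point central difference
averages the slope over a 0.04 mm window and clips sharp derivative peaks
by ≈1.7% on a realistic sharp-pit profile; maximizing a spline derivative
on a sub-lattice instead chases interpolation kinks of sparsely sampled
raster data (inflating raw slope by >10% even without noise). The chosen
estimator tracks a 0.0005 mm dense-lattice reference to ≈0.06% while
retaining the averaging behaviour of a lattice stencil.

For fitted profiles the same rules apply to the fitted values, except
parameters a model pins to raw landmarks are copied from the raw
estimates (scheibe: CFT; yadav: CFT, rim height, rim radius) and are
rendered as dashes in report tables.

## Agreement statistics

* **Dalign** — mean absolute TRT difference between the co-registered
  raster and star maps of one eye, over cells defined in both.
* **Fitting RMSE** — root mean square raw-vs-fitted difference.
* **Relative bias** — 100·(x_model − x_raw)/x_raw; negative =
  underestimation.
* **ICC(2,1)** — two-way, absolute-agreement, single-measurement
  intraclass correlation in the Shrout–Fleiss mean-squares form; 95%
  confidence intervals by percentile bootstrap (default 10⁴ resamples)
  over subjects, keeping each eye's raster/star pair intact. The
  implementation is cross-checked in the test suite against `pingouin`'s
  ICC2 and a brute-force ANOVA oracle.
* **Distribution comparisons** — Kruskal–Wallis across methods, pairwise
  Mann–Whitney U (exact for tie-free groups of ≤20, tie-corrected normal
  approximation otherwise), Shapiro–Wilk normality screening; flagged at
  α = 0.01.

## Synthetic data generator

The generator replaces unavailable clinical volumes and defines the
conditions under which the package's directional claims are tested.

**Surface.** Thickness is CFT plus a radial rise: a unit-peak transient
(the center-anchored family above with μ = 1) plus a settle term,
numerically normalized per direction so the rise peaks at exactly the pit
depth, exactly at the rim radius. Pit depth and rim radius are modulated
by first and second angular harmonics (default amplitudes 5% and 3%,
random phases) to create nasal/temporal asymmetry. Ground-truth
per-direction parameters are evaluated on a 0.0005 mm lattice.

**Acquisitions.** Raster: 25 B-scans × 512 A-scans over 9.0 × 7.5 mm;
star: 12 diametric B-scans × 768 A-scans over a 4.5 mm diameter (30° ≈
9.0 mm, 15° ≈ 4.5 mm at the ≈0.3 mm/degree schematic-eye convention — a
stated convention, since per-eye axial-length scaling is out of scope).
Each acquisition gets (a) an independent fixation decentration, (b)
correlated Gaussian noise along each B-scan (white noise filtered to a
0.08 mm correlation length, rescaled to the target SD — the "wiggliness"
that corrupts slope estimates), and (c) sparse single-A-scan blips
(rate 0.002, ±40 µm) imitating segmentation failures. Star scans get
1.75× the raster noise SD (default 3 µm), consistent with star scans
looking visually noisier.

**Cohorts.** Per-eye shape parameters are drawn from CFT 225 ± 20 µm, rim
height 340 ± 20 µm, rim radius 1.0 ± 0.15 mm — order-of-magnitude
realistic conventions for healthy adult eyes, not estimates of any
dataset. Eyes are randomly OD/OS (left eyes stored mirrored). Default
decentration is drawn isotropically with 0.10 mm SD truncated at 0.15 mm:
the cap keeps the 2 mm radial pattern inside the star acquisition's
2.23 mm data hull even after adding the center-location error of a noisy
scan, so the model-comparison workflow always sees (nearly) complete
profiles. Center-location studies explicitly use a heavier misfixation
regime (SD 0.15 mm, truncated at 0.4 mm, bracketing the worst observed
clinical misfixation of ≈0.35 mm), since large offsets are exactly what
those methods exist to correct.

**What the generator does not emulate:** reflectivity images and
segmentation itself; pathology (hypoplasia, edema — all surfaces are
concave pits); fan-beam display distortion; axial-length-dependent
lateral scaling; inter-eye correlation. Passing tests therefore
demonstrate the pipeline's internal correctness and the direction of its
noise/smoothing trade-offs, not clinical performance on real scans.

A note on fitting-error comparisons: because the generator's radial family
coincides with the scheibe model family, scheibe fits synthetic cohort
data with zero model bias, an advantage real data would not grant it. The
model-flexibility ordering of fitting errors (yadav ≤ scheibe ≤ dubis ≤
ding) is therefore asserted on out-of-family pit shapes (cosine bowl with
power-law decline) where no model is privileged.

## Study workflows and problem sizes

`run_center_comparison` centers each acquisition with each strategy's own
estimate, resamples both maps to the common grid, computes Dalign per eye
and method, and compares method distributions (Kruskal–Wallis + pairwise
Mann–Whitney). `run_model_comparison` centers with smooth+min (the best
aligner), builds radial sets, computes raw parameters, fits every
configured model/smoother, and reports RMSE (raster/star), per-parameter
ICC(2,1) with bootstrap CIs, per-parameter bias, and a LOESS span-sweep
ICC-vs-bias curve. Both are deterministic under a fixed seed; eyes are
independent work units.

The test suite exercises 50-eye cohorts; `scripts/acceptance.py` runs the
center comparison on 40 eyes and the model comparison on 20 eyes with 10⁴
bootstrap resamples — sizes chosen so a complete run finishes in a few
minutes on one core while keeping the rank-based comparisons well
powered.

## Known limitations

* The six model equations are reconstructions; coefficient values are not
  comparable with the original publications.
* Raster acquisitions carry an irreducible cross-B-scan interpolation
  error that inflates raw slope estimates; on synthetic raster data the
  smooth scheibe fit reads ≈10% below the raw slope even without noise.
  This mirrors the raster/star slope asymmetry seen clinically but means
  "raw" is not ground truth for slope on sparse patterns.
* The interchange format stores 6 significant digits (sub-0.01 µm digits
  are meaningless at 3.87 µm axial resolution); round-trips are exact at
  that precision, not bit-exact for arbitrary floats.
* ICC bootstrap CIs are percentile intervals; no bias correction (BCa) is
  applied.
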