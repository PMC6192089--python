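# Methods

This note documents the models and numerical choices behind `octlayers`:
what each stage assumes, which parameters matter, what the synthetic
generators do and do not emulate, and the known limitations.

## Coordinate and depth conventions

Volumes are indexed `(b, z, x)`: B-scan, depth pixel (vitreous →
choroid), A-scan. All indices are 0-based; A-scan ranges are half-open.
An interface depth is the first pixel row of the *lower* (deeper)
tissue, so layer k occupies rows `[z_k, z_{k+1})`. The directional
gradient is placed accordingly: the value at row z is
`I[z] − I[z−1]` (negated for bright-to-dark polarity), so a step edge
peaks exactly at the interface row under this convention.

Default scan geometry follows a 20° × 15° macular raster: 73 B-scans of
1024 A-scans, 3.9 µm axial pixels, 62 µm B-scan spacing. The lateral
A-scan spacing (5.7 µm) assumes ≈291 µm/degree in an emmetropic eye;
it is an explicit geometry field, so no computation depends on that
conversion being right for a particular eye. The axial pixel count per
A-scan is instrument-dependent and configurable (default 496).

## Graph segmentation

### Model

An interface is a connected left-to-right path (one row per column,
|Δrow| ≤ 1) minimizing total edge weight `2 − (g_a + g_b) + w_min` over
a normalized directional-gradient map. Because every path has the same
edge count, this is equivalent to maximizing the summed gradient along
the path; the dynamic-programming sweep accumulates that gradient sum
directly. This has two benefits: it is an exact optimum (verified
against brute-force enumeration in the tests), and tie comparisons
involve no per-edge constants, so the deterministic tie-break (prefer
the smaller row, then the smaller row change — i.e. the
lexicographically smallest optimal path) is numerically robust.
Endpoints are free: the classical construction appends two virtual
minimal-weight columns, which contribute equally to every path and are
therefore elided.

### Sequential detection

Interfaces are found in the order 1 (vitreous/NFL), 6 (ONL/OSL),
8 (RPE/choroid), 7 (OSL/RPE), 5 (OPL/ONL), 2 (NFL/GCLIPL),
3 (GCLIPL/INL), 4 (INL/OPL): the highest-contrast boundaries first,
each later search confined to the rows between already-found
neighbours, with `min_gap_px` (default 1) rows reserved per undetected
interface in between. The ordering matters: detecting GCLIPL/INL before
OPL/ONL fails, because both are bright-to-dark edges and OPL/ONL has
the larger contrast, so a wide-band search for the former locks onto
the latter. Detecting OPL/ONL first (disambiguated as below) leaves
each weaker edge alone in its band. Gradient polarities default to the
relative reflectance ordering of the bounded tissues (vitreous < NFL <
GCLIPL > INL < OPL > ONL < OSL < RPE > choroid).

### Robustness components

* **Noise-adaptive lateral smoothing.** The B-scan is smoothed along x
  with a Gaussian (σₓ = 3 px) before the gradient. Lateral-only
  smoothing suppresses noise without displacing vertical edges. The
  configured σ is scaled by `min(1, σ̂/0.01)`, where σ̂ is a robust
  noise estimate (1.4826 · median |vertical difference| / √2 — exact for
  piecewise-constant images whose edges are sparse). A noise-free image
  is therefore not smoothed at all and every boundary is localized at
  the voxel quantization limit.
* **Column padding.** Columns are reflect-padded (12 px) during the
  search so path endpoints are supported from both sides; unpadded
  endpoints showed several-pixel dives in noise.
* **Low-contrast interfaces.** NFL/GCLIPL and INL/OPL separate nearly
  iso-reflectant tissues (intensity steps of ~0.07 and ~0.02 against
  noise of σ = 0.05). They use a wider lateral smoothing (σₓ = 12 px),
  trading lateral resolution for the averaging these edges need.
  Taller (multi-row) gradient kernels were rejected: their response
  leaks below neighbouring strong edges and systematically misplaces
  the next interface down.
* **Darkness weighting for OPL/ONL.** The ONL is the darkest retinal
  band. Interface 5's gradient is multiplied by a sub-edge darkness
  score (1 − mean intensity over the 8 rows below), which cleanly
  separates it from the same-polarity, similar-contrast GCLIPL/INL
  edge; without this the path can ride the wrong boundary for long
  stretches.

All of these are `GraphParams` fields with the defaults above.

### Manual correction and disruptions

`refine_with_manual` re-runs the search in a ±`half_band_px` (default
5) band around an operator-drawn line — the banded re-search model of
interactive correction. Disruptions are *inputs* (operator
annotations): `apply_disruptions` flags the annotated A-scans invalid
without touching depths. There is no automatic disruption detection.

## Enface maps and subfield metrics

Thickness at (b, x) is `(z_{k+1} − z_k) · 3.9 µm` from the (possibly
sub-pixel) interface depths; reflectance is the mean intensity of rows
`[⌈z_k⌉, ⌈z_{k+1}⌉)`. A pixel is unassigned when either bounding
interface is invalid (or the row range is empty), and unassigned pixels
are excluded from every downstream quantity — corrupting data inside
disrupted regions provably changes no metric.

The ETDRS central subfield is the set of enface pixels within 500 µm of
the centre under the anisotropic physical spacings (62 µm × 5.7 µm; no
resampling to an isotropic grid, which would require interpolation
choices the rest of the pipeline never needs). The default centre is
the grid centre (scans are fovea-centred); `find_fovea` offers
auto-centering via the argmin of the 3×3-boxcar-smoothed total
thickness map, with ties broken toward the grid centre and then the
smallest indices.

Reflectance ratios divide subfield *means* (mean layer intensity / mean
RPE intensity) rather than averaging per-pixel ratios; this matches the
definition of a normalization against imaging variability and stays
stable when assigned RPE pixels are sparse. A metric with no assigned
pixels in the subfield is reported as missing (`None`), never as 0.
RPE_T and RPE_R (≡ 1) are computed but excluded from the six-layer
statistical family. Disruption percentages are unions of the two named
interfaces' disrupted areas (NFL_d: 1∪2, INL_d: 3∪4, ONL_d: 5∪6,
RPE_d: 7∪8) over the subfield pixel count — a union, so overlapping
annotations never count twice.

## Statistics

* **DME classification**: CST strictly greater than 320 µm (men) /
  304 µm (women).
* **Acuity models**: OLS of logMAR on one metric plus age, sex, race
  (three dummies, White reference), diabetes type, duration and HbA1c,
  solved by statsmodels' pinv/QR path (never the raw normal equations —
  those serve as the independent oracle in tests). Coefficients are
  rescaled to per-10-µm or per-0.1-ratio units; CIs and two-sided
  p-values come from the t distribution on n − p degrees of freedom.
  A rank-deficient design raises a collinearity error naming the
  offending columns; `drop_degenerate=True` instead drops constant
  columns, which matters in simulation studies where a rare category
  (e.g. the ~3% Asian stratum at n = 121) is occasionally absent.
  Influential-point sensitivity refits exclude observations with
  Cook's distance above 4/n (the conventional cutoff; none is
  prescribed for this analysis).
* **Multiplicity**: Bonferroni with family size m = 6 (six layers per
  metric family); 0.05/6 reported as 0.008 at 3-decimal rounding. The
  family size is configurable since thickness and reflectance could
  also be pooled (m = 12).
* **Group comparisons**: one-way ANOVA and Kruskal–Wallis (midranks,
  tie correction, χ² with k−1 df) via scipy; the all-identical
  degenerate case returns H = F = 0, p = 1 explicitly since the tie
  correction is undefined there. Severity bins: exactly 0%, (0, 10)%,
  and ≥10% (boundary inclusive).
* **Power**: Fisher-z approximation for the partial correlation of one
  predictor among k total variables,
  `Φ(z_r √(n − (k−1) − 3) − z_{1−α/2}) + Φ(−z_r √(n − (k−1) − 3) − z_{1−α/2})`,
  the second tail giving power = α at r = 0 under the two-sided
  convention. "k variables" is read as 1 tested predictor + (k−1)
  controlled covariates; k is an argument, so the alternative reading
  (race as one variable vs three dummies) is equally computable. The
  approximation is documented as such — it tracks the exact
  noncentral-t power to within a few percentage points, and a
  simulation mode (OLS on data with the requested population partial
  correlation) provides the cross-check.

## Synthetic generators

### Phantoms

Interface depths are cumulative layer thicknesses below a flat inner
surface (default 390 µm; 120 µm in the reduced test geometry). Central
thickness defaults (18, 28, 21, 21, 114, 44 µm for NFL…OSL) are typical
no-DME central-subfield means; RPE thickness (30 µm), vitreous level
(0.05) and choroid level (0.20) are modelling defaults. Reflectance
levels relative to RPE = 1 are (0.54, 0.61, 0.50, 0.52, 0.37, 0.81,
1.00). A Gaussian foveal pit (depth fraction 0.6, σ = 300 µm) thins
GCLIPL, INL and OPL only — the inner layers that vanish at the fovea.
The pit fraction default stays below ~0.75 so the thinned layers remain
at least ~2 px thick at 3.9 µm/px and adjacent interfaces stay
resolvable; deeper pits are expressible but place two interfaces inside
one voxel, where sub-voxel recovery is not meaningful.

Noise is additive Gaussian on [0, 1] intensities (σ = 0.05 by default,
emulating the residual noise of frame-averaged clinical B-scans), with
an optional multiplicative speckle-style mode; neither reproduces true
OCT speckle statistics, vessel shadows, or motion artifacts, so passing
phantom tests demonstrates correctness of the algorithmic chain, not
clinical-grade robustness. Cysts are hypo-reflective ellipsoids
(level 0.10) whose vertical chord locally inflates the host layer, so
they displace boundaries as real fluid does. Disruption zones blend the
two adjacent layers' levels to zero interface contrast and are emitted
as ground-truth annotations — disruption is modelled as contrast loss,
matching its definition as a visually indiscernible interface.

### Cohorts

Covariates follow the study population: age 56.0 (11.8) y, 58.4%
female, race 16.8/51.7/28.2/3.4% (White / African American / Hispanic
or Latino / Asian), 91.9% type 2, duration 16.3 (10.1) y, HbA1c
7.9 (1.7)%. Metrics default to the no-DME means/SDs (e.g. INL_T
21 ± 8 µm, CST 263 ± 23 µm); thickness draws are truncated at 0, which
shifts the most dispersed mean (GCLIPL_T 28 ± 12) by < 0.05 µm. Acuity
is `intercept + β·metrics + γ·covariates + N(0, residual_sd)` with
residual SD 0.11 — chosen to match both the no-DME acuity scatter
(0.02 ± 0.11 logMAR) and the CI widths of the published-scale
regression (an INL_T CI of width ≈ 0.05 per 10 µm at n = 121). Draws
are independent across metrics; real layer metrics are correlated, so
cohort tests validate estimation machinery, not multivariate structure.

## Problem sizes in tests

Tests and the acceptance checks run phantoms of 3–17 B-scans × 200
A-scans × 160 depth px, which preserve the physical pixel spacings, the
pit scale and the noise level while keeping the suite fast. The 17-row
geometry is the smallest that contains the full 1-mm subfield at 62 µm
B-scan spacing. Segmentation accuracy was additionally verified at
120/200/240 A-scans over 150 noise seeds. Regression recovery uses 200
cohorts of n = 121 and the type-I calibration 2,000 null cohorts.

## Numerical details

* Shortest-path ties: exact gain comparison, smaller row first; a
  uniform map returns the topmost band row.
* `w_min = 1e−5` keeps all edge weights positive (Dijkstra-compatible)
  without affecting path ranking.
* Volume TIFF round trips quantize to uint8 (exact to 1/255); interface
  CSVs are written at %.17g and parsed with round-trip float precision,
  so they are lossless.
* Thickness-map conservation (Σ layer maps = total map) holds to float
  rounding (≤ 1e−9 µm), since the sums telescope over shared interface
  arrays.
* Seeding: all generators use `numpy.random.default_rng`; identical
  (spec, seed) pairs are bit-reproducible.

## Known limitations

* The INL/OPL boundary carries an intensity step (~0.02) smaller than
  the default noise σ (0.05); per-column evidence is therefore
  sub-threshold and the path relies on heavy lateral averaging. On the
  default phantom its MAE stays ≤ 1 px across all tested seeds, but
  when layer thicknesses are also randomized ±20% under full noise,
  roughly one phantom in ten exceeds 1 px MAE (worst observed 1.07 px)
  on that single interface. Wider kernels, taller kernels and
  path-stiffness penalties were evaluated and did not improve this;
  it is a signal-to-noise limit of the per-B-scan formulation (no
  cross-B-scan regularization, which is out of scope).
* Segmentation quality on images with pathology beyond the phantom
  vocabulary (large cysts crossing layers, shadowing, detachments) is
  unvalidated; the disruption-annotation mechanism is the intended
  escape hatch, as it is in operator-reviewed clinical workflows.
* The fovea finder assumes the pit is the thinnest smoothed location;
  it will mislocate in eyes where edema inverts the profile, which is
  why the subfield centre defaults to the grid centre instead.
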