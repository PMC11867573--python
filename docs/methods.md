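# Methods

## Problem setting

Contour variability studies compare binary organ masks drawn by different
observers, on different MR sequences, or by automatic models, for the same
patient on a shared image grid. `contourvar` implements the standard
agreement metrics and study designs for the pelvic organ-at-risk setting
(bladder, rectum, anal canal, left/right femoral heads; sequences T1WI,
T1dixonc, T2WI; observers R1, R2 and AUTO) and a synthetic phantom module
that emulates such cohorts, because the clinical MR delineations this kind
of study uses are access-restricted.

## Geometry and metric conventions

**Grid model.** A mask is a binary occupancy array on a regular,
axis-aligned, anisotropic grid; indices are 0-based and a voxel center
sits at `origin + (index + 0.5) * spacing` (mm). NIfTI affines that are
not axis-aligned with positive scales are rejected rather than silently
reoriented: all masks within a patient must already share one grid, and
resampling is out of scope. Masks are binarized at 0.5 on load so
float-stored labels survive a round trip.

**Point sets for distance metrics.** Hausdorff-type distances are
computed between boundary point sets: centers of foreground voxels with
at least one 6-connected background (or out-of-grid) neighbour. This is
the common choice in segmentation evaluation, yields a finite set with an
exact brute-force oracle, and is configurable (`points="filled"` uses all
foreground voxel centers) since the convention is not universal. All
distances are Euclidean in physical mm, so 1 x 1 x 3 mm grids — the
3 mm slice thickness typical of pelvic MR protocols — are handled
correctly.

**95% HD.** The directed 95th-percentile distance uses linear
interpolation between closest order statistics (the most common
percentile rule; `q = 100` reproduces the directed HD exactly). The
symmetrized value is the *average* of the two directed 95th percentiles.
Sources sometimes print this symmetrization with the same directed term
twice, which would make the symmetrization a no-op; averaging the two
opposite directions is the reading that makes it meaningful and is what
this package computes. It is bounded above by the undirected HD.

**Undefined cells.** Metrics on empty or missing masks raise
`MetricUndefinedError`; the pipeline records such cells as "not
available" and excludes them from aggregation with the per-cell `n`
reported. Zeros are never imputed — they would corrupt mean ± SD tables.

**Nearest-neighbour search** uses a k-d tree but is contractually
identical to the exhaustive double loop; the test suite enforces
agreement to 1e-9 on random mask pairs.

## Statistics

**ICC(2,1)** (two-way random effects, absolute agreement, single
measures) is computed from the two-way ANOVA mean squares:
`ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))`. Rater bias
(the column effect) counts against agreement — that is what "absolute
agreement" means. Negative estimates are reported as computed, not
clipped; the `good` flag applies the conventional 0.75 threshold. The
estimate is invariant to shifting and positive rescaling of all cells.

**Wilcoxon rank-sum.** The statistic is the sum of midranks of the first
sample. The exact two-sided p-value is the permutation probability
P(|W − E[W]| ≥ |w_obs − E[W]|), computed by a dynamic program over the
permutation distribution of doubled midranks (doubling makes tied
midranks integral, so the same code is exact under ties when exactness is
forced). The automatic rule uses the exact path when min(n, m) ≤ 10 and
the pooled sample has no ties, otherwise a normal approximation with tie
correction and a 0.5 continuity correction. The cohort pipeline applies
the rank-sum test to the two volume samples as stated in standard
practice for this analysis, even though the volumes are paired per
patient; a paired signed-rank variant is available
(`volume_test="signed_rank"`). No multiple-testing correction is applied.

**Aggregation.** Metrics are computed per patient and then aggregated as
mean ± sample SD (ddof 1) across patients — no pooling of voxels across
patients. Cells with one record get their SD marked absent.

## Synthetic phantom cohorts

**Geometry.** Each patient is a set of five pairwise-disjoint analytic
shapes rasterized at voxel centers on a 96 x 96 x 48 grid at 1 x 1 x 3 mm:
a bladder ellipsoid (semi-axes 20 x 16 x 15 mm) anteriorly, a curved
rectum tube (radius 9 mm) posteriorly with a shorter anal-canal tube
(radius 5 mm) stacked inferiorly below it, and two lateral femoral-head
spheres (radius 12 mm). The arrangement mimics the anatomical
relationships (bladder anterior to rectum; anal canal from the anorectal
line down; femoral heads lateral) at a scaled-down field of view. One
uniform per-patient scale factor in 1 ± 0.10 jitters all radii, providing
the between-patient volume variance that ICC estimation needs.
Construction raises if shapes leave the grid or overlap.

**Perturbation model.** Observer/sequence variability is emulated on the
signed-distance representation of each structure: the perturbed mask is
the sublevel set `sdf(x − t) ≤ f(x)`, where `t` is a rigid translation
with per-axis SD `translation_sd` (mm) and `f` is a smooth random field
with SD `boundary_sd` (mm) — trilinear interpolation of a white-noise
lattice with 24 mm node spacing, normalized to unit SD on a fixed probe
of the grid. Because `|∇sdf| = 1`, the field value is directly a boundary
displacement in mm, which makes `boundary_sd` interpretable against 95%
HD values. The field is re-centred to zero mean over the structure's
boundary band, so stochastic noise deforms the boundary without a random
global inflate/deflate: systematic over-/under-segmentation is expressed
only through the explicit `dilation_bias` (voxels of 6-connected
dilation/erosion applied last). The zero model is the identity, and a
perturbation that empties a mask raises. Internally all level-set work
happens on padded bounding-box crops (4-sigma padding) purely for speed.

**Cohort composition.** Each observer x sequence cell composes two draws
applied jointly to the ground-truth level set: a sequence-level draw
seeded by (patient, sequence) only — *shared* by all observers reading
that sequence, representing how the sequence renders the anatomy — and an
observer-level draw seeded by (patient, observer, sequence). Shifts and
fields add. This makes interobserver disagreement on one sequence smaller
than intersequence disagreement for one observer, the statistical
structure the cohort designs quantify. Observer errors are modelled
independently per structure; real observers likely have correlated errors
across structures, which this generator does not emulate. Seeds split
hierarchically from one master seed via spawn keys, so adding patients
never reshuffles existing ones.

**Presets.** `clean` is the all-zero identity cohort (used for end-to-end
self-agreement contracts). `paper_like` gives the human observers ~1 mm
boundary noise and 0.4 mm translation noise, the AUTO observer a larger
and more sequence-dependent profile (best on T2WI), and puts 2.25x the
noise on T1dixonc at both the sequence and observer level, so T1WI–T2WI
is the most similar pair for every observer — the qualitative ordering
reported for clinical pelvic delineations. `heavy_noise` scales
`paper_like` by 2.5. The default cohort size is 29 patients, the
testing-cohort scale the phantom module emulates.

**What passing tests show.** The phantoms validate the metric and
pipeline machinery — exactness, symmetry, calibration, ordering, shapes —
under controlled noise. They do not establish anything about real
observers: phantom shapes are smooth and convex-ish, noise is stationary
and structure-independent, and no intensity information exists. Numeric
agreement values from the synthetic cohort characterize the preset, not
clinical variability.

## Numerical and design choices

- Percentile rule: linear interpolation (pinned by an independent
  sort-and-interpolate oracle in the tests).
- Grid comparability: spacing/origin/shape must match within 1e-6
  relative tolerance; mismatches raise naming the offending field, as
  they signal unregistered inputs.
- ICC degenerate cases: MSE is clamped at zero against floating-point
  negatives; a zero denominator with positive subject variance reports
  ICC 1.
- The ICC recovery simulation draws the rater contribution independently
  per measurement (variance budget 4/1/1, population absolute-agreement
  ICC 2/3). With only two raters, a single draw of systematic rater
  offsets would leave the estimate dominated by that one realized offset
  (estimator SD ≈ 0.12) — no fixed tolerance near ±0.03 would be
  meaningful — while the per-measurement design concentrates the
  estimator (SD ≈ 0.017 at n = 1000) at the same population target.
- Wilcoxon exactness is feasible because doubled midranks are integers;
  the DP is O(N · n · S) and is only entered for small `min(n, m)` (or on
  request).
- Problem sizes: the acceptance script uses a 29-patient cohort for the
  paper_like run, 3 patients for the zero-noise identity contract,
  n = 1000 subjects for ICC recovery and 4000 null simulations for
  Wilcoxon calibration — sizes chosen so the whole script reruns in a
  couple of minutes on one CPU while keeping Monte-Carlo error well
  inside the checked tolerances.
- Determinism: cohort generation and the pipeline are pure functions of
  (inputs, seed); reports contain no timestamps, so re-runs are
  byte-identical.

## Known limitations

- No image registration or resampling: masks must already share a grid.
- No DICOM RT-STRUCT parsing; NIfTI only.
- Boundary extraction is voxel-based (no sub-voxel surface meshing); at
  3 mm slice spacing the discretization of the 95% HD is of voxel order.
- The automatic observer is a noise model, not a segmentation network;
  it reproduces the *statistical* pattern of auto-vs-manual comparisons
  only.
- ICC confidence intervals and other ICC forms ((1,1), (3,1), (2,k)) are
  not provided.
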