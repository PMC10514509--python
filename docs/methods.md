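# Methods

`orgwound` quantifies single-cell repair dynamics in airway organoids after
targeted laser ablation of 1–10 cells. Because such organoids are nearly
centrosymmetric epithelial spheres, all spatial readouts are computed on 2D
representations of the confocal/multiphoton z-stacks, and every distance is
expressed as the geodesic (arc) distance along the fitted epithelial circle
from the ablation site, grouped into 30-µm bins.

## The measurement model

**Projection.** Tracking uses maximum-intensity projections of the slices
around the ablation plane; EdU quantification uses sum projections. Both are
pixelwise reductions over a half-open z-slice window.

**Nucleus detection.** Nuclei are local maxima of a scale-normalized
Laplacian-of-Gaussian response at the nuclear scale σ (default 1.0 µm),
thresholded at a fraction (default 0.15) of the peak response, separated by
at least 2 µm, with subpixel positions from the intensity-weighted centroid
of the positive response in a ±2σ window. A deterministic blob detector was
chosen over a learned instance detector: the target objects are blob-like
fluorescent nuclei at a known scale, the artifact then carries no trained
weights, and results are exactly reproducible. Every downstream stage also
accepts plain point tables, so detection can be bypassed entirely. An
optional exclusion disc around the declared ablation site suppresses
detections inside the wound's transient autofluorescent scar (default
radius 0, i.e. off).

**Tracking.** Consecutive frames are linked by a linear assignment problem
over squared Euclidean distances; links longer than 15 µm per 30-min frame
are forbidden, and the alternative (non-link) cost equals the squared
linking radius so that any feasible link beats opening/closing a track. A
second global LAP pass closes gaps of up to 2 missing frames when the jump
does not exceed the linking radius times the number of frames spanned. Cost
terms use geometry only (no intensity/size features). Per track we report
three migration metrics — total path length, net start-to-end displacement,
and maximum excursion from the start — with **path length** as the default
headline metric; the original figure of per-cell "distance traveled"
visualizes cumulative distance, but the choice is a single config switch
(`quantify.migration_metric`). Tracks covering fewer than 50 % of the
movie's frames are excluded from migration statistics, since partial tracks
bias distance sums; per-track frame coverage is recorded so other policies
can be applied downstream.

**Shell geometry.** The cell positions of a frame are fitted with an
algebraic least-squares circle (Kåsa linear solve), which is exact on
noiseless rings; an optional Gauss–Newton refinement of the orthogonal
residuals (tolerance 1e-8, ≤ 50 iterations) is off by default. The ablation
site comes from the laser coordinates in the config (or, for synthetic
runs, the circular mean of the ablated cells' angles) and is projected onto
the circle per frame. Distances are arc lengths r·Δθ. Arc rather than chord
is forced by the data layout: chordal distances can never exceed the
organoid diameter (~150 µm), while distance bins up to 180–210 µm occur;
half the circumference of a 150-µm organoid is ~235 µm. The chordal metric
remains available (`geometry.distance_metric: chord`) for sensitivity
analyses only. Bins are half-open, 0-based, 30 µm wide. Migration binning
uses each track's position at the reference frame (first post-ablation
frame); EdU binning uses the fixed imaging timepoint.

**EdU positivity.** Per organoid, nuclei are called EdU-positive when their
mean EdU-channel intensity (disc aperture = detection radius) exceeds a
threshold. Default strategy: Otsu's threshold on the per-nucleus intensity
distribution, assuming a bimodal positive/negative mixture; alternatives
are a fixed absolute value or median + k·MAD. Explicit boolean labels can
be passed instead (bypass mode), which is how ground-truth identity checks
are run.

**Morphometry.** Per z-slice the whole organoid is segmented: Gaussian
smoothing (2 µm), Otsu threshold, an exact Euclidean morphological closing
(radius 10 µm, implemented with two distance transforms) that bridges the
gaps between neighbouring nuclei so that the lumen becomes a hole, largest
connected component, hole filling. Slices whose foreground–background
separation is below 5 background SDs are rejected as "no organoid found"
(this is what happens on z-planes beyond the organoid) and skipped with a
warning. The slice diameter is the mean of the minor and major axes of the
mask's second-moment ellipse; the timepoint diameter is the mean over
slices; the series is normalized to timepoint 0 = 100 %. The slice count is
always taken from the data, not assumed.

A known, documented bias: thresholded masks carry a roughly constant
outline halo of a few µm (smoothing + nuclear extent + radial jitter),
which slightly damps relative growth — at the default growth law
(+6 %/24 h) the recovered endpoint is within 1 % of truth, but for much
larger growth the damping grows with the growth itself.

**Statistics.** Dispersion is mean ± SEM with n counting organoids, never
cells; per-bin aggregation across organoids gives each organoid one value
per bin, and organoids lacking a bin are excluded from that bin (absence is
not a zero). Group comparisons use the two-sided pooled-variance Student's
t-test and one-way ANOVA at α = 0.05; for two groups F = t² exactly.
Zero-variance inputs are handled explicitly and flagged degenerate. No
multiple-testing correction is applied by default, matching per-bin
reporting practice; Holm adjustment is available.

## The synthetic generator

The generator emulates the imaging experiments so that every stage can be
verified against ground truth without external data. An organoid is a 2D
ring of `n_cells` nuclei: angles equally spaced with small Gaussian jitter
plus a random global rotation, per-cell radius drawn once from
N(R₀, jitter²) and held fixed (cells stay in the epithelial monolayer).
Motion is tangential: per frame each angle advances by N(0, (σ_t/R)²), plus
a wound-directed step of `drift_speed` for cells within `drift_range` arc
distance of the wound (clamped at the wound). The shell radius follows
R(t) = R₀(1 + g·t). Ablation removes k angularly contiguous cells after the
ablation frame; the wound is the circular mean of their angles projected to
the circle. EdU labels are independent Bernoulli draws with probability
baseline + per-bin boost. Rendering paints each nucleus as a 3D Gaussian
(lateral σ 1 µm, Gaussian axial attenuation, σ_z 3 µm) into a
frames × z × channels × y × x stack, scales EdU-positive nuclei by the
channel contrast (default 5), optionally adds a bright static scar blob at
the wound for the first frames (autofluorescence mimic, excluded from
ground truth), and applies Poisson shot noise plus Gaussian read noise.
All randomness flows from one seeded generator per operation.

Defaults are the study conditions: R₀ = 74 µm (148-µm organoids), 30-min
frames, z ± 8 µm at 2-µm steps, 0.4 µm/px, 100 cells (≈ 4.7-µm nuclear
spacing on a 465-µm circumference), growth 0.25 %/h (+6 %/24 h, the cohort
148 → 157 µm), σ_t = 0.8 µm/frame (≈ 30-µm mean 24-h path length), drift
0.7 µm/frame within 60 µm (≈ ×1.33 path in the near bin), baseline EdU rate
0.13 with default boosts {bin 1: +0.065, bin 4: +0.135}. Motility and
labeling parameters are calibrated only loosely to cohort-level summaries
and are test scaffolding, not biology.

What the generator does **not** model: 3D shells (rings only), nuclear
shapes and PSFs, spectral bleed-through, cell division, and steric
(volume-exclusion) interactions between nuclei. The last one matters for
experiment staging: under long free tangential diffusion, simulated nuclei
can drift unphysically close and merge under any finite-resolution
detector, which inflates per-detection label rates. Real epithelia maintain
spacing. The fixed-specimen EdU experiment is therefore staged on the
intact post-ablation ring (first post-ablation frame, scar excluded, the
ablated cells gone), while the time-lapse experiments (tracking, migration,
morphometry) use the full movie. Passing tests consequently demonstrate
correctness of the measurement pipeline on well-spaced blob-like nuclei;
they do not certify detector performance on overlapping or irregular
nuclei.

## Numerical choices and degenerate inputs

- Circle fit: < 3 points, collinear points, or a non-positive squared
  radius raise a configuration error; fit is translation/rotation invariant
  to 1e-9 µm.
- Angle convention: radians in [-π, π), origin at image top-left, y
  downward (so "north" in image coordinates is +π/2); a point at the circle
  centre has no angle and is an error.
- Bin boundaries are half-open: 60 µm falls in [60, 90).
- LAP infeasible entries use a large finite cost (1e12) so the solver
  always finds a solution; ties in the assignment are broken by the
  solver's deterministic ordering.
- Empty frames, empty detection lists, and all-background images are valid
  inputs with defined results (empty assignments, zero detections, a
  "no organoid found" error, respectively).
- Zero-variance statistics: t = 0/p = 1 for equal means, p = 0 flagged
  degenerate for unequal means.

## Problem sizes used in validation

Validation runs are sized for a single CPU: 12-cell organoids for exact
track-identity checks (38-µm spacing keeps trajectories disjoint, so
ground-truth identity is well defined; at denser spacing free diffusion
produces genuine crossings within a few frames, and identity is physically
unrecoverable), 100-cell organoids for detection and rate recovery,
50-replicate recovery studies of 8–12 organoids each, 24 simulated hours at
3-h spacing for morphometry, and 10,000 replicates for t-test calibration.

## Known limitations

- The detector is a single-scale LoG; touching or strongly heterogeneous
  nuclei need an instance segmenter, which can be plugged in via the point
  table interface.
- Migration metrics assume no track splitting/merging (no division).
- The per-bin binomial label model treats cells independently; spatially
  correlated proliferation is out of scope.
- Arc distances presuppose a near-circular shell; strongly deformed
  organoids violate the model and show up as large circle-fit residuals
  (reported per frame as `rms_residual_um`).
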