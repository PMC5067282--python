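# Methods

This note records the models, estimators, conventions and limitations
behind `mitoarbor`, in the order the pipeline uses them.

## Morphology and morphometry

A reconstruction is a rooted tree of SWC nodes (soma, axon, basal/apical
dendrite) with coordinates in μm.  Validation enforces a single connected
component, a single root, acyclic parent links and finite coordinates.
The **soma centre** is the centroid of the soma-typed nodes (overridable;
single-point somas and somas traced as outlines are both common across
tracing tools).  If all z coordinates are equal the analysis is effectively
2-D; no special casing is needed.

**Distance convention.**  Shell-based statistics (Sholl, BP⁹⁰, MPM) use
radial Euclidean distance from the soma centre — shells radiate from the
soma, so the radial metric is the natural one.  Path distance along the
trace is exposed as an option (`metric="path"`) and is used where a
quantity is measured along a process (occupancy gaps, axonal density).

**Sholl.**  Intersections are counted per sphere at radii step, 2·step, …
by exact segment–sphere crossing counts: roots of the per-edge quadratic
in (0, 1], tangencies excluded.  This handles tortuous segments that cross
a sphere twice, which endpoint-only bookkeeping misses.  Branchpoint
profiles bin branchpoints into half-open annuli [k·step, (k+1)·step); a
point exactly on an edge belongs to the outer annulus (deterministic
tie-break).  Shells extend to the farthest reachable radius; since the
distance maximum along a segment is attained at an endpoint, no crossing
exists beyond the farthest node.

**BP⁹⁰.**  Branchpoint distances are normalised by the per-cell maximum
tip distance (tip = 1; per-cell rather than per-dendrite normalisation)
and the 0.90 empirical quantile is taken with linear interpolation between
order statistics — continuous in the data where a step-function quantile
is not.  A branchpoint that sits farther than every tip (possible on
strongly recurved traces) is clipped to 1.  BP⁹⁰ is invariant under rigid
motion and uniform scaling.  It is undefined (an error, not 0) for cells
without branchpoints.

## Mitochondrial distribution

**Segmentation.**  Otsu by default with foreground = intensity ≥
threshold; a fixed threshold is available and is the right choice when
foreground occupies a tiny pixel fraction, where Otsu's two-class
assumption fails.  A constant image raises with advice to use the fixed
mode.

**Pixel shells and MPM.**  Foreground pixels are counted per half-open
annulus of Euclidean distance between pixel centres (fractional soma
centres allowed), default shell width one pixel.  The MPM divides the
cumulative counts by total mass and the distances by the cell's maximum
dendritic tip distance when a morphology is available, otherwise by the
farthest dendrite-mask pixel — the tip, not the farthest mitochondrion,
defines 1, so proximal accumulation genuinely shifts the curve left.
**Mito⁶⁰** is the first crossing of 0.60, linearly interpolated between
bracketing grid points (the grid point itself if the curve hits 0.60
exactly).  If ≥ 60% of mass sits exactly at the soma the value degenerates
to 0; it is otherwise in (0, 1].

**Mitochondrial index** counts mitochondrial pixels only where they
overlap the dendrite-marker mask (optionally within an ROI), excluding
somatic and axonal signal from both numerator context and denominator.

**Occupancy gaps.**  The path is sampled every 0.1 μm (default); a sample
is occupied if it falls in a mitochondrion's half-open footprint
centroid ± length/2 along the path, or (image mode) within 0.5 μm of a
foreground pixel.  The 0.5-μm capture radius approximates a mitochondrial
radius at typical magnifications; both values are configurable.  An empty
mitochondrion set yields fraction 1.0 with one full-length gap.

**Axonal statistics.**  Density is 10·count/length (per-10-μm units);
relative positions are centroids divided by path length, clipped to [0, 1].

## Kymographs and trafficking

Kymographs sample each frame at unit-pixel arclength steps along a
polyline, taking the maximum over an odd `line_width` of perpendicular
offsets (default 5 px).  Columns are frames, rows positions; `soma_end`
records which end of the path faces the soma.

**Detection and linking.**  Per-column peaks above an intensity threshold
(parabolic sub-pixel refinement) are linked frame-to-frame by greedy
nearest-neighbour assignment with a displacement budget of `max_jump` μm
per elapsed frame.  Greedy linking rather than global assignment is a
deliberate simplification, adequate at the low particle densities of
dendritic organelles; it is the documented limitation of this module.
Two mitigations matter in practice: a track survives up to `max_gap`
(default 3) missed frames, and closed fragments are stitched end-to-start
within a `stitch_gap` window (default 40 frames) and the displacement
budget, with one-frame-overlap stitches allowed — crossings hand identities
off between trajectories, and a particle that pauses underneath another
spot can be occluded for many seconds.  Without stitching, fragments
inflate cohort track counts and bias the motile fraction upward.
Tracks shorter than 3 detections are discarded.

**Classification.**  Net displacement is signed positive away from the
soma.  |net| < 2 μm (default) → stationary; the threshold is the package's
choice — over a 2-minute movie, slower drift is indistinguishable from
stage noise — and a displacement exactly at the threshold counts as
mobile.  **Run velocities** merge consecutive same-sign steps whose
per-frame magnitude exceeds a noise floor (default 0.1 μm/frame,
≈ sub-pixel detection jitter); each run reports |displacement|/duration,
pauses excluded.  Cohort summaries compute directional percentages over
mobile tracks and pool run velocities across mobile tracks only — the
statistic is the velocity of *moving* organelles; stationary tracks
contribute only jitter.  With no mobile tracks the directional and
velocity fields are reported as missing, never 0.  Flipping the declared
soma end exchanges anterograde and retrograde exactly and leaves the
motile fraction unchanged.

## Synthetic data

The generators exist to give every estimator a ground-truth recovery test;
they are deterministic under a fixed seed (byte-identical outputs).

**Trees.**  Primary dendrites grow from a soma in 1-μm steps with a
direction random walk (tortuosity = angular s.d. per √μm).  Bifurcations
form a Poisson process of `branch_rate` per μm of grown cable while branch
order is below `max_depth`; each branch terminates after a natural length
drawn from `segment_length`.  Because branching is a Poisson process on
grown cable, branchpoints-per-μm estimates `branch_rate` directly when
the depth cap rarely binds — the module's analytic oracle.  Defaults
(5 primaries, 0.025/μm, 45 ± 15 μm segments, depth ≤ 7) yield cells of
roughly 3.5–4 mm total dendritic length with ~50–60 branchpoints,
matching mature cultured hippocampal pyramidal neurons.

**Placements.**  Normalised positions u are drawn i.i.d. either uniformly
(homogeneous, the wild-type-like condition; expected Mito⁶⁰ = 0.6) or from
the truncated exponential ∝ exp(−u/τ) on [0, 1] (proximal accumulation,
the knockout-like condition; default τ = 0.3 gives Mito⁶⁰ ≈ 0.259 via the
closed-form inverse CDF).  On a morphology, each mitochondrion is assigned
a root-to-tip dendritic path with probability proportional to its length
and placed at u times that path's length, so the normalised position
follows the model density exactly whatever the topology — this keeps the
analytic oracle exact.  The raw draws are retained as ground truth.

**Rasterization** paints the soma disk and dendritic cable at trace radii
into a cell-fill channel and mitochondria as capsules (default half-width
0.25 μm) into a mitochondrial channel, then applies Gaussian PSF blur and
additive Gaussian noise; pre-blur boolean masks are the ground truth.

**Time-lapse.**  Particles on a 1-D path are stationary with probability
1 − p_mobile; mobile particles get a direction and alternate runs (speed
drawn per run, default 0.4 ± 0.08 μm/s) with pauses via exponential
pause/resume rates (defaults 0.05/s and 0.2/s).  Boundaries reflect
(reversing the instantaneous velocity) so the particle count stays
constant and motile-fraction recovery is unbiased in expectation.  Frames
are rendered as Gaussian spots on the centre row of a thin 2-D image plus
noise, so the kymograph builder is exercised end-to-end.  Defaults
(120 frames at 1 s — a 2-minute movie — 0.1 μm pixels) match typical
organelle-trafficking acquisitions.  Cohorts of 200 particles are
simulated as 25 independent 8-particle movies on 80-μm paths: one particle
per 10 μm is a realistic linear density, and a single dense path would be
untrackable by any method.

What the simulations do **not** model: motor kinetics, microtubule
polarity, calcium-dependent stopping, photobleaching, focus drift, or
out-of-focus background.  Passing recovery tests therefore demonstrates
the estimators are correct on data satisfying the stated models, not that
tracking is robust to every real-microscopy artifact.

## Statistics

Two-group contrasts use Welch's t test or the Mann-Whitney U test.  The
exact U distribution (tie-free, both n ≤ 20) comes from the standard
dynamic-programming enumeration; small tied samples (both n ≤ 7) use full
permutation enumeration of the pooled mid-ranks; otherwise the normal
approximation with tie and continuity corrections applies.  Two-sided
p-values are 2·min(P(U ≤ u), P(U ≥ u)) capped at 1.  Group differences are
reported as percent change, 100·(reference − test)/reference, so a
decrease is positive.  Multi-group procedures are out of scope; the
pipeline's contrasts are two-group by design.

## Problem sizes and determinism

Recovery suites use n = 2000 placements per cell for analytic-limit
checks, cohorts of 15 cells × 150 mitochondria for group discrimination,
and 200-particle trafficking cohorts — sizes at which sampling error is
comfortably inside the stated tolerances (the 0.6 empirical quantile at
n = 2000 has s.d. ≈ 0.011, so single-seed Mito⁶⁰ values scatter by ±0.03
and the 10-seed mean is accurate to ±0.01).  All randomness flows from
explicit seeds; analyses of fixed inputs use none, so identical inputs and
configuration give byte-identical output tables.
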