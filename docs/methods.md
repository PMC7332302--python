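# Methods

## Coordinate and angle conventions

All physical coordinates are mathematical y-up micrometres with +x along
the anode→cathode axis unless a config overrides the field direction.
Label-mask images arrive in raster convention (row index downward), so
mask ingestion negates the row axis before any angle is computed; this
keeps the sign of directedness (−1 anodal, +1 cathodal) independent of
imaging orientation.  Directional angles live in (−π, π]; axial angles
(cell long axes) in [0, π) and are doubled before any circular
operation, with means halved back, the standard treatment of axial data.

Track tables are one fixed dialect — comma-separated UTF-8 with header
`cell_id,frame,x,y`, 0-based frames — to rule out silent misreads.
Times are `frame × frame_interval/60` hours.

## Migration metrics

Directedness uses the endpoint (first-to-last frame) displacement.  Its
time-resolved variant uses cumulative origin-to-frame displacement; the
per-interval alternative was rejected because the cumulative series
converges to the endpoint value and matches how a 6-h endpoint figure is
read.  Frame 0 is omitted (zero displacement, undefined angle).  Cells
with exactly zero net displacement are excluded from directedness and
angle sets with a logged count rather than imputed; likewise regions
with no defined long axis are excluded from orientation statistics.

Speed is the net-displacement rate (μm/h).  The total-path-length rate
is emitted only as an auxiliary column (`path_speed`), since net and
path rates answer different questions and only the former is the
headline metric here.

## Mask morphometry

Regions come from scikit-image `regionprops` on integer label images
(same label = same cell across frames, as tracking tools guarantee).
The long-axis angle is the principal eigenvector of the second
central-moment matrix, computed from `moments_central` with the row axis
negated: `angle = ½·atan2(2·cov_xy, var_x − var_y) mod π`.  Regions of
fewer than 3 pixels report area but no axis (no minimum size is standard;
3 is the smallest count with a nondegenerate moment matrix).  Isotropic
regions (moment tie) deterministically report 0 and are flagged.
Validation against rasterized ground truth shows orientation recovered
within 2° and area within 5% for aspect ratios ≥ 3; discretization makes
both bounds looser for near-circular cells.

## Mardia–Watson–Wheeler test

The pooled sample is ranked around the circle, ranks mapped to uniform
scores β = 2πr/N, and `W = 2Σⱼ(Cⱼ² + Sⱼ²)/nⱼ`.  W is exactly invariant
under common rotation of both samples in the absence of ties.  Ties are
broken by infinitesimal uniform jitter (±10⁻⁹ rad) under the caller's
seed — the standard approach for uniform-scores tests; the jitter is far
below measurement resolution.  The asymptotic p-value is the χ²₂
survival function `exp(−W/2)`; with both groups below 10 observations a
flag recommends the permutation p-value, reported as `(b+1)/(B+1)` over
`B` random relabellings (default 10 000).  Monte-Carlo calibration in
the test suite: type-I error 0.05 ± 0.01 under the uniform null
(5 000 replicates at n = 30+30), and permutation/asymptotic rejection
rates agreeing within 0.02 at n = 50+50.

## Synthetic data

The walk generator is phenomenological — no membrane-polarization or
ion-flux mechanism — and models each step's heading as a single von
Mises draw centred on the circular weighted mean of the bias target
(weight `mix_weight`, concentration `kappa_bias`) and the previous
heading (weight `1 − mix_weight`, concentration `kappa_persist`).  The
two weighted concentration vectors are added vectorially; the resultant's
argument is the mean, its magnitude the effective concentration.  This
single-draw form was chosen over a mixture because it yields closed-form
checks: with `mix_weight = 1` headings are i.i.d. von Mises and the mean
resultant length equals I₁(κ)/I₀(κ), which the suite verifies by
numerical quadrature within 0.02 for κ ∈ {0.5, 1, 2, 5}.  Per-step
speeds are independent gamma draws (positive, right-skewed,
two-parameter); step length is speed × dt.

Defaults mirror the experimental design: dt = 10 min, 36 steps (6 h),
`speed_mean` 10 μm/h with gamma shape 2 — an order-of-magnitude choice
inside the 2–20 μm/h net-speed range such experiments report.  One root
seed is spawned into per-cell substreams, so output is reproducible and
per-cell streams stay aligned when unrelated parameters change (this is
what makes the speed-doubling invariance exact at matched seeds).

The shape generator rasterizes non-overlapping filled ellipses (areas
gamma-distributed about `mean_area` with CV `area_cv`, fixed aspect
ratio) whose axial orientations satisfy 2θ ~ von Mises(2×preferred_axis,
`kappa_axial`); placement is rejection sampling with a bounded retry
budget, failing loudly rather than overlapping.  Frames repeat the same
mask (static shapes), which suffices for orientation-vs-time plumbing.

What the generator does *not* emulate: segmentation errors, track
breaks, cell division and death, contact interactions, shape change
coupled to motion, or spatial field inhomogeneity.  Passing tests
therefore demonstrate the correctness of the analysis given clean,
completely tracked input — the condition the completeness filter
enforces — not robustness to upstream tool failures.

## Chip field model

The multi-field chip is modelled as a lumped resistor network, not a
finite-element continuum.  Channel segments are ohmic resistors
`R = L/(σwh)` with medium conductivity defaulting to 1.536 S/m; node
potentials come from dense nodal analysis (modified nodal analysis when
the source is a voltage), with the Kirchhoff current residual returned
and required < 10⁻⁹ relative.  The R-2R ladder helper terminates the
last rung with a parallel 2R so successive rung currents halve exactly.
Section field strengths are `E = I/(σA)`; they scale linearly with the
source, so the design ratio is rescaled exactly to any maximum.  A
continuum simulation of the same chip yields a slightly compressed ratio
(≈ 4.99 : 2.45 : 1 : 0 versus the lumped 5.25 : 2.5 : 1 : 0) because the
lumped model ignores junction and fringing effects; the discrepancy is
inherent to lumping and is documented rather than corrected.  Hydraulic
resistances use the shallow rectangular-duct formula
`12μL/(wh³(1 − 0.63h/w))` (h ≤ w), adequate for order-of-magnitude
transport-isolation arguments (~13% low in the square limit).

## Pipeline rules

* Completeness filter: a cell is analyzed only if observed at every
  frame of its viewfield's range, inferred as [min, max] observed frame
  unless configured; exclusions are logged by id.
* Cohort size: conditions below `min_cells` (default 100) are flagged,
  not dropped.
* Intervals: group values are mean ± 1.96 × SEM with the sample SD
  (n−1), at any n — deliberately the normal-theory interval rather than
  t-quantiles, matching how such experiments conventionally report, and
  documented as slightly anticonservative at small n.
* Scalar two-group tests are Welch t (scipy); three or more groups go to
  one-way ANOVA with Tukey HSD (scipy/statsmodels).  Identical
  zero-variance groups short-circuit to t = 0, p = 1.
* Experiments pool cells across replicates at the cell level, with
  condition labels retained per trajectory.
* Determinism: one config seed feeds simulation substreams, MWW jitter
  and permutations; rerunning a config byte-identically reproduces the
  CSV/JSON report, and reports embed the config hash, seed and package
  version.

## Problem sizes in the test suite

Monte-Carlo suites use 2 000 simulated cells for the "random ⇒ index 0"
checks (binomial half-width ≈ 0.016 at that n, comfortably inside the
0.05 band), 5 000/2 000 replicates for MWW calibration, 300 permutations
per replicate in the permutation-agreement check, 100 random networks for
solver residuals, and 100 seeded end-to-end runs at 200 cells per
condition.  The full suite runs in well under a minute on one core.

## Known limitations

* The lumped network cannot reproduce continuum fringing; absolute
  section fields should come from measurement or FEM when accuracy
  beyond a few percent matters.
* The MWW jitter makes W non-deterministic across *different* seeds when
  heavy ties exist; seeded runs are exactly reproducible.
* `1.96 × SEM` intervals undercover for n ≲ 30.
* The generators sample independent cells; collective effects (contact
  inhibition, paracrine gradients) are out of scope.
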