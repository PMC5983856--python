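# Methods

## Overview

`nodulesig` re-creates, end to end, an exemplar-based CT characterization
pipeline for lung adenocarcinoma (ADC) nodules and the statistical battery
used to quantify its inter-observer reproducibility. Because the original
patient CT data and trained exemplars of such pipelines are not publicly
deposited, every stage here runs on synthetic phantoms with simulated
observers: the package learns its *own* nine-class exemplar model from
phantom data and studies the reproducibility of the resulting
characterization under controlled observer variability. Passing results
therefore demonstrate the internal consistency and statistical behavior of
the method — not agreement with any particular clinical dataset.

## Phantom model

A phantom is an axis-aligned HU grid containing:

- aerated lung parenchyma (default −850 HU),
- a spherical nodule of radius `nodule_radius` (mm) with a solid core of
  radius `solid_core_radius` at `solid_hu` (default 40 HU, soft tissue) and
  a ground-glass shell at `ggo_hu` (default −550 HU). Sweeping
  `solid_core_radius` from 0 to `nodule_radius` spans pure ground-glass
  opacity (GGO) through fully solid attenuation,
- optionally a vessel: a soft-tissue cylinder tangent to the nodule surface
  (so it abuts and marginally interpenetrates the sphere), and a chest-wall
  slab on one face of the grid,
- additive i.i.d. Gaussian noise of standard deviation `noise_sd`
  (default 30 HU in the cohort sampler, a typical low-dose chest CT noise
  magnitude). No reconstruction texture, beam hardening or partial-volume
  modeling is attempted.

The default cohort sampler draws nodule radius uniformly on 4–8 mm, solid
fraction uniformly on [0, 1], vessels on half the nodules, a chest wall on
roughly a third, on a 40 x 56 x 56 grid with (1.25, 0.7, 0.7) mm voxels —
thick-slice, fine in-plane, as in screening chest CT. All randomness is
driven by `numpy.random.default_rng` seeds recorded in the cohort manifest;
every phantom is exactly reproducible from its spec.

### Simulated observers

Manual border adjustment is modeled as a level-set perturbation: the signed
Euclidean distance to the true nodule surface is compared against a
Gaussian-smoothed random field (correlation length 3 mm) rescaled to
standard deviation `boundary_sd` mm. Thresholding the field at the surface
yields a smoothly displaced border; the largest 26-connected component
overlapping the truth is kept. With probability `vessel_inclusion_prob` the
abutting vessel segment (vessel voxels within 2 mm of the nodule) is
retained, emulating an observer who declines to erase it. `boundary_sd = 0`
with no vessel retention reproduces the truth voxel-for-voxel.

The jitter parameters are free knobs, not estimates: the distribution of
real observers' edits is not characterized anywhere we can calibrate to.
The frozen study conditions used by the acceptance analysis are three
observers with `boundary_sd = 0.5 mm` and `vessel_inclusion_prob = 0.2` —
"low jitter" in the sense that the displacement is sub-voxel in-plane.
Expected Dice overlap against truth decreases monotonically in
`boundary_sd` (property-tested at 0.5/1.5/3 mm over 50 replicates).

## Segmentation

Seeded region growing with fixed dual HU thresholds: the maximal connected
component (6- or 26-connectivity, default 26) of voxels with HU in
[−750, 200] containing the seed, clipped to an axis-aligned volume of
interest (VOI) box of half-width 20 mm around the seed. The thresholds
bracket the GGO-to-solid range; they are explicit, configurable assumptions
— the growing criterion of the original interactive tool is not published.
Manual edits are two primitives applied in order: a closed-ball eraser
(voxel-center inclusion, radius 0 removes at most one voxel) and a
half-space exclusion plane (strict positive side removed). A session object
records seed, parameters, edits and result; replay must reproduce the
stored mask exactly or a reproducibility error is raised, giving an exact
audit trail for inter-observer comparisons.

On noiseless solid phantoms the default thresholds recover the true mask
with Dice 1.0 (tested); on noisy phantoms the simulated-observer pathway,
not region growing, is used to produce masks, so segmentation imperfections
do not confound the agreement analysis.

## Exemplar model

Training samples `n_vois` 9x9 in-plane patches (VOIs) uniformly without
replacement from all nodule voxels with full in-plane support across the
training cohort (774 by default, matching the scale such models are trained
at). Each patch is reduced to a 16-bin normalized HU histogram over
[−1024, 200] (values clamped, half-open bins, last bin closed) plus mean
HU, HU standard deviation and histogram entropy. Features are z-scored
column-wise over the training set (zero-variance columns map to 0), which
makes the similarity invariant to affine rescaling of the inputs; the
similarity is the canonical affinity-propagation choice, negative squared
Euclidean distance. Whether the original pipeline used raw histograms or
derived texture statistics is unknown; both are available through
`FeatureConfig`, and no claim of equivalence to the original feature set is
made.

### Affinity propagation

Implemented directly (not delegated) as damped responsibility/availability
message passing, default damping 0.9, at most 1000 iterations, convergence
declared after 50 iterations with an unchanged exemplar set;
non-convergence is flagged and warned, never silent. Ties in assignment go
to the lowest exemplar index. Because message passing alone lands on a
locally suboptimal exemplar set on roughly one in ten tiny instances, the
converged solution is polished deterministically on the exact
net-similarity objective (the facility-location form AP maximizes):
cluster-wise exemplar re-selection alternating with a greedy
add/drop/1-swap local search until stable. The swap scan is skipped when
k·n² exceeds ~5·10⁷ to bound the polish cost on large instances. With the
polish, the exemplar set attains the brute-force optimal net similarity on
≈94–95% of random n ≤ 10 instances (measured over 400); the brute-force
oracle in the tests enumerates all 2ⁿ−1 exemplar subsets.

### Nine-class calibration and labeling

The exemplar count is controlled through the similarity diagonal
("preference"): a bisection between the minimum similarity and the maximum
off-diagonal similarity — expanded geometrically downward if the lower end
still yields too many classes, and upward toward preference 0 if the upper
end yields too few (needed for the k = n corner) — runs AP repeatedly until
exactly nine exemplars emerge. The count is non-decreasing in the
preference in practice; rare non-monotone flips are tolerated (at most one
in a 20-point scan, property-tested). If nine is unattainable the
calibration fails loudly, reporting the nearest achievable counts.

The nine exemplars are ranked by mean HU and labeled with the conventional
palette: ascending attenuation G, C, B (lepidic/ground-glass group), P, Y
(intermediate), then I, V, O, R so that the four most attenuating classes
form the invasion-associated VIRO group {V, I, R, O} with R the most solid.
The sub-order within each group is a frozen convention; only the group
membership carries meaning. The middle pair is ordered P below Y, likewise
frozen.

## Classification and risk call

Every mask voxel whose 9x9 in-plane window (the voxel plus its 80
surrounding voxels) lies fully inside the grid is featurized identically to
training and assigned the nearest exemplar's class in standardized feature
space (exact ties to the lowest index). Mask voxels without full support
are reported as unclassified rather than padded — padding would fabricate
attenuation — and the signature denominators use classified voxels only.
The per-class fraction vector is the nodule's parametric signature; the
VIRO fraction is the summed V+I+R+O fraction.

The Good/Intermediate/Poor characterization thresholds the VIRO fraction at
`t_good = 0.10` and `t_poor = 0.45`, boundary values going to the more
severe category. These cut-points are this package's explicit assumption —
the published clinical cut-points live in work we do not reproduce — and
are isolated behind `RiskRule`; every call records the rule and the VIRO
value it used, so any alternative rule (including one using the full
nine-class composition) can be swapped in and audited.

Note that on an all-solid nodule the rim voxels' windows mix lung
attenuation, so rim voxels legitimately take intermediate classes; only
interior voxels (window fully inside the nodule) are guaranteed the
most-attenuating class. The rim is an O(window/radius) fraction of the
nodule and dominates small nodules' signatures — the same partial-window
effect a real scanner's partial-volume averaging produces at nodule edges.

## Agreement statistics

Class fractions are analyzed on the percent scale, untransformed (a logit
option exists but is off by default), under a two-way random-effects model
y_ij = μ + nodule_i + observer_j + e_ij with a complete nodule-by-observer
crossing. Components are estimated by ANOVA mean squares (method of
moments): σ²_resid = MSE, σ²_obs = (MS_obs − MSE)/n, σ²_nod =
(MS_nod − MSE)/k. REML would be the natural alternative and can differ
slightly; the moment estimator is chosen for closed-form testability.
Negative moment estimates are truncated to zero (and flagged) for the
variance-decomposition report only.

The ICC is ICC(2,1) — two-way random effects, absolute agreement, single
rater: σ²_nod / (σ²_nod + σ²_obs + σ²_resid), computed from untruncated
mean squares. The 95% interval is the McGraw–Wong F-based interval with
Satterthwaite degrees of freedom, deliberately not clipped at zero, so the
lower bound can be negative under weak signal. When observer and residual
variance both vanish exactly (a degenerate perfect-agreement table) the ICC
is 1 with interval (1, 1); a table with zero total variance raises an
undefined-statistic error. The implementation agrees with pingouin's
ICC(A,1) to 1e-9 (cross-checked in tests).

The per-class panel reports one ICC per palette class, a VIRO row computed
on the *summed* V+I+R+O fractions per nodule-observer (its own measurement,
not an average of per-class ICCs), and an "Avg." row that is the arithmetic
mean of the nine per-class ICCs — the mean-of-ICCs reading; an ICC of the
pooled data would be a different statistic. Classes with undefined ICCs
appear as NaN and are excluded from the average; strata with fewer than two
nodules are skipped with a warning.

Dice similarity is 2|A∩B|/(|A|+|B|) on aligned grids (undefined when both
masks are empty); 0.7 is carried as the conventional strong-overlap
threshold. Fleiss' kappa uses the standard multi-rater formulation with the
Fleiss–Nee–Landis large-sample standard error for the interval and the
conventional interpretation bands (0.61–0.8 substantial, 0.81–1.0 almost
perfect). With two raters Fleiss' kappa coincides with Scott's pi (pooled
marginals), not Cohen's kappa, and the tests assert exactly that.
Kruskal–Wallis delegates to `scipy.stats.kruskal` (tie-corrected H,
chi-square p on groups−1 df); it accepts generic grouped values because the
natural grouping unit for slice-thickness comparisons is study-dependent.
No multiple-testing correction is applied anywhere.

### Estimator calibration studies

`simulate_icc_table` draws tables from the generating model itself. The
recovery study uses 200 nodules x 3 observers, total variance 10
squared-percent with a 1% observer share (σ²_obs = 0.1), residual taking
the remainder, at true ICC 0.2/0.5/0.9 over 20 independent seeds per level.
Two deliberate choices:

- the observer share is small because (a) that is the regime the
  inter-observer finding describes — observer effects contribute minimally
  to class-fraction variance — and (b) with only three raters, MS_obs has
  2 degrees of freedom, so an absolute-agreement ICC is intrinsically
  unrecoverable to tight tolerance when the observer component is large;
- recovery is judged on the seed-averaged estimate (|mean − truth| ≤ 0.03).
  A per-draw tolerance that tight is infeasible for *any* estimator at this
  design: the Fisher large-sample standard deviation of the ICC at ρ = 0.5,
  n = 200, k = 3 is ≈ 0.041, so the expected absolute error of a single
  draw already exceeds 0.03.

CI calibration is checked per draw: the 95% interval covers the truth in
≥ 90% of runs (measured ≈ 95–96% per level over 400 replicates).

## The phantom observer study

`observer_study` chains everything: each simulated observer segments every
nodule (jittered truth), each segmentation is classified against the
trained model into a signature and risk call, and the battery (ICC panel,
variance decomposition, pairwise Dice summary with a normal-approximation
CI over all nodule-pair values, Fleiss kappa on risk categories) is
computed over the resulting tables. Per-nodule observer seeds are derived
deterministically from each observer's base seed, so the full report
replays bit-identically.

The acceptance analysis runs this on 30 phantoms with the three low-jitter
observers above and a model trained on the same cohort (774 VOIs, nine
classes). The problem sizes — 30 phantoms, 774 VOIs, 8 phantoms for the
degenerate chain, 50 clustering instances, 20 seeds x 3 ICC levels — are
the package's chosen desk-scale study conditions. Under them, the
class-average ICC, mean pairwise Dice and Fleiss kappa land far inside the
qualitative bands the method is expected to occupy under low observer
variability (ICC ≥ 0.8 high agreement, Dice > 0.7 strong overlap,
kappa > 0.61 substantial). With zero jitter the whole chain degenerates to
ICC = Dice = kappa = 1 exactly.

## What the phantoms do not show

Phantoms are piecewise-constant spheres plus white noise: no spiculation,
lobulation, air bronchograms, reconstruction kernel texture, respiratory
motion, or anatomic context beyond one vessel and a wall slab. Observer
jitter is a smooth random field, not a model of human perceptual error, and
its magnitude is a knob. Consequently the study demonstrates that the
pipeline is internally consistent, deterministic, and statistically
well-calibrated — it cannot certify agreement levels on clinical CT, and
the numeric ICC/Dice/kappa values produced here should not be compared
digit-for-digit with clinical studies.

## Numerical conventions

- Coordinates: 0-based (slice, row, col); world mm = origin + index ·
  spacing; half-open extents; grids are axis-aligned and direction cosines
  in files are preserved but not interpreted.
- Grid alignment tolerance 1e-6 mm on spacing and origin.
- Masks are uint8 labeled images (1 = nodule); volumes are written float32.
- Histogram bins half-open with the last bin closed; out-of-range HU
  clamped to the range ends.
- All ties frozen: lowest index in exemplar assignment and voxel
  classification, severe side in risk thresholds, stable sort in class
  labeling.
- Seeds: everything flows from `numpy.random.default_rng` with explicit
  integers; derived seeds stay below 2³¹.
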