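# Methods

This note records what the package computes, the defaults it ships
with and why, what the synthetic-data generator does and does not
emulate, and the numerical and design choices a maintainer should know
about.

## Superimposition

`gpa()` is the classic iterative scheme: every configuration is
centred and scaled to unit centroid size, rotated onto the current
consensus by SVD (rotation only — the determinant is forced to +1, so
a digitisation that mirrored an animal is *not* silently absorbed;
mirroring is an explicit ingest step, `mirror_configurations`), and
the consensus is replaced by the rescaled mean until the summed squared
deviation changes by less than `tolerance` (default 1e-10, at most
`max_iter = 100` iterations; non-convergence warns and flags the
result rather than raising). Because GPA fixes shape only up to a
global rotation, the consensus is then oriented by its principal axes
with a sign convention (largest-|x| landmark positive), which makes
repeated and permuted runs bit-comparable.

After convergence the aligned sample is projected orthogonally into
the linear tangent space at the consensus (removing residual
components along the consensus's scaling and rotation directions).
The superimposition constraints are nonlinear, so without this step a
k = 6, 2-D sample has small spurious variance beyond the 2k − 4 = 8
shape dimensions; with it, PCA yields exactly at most eight non-null
axes.

Centroid size defaults to CS = sqrt(Σ‖xᵢ − x̄‖²). The squared and log
variants are available (`size_measure`, and `size_variant` in the
ANOVA model) because size enters the analyses only as a covariate and
monotone variants of the same measurement are all defensible.

**Repeatability.** With every photo digitised in m sessions,
`repeatability()` runs a one-way Procrustes ANOVA on individual
identity over all 2k coordinates and reports the variance-component
ratio s²_among / (s²_among + s²_within) with
s²_among = (MS_among − MS_within)/m, clamped to [0, 1]. This is the
standard intraclass-correlation convention for digitising error.

## Procrustes ANOVA (RRPP)

The response is the n x 2k matrix of aligned coordinates. Sums of
squares are sequential (type I) in the declared term order — default
`(size, instar, clone, risk, risk:instar, risk:clone)`, the order the
factors enter the biology (allometry first, then design factors, then
plasticity interactions). Predation risk is a 6-level categorical
factor (df = 5; the interactions then carry df = 5 and 10). Each
term's SS is the drop in residual SS when the term joins the model,
computed via orthonormal bases of the nested column spaces, so the
decomposition is exact to round-off and rank deficiency is detected
(an aliased term raises, naming it).

Significance is by residual randomization: for term t with reduced
model X_red, the statistic under a permutation π is
‖Q_tᵀ R_red[π]‖², where Q_t spans the subspace the term adds and R_red
are the reduced-model residuals (the fitted values are invariant, so
only permuted residuals contribute). p = (b + 1)/(B + 1) counting
permuted SS ≥ observed; Z is the standard-normal deviate of the
observed SS within the permuted distribution. B defaults to 10,000;
`exhaustive=True` enumerates all n! assignments (practical to n ≈ 8)
and then p is the exact enumeration proportion.

Least-squares means (`fit_lsmeans`) are computed on the finest cross
of the requested grouping factors with the remaining categorical
design factors, then averaged with equal weight over the non-grouping
factors — on balanced data this is the per-cell arithmetic mean, on
unbalanced data the mean of cell means rather than the pooled mean.

## Trajectory analysis

A trajectory is a group's sequence of mean shapes over the ordered
gradient. Attributes of a pair:

- **magnitude** — |PD₁ − PD₂| with PD the summed segment lengths;
- **direction** — the angle between first principal axes of the two
  point sets, each sign-oriented along increasing risk. The principal
  axis is preferred over the first-to-last chord (both are available,
  `angle_method="chord"`) because the study's third shape axis (the
  carapace bulge) is non-monotone in risk, which a chord misses;
- **shape** — both L-point sets are centred, scaled to unit size and
  optimally rotated (orthogonal superimposition in the trajectory
  space); the residual norm is the trajectory shape distance.

The RRPP null permutes residuals of the group + gradient main-effects
model (the reduced model for their interaction) and recomputes every
attribute per permutation; `extra_terms` adds further known design
factors (instar, in the study design) to the reduced model so their
systematic variation is not treated as exchangeable noise. The whole
null is evaluated with batched linear algebra (stacked SVDs), so
B = 1,000 on a 432-specimen study takes well under a second.

**Calibration caveat.** These attribute statistics are nonlinear
functionals of cell means, and RRPP calibrates them only
approximately: in the observed data the group trajectories share their
estimated main-effect noise (and in a balanced design the interaction
residual means are linearly constrained across groups), whereas each
permuted dataset gives every group independent noise in all cell-mean
directions. Measured over 500 simulated null studies under the default
design (B = 999), rejection rates at α = 0.05 were 0.037 (magnitude),
0.057 (angle) and 0.026 (shape): the magnitude and shape tests run
somewhat conservative. They do not over-reject; confirmatory use is
safe, but borderline non-significant shape differences should be read
with the conservatism in mind.

## Modularity and integration

Partitions are declared over landmark *labels* (each contributes its
x and y columns); the study's two partitions ship as presets
`HEAD_BODY` (rostrum, eye, neck | mid-ventral, spine-base, mid-dorsal)
and `DORSAL_VENTRAL` (eye, neck, mid-dorsal | rostrum, mid-ventral,
spine-base).

CR = sqrt(Σ S₁₂²ᵢⱼ / sqrt(Σ* S₁₁²ᵢⱼ · Σ* S₂₂²ᵢⱼ)), diagonals excluded
from the within-block sums. The null re-assigns whole landmarks to
blocks of the observed sizes; p is one-tailed low. When the number of
distinct assignments does not exceed the requested permutations the
null is enumerated exhaustively (with a warning) and p is exact.
**Granularity:** with six landmarks split 3|3 there are C(6,3) = 20
assignments and the complement split always reproduces the observed CR
exactly, so p moves in steps of 0.05 with a floor of 0.10 — at this
landmark count the CR test cannot reject at α = 0.05, and its
calibration is therefore demonstrated (tests) on 12-landmark
configurations where the null resolves. Effect size is
(CR_obs − mean null)/sd null.

r-PLS is |corr| of the first singular-warp score pair of the
between-block covariance; singular-vector signs are fixed (largest
block-A loading positive). The integration null permutes the rows of
one block (exhaustively for n! ≤ B); p is one-tailed high.

Note that Procrustes superimposition itself induces covariance between
anatomically independent landmark sets (all coordinates share the
estimated translation, rotation and scale), so "independent blocks"
are only a meaningful null for data whose covariance is specified
directly in shape space; the tests correctly report the
alignment-induced integration otherwise.

## Shape space and thin-plate splines

PCA is the SVD of the centred coordinate matrix; axes with eigenvalue
below 1e-10 of the leading one are dropped, axis signs follow the
largest-loading convention, and variance fractions are reported over
the non-null axes (whole-percent rounding is provided for readable
summaries). `axis_extreme_shapes` returns consensus + score·loading
for an observed extreme or a multiple of the axis SD.

The TPS warp uses the kernel U(r) = r² ln r² with U(0) := 0, solving
the standard (k + 3) system per output coordinate; the reference
design matrix is rank-checked so collinear references fail loudly.
Bending energy is the quadratic form of the non-affine weights with
the kernel matrix, clamped at zero against round-off; it vanishes iff
the map is affine. Grids default to a 24 x 24 lattice over the
reference bounding box padded by 10%.

## The synthetic-data generator

`SimulationSpec` encodes one study: a stylized six-landmark *Daphnia*
outline (a fixed, non-degenerate hexagon; it claims no fidelity to
real specimens), risk levels (0, 0.1, 0.25, 0.5, 0.75, 1 μL mL⁻¹),
instars 2 and 3, three clones, and 12 replicates per cell (the
midpoint of the study's 4-20 range; `unbalanced_replicates` draws an
unbalanced 4-20 preset). Each specimen is its cell mean plus
correlated noise plus digitisation noise, then rotated, translated and
scaled per photo.

Cell means are
base + instar offset + gain_c · f(risk) · direction_c +
neck_gain · risk · neck-direction, with f linear by default and a
saturating option (risk/(risk + 0.25), normalised), because the study
system shows both monotone neck change and non-monotone body-width
change. Defaults: neck_gain 0.08 (about 4% of the base size across
the full gradient — a visible but not caricatured defence), one
high-induction clone (gain 0.06) and two low-induction clones (gain
0.03) of which one responds in a different direction (recruiting the
carapace bulge), matching the high/low-induction contrast the package
is designed to analyse.

Displacement fields ("neck", "head-height", "bulge", "elongation") are
projected into the tangent space of the base shape — components along
pure translation, scaling and rotation are removed before
normalisation — so they are genuine shape directions: ground-truth
angles and path distances then survive superimposition, and raw-unit
path distances convert to the Procrustes scale by dividing by the base
centroid size (`GroundTruth.path_distances_procrustes`).

Noise covariance is modular: equal coordinate variance (σ = 0.02,
about 1% of base size — a realistic biological scatter) with
correlation ρ_within = 0.6 inside the head/body modules and
ρ_between = 0.3 across them, validated positive semi-definite at
construction. Digitisation noise is iid with σ_d = 0.0055, chosen so
the implied two-session repeatability σ²/(σ² + σ_d²) ≈ 0.93, the
precision of careful manual landmarking the pipeline is meant for.
Every dataset carries its `GroundTruth` (true cell means, trajectory
path distances and pairwise angles, population CR and r-PLS in closed
form from the noise covariance).

What the generator does **not** emulate: real carapace geometry and
allometric curvature of the outline, non-Gaussian digitisation error,
landmark-specific error variance, unbalanced missingness, and any
biomechanics of the defence. Tests passing on these simulations
demonstrate that the estimators recover the statistical structure they
assume — not that real *Daphnia* data satisfy that structure.

## Problem sizes used in the test suite

The statistical acceptance tests run at desk scale, chosen to give
tight Monte-Carlo error while keeping the suite quick: 500 simulated
studies for each type-I rate (B = 999), 100 simulations per true angle
for parameter recovery at 50 replicates per cell, n = 5,000 for CR
convergence, and exhaustive enumeration (7! residual assignments,
C(6,3) landmark splits, 6! row permutations) for the
permutation-oracle equalities. The parameter-recovery experiment uses
the default neck-scale effect (gain 0.08) with digitisation-scale
noise (σ = 0.005), a regime where the known positive small-sample bias
of path-distance and angle estimators stays within the stated 5% / 5°
tolerances; at lower signal-to-noise both estimators are biased
upward, which is a property of the statistics, not the implementation.

## Known limitations

- Semi-landmarks are treated as fixed; there is no sliding by bending
  energy or Procrustes distance, and no 3-D support.
- The CR test is granular at six landmarks (see above).
- The trajectory magnitude and shape attribute tests are mildly
  conservative under RRPP (see calibration caveat).
- Sequential SS is order-dependent on unbalanced designs by
  construction; the term order is explicit in `ModelSpec` and the
  balanced-design invariance is tested.
- The Dryad-deposit adapter (`morphokit.dryad`) maps a conventional
  local directory layout (landmarks + factors files) and makes no
  attempt to fetch or to guess exotic layouts.
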