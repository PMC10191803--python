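# Methods

This note documents the model, the numerical choices, what the synthetic
generator does and does not emulate, and the known limitations. It states no
empirical result that the test suite does not itself compute.

## Occurrence model

Presence/background labels are one Bernoulli likelihood: background
pseudo-absences (mesh vertices plus a regular grid inside the terrestrial
mask) and surveyed nondetections both enter as `Z = 0`; the distinction is
kept only as a `role` tag. The linear predictor combines an intercept,
z-scored covariates, an optional latent Matérn field, and an optional
clustering covariate.

**Covariate scaling.** Each covariate is z-scored; the (mean, sd) record is
stored on the fit and reused verbatim at prediction time. Scaling is
computed on the training rows only and then applied to test rows and
prediction grids — the alternative (scaling before the split) changes
nothing materially at these sample sizes but would leak test information in
principle.

**The εNN clustering covariate** is log(1 + distance to the nearest presence
other than the point itself), z-scored with the rest of the design. This is
one concretization of a "distance to conspecific detections" term; other
definitions exist, so the term is off by default in selection ladders and
switchable in `RunConfig`. Coordinates alone cannot distinguish a presence
from a background point placed exactly on one, so `nn_covariate` takes an
explicit `is_presence` mask (zero-distance points default to "presence").

## Latent field

The Matérn smoothness is fixed at ν = 1 (α = 2), the standard default of
the SPDE approximation family in two dimensions. Range means √(8ν)/κ:
correlation ≈ 0.13 at one range. The finite-element mass matrix is lumped
(diagonal), which keeps the precision sparse with the standard stencil; the
difference from the consistent mass matrix is far below test tolerances.

Mesh defaults: interior max edge = domain diameter / 25, buffer = diameter /
5, exterior max edge = 2× interior, cutoff = interior / 5 — all
config-overridable, since no single resolution suits every range. The mesh
is built from a near-equilateral lattice (fine inside the domain, coarse in
the buffer) with a deterministic micro-jitter to avoid cocircular Delaunay
degeneracies; observation sites can be supplied as extra vertices and are
merged under the cutoff. Discretization accuracy: the Q⁻¹-implied
correlation deviates from the closed form mostly at lags comparable to the
edge length; edges ≲ 0.2× range keep the maximum deviation ≤ 0.07 (checked
in the tests). Doubling the buffer moves interior marginal variances by
< 2%, so the default buffer suffices for boundary control.

## Inference

Joint mode and curvature of (β, field) come from damped Newton iterations
(step-halving line search, ≤ 60 iterations, divergence guard against
separation). Fixed effects get a Gaussian prior, mean 0, sd 10; range and
marginal sd get log-Gaussian hyperpriors (unit log-sd) whose medians default
to domain diameter / 5 and 1. Hyperparameters maximize the Laplace
approximate marginal likelihood plus hyperprior over a log-spaced grid —
7 × 7 around the prior medians by default, with a short Nelder–Mead
refinement of the best cell. Simulation-heavy tests pass a single fixed
grid cell instead; that is a runtime decision (hundreds of fits in the
budget), not a calibration, and any single-cell choice only has to be a
reasonable hyperparameter to preserve coefficient coverage.

Posterior summaries are Gaussian: means at the mode, sds from the inverse
curvature, quantiles from the normal. WAIC uses 200 draws from the Gaussian
approximation by default (seeded); the Monte-Carlo sd of WAIC at 200 draws
is a few tenths to ~1 unit depending on n, which matters when comparing
models separated by less — the selection tests use 400 draws. The
independence-Metropolis MCMC mode proposes from the Laplace Gaussian; with
this model family acceptance rates are high and the chain is an adequate
slow oracle for the approximation (checked to 0.05 on posterior means).

## Model selection

Stage 1 fits all non-empty habitat subsets, stage 2 adds climate covariates
univariately against an explicit no-climate null, stage 3 adds all
anthropogenic subsets; every candidate carries the intercept and the field.
Candidates containing a covariate pair with |Pearson r| > 0.6 are dropped
before fitting. Stages rank by WAIC; models within 2 ΔWAIC of the stage best
are flagged as ties but only the top-ranked model advances. Exact ties
(within 1e-6) break toward fewer covariates, then lexicographic names, which
also makes the ladder invariant to candidate ordering. A habitat-free
stage-1 option is not fitted.

WAIC, like AIC, is not selection-consistent: a pure-noise covariate lowers
WAIC with probability ≈ P(χ²₁ > 2) ≈ 0.16, so with two decoy habitat
candidates the strict rule picks exactly the generating singleton only
~70% of the time no matter how large n grows, and a no-effect climate stage
keeps the null only ~60% of the time with three candidates. For analysts who
prefer to guard against carrying such uninformative parameters forward,
`SelectionContext(parsimony_band=2.0)` switches the stage winner to the
fewest-covariate model among those within 2 ΔWAIC of the best; the strict
lowest-WAIC rule remains the default because it is the convention this
pipeline follows.

## Effects, surfaces, validation

RSS is exp(β) per scaled unit, with the raw-unit increment (the covariate's
sd) reported alongside; rounding happens only at report time. Surfaces are
inverse-logit linear predictors at cell centres of a 2-km grid (covariates
looked up nearest-cell from the stack), divided by their maximum, in two
variants: with the posterior-mean field projected onto cells, and fixed
effects only. Effect curves smooth the scaled relative probabilities at the
observation sites against the raw covariate with a penalized B-spline of
basis dimension ≤ 5 (statsmodels GLMGam); the band is ±2 pointwise standard
errors of the smoother, clipped with the curve to [0, 1].

Validation splits the labelled set 80/20 by seeded permutation with exact
counts (so a given n yields a fixed test fraction). The threshold maximizes
sensitivity + specificity over a 0.001-step grid with `score ≥ threshold`
classified present; AUC is the rank-based Mann–Whitney concordance with ties
counted ½; TSS = sensitivity + specificity − 1 holds exactly by
construction. AUC/TSS are computed on the held-out 20% only. Occupancy
classes are fixed-width 0.2 bins, upper-closed, with 0 in the first class;
proportions are over cells, with each cell assigned to exactly one ecoregion
(first listed wins on shared boundaries).

## Synthetic landscapes

The generator emulates the statistical structure this analysis assumes, not
any real geography. Habitat layers are zero-truncated Gaussian fields
(mean 6, sd 6 m²/ha, range 10 km by default): right-skewed with exact
zeros, like basal-area rasters. Climate layers share one Matérn structure
(range 20 km) and are mixed to a target 6 × 6 correlation matrix; the base
draws are empirically whitened over cells first, so realized cell-wise
correlations equal the target exactly rather than fluctuating with the
effective number of independent cells. Percentage-valued winter indices are
clipped to [0, 100]. Roads are random chords (Poisson count from a
segments-per-100-km² density; about a quarter flagged arterial), from which
road-density (km/km²) and distance-to-major-road layers are derived;
housing density is a truncated field nudged by road density; conservation
lands are random discs. Occurrences are uniform sites labelled through the
model's own inverse-logit with a fresh field draw; roadside detection bias
is optional presence-thinning with retention exp(−bias × distance to major
road).

Not emulated: temporal drift (occurrences are pooled over years in the
motivating use case and the generator is static), anisotropy or
non-stationarity of the field, survey-effort heterogeneity beyond the
roadside bias, and real ecoregion shapes (seeded cell-based Voronoi
partitions stand in). A green test therefore establishes correctness of the
machinery under the stated model, not robustness to violations of it.

## Degenerate inputs and failure modes

Constant covariate columns, single-class test sets, empty masks, zero road
density, infeasible correlation matrices, labels outside {0, 1}, points
outside the mesh, and non-finite pointwise likelihoods all raise with
specific messages naming the offender. The GRF covariance gets escalating
jitter before a non-positive-definite failure is reported with the smallest
eigenvalue. All randomness flows from named integer seeds; identical
configurations reproduce outputs byte-for-byte (wall time lives only in the
run manifest).
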