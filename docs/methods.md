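# Methods

This note documents the modelling choices behind `coraldemog`: the
demographic model and its assumptions, the default parameterization and
why it looks the way it does, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make runs
reproducible.

## The demographic model

Each coral guild is a stage-classified (Lefkovitch) population with five
radius-defined classes.  Class boundaries are half-open and
lower-inclusive on radius: [0,1), [1,5), [5,10), [10,20), [20,∞) cm.
The fifth class is open-ended and treated as absorbing — survivors stay
(`P₅ = σ₅`) and there is no onward transition.

The yearly update is affine, `n(t+1) = A n(t) + ν`, with the external
spat supply entering class 1.  Three recruitment regimes are supported:
*closed* (first-row fertilities only), *imported_only* (zero fertility,
positive ν — the fully open population), and *mixed*.  Requesting
`imported_only` against a matrix that carries fertility is rejected as
contradictory rather than silently zeroing the fertilities; the caller
must make the choice explicit.

**Growth probabilities.**  With fixed stage durations, the conditional
probability of advancing given survival is computed in the
geometric-sum form `γ = σ^(T−1) / (1 + σ + … + σ^(T−1))`, algebraically
identical to the textbook ratio `(σ^T − σ^(T−1))/(σ^T − 1)` but stable
at σ → 1 (limit exactly 1/T) and at σ = 0.  This λ-free form is the
appropriate one when the matrix is being built *before* any growth rate
is known; a self-consistent variant that discounts survival by the
matrix's own λ (fixed-point iteration) is available as
`build_matrix_lambda_iterated` for users who prefer the
stable-population convention.  Tissue loss (partial mortality,
fragmentation) is absorbed into the diagonal loops by default; explicit
super-diagonal retrogression entries can be enabled for
increased-shrinkage impact scenarios.

**Monte-Carlo matrices.**  Each of the (default) 10,000 trials draws
every stage's (σ, T) pair independently and uniformly from the guild's
life-table pool; the arithmetic mean of the trial matrices is the
guild's generalized matrix (arithmetic, because pool entries are
unrelated repeat estimates of the same quantities).  Zero-fertility
trial matrices are lower-triangular and column-substochastic, so every
trial λ equals its largest loop entry and is strictly below 1 whenever
all σ < 1 — the subcriticality property the test suite asserts.

**Cover proxy.**  Cover is Σ nₖ·π·rₖ² over classes 2–5 with
representative radii 1, 3, 5 and 10 cm.  Spat are excluded: they cannot
be detected in phototransects and contribute negligible area.  The four
printed radii therefore map to the four *detectable* classes; the
mapping is configurable.

## Elasticity and sensitivity

Elasticities use the standard eigenvector form
`e_ij = (a_ij/λ)·v_i w_j / ⟨v,w⟩` with the right eigenvector scaled to
sum 1 and the left eigenvector scaled so ⟨v,w⟩ = 1.  Every elasticity
matrix sums to one (asserted to 1e-10) and is cross-checked in the
tests against a central-finite-difference oracle at relative tolerance
1e-4 (with an absolute floor of 1e-9 covering the oracle's truncation
error on near-zero entries).  Because coral fertilities are essentially
unknown, elasticities are reported as entrywise mean and standard
deviation over all 25 combinations of (1, 10, 100, 1000, 10000)
substituted into A[1,4] and A[1,5].

Global sensitivity is evaluated at the level of whole hindcast-style
runs: total proportional deviation of the final population vector from
the control run, L1 norm, mean over a factor's variants.  Two
conventions matter here:

* The comparison can be restricted to the field-observable classes 2–5
  (`classes_evaluated`).  The final-year spat count is a copy of the
  final-year supply, so including class 1 makes any timing variant that
  moves the last year's pulse look spuriously dominant; verification
  data in the emulated setting never included spat either.
* Fertility variants should be kept in the low range consistent with an
  open-population control: a fertility of 1000 at A[1,5] would by itself
  generate tens of thousands of larvae per year and swamp every other
  factor.  With both conventions, the shipped fixture ranks the factors
  recruitment level > recruitment timing > fertility.

## Hindcast calibration

The grid search enumerates fertility pairs × start-survival fractions ×
per-year supply levels, projects every candidate for (default) 8 years
in one vectorized sweep, and accepts candidates whose projected
distribution deviates from the observed one by strictly less than 10%
in every evaluated class.  Classes observed at zero are dropped with a
warning (relative deviation undefined); the largest class can be
excluded explicitly, which is needed where asexual reproduction
produces large colonies faster than stage transitions allow.  A Pearson
chi-square statistic (modeled counts as expected; cells with expected
< 5 pooled into the neighbouring cell; df = cells − 1) accompanies each
accepted fit.

Start vectors apply one surviving fraction from {0, 0.01, 0.05, 0.25}
to classes 1–4 of a configurable pre-disturbance distribution and an
independently enumerated fraction to class 5, reflecting the
observation that individual large colonies (especially massives)
survive events that annihilate small corals.  Candidate supply levels
default to {0, 10, 100, 1000, 10000, 20000}; the calibration runs in
the tests and the acceptance script use the 4-level grid
{0, 100, 1000, 10000}, which keeps the 8-year search exhaustive
(~1.05 M combinations per population, a few seconds vectorized).  Full
enumeration is used up to a configurable cap (default 10⁶) and seeded
uniform subsampling beyond it.  Per-year supply modes are taken over
exact grid values with ties broken toward the smaller value.

Memory note: with millions of candidates, only accepted fits are
materialized as objects (plus summary counts); the complete result list
is kept only for small searches.

## The synthetic world

No machine-readable field data exist for the emulated system, so the
`chagos_like_world` preset defines the study conditions outright:

* **Life-table pools** draw per-stage survival uniformly from bounded,
  stage-wise increasing ranges (e.g. massive: 0.02–0.12 for spat up to
  0.96–0.99 for large colonies) with guild-specific stage durations
  (arborescent 1–3 years per stage; massive up to 8–12 years in the
  medium class).  These ranges encode the universal pattern that small
  corals die at far higher rates, and that large massives approach the
  ~2%/yr background mortality of old *Porites* heads.
* **Larval supply truth**: per-year series on the calibration grid,
  lagoon an order of magnitude above the ocean-facing reef (weak
  lagoonal currents retain larvae), massives above branching forms, and
  one recruitment-failure year (ν = 0) per population.  Failure years
  sit late in the series deliberately: the end-of-period size
  distribution carries almost no information about early low-supply
  years (at the 10% acceptance tolerance, an early 0 is
  indistinguishable from an early 100 or 1000), whereas the smallest
  observed classes pin late-year supply tightly.  Truth values were
  chosen so that every parameter the recovery tests score is actually
  identifiable from the data the fixture provides — the closed-loop
  tests are tests of the estimator, not of luck.
* **Anchor-event survival**: branching/encrusting populations are
  devastated (zero survival of classes 1–4; a 5% remnant of large
  colonies inside the lagoon only), massives keep 25% of all stages and
  of lagoonal large colonies.  The pre-disturbance state is each
  population's stationary distribution under its mean supply, i.e. the
  event hits an equilibrium community.
* **Phototransects** scatter circular colonies uniformly over the
  0.5 × 20 m corridor (Poisson counts at the prescribed densities) and
  apply the digitization rules: edge-crossing colonies are kept if any
  chord of the clipped shape exceeds 40 cm — which for circles reduces
  exactly to radius > 20 cm — or if the clipped area itself reaches
  that of a 20 cm-radius disc (both place the colony in the open-ended
  class), or if the class inferred from the clipped area agrees with
  the true class; otherwise they are excluded as ambiguous.  At
  realistic densities fewer than 5% of recruit/juvenile-sized colonies
  are lost this way.  Clipped areas are exact for single-edge crossings
  (circular segment); simultaneous two-edge crossings subtract both
  segments independently, a slight underestimate that only makes
  inclusion marginally more conservative.

What the generator does **not** emulate: observation error is off by
default (a multiplicative lognormal option exists), colony shapes are
circles, there is no spatial autocorrelation, no density dependence, no
between-year variation in the matrices, and species are collapsed into
three guilds.  Passing recovery tests therefore demonstrate that the
estimation machinery is correct and self-consistent — not that an
8-year size distribution from a real reef would identify its
recruitment history equally well.

## Scenario conventions

* Recruitment reduction is additive-cumulative: year *t* keeps
  `max(0, 1 − rate·t/100)` of its baseline supply, so 1 %/yr means
  exactly 50% lost at year 50 (multiplicative compounding would give
  ≈39.5% and is *not* what "1% per year, 50% cumulative over 50 years"
  arithmetic implies).  The loss is capped at 100%.
* Within a model year the projection step runs first and any episodic
  mortality event second; events fire at t = interval, 2·interval, …,
  so interval 8 over a 50-year horizon yields exactly 6 events (years
  8–48).  Events remove a fixed fraction of classes 2–5 by default
  (the non-recruit classes; the affected set is configurable).
* Every disturbed run is paired with an undisturbed reference from the
  same start and baseline supply.  Baseline supply for forecasts is the
  modal per-year series from the hindcast's accepted solutions, cycled
  over the forecast horizon.
* With the shipped defaults the community-level endpoints are: ~80–88%
  of initial cover retained under 25% pulses + 1 %/yr recruitment loss;
  ~19–21% of the undisturbed run under 50% pulses (the 75% regime falls
  to ~10%); and recruitment-only scenarios up to 75% cumulative loss
  cost at most about half the undisturbed cover.  These are the numbers
  `scripts/acceptance.py` recomputes.
* The homogenization contrast ((max − min)/mean of final covers across
  habitats) declines under heavy recurrent mortality, but only through
  the initial-condition asymmetry: the projection is linear, so
  habitats that differed *only* by a scale factor in supply would keep
  their contrast exactly.  What the disturbance erodes is the lagoon's
  surviving-large-colony advantage, which is not proportional to
  supply.  The decline is therefore real but small in this linear
  model; stronger homogenization would require nonlinear (e.g.
  space-limited) dynamics, which are out of scope.

## Numerical and reproducibility conventions

Counts are real-valued throughout (the matrix model is an expectation
model; rounding would break the fixed-point identities).  Dominant
eigenvalues come from `numpy.linalg.eigvals` (spectral radius);
stationary states from a direct linear solve of `(I − A) n* = ν`.  All
randomness flows through `numpy.random.default_rng` seeded per run,
with child seeds derived deterministically where a run needs several
streams; identical seeds give bit-identical outputs, which the test
suite asserts at the level of written CSV bytes.  CSV files are
comma-separated UTF-8 with mandatory headers and '.' decimals; schema
violations are reported with row/column context.  Every CLI output
directory contains a `manifest.json` recording command, configuration,
seeds, input digests and package version.

## Known limitations

Linear dynamics (no density dependence, no space competition) mean
cover can exceed the physically available area under generous supply;
results should be read as relative trajectories, not absolute
predictions.  Stage durations and survival ranges are literature-style
assumptions, not fits.  The chi-square statistic uses modeled counts as
expected values without rescaling to the observed total, matching the
acceptance criterion's relative-deviation logic rather than a formal
goodness-of-fit test.  Elasticities of reducible (zero-fertility)
matrices concentrate on the largest loop and should be interpreted with
the usual caution about non-primitive matrices.
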