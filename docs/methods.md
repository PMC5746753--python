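# Methods

## Scope and model

`ipmsim` models the chromatography segment of a purification train: the
load of the first modeled column is the starting point (upstream
fermentation and primary recovery enter only through the initial-state
distribution), and the pool of the last modeled column is treated as
drug substance (no clearance is attributed to a final
ultrafiltration/diafiltration).  State per simulation is the specific
concentration of each CQA (impurity amount per product amount) plus the
product amount; a unit operation transforms it by

    c_pool = c_load / SC,      p_pool = p_load * SY,

and the pool of one column is the load of the next.  Only upper
specification limits are modeled; impurities have no meaningful lower
limit and the schema rejects one.

## Sampling distributions

* **Process parameters.** Independent normals centered at the set-point
  with the routine-manufacturing SD, one draw per simulation and unit
  operation.  Classical pseudo-random sampling is deliberate: variance
  reduction schemes (Latin hypercube, quasi-random sequences) would
  distort the tail mass that an OOS estimate is made of.  No PP-PP
  covariance is modeled; set-points are controlled independently.
  Relative SDs quoted as percent of set-point are converted to absolute
  once at load time.  pH is treated like any other PP even though a
  "percent of set-point" SD on a log-scale quantity is a convention,
  not a ratio — the caveat is inherited from how such tables are
  reported.
* **Initial state.** Per-CQA normal with mean/SD estimated from
  large-scale runs, and a normal product amount.  The product-amount
  distribution is a configuration field like the CQA distributions; it
  is needed because the impurity loading density depends on the
  absolute product load.
* **Model error.** A DoE-model clearance is drawn from the uncertainty
  of the *mean* response, `N(ŜC(x), s²(1/n + h(x)))`, not from a
  prediction band: residual variance is attributed to assay error, not
  to batch-to-batch process variation, so it is not re-added to new
  batches.  Constant models draw from the full large-scale variance,
  which *is* batch-to-batch variation.  This asymmetry is intentional
  and is what the end-to-end recovery tests encode: the synthetic truth
  evaluates DoE-governed responses deterministically and
  constant-governed responses stochastically.

## Regression details

Factors are coded before fitting: centered at the design mean and
scaled to the design half-range; term columns (mains, two-factor
interactions, pure quadratics) are then centered to their design means.
With the model matrix orthogonal to the intercept, the mean-response SD
decomposes exactly into the `1/n` and leverage terms, and the
formulation is algebraically identical to the textbook
`s·sqrt(x(X'X)⁻¹x')` on the raw matrix with intercept (asserted against
that oracle at 1e-10 relative in the tests).  Coefficients are reported
in coded and natural units; predictions are coding-invariant.

Stepwise selection is bidirectional: among candidates with partial
p-value (coefficient t-test in the current multivariate model) below
0.05, the smallest enters first; after each entry, included terms with
partial p above 0.10 leave, worst first, one at a time; iteration stops
when the structure stops changing, with a repeated-state guard against
oscillation.  Candidates that would exhaust the residual degrees of
freedom or alias the design are skipped.  The procedure is
deterministic given data, candidate order and thresholds.  Its
operating characteristics are what classical theory predicts: power for
effects at SNR ≥ 5 on a 13-run definitive screening design is ~1, and
the probability of at least one false entry is the min-of-null-p-values
order statistic (~15% with three null candidates at p_enter = 0.05) —
an inherent property of per-candidate thresholds, frozen in the tests
as regression constants rather than "fixed".

Weak heredity is not enforced; the candidate set is caller-configurable
and defaults to mains + interactions + quadratics, which both shipped
design families can partially resolve.

Spiking models are strictly one-factor linear in the impurity loading
density.  Q² is 1 − PRESS/TSS with PRESS from the leave-one-out
identity `e_i/(1−h_ii)` (asserted against an explicit refitting loop).
The screen (slope p < 0.05 and R² − Q² < 0.3) gates attachment; DoE and
large-scale points are pooled by default — both populations sit on one
regression — while the anchoring mean ILD is taken from the DoE points.
The combination with the PP-driven draw is multiplicative and neutral
at the mean loading density; the ILD of a simulation is evaluated from
the *incoming* state before any clearance draw, so spiking responds to
upstream variability.  The two draws use independent streams; no joint
error model is assumed.

## Random numbers, floors, determinism

One master seed spawns named substreams (PP sampling per unit
operation, initial state, model error per unit operation and response,
spiking error per unit operation and CQA) via hashed `SeedSequence`
spawn keys.  Consequences: identical inputs and seed reproduce results
bit-for-bit; disabling the spiking components does not perturb any
other draw (the ablation is draw-for-draw comparable, up to the last
bit of the neutral multiplicative factor); and sensitivity analyses
reuse common random numbers, because PP and initial-state draws are
standard normals scaled after the fact — a shifted set-point or scaled
variance moves every simulation deterministically.  The 0% grid point
of every PSA therefore equals the baseline exactly, and one-at-a-time
curves are smooth in the perturbation at n_sims = 1000.

Normal draws of quantities that must be positive (clearances, yields,
concentrations, product amounts) are redrawn up to 100 times while at
or below a floor of 1e-6, then clipped; yields are additionally capped
at 1.  All interventions are counted and reported.  Under the default
noise levels the counters are zero; they exist for pathological
configurations, which are flagged rather than dropped.

Default n_sims is 1000 — the convention for this kind of study, and
enough to resolve OOS probabilities in the percent range (Wilson 95%
interval of ±~1.6% near 7%); the interval is always attached so the
user sees the resolution.

## Out-of-specification estimates

Simulated OOS is counting above the limit.  Observed-data OOS from a
small campaign uses a fitted normal (mean, n−1 SD) upper tail — with 9
runs an empirical tail fraction would only take values 0, 1/9, ...  The
overlay report max-normalizes simulated and observed values by the
maximum of their union per panel and attaches a two-sample
Kolmogorov–Smirnov statistic; distribution comparison in practice is
visual, but tests need a number.  Observed values below the limit of
quantification are excluded, never imputed, and counted; an all-missing
panel is emitted empty and flagged.

## Synthetic template

The generator emulates the structure of an industrial
process-characterization study: three columns with 5/3/4 varied PPs
(pH, column loading density, wash/elution strength, gradient slope, end
pooling) at realistic relative SDs (0.8–12.8% of set-point, SD/half-NOR
ratios 0.2–0.62), a 13-run DSD, an 11-run full factorial with three
center replicates, a 9-run DSD, a 9-run large-scale campaign, and a
mixed model pattern — DoE models where effects exist, constant
large-scale clearances elsewhere, four spiking components, 10 points
per spiking fit (6 spanning 0.5–1.8× the routine loading density, 4
clustered large-scale points).

Noise defaults are chosen once as representative of a well-controlled
process with validated analytics (a stated assumption of this modeling
approach): DoE residual SD and large-scale clearance CV 2% of the base
clearance, spiking residual 2%, yield residual SD 0.008, active effects
at 6 residual SDs, initial burden CV 20%, product amount CV 5%.  Base
clearances (3–15 per column per impurity) are jittered ±15% across
seeds so replicate scenarios are genuinely different processes; signs
are fixed (clearance falls with rising pH, rises with the second
control), giving every DoE model a known favorable direction for
sensitivity tests.  Upper specification limits are calibrated at
generation time from a seeded 200k-draw simulation of the true process:
the designated near-limit CQA gets the quantile that makes its true OOS
7% — the regime where an OOS estimate is interesting — and the others
sit far below their limits, exercising both regimes.  Feasibility
(positive clearance over the sampling region) is checked on the same
draw.

Definitive screening designs are conference-matrix fold-overs
([C; −C] plus center), orders 4–12, with Paley constructions over
GF(5), GF(7), GF(9), GF(11), GF(13) and a literal order-4 skew matrix,
each verified by C'C = (n−1)I at construction.  For an odd number of
factors the order-(k+1) matrix is used with its last column dropped —
the standard construction, 2k+3 runs (13 for k = 5); the fold-over pair
whose mid level sat in the dropped column has no mid-level entry.

What the generator does *not* emulate: assay nonlinearity and
censoring except via explicit below-LoQ gaps, correlated PPs, lot-to-lot
resin aging, non-normal initial states, ILD-by-PP interactions (assumed
absent, as the spiking design cannot resolve them), and any attempt to
match the proprietary coefficients behind published, max-normalized
figures.  Passing tests therefore demonstrate that the machinery
recovers processes *of this structure* — not that any particular real
process satisfies the structural assumptions.

## Problem sizes in the shipped checks

The test suite and the acceptance script use: 1000-simulation Monte
Carlo runs for end-to-end comparisons (10⁵ where a closed form is
available), a 10⁶-draw brute-force oracle per scenario, 20 replicate
scenarios for end-to-end recovery, 200 replicates for stepwise and
spiking operating characteristics, and 100 replicate campaigns for the
overlay self-consistency check.  These sizes resolve the quantities
being asserted to well inside their stated tolerances.

## Known limitations

* The mean-response error band understates batch-to-batch variation if
  residuals contain true process noise; with precise assays the
  understatement is small, with noisy assays the simulated
  distributions will be too narrow.
* With 9 large-scale runs, fitted constant-model means carry ~CV/3
  sampling error per column; stacked across a chain this is the
  dominant term in the error of an OOS estimate near a few percent, and
  it is irreducible at fixed campaign size.
* One-at-a-time sensitivity only; no global (Sobol-type) indices, no
  simultaneous multi-PP grids beyond the hook for interaction pairs.
* Clearances are assumed exchangeable across scale once estimated;
  scale-down offsets appear only as what they are in the data.
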