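# Methods

This note documents the statistical procedures implemented in `cihkit`,
the assumptions behind them, the defaults and why, and what the synthetic
test bed does and does not establish.

## The measurement model

The toolkit assumes a *formative* measurement model: the composite is
defined by its elementary indicators, the indicators are judged
non-substitutable (a surplus on one cannot compensate a deficit on
another), and all indicators within a pillar — and all pillars within the
composite — carry equal weight unless a configuration says otherwise.
Indicators carry a *polarity*: positive if larger raw values mean more of
the measured concept, negative otherwise (mortality rates, crime rates,
pollution exceedances).  Unit identifiers are opaque strings; the toolkit
never infers geography from them.

## Normalization (goalposts)

Each indicator j is mapped onto the 70–130 scale by an affine *goalpost*
transform; with goalposts (low_j, high_j):

    positive polarity:  r_ij = 60 · (x_ij − low_j) / (high_j − low_j) + 70
    negative polarity:  r_ij = 60 · (high_j − x_ij) / (high_j − low_j) + 70

The constants 60/70 are forced by requiring the map to carry the goalpost
interval onto [70, 130].  Two goalpost rules are implemented:

* **minmax** (default): (low, high) = observed column (min, max).  Every
  normalized value is then in [70, 130] by construction.
* **reference**: (low, high) = (ref_j − Δ_j, ref_j + Δ_j) with
  Δ_j = (max_j − min_j)/2.  A unit at the reference value maps to exactly
  100 for either polarity; values may leave [70, 130] when the reference is
  off the midrange, and such cells are *reported, never clamped* — clamping
  would destroy the affine invariance of the construction and distort the
  penalty term.

The two printed anchors of the scale (bounds 70/130 and reference = 100)
cannot both hold under a single rule unless the reference is the midrange,
which is why the rule is a mode switch rather than a guess.  A constant
indicator column has no goalposts and is rejected as degenerate.

Minmax normalization is invariant under increasing affine transforms of a
raw column, and the two polarities of the same column always sum to 200
cellwise; both properties are tested.

## Aggregation (penalized mean)

For unit i over values r_i1…r_ik with positive weights w_j (normalized to
sum to 1):

    M_i  = Σ_j w_j r_ij
    S_i  = sqrt( Σ_j w_j (r_ij − M_i)² )        (population form)
    cv_i = S_i / M_i
    score_i = M_i − S_i·cv_i  (minus direction)  or  M_i + S_i·cv_i (plus)

equivalently M_i ∓ S_i²/M_i.  The population (n-denominator) form of S is
used deliberately: it matches the coefficient-of-variation convention of
the adjusted-penalty literature and makes the two-point case exact
({70, 130} → 91 in the minus direction, 109 in the plus).  The minus
direction (penalize imbalance) is the default for positive phenomena.

On the 70–130 scale the Bhatia–Davis inequality
S² ≤ (M − 70)(130 − M) implies 70 ≤ M − S²/M and M + S²/M ≤ 130, so in
minmax mode every pillar score and the composite remain in [70, 130]; the
acceptance suite stresses this over 200 randomized panels.

Pillar scores are the penalized mean of the pillar's member indicators
(single-indicator pillars pass through unchanged); the composite is by
default the penalized mean of the pillar scores *without re-normalizing
them* (they already share the scale).  A `composite_level="indicators"`
option aggregates all elementary indicators directly instead — the
construction is stated ambiguously in the source methodology, so both
levels are supported with pillars as the default.  Ranks are descending in
the composite with ties broken by panel order, which keeps the influence
analysis reproducible.

Numerical note: the weighted moments are computed relative to the unit's
first value so that an exactly constant profile yields S = 0 and
score = M with no floating-point residue.

## Hot-deck imputation

The donor for a missing cell (i, j) is the unit observing j that minimizes
the Euclidean distance to i over the z-standardized indicators observed on
both units (column mean/SD over observed values; zero-SD columns contribute
zero distance).  Design choices, since the method name alone does not fix
them:

* **Simultaneous, not sequential**: all donor searches run against the
  original observed data, so the result is order-independent.
* **Ties** break on the lexicographically smallest donor id, making
  imputation equivariant under row permutations.
* **Fallbacks**: if nothing observes j, or i shares no observed indicator
  with any donor, the cell takes the configured reference value (the
  "national average" generalized); absent that, the column's observed mean
  (logged) — this keeps the pipeline total on synthetic data.  A fully
  missing column with no reference is an error.

Hot-deck never invents numbers: every imputed value is an observed value of
its column or an explicitly supplied reference, which the tests assert.

## Influence analysis

For each elementary indicator k the *entire* construction (imputation,
normalization with goalposts recomputed on the reduced set, aggregation,
ranking) is rerun without k, and the rank shifts d_i = rank_i(full) −
rank_i(−k) are summarized by σ_k = sqrt(mean_i d_i²).  Because both
rankings are permutations of 1..n the shifts sum to zero, so σ is also
their population SD; mean |d| and max |d| are reported alongside.  Shifts
are defined on ranks (the published use of σ concerns ranking changes); a
score-shift variant is available behind a flag.  If k is its pillar's only
indicator the pillar drops out of that rerun (logged).  A brute-force
oracle that rebuilds every reduced pipeline with plain loops validates σ on
small panels.

## Correlation analysis

Pillar scores are correlated pairwise with Pearson's r; p-values come from
the exact two-sided t transform on n − 2 degrees of freedom (exact under
bivariate normality), significance at α = 0.05.  No multiple-testing
correction is applied at this stage, matching common reporting practice for
a 6×6 pillar matrix; the matrix is exported in lower-triangle layout.

## Spatial autocorrelation

Contiguity weights are binary and symmetric (asymmetric input is
symmetrized by union with a warning), then row-standardized.  With
z_i = (x_i − x̄)/SD (population SD):

    global:  I = (n/S0) Σ_i Σ_j w_ij z_i z_j / Σ_i z_i²,   S0 = Σ_ij w_ij
    local:   I_i = (z_i / m2) Σ_j w_ij z_j,                m2 = Σ_k z_k²/n

With row-standardized weights S0 = n and mean(I_i) = I over non-island
units (asserted to 1e-10).  The null expectation of I is −1/(n−1).

Inference is by permutation with the +1-corrected pseudo p-value,
two-sided: the global test permutes all values over units, referenced to
−1/(n−1); the local test is *conditional* — z_i stays fixed while the
remaining n−1 values are redrawn over i's neighbor positions — referenced
to 0.  Two-sided tests are used because the negative-association classes
(High-Low, Low-High) are substantively meaningful.  Significant units are
classified by the signs of (z_i, lag_i) into HH/LL/LH/HL; everything else
is Not-significant.  Zero z or lag counts as "low" (measure-zero tie-break
on continuous data).

With M permutations the pseudo p-values live on {1/(M+1), …, 1}, so the
attainable level at threshold α = 0.05 with M = 199 is 9/200 = 0.045 — the
calibration test centers its binomial band there, since that is what a
correct implementation achieves.

Islands (units with no neighbors) are an error by default; with
`allow_islands` they are excluded from the statistics and labeled
Not-significant with an island flag — motivated by real provincial systems
that contain islands.  An optional Benjamini–Hochberg adjustment across
units is available on the CLI (`--fdr`) and off by default.

## Synthetic panels

The generator emulates the structure of a territorial indicator panel:

* units on a rows × cols rook lattice (default 8 × 8);
* a latent health factor u = (I − ρW)⁻¹ ε, ε ~ N(0, I) — a simultaneous
  autoregressive (SAR) scheme chosen over CAR for its one-line closed form;
  ρ (default 0.4, a moderate positive autocorrelation) controls spatial
  structure;
* per-pillar factors p = a·u + √(1−a²)·η with a = `pillar_loading`
  (default 0.85), so pillars are correlated through the common factor but
  not collinear;
* indicators x = 100 + loading·p + noise (loading 1.0, noise SD 0.5), with
  the signal negated before the offset for negative-polarity indicators so
  healthier units show lower raw values there;
* MCAR missingness at rate 0.02 (sparse, as in curated official extracts);
* the default indicator layout mirrors the 23-indicator / 6-pillar
  well-being schema, including its polarity mix.

All draws flow from a single seed; identical seeds give bitwise-identical
panels.  What the generator does *not* emulate: real administrative
geographies (irregular contiguity, true islands), non-Gaussian indicator
distributions, informative missingness, measurement error correlated
across indicators, or temporal structure.  Passing tests therefore
establish the correctness and calibration of the *construction*, not the
substantive validity of any particular published index value.

## Problem sizes used in the test and acceptance runs

Stress and calibration runs use deliberately modest sizes chosen to give
stable Monte-Carlo estimates: 200 panels of 40 × 8 for the range law, 500
null panels (6 × 6 lattice, 199 permutations) for LISA calibration, 50
seeds per ρ ∈ {0, 0.3, 0.6} (6 × 6) for spatial parameter recovery, and
n ≤ 7 graphs for the brute-force Moran oracles.

## Known limitations

* Hot-deck donor search is O(n²·p) per panel — fine for hundreds of units,
  not tuned for tens of thousands.
* Reference-mode goalposts use the observed half-range Δ of the analyzed
  panel; comparing several vintages requires fixing Δ externally, which the
  API does not yet expose.
* The LISA permutation engine assumes row-standardized binary contiguity
  (equal weights within a row) when shuffling neighbor values; general
  (unequal) row weights are assigned to sampled values in arbitrary order,
  which is distributionally equivalent for exchangeable draws but would
  matter for deliberately ordered weight schemes.
* No Getis–Ord statistics, distance-band/kernel weights, or map rendering.
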