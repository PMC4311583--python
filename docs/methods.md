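# Methods

## Scope and model

`mediaopt` implements the two-stage statistical media-optimization
workflow for fermentation processes: Plackett–Burman (PB) screening of
many candidate factors, then response-surface modelling of the few
retained factors on a rotatable central composite design (CCD). All
inference is frequentist and least-squares based; responses are treated
as continuous measurements (activity, titer) with additive i.i.d.
Gaussian error.

### Screening stage

A PB design with *N* runs accommodates up to *N* − 1 two-level factors
in mutually orthogonal, balanced ±1 columns. The package stores
generator rows for *N* ∈ {8, 12, 16, 20} and builds the matrix
cyclically: the generator is run 1, each later run is a one-position
right rotation, and the final run is all −1. Orthogonality and balance
of every stored size are asserted in the test suite by brute force over
all column pairs.

The main effect of a column is the difference of mean responses at its
two levels, `E = 2(ΣM₊ − ΣM₋)/N`. Because the design is orthogonal,
this equals exactly twice the least-squares slope of the response on
that coded column — a property the tests verify to 1e−10 on random
data. Columns not assigned to real factors ("dummies") have zero true
effect by construction, so their apparent effects estimate experimental
error: `Veff = ΣEd²/n`, `Es = √Veff`. Each factor's t statistic
`E/Es` is referred to a Student t distribution with **degrees of
freedom equal to the number of dummy columns** (3 in the bundled
study). The choice of df is the package's own: it is the number of
independent error contrasts the dummies supply, and it reproduces the
bundled study's printed p-value for CMC (0.0216) exactly. p-values are
two-tailed, since screening acts on effect magnitude; effects are
stored signed with a `magnitude` column mirroring conventional display.

When every dummy effect is exactly zero (noiseless synthetic data),
`Es = 0` and the t statistic is undefined; the analysis then reports
infinite t with p = 0 and sets a `degenerate_error` flag rather than
raising, so noiseless end-to-end pipelines still run.

Known inconsistency in the bundled study's printed screening table: the
printed standard error is 3.963858 for the CMC row but 5.04375 for all
other rows. Only 3.963858 follows from the dummy-variance formula (and
only it is consistent with the printed t = |effect|/SE for CMC). The
package applies the single pooled `Es` to every factor, as the formula
dictates; the 5.04375 value is not reproduced because no defensible
derivation of it exists. Similarly the printed yeast-extract effect
(2.778333) differs in the third decimal from the value the printed
design and responses yield (2.770); the package reports the computed
value.

### Response-surface stage

The CCD consists of a 2ᵏ factorial core at ±1, 2*k* axial points at
±α, and `n_center` replicated centre runs (total 2ᵏ + 2k + n_center).
The default axial distance is the rotatable value α = (2ᵏ)^¼, which
makes the prediction variance of the quadratic model a function of
distance from the centre only; the tests verify this numerically on
direction samples at several radii (constant to ~1e−15 relative). The
bundled study's design tables are consistent with the rotatable
α = 1.6818 for k = 3 and with six centre runs, and the package follows
the tables. α is overridable by a numeric value for users who want
face-centred or other variants.

Run order is deterministic and unrandomized: factorial block in
standard order (first factor fastest), axial pairs in factor order
(−α before +α), centres last. Randomization of run order is an
execution-time concern outside this package's scope.

Coded and actual units are linked by `actual = center + step × coded`.
Axial points can map to physically impossible levels (the bundled
study's MgSO₄ −α level is −0.1034 g%); the package returns the computed
value, attaches an `InfeasibleLevelWarning` and records the run/factor
pair, but never clips — silently altering the design would invalidate
the coded-space analysis, and flagging lets the user re-centre instead.

The full quadratic (p = 1 + 2k + k(k−1)/2 parameters; 10 for k = 3) is
fitted by OLS (statsmodels) in **coded** space; actual-scale coordinates
are a derived view. Rank deficiency is reported with the names of the
collinear model columns (e.g. pure-quadratic columns on a two-level-only
design). ANOVA sums of squares:

* SS(model) = Σ(ŷ − ȳ)², SS(residual) = Σ(y − ŷ)².
* Per-term SS by single-term deletion, SS(full) − SS(without term). On
  an orthogonal CCD this equals the sequential SS and also β²Σx²
  (asserted to 1e−8 in tests); on non-orthogonal user designs it is a
  partial (type-III-style) SS.
* Pure error is pooled within replicate groups — runs identical in all
  coded columns to 1e−9 (the six centre runs, df = 5, in the bundled
  study); lack of fit is the remainder of the residual. Without
  replicates the lack-of-fit rows are omitted.

Diagnostics: R², adjusted R², CV = 100·√MS_res/ȳ (undefined and
flagged when ȳ = 0), and adequate precision defined as
`[max(ŷ) − min(ŷ)] / √(p·MS_res/n)` over the design points — with
p = 10, n = 20 this reproduces the bundled study's printed 6.553, which
fixes the convention since the quantity has no single standard
definition.

### Optimum location

The stationary point solves 2Bx = −b, where b holds the linear
coefficients and B the quadratic-form matrix (diagonal βᵢᵢ,
off-diagonal βᵢⱼ/2); its nature follows from the eigenvalues of B
(threshold 1e−10 for "zero"). A singular B (ridge system) raises a
linear-algebra error that points the user to the constrained search.

The constrained optimum maximizes the fitted quadratic over the
explored region — the coded box [−α, α]ᵏ by default, since axial runs
probe the box directions; a sphere of radius α is available. The search
is deterministic: the analytic stationary point (when interior) plus
bounded local ascents (L-BFGS-B, or SLSQP for the sphere) from the fixed
3ᵏ lattice of region corners, centre and face points. For concave
surfaces with an interior vertex this returns the vertex exactly; tests
also check agreement with a dense grid oracle (0.01 coded resolution) to
1e−3 in response.

The bundled study's narrative optimum is not the fitted model's: its
stated best point (CMC at +α, other factors at centre) is run 10 of the
design, and the activity quoted for it (29.95 U/mL) is that run's
*observed* response, while the model predicts 28.3188 there and places
its true maximum at coded (0.937, 0.018, −0.510), predicted
28.51 U/mL. The package reports only model-consistent numbers; the
study's reported optimum, its validation measurement (30.62 U/mL) and
its fold-increase claim (6.81×, against an unprinted baseline) are kept
as metadata fixtures in `mediaopt.datasets.VALIDATION_METADATA`, never
computed.

## Synthetic data

`mediaopt.simulate` draws responses with known ground truth:

* PB: `y = baseline + Σ (effect_j/2)·x_j + ε`. The slope is effect/2 so
  that the difference-of-means estimator returns the stated effect
  exactly — truth and estimand live on the same scale.
* CCD: the full quadratic polynomial at each coded point plus noise;
  centre replicates get independent draws, so pure error is real.

Noise is i.i.d. Gaussian (`noise_sd`), seeded through
`numpy.random.default_rng`; the same seed gives bit-identical output.
Defaults in the test suite mirror the bundled study's conditions:
12-run/8-factor screens with noise of the order of the study's effect
standard error (≈ 4–5 U/mL), and 20-run CCDs with noise_sd ≈ 2.36
(≈ √MS_residual of the bundled fit). What the generator does *not*
emulate: heteroscedastic or non-Gaussian error, run-order drift, batch
effects, and any mechanistic fermentation kinetics. Passing tests
therefore certify the statistical machinery under the stated error
model, not robustness to real-world assay pathologies.

Monte-Carlo checks and their sizes (chosen to keep the suite fast while
leaving sampling error well inside the asserted bands): type-I error of
the screen at the 95 % threshold over 2000 replicates (asserted
0.035–0.065 around the nominal 0.05); power sanity over 500 replicates;
coefficient RMSE against the exact OLS standard error σ/√(Σx²) over 500
replicates (within 15 %); mean model F against the noncentral-F
expectation over 400 replicates.

## Numerical conventions

* Coefficients and effects are kept at full double precision
  internally; report files round to a configurable number of decimals
  (default 6) so identical inputs produce byte-identical reports.
* Replicate-group matching tolerance 1e−9 in coded units.
* CSV dialect: comma-separated, UTF-8, header row required, `.`
  decimal; design column roles travel in a JSON sidecar.
* The bundled coded design stores the axial distance at the 6-decimal
  printed precision of the source tables (1.681793) rather than the
  full (2³)^¼; the difference is below 1e−6 and below every assertion
  tolerance used.

## Limitations

* PB screening estimates main effects only; interactions are aliased
  onto other columns. No fold-over augmentation, Lenth's method, or
  half-normal plots.
* Only PB and CCD generators are provided (no Box–Behnken, D-optimal,
  or blocking), and no model reduction or Box–Cox transformation in the
  RSM stage.
* Single-response optimization only; no desirability functions or
  follow-up (steepest-ascent) design generation.
* Surface grids are exported as CSV for external contour plotting; the
  package does not render figures.
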