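# Methods

This note documents the statistical procedures `qsarkit` implements, the
conventions chosen where the literature is ambiguous, and what the
packaged and synthetic datasets can and cannot demonstrate.

## The model

The activity model is multiple linear regression,

    pIC50 = a0 + a1·x1 + … + ap·xp + ε,   ε ~ N(0, σ²),

fitted by ordinary least squares on the training subset.  PLS regression
with all latent components retained is algebraically identical to OLS, so
OLS is used throughout: it is deterministic, exact, and has closed-form
diagnostics.  Genuine latent-variable PLS (with component selection) and
regularized regression are deliberately out of scope.

The packaged chalcone dataset has n = 20 training compounds and p = 4
descriptors; with only 15 residual degrees of freedom, the
degrees-of-freedom conventions below are not cosmetic — they change the
second decimal of every reported error statistic.

## Fit statistics and conventions

* r² = 1 − SSE/SST; adjusted r² = ((n−1)·r² − p)/(n−1−p).
* **Fit RMSE** defaults to the residual standard error √(SSE/(n−p−1)).
  On the chalcone training set this gives 0.287; the population form
  √(SSE/n) gives 0.249.  Both are available
  (`fit_statistics(..., rmse_convention=...)`); only the residual-SE form
  is consistent with the reported reference statistics.
* **LOO RMSE** is √(PRESS/n) — the cross-validated analogue conventionally
  uses the plain-mean denominator, and does so here.
* F = ((SST−SSE)/p)/(SSE/(n−p−1)); coefficient p-values come from the
  classical two-sided t-test with n−p−1 degrees of freedom.

## Descriptor screening

Screening runs on the **training subset** by default: descriptor selection
is part of model building, and computing it on data that includes the test
compounds would leak information.  (On the packaged dataset the
training-subset correlation matrix and VIFs match the reference values to
four decimals; the all-25-compound versions do not.)

The screen applies three filters in order — zero/low variance, low
absolute correlation with the activity, then iterative removal of the
highest-VIF descriptor until all VIF ≤ 5 (ties broken toward the
later-listed descriptor, so the procedure is deterministic).  VIF is
computed by the auxiliary-regression definition 1/(1−r²_j); the test suite
cross-checks it against the inverse-correlation-matrix diagonal and
against statsmodels.

## Leave-one-out cross-validation

Each training compound is held out in turn and predicted by a model
refitted on the remaining n−1.  Q² = 1 − PRESS/SST with SST about the
**full training mean** (not the per-fold mean).  The implementation uses
explicit refits; the identity ŷ₍ᵢ₎ = yᵢ − eᵢ/(1−hᵢᵢ) serves as an
independent oracle in the tests (agreement to 1e−8).  PRESS ≥ SSE always,
so Q² ≤ r² — asserted property-style on random datasets.

## Roy's r²m metrics

The r²m family penalizes the gap between the correlation of observed and
predicted values with and without an intercept.  Published formulations
disagree in two respects: whether the vectors are min–max scaled first,
and which axis carries the through-origin regression.  `qsarkit` defaults
to the **scaled** variant (Roy's later recommendation — the unscaled form
depends on the measurement units), with r0² taken from the through-origin
regression of predicted on observed and r0′² from the reverse:

    r²m = r²·(1 − √|r² − r0²|),   Δr²m = |r²m − r²m′|.

On the chalcone LOO predictions the scaled form gives r²m ≈ 0.56, in line
with the reference value (0.57); the unscaled forms give 0.68–0.77.  The
unscaled variant remains available via `rm_metrics(..., scale=False)` and
is what the Golbraikh–Tropsha slope-gap conditions use (their original
definition).  The slopes k = Σ(obs·pred)/Σ(pred²) and k′ are always
reported on the raw vectors.

## Y-randomization and cRp²

Each run permutes the training activities, refits on the unchanged
descriptors, and records R = corr(permuted y, fitted), R², and the LOO Q²
of the permuted fit (via the hat-matrix identity; the hat diagonal is
permutation-invariant, so it is computed once).  The summary statistic is

    cRp² = R·√(R² − (avg R_r)²),

with R, R² from the unpermuted fit and avg R_r the mean correlation of
the randomized models — the published form of the statistic.  An
alternative convention averages the randomized R² values instead
(`average="r2"`); both are close on 20-run batches but differ slightly in
the large-run limit.

A point worth stating explicitly: under the permutation null the expected
random R² is p/(n−1) = 4/19 ≈ 0.21 for this design, with a single-run SD
of ≈ 0.13.  A 20-run batch can therefore easily average 0.15, and a
100-run batch concentrates near 0.21.  Consequently cRp² computed with
many runs settles near 0.78–0.79 rather than 0.81; the conclusion the
statistic supports (cRp² ≫ 0.5, no chance correlation) is unaffected.
Default n_runs = 100 — more stable than small batches at negligible cost —
with seed 0 as the package-wide default seed.

## External validation

r²test is the squared Pearson correlation between observed and predicted
test activities (0.71 on the packaged data).  The predictive variant

    Q²(F2) = 1 − Σ_test(obs−pred)² / Σ_test(obs − ȳ_train)²

is reported separately (0.53); the two are sometimes conflated in the
literature but answer different questions — correlation vs calibrated
accuracy relative to the naive train-mean predictor.  The
Golbraikh–Tropsha checklist contains exactly four conditions: Q²_LOO > 0.5,
r²test > 0.6, a through-origin closeness condition
((r²−r0²)/r² < 0.1 with 0.85 ≤ k ≤ 1.15, on either axis), and
|r0² − r0′²| < 0.3.

## Applicability domain

Leverage uses the intercept-augmented training design matrix (standard
Williams-plot practice): h = x̃ᵀ(X̃ᵀX̃)⁻¹x̃, threshold h\* = 3(d+1)/n.
Standardized residuals divide by √(SSE/(n−p−1)) — the same scale as the
fit RMSE; externally studentized variants are out of scope.  The residual
cut defaults to ±2σ, matching the reference analysis; conventional
Williams plots often use ±3σ, which is exposed via
`residual_sigma_mult` (compound 10d of the packaged set is an outlier
under either cut, at −3.4σ).  Train leverages satisfy Σh = d+1 and
h ∈ [1/n, 1]; leverage is invariant under invertible affine maps of the
descriptor columns — both asserted in the tests.

## Drug-likeness rules

Thresholds follow the SwissADME published definitions of the five rule
sets (Lipinski with a one-violation allowance, Veber, Egan, Muegge,
Ghose).  Properties are inputs, never computed from structures; any
condition whose input is absent is reported "not evaluable" and excluded
from the violation count rather than guessed.  The packaged property
table prints MW, LogP, HBA, HBD and TPSA only, so the Ghose verdicts —
which hinge on WLOGP — ship as stored expectations, and the engine's
consistency with them is checked by evaluating the rule at WLOGP values
on both sides of the 5.6 cut.  The bioavailability score implements the
Abbott decision rules: anions are binned by TPSA (0.85 / 0.56 / 0.11);
everything else scores 0.55 unless it has ≥ 2 rule-of-five violations
(0.17).

## Descriptor contributions

Raw coefficients are incomparable across descriptors with different units
(the largest raw coefficient in the chalcone model, 8.47 on BCUT_SMR_2,
multiplies a descriptor with SD 0.04).  Contributions are therefore
standardized coefficient magnitudes |aj|·sd(xj), normalized to sum to 1,
computed on the training subset; under this measure SlogP_VSA4 (a
van-der-Waals surface-area term tracking fluorination) dominates with
≈ 0.45 of the total.

## Synthetic data

The generator draws p correlated Gaussian descriptors (Cholesky of a
user-supplied correlation matrix, then scaled/shifted) and a linear
activity with Gaussian noise, split 80/20.  Defaults mirror the packaged
chalcone regime: n = 25, the four-descriptor correlation block and column
scales of the training set, the fitted coefficients as ground truth, and
noise SD 0.29 (the fit's residual SE).  Under these defaults the fitted
r² across 100 seeds spans ≈ 0.70–0.97 with median ≈ 0.88, and 95 %
coefficient confidence intervals cover the truth at nominal rate
(asserted over 200 seeds).  `generate_null` draws the activity i.i.d.
with the marginal mean and variance the structural model would produce,
independent of the descriptors — the chance-correlation regime, used to
verify E[null r²] ≈ p/(n−1) and predominantly negative null Q².

What the synthetic tests do *not* show: real descriptors are neither
Gaussian nor homoscedastic (SlogP_VSA4 in the chalcone set is nearly
discrete, taking three main levels), activities carry assay error with
structure, and descriptor selection upstream of the model induces
selection bias the generator does not emulate.  Passing synthetic checks
demonstrates correctness of the estimators, not validity of any
particular real-data model.

## Numerical notes and limitations

* All linear algebra is dense `numpy.linalg` (lstsq / inv); problem sizes
  are tens of rows, so conditioning, not speed, is the only concern.
  Rank deficiency is detected explicitly and reported with the collinear
  column names; near-duplicate columns surface as unbounded VIF before
  they reach the fitter.
* Missing cells are absent values, never zeros; every operation that
  needs a value raises naming the compound and descriptor.
* Determinism: every stochastic operation (splitting, Y-randomization,
  synthesis) takes an explicit integer seed and uses
  `numpy.random.default_rng`; equal seeds give bit-identical results.
* The packaged tables preserve their printed sources verbatim, including
  small mutual inconsistencies in the last decimal of some activities;
  loaders do not harmonise them, and tests anchor each statistic to the
  table it derives from.
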