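# Methods

This note documents the models implemented in `metscreen`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Trial model and balanced ANOVA

Per irrigation condition the plot-level model is

```
y_ijk = mu + a_i + b_ij + g_k + (ag)_ik + e_ijk
```

with `a` the year/location environment effect, `b` the block within
environment, `g` the genotype, `(ag)` the genotype-by-environment
interaction and `e` the plot residual. Year and location are confounded
by design in trials where locations change across years, so the package
exposes a single "year" factor representing both. The engine computes
classical balanced sums of squares by the containment recursion over
crossed/nested terms; on balanced data these equal sequential
regression-projection sums of squares in any term order, which is the
oracle the test-suite checks against (statsmodels type-I ANOVA).

Unbalanced or incomplete tables are rejected with the first missing
cell named. The expected-mean-square estimators downstream presuppose
balance; silently switching to an unbalanced approximation would change
their meaning.

F denominators default to the residual mean square for every source
(the fixed-effects GLM behaviour of the software this workflow
reproduces). `ModelSpec.per_condition(ems=True)` switches to the
random-model expected-mean-square tests (genotype against
genotype:year, year against block(year)).

Mean separation uses the LSD, `t(1-alpha/2, df_e) * sqrt(2 MS_e / r)`,
with compact letters assigned from maximal non-significant runs of the
sorted means. Duncan's multiple range test is deliberately not
implemented; LSD is the documented method of this workflow and the two
disagree only in how conservative the letter display is.

## Variance components and indices

The component estimators are implemented verbatim as the workflow
defines them (see README for the formula block). Two of them differ
from the textbook moment estimators:

* the genotypic component subtracts `MS_res` rather than `MS_gxy`, so
  its expectation is `s2_gn + s2_gxy / yr` rather than `s2_gn`;
* the "year" component has the unusual numerator
  `MS_blk(yr) - MS_gxy + s2_res`.

Both are kept because fidelity to the published estimator is the point;
a `genotype_formula="textbook"` flag provides
`(MS_gn - MS_gxy)/(blk*yr)` for users who want the unbiased version.
`formula_expectations` returns the analytic expectation of every
estimator under the model, so simulation recovery is checked against
what the estimators actually converge to, not against the raw planted
values. The recovery suite verifies these expectations independently
with sympy before using them.

Environmental variance is reported as `s2_pn - s2_gn` (which makes the
three reported variances additive) alongside the raw `s2_yr` formula
value; the two are not mutually consistent and which one a given report
used cannot generally be determined, so both are emitted.

Negative raw components are reported as-is and clipped to zero for
index computation (the common convention, keeping heritability in
[0, 100]). Heritability with a non-positive phenotypic variance, and
CVs at zero mean, return NaN with a warning rather than raising.

Two CV conventions coexist because practice does: `methods_sqrt` is the
standard `100*sqrt(s2)/mean`; `table_ratio` is `100*s2/mean`, the
convention that every printed index of the calibrating trial satisfies
(e.g. 47.06/305.1*100 = 15.43). `table_ratio` is the default so those
printed values reproduce; the flag records which scale a number is on.

## Stepwise feature selection

Regression units are genotype means across years and blocks. The
algorithm is SAS-semantics stepwise: enter the candidate with the
smallest partial-F p-value if `p <= SLE` (default 0.15), then remove
retained variables with `p > SLS` (default 0.15), repeat to a fixed
point with a visited-state guard against cycling. Partial R² at entry
is the residual-SS drop over the total corrected SS. Ties in F-to-enter
break by candidate column order (input file order). Zero-variance
candidates are dropped with a warning, numerically singular additions
skipped. Standardized coefficients are `b * sd(x) / sd(y)` with sample
standard deviations; for one predictor this is the Pearson correlation,
which bounds it to [-1, 1] — a published magnitude above 1 for a
single-predictor model is not reproducible under this definition and is
not matched.

"Planted-set recovery" in the tests and acceptance script means the
planted predictors are contained in the selected set. At SLE 0.15 a
handful of free entries among nine noise candidates is the expected
behaviour of the algorithm (the minimum of nine uniform p-values is
below 0.15 most of the time), so exact set equality would measure the
threshold, not the power. The ≥ 90 % recovery threshold was fixed from
a pilot run of the simulator before being frozen into the tests.

## Multivariate screening

Traits are z-scored column-wise (sample sd); constant columns are
dropped with a warning. Distances are Euclidean. Ward clustering
defaults to Ward.D2 (scipy's `ward` on Euclidean distances, the modern
ecosystem default); Ward.D — the classical criterion on squared
dissimilarities — is available via `variant="D"`. The dendrogram cut
defaults to k = 3 clusters, a parameter.

PCA is the eigendecomposition of the trait correlation matrix
(correlation mode, since traits have incommensurate units). Components
are ordered by decreasing eigenvalue and signed so each component's
largest-magnitude loading is positive, making outputs deterministic.
Scores are the standardized data on unit eigenvectors (distance
scaling); biplot loadings carry the sqrt-eigenvalue scaling.

The heatmap is reduced to its analysis content: rows and columns in
dendrogram leaf order and values binned into `n_bins` equal-width bins
over the global range. Rendering is cosmetic and excluded from tests.

Contrast-pair selection: (1) the pair maximizing inter-cluster
Euclidean distance, alternates being the same-cluster members of each
endpoint; (2) endpoints oriented and ranked by the projection of their
PC1/PC2 scores onto the mean loading direction of the target traits
(SOD and yield by default); (3) remaining ties break on the mean
z-scored target traits, then lexicographically on the genotype label.
With both conditions screened, the stress-condition result decides and
the normal-condition pick is recorded in the trace.

## Expression (ddCt)

`dCt = Ct_target - Ct_reference`; the control baseline per cell
(genotype, tissue, time, gene) is the mean dCt over the control pot's
replicate wells; `ddCt = dCt - baseline`; relative expression is
`base^(-ddCt)` with base 2 (the Livak convention, 100 % amplification
efficiency) — the base is a configuration knob since the underlying
transformation is only ever described as a proportion. Control wells
are assigned ddCt 0 and fold 1 by definition: they *are* the baseline.
The factorial ANOVA runs on folds by default; `response="ddct"`
analyses the log scale instead, which is the better-behaved choice when
fold noise is multiplicative (the fold scale is heteroscedastic across
cells with different means, and its interaction F is anti-conservative).

## Promoter scanning

Motifs are IUPAC consensus strings. Matching is positional over both
strands, overlaps allowed; a palindromic consensus (equal to its IUPAC
reverse complement) is counted once per position, not once per strand.
`N` in a sequence never matches; `N` in a motif matches any base. These
rules are fixed and stated because database semantics are undocumented.
The bundled 16-class dictionary contains curated PlantCARE-style
consensus strings and is an approximation for local scanning: counts
from live database versions (which carry many more site variants per
class) will differ, and published database-derived count tables are
therefore not reproduction targets. A PlantCARE-export ingestion path
(site/position/strand TSV plus a user-editable site-to-class map) is
provided as the alternative to scanning.

## Synthetic generators

`simulate_trial` draws all random effects as independent normals — the
standard variance-components model; distributional assumptions are
never stated in field reports, and normality is what makes the EMS
estimators' expectations exact, which the recovery tests rely on.
Cross-trait correlation is applied to genotype effects only (the
screening stages operate on genotype means); residual, year and block
effects are independent across traits — a documented simplification.
Grain yield is a linear combination of a trait subset plus white noise
at the plot level.

Default study conditions: 30 genotypes, 6 environments, 3 blocks, two
conditions, 11 traits. Per-trait genotypic/environmental variances and
means are calibrated to a published triticale panel; the environmental
variance is split across year / block(year) / GxE / residual in the
fixed ratio 1.5 / 0.25 / 0.6 / 1.0 (years dominate non-genetic spread,
blocks contribute least — chosen once as realistic magnitudes, not
fitted). The stress yield model is 4.66·SOD − 4.15·PRL − 8.44·GR around
a 305 mean; the normal model −27.79·Prtn around 741; plot-level yield
noise (3500 and 1700 units²) was set so the genotype-mean-level model
R² lands near 0.8–0.9, the regime of the calibrating trial. Yield units
are treated as opaque labels throughout (the calibrating sources mix
g/m² and kg/m²).

What the generator does *not* emulate: real trait distributions (skew,
bounded supports), genotype pedigree structure, spatial field trends,
missing plots, or measurement error correlated across traits within a
plot. Passing tests therefore demonstrate correctness of the estimators
and procedures under the stated model, not robustness to those field
realities.

`simulate_ct_table` plants fold changes as Ct shifts of `-log2(f)` with
i.i.d. normal well noise (default sd 0.2 cycles) and a stable reference
gene; one control pot with replicate wells per cell, mirroring the
destructive-sampling layout of the greenhouse assay.

`simulate_promoters` makes planted truth exact: backgrounds are drawn
from a fixed base composition, every chance dictionary match is
re-randomized away (iterative scrubbing), concretized motif instances
are planted at non-overlapping positions, and the finished sequence is
re-scanned — any discrepancy (e.g. a junction creating an accidental
site) rejects the sequence and retries. The emitted truth table
therefore equals a brute-force scan by construction; an infeasibly
dense composition raises a specification error.

## Numerical conventions

* Sums of squares are clipped to zero when within `1e-10` of the total
  SS scale; SS additivity and df accounting are asserted on every
  accepted input in the test-suite.
* PSD checks on correlation matrices tolerate eigenvalues down to
  `-1e-10`; factorization uses the eigendecomposition so singular PSD
  matrices are valid.
* All tabular pipeline output uses fixed column order and 6 significant
  digits so golden comparisons are platform-stable.
* Every generator consumes a single integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical
  outputs.

## Problem sizes

The Monte-Carlo suites use 200 replicates of the 30 × 6 × 3 single-trait
trial for component recovery, 60–100 replicates for stepwise planted-set
recovery, 500 small assays for Ct fold recovery, and 100 random
sequence/motif pairs for scanner-oracle agreement; these sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
while keeping the default test run in the tens of seconds.

## Known limitations

* No REML or unbalanced mixed-model estimation: balance is a hard
  requirement, by design.
* No narrow-sense heritability or response-to-selection prediction.
* No multiple-testing correction across traits (none is applied in the
  workflow being reproduced).
* The promoter dictionary is a curated approximation; absolute counts
  are only meaningful relative to the dictionary used.
* The command-line layer writes figures nowhere; plotting is left to
  the user's environment, the analysis artifacts are complete without
  it.
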