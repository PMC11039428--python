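# Methods

## Effect sizes

A record is one control-vs-alternative contrast of symbiont fitness
summarised by group means, dispersions and replicate counts. The effect
size is the percent change `pc = 100·(x̄_c − x̄_a)/x̄_c`, positive when
fitness is greater in the control condition (in symbiosis, ambient
environment, younger host). Records with a zero control mean are
rejected — a ratio effect size is undefined there and no continuity
correction is applied; negative means are flagged with a warning but
computed, since they indicate a data-entry problem rather than an
arithmetic one.

The sampling variance is the first-order delta-method variance of a
ratio of two independent means,
`var = 100²·r²·(SE_c²/x̄_c² + SE_a²/x̄_a²)` with `r = x̄_a/x̄_c`. The
test suite checks it against a 10⁶-draw Monte-Carlo simulation of the
two group means; agreement is within 5% whenever both coefficients of
variation are below ~0.2, the regime in which a first-order expansion is
trustworthy. Dispersions default to standard deviations
(`SE = sd/√n`); records reporting standard errors must say so via
`dispersion_kind="se"`, because silently misreading one for the other
scales variances by n.

Both the effect and its variance are then cube-root transformed with the
sign preserved (`sign(x)·|x|^(1/3)`), which compresses the extremely
large percent changes that ratio effect sizes produce while keeping
direction. Cube-rooting a *variance* is unconventional — the transformed
v is no longer the delta-method variance of the transformed y — but it
is the definition this pipeline standardises on; a `variance_mode="delta"`
option instead propagates the variance of the cube-rooted effect
(`v' = var/(9·|pc|^{4/3})`, guarded near pc = 0) for sensitivity
analysis. The default remains the literal cube root.

## Phylogenetic correlation

Trees are newick files with branch lengths (missing lengths are an error
unless an imputation constant is given). Three editing operations
prepare a source tree for analysis:

- **tip substitution** — a species absent from the source tree is
  represented by its closest available relative: the stand-in tip is
  relabelled, leaving topology and lengths untouched;
- **population expansion** — a species contributing k effect sizes
  becomes a polytomy of k population tips on pendant branches of ε/2
  (default ε = 10⁻⁶, constrained to < 10⁻⁵), so within-species
  correlations are ~1 yet every record maps to its own tip and the
  matrix stays numerically nonsingular;
- **pruning** — the induced subtree on the analysed species, with unary
  nodes suppressed and their lengths summed, preserving pairwise tip
  distances exactly.

Under Brownian motion the covariance of two tips is the depth of their
most recent common ancestor (shared root-to-tip path length, including a
root edge if present); dividing by `√(C_ii·C_jj)` gives the correlation.
The normalisation handles non-ultrametric trees — source trees are not
guaranteed ultrametric — and polytomies need no resolution since only
shared path lengths enter. Correlation matrices are validated on
construction (symmetry, unit diagonal, entries in [0, 1], PSD up to
10⁻⁸) and can be ridge-regularised (`with_ridge`) if a downstream solve
reports near-singularity; the default adds nothing.

## The multilevel model and REML

With y the transformed effects and v their known variances, the marginal
covariance is

```
M(σ²) = diag(v) + σ²_study·S + σ²_within·I + σ²_phylo·Z R Z',
```

S the same-study indicator and Z the record-to-tip incidence. The
restricted log-likelihood

```
ℓ_R = −½ [ log|M| + log|X'M⁻¹X| + y'Py + (n−p)·log 2π ],
P = M⁻¹ − M⁻¹X(X'M⁻¹X)⁻¹X'M⁻¹
```

is maximised over the non-negative components by L-BFGS-B with the
analytic gradient `∂ℓ/∂σ²_k = −½[tr(P G_k) − y'P G_k P y]`, from three
starting points (all zero; a method-of-moments split assigning the
residual excess variance to the record level; an equal split), keeping
the best optimum. Convergence requires optimizer success plus interior
gradient components below 10⁻⁴·(1+|ℓ|); active bounds are reported, not
hidden. Fixed effects and their covariance follow by GLS at the optimum.
Sampling variances of exactly zero are floored at 10⁻¹⁰ with a warning
(they arise from degenerate source data and break the solve).

Moderator designs keep the intercept and code a k-level factor as k−1
dummies against the alphabetically first level — the omnibus QM test
(`β_B'·cov(β_B)⁻¹·β_B` against χ²_{k−1}) is invariant to that choice,
though per-level z values are not. Continuous moderators enter centered
with df = 1. Per-coefficient tests use two-sided normal p-values; no
small-sample t/F correction is applied. The implementation is
cross-checked in the test suite against an independent REML fitter of
the same model class (R metafor's `rma.mv`, whose restricted likelihood
differs by a known `+½log|X'X|` constant): fixed effects and components
agree to ~10⁻⁴ on a three-component moderator fit.

## Influence screening

Cook's distance for record i is
`D_i = (β_{(−i)} − β)' cov(β)⁻¹ (β_{(−i)} − β)` with the full-data
covariance. By default the variance components are re-optimised for each
deletion (warm-started from the full-data optimum); a fixed-components
mode recomputes only the GLS fixed effects, which matches the full
refit closely and is used for large simulation batteries. Records with
D strictly greater than 3× the mean D (the candidate included in the
mean) are removed in a single pass — the rule is a sensitivity analysis,
not an iterated trimming — and every report carries the all-records and
outliers-removed fits side by side. If a deletion empties a moderator
level, that record's D is computed on the reduced design over the shared
coefficients, with a warning.

## Pipeline conventions

Analyses (host association, environment, time, and the intracellular
subset of environment) are independent runs over their record subsets;
no cross-analysis multiplicity correction is applied. Moderator
batteries skip moderators with fewer than two observed levels in a
subset (logged) rather than aborting. Aggregation to one record per
symbiont (or per host–symbiont pairing) uses the mean transformed effect
with variance `mean(v)/k` — the variance of a mean of independent
effects — with plain `mean(v)` as a config alternative; a continuous
moderator that varies within an aggregation group is an error, forcing
an explicit per-group covariate rather than a silent average. Either
phylogeny (symbiont by default, host by flag) can supply the random
effect; swapping trees never changes the record set. Reports embed input
hashes and the full configuration and are byte-identical across reruns
of the same inputs.

## Synthetic data generator

The generator draws exactly the structure the model assumes: study
effects `N(0, σ²_study)`, record effects `N(0, σ²_within)`, tip effects
`MVN(0, σ²_phylo·R)` from the Brownian correlation of a simulated
pure-birth tree (exponential waiting times, rescaled to unit depth),
sampling errors `N(0, v_i)` with v_i uniform on a stated range, plus
optional categorical level shifts and continuous slopes. Each record is
also back-transformed into raw two-group summaries (control mean fixed
at 100, alternative mean `100 − pc`, the relative variance split evenly
between groups, n = 10 per group) whose percent change and delta-method
variance reproduce (y, v) exactly, so the effect-size stage can be
exercised end to end; records with pc ≥ 100 cannot be realised with
positive means and are emitted on the transformed scale only, flagged
(`raw_feasible = False`), mirroring how ratio effect sizes saturate at
+100%. A single numpy Generator stream keyed by the seed makes every
table and tree reproducible.

Defaults emulate a mid-sized experimental corpus: 50 studies
contributing 1 + Poisson(1.4) effect sizes (~120 records), 40 taxa,
components (σ²_study, σ²_within, σ²_phylo) = (1, 0.5, 1) on the
cube-root-percent scale (transformed effects of typical magnitude a few
units), sampling variances uniform on [0.2, 1] — heterogeneity dominated
by between-study and phylogenetic structure, as multi-system corpora
tend to be. The generator does not emulate taxonomic composition of any
real corpus, correlated moderators, publication bias, or non-normal
errors, so passing recovery tests demonstrate correctness of the
estimator under its own assumptions, not robustness to their violation.

## Verification scale and test design

The test suite runs entirely on synthetic data in a few minutes: the QM
type-I suite uses 1000 replicates of a reduced corpus (20 studies,
~50 records, a null 3-level moderator, no phylogenetic component, which
the null does not need) and checks the 0.05-level rejection rate within
99% binomial bounds; power and level checks of the full pipeline use 100
replicates at 15 studies. Parameter recovery is evaluated at 80 studies
× ~5 effects × 60 taxa against a 30% band on variance components.
Because a single replicate's phylogenetic-component estimate has ~27%
relative sampling error at that size (one tree is one draw of shared
history), the recovery check compares the *mean* estimate over five
seeded replicates: with Monte-Carlo error controlled, the band tests
estimator bias rather than replicate luck. Single-replicate scatter is
shown in `examples/simulate_and_recover.py`.

## Known limitations

- The literal cube-root of the variance is a modelling convention, not a
  delta-method propagation; the alternative mode exists for sensitivity
  checks and the two can disagree materially for |pc| near zero.
- REML with three components on flat likelihoods can sit on a boundary
  (a component estimated at exactly 0); multi-start plus the gradient
  report makes this visible but cannot manufacture information the data
  lack.
- Cook's distances with per-deletion re-optimisation cost one REML fit
  per record; the fixed-components mode is the practical choice above a
  few hundred records.
- Wald z and χ² QM tests are asymptotic; at very small study counts they
  run slightly liberal (visible in the type-I suite's upper tail), and
  no Knapp–Hartung-style correction is provided.
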