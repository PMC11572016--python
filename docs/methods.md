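# Methods

## The model

`collidersim` simulates a randomized two-arm preclinical experiment — the
motivating setting is middle cerebral artery occlusion (MCAO) stroke
surgery in rats — in which animals can be lost before outcome assessment
and the loss is informative. Five variables describe each animal:

| symbol | meaning | units |
|---|---|---|
| `A` | treatment arm (1 treated, 0 control) | binary |
| `L` | initial infarct volume | mm³ |
| `W` | welfare score (lower = worse) | arbitrary |
| `Y` | final infarct volume | mm³ |
| `S` | survived to outcome assessment | binary |

The structural equations are linear with independent Gaussian errors:

    L ~ Normal(mu_L, sigma_L)
    W = gamma0 + gamma1·A + gamma2·L + eps_W,   eps_W ~ Normal(0, sigma_W)
    Y = beta0  + beta1·A  + beta2·L  + eps_Y,   eps_Y ~ Normal(0, sigma_Y)

Default parameters: `mu_L = 25`, `sigma_L = 5` (an early infarct size
detectable by in-vivo imaging after reperfusion), `beta0 = 0` (no final
infarct without an initial one), `beta2 = 8` (so the mean final volume is
`8 × 25 = 200` mm³, a typical absolute infarct volume for a rat stroke
model), `sigma_Y = 10`, `gamma0 = 0`, `gamma2 = −1` (larger strokes mean
worse welfare), `sigma_W = 2`. The treatment effect on the outcome is
null by construction, `beta1 = 0`: any non-zero estimate is bias. The
treatment side effect on welfare `gamma1` takes the values −1, −3, −6
("minor" / "moderate" / "major").

Attrition is deterministic given welfare: within each simulated dataset,
every animal whose welfare lies strictly below the empirical
`q`-th percentile of all welfare scores is censored (`S = 0`), with
`q ∈ {0.10, 0.25, 0.50}` ("low" / "moderate" / "high" attrition),
spanning the attrition frequencies reported for in-vivo stroke research.

In graph terms `W` is a collider on `A → W ← L → Y`. Restricting the
analysis to survivors conditions on `S`, a child of `W`, which opens this
non-causal path: among survivors, treated animals are selectively the
ones with smaller initial infarcts, and since `Y` grows with `L`, the
complete-case contrast is biased in favor of the treatment even though
the treatment does nothing. Adjusting for `L` closes the path again.

## Estimators

Per replication three estimates of the treatment effect are computed
(negative = apparently beneficial):

* **oracle** — `mean(Y | A=1) − mean(Y | A=0)` over all animals,
  including the censored ones. Unobservable in practice; the unbiased
  benchmark.
* **naive** — the same contrast among survivors (`S = 1`). Missing when
  an arm has no survivors.
* **adjusted** — the `A`-coefficient of OLS `Y ~ 1 + A + L` among
  survivors. Because all structural relations are linear, this
  `L`-conditional effect equals the marginal one, so it is directly
  comparable to the oracle. Missing when fewer than three animals
  survive, an arm is empty, or the survivor design matrix is rank
  deficient (`L` constant within arms — measure-zero under the model but
  guarded, since it occurs in degenerate zero-noise configurations).

Missing estimates are excluded per approach from the across-replication
mean and percentiles and are counted separately; a joint-exclusion mode
is deliberately not the default.

The OLS is solved by orthogonal decomposition, never by forming normal
equations: the scalar path uses `numpy.linalg.lstsq`, the vectorized grid
path a stacked QR factorization in which non-survivor rows of the design
matrix and response are zeroed (a zero row contributes zero residual for
any coefficient vector, so the solution over the survivor subset is
unchanged). Tests require agreement with a normal-equations solve to
1e-10 relative tolerance on random cohorts.

## The scenario grid

The standard grid crosses `n_total ∈ {10, 20, 50}` (equal arms of 5, 10,
25), severity `{minor, moderate, major}` and attrition `{10%, 25%, 50%}`
— 27 scenarios, 10,000 replications each, summarized per approach by the
mean and the 2.5th/97.5th percentiles of the non-missing estimates.
Canonical ordering is `n` ascending, then attrition ascending, then
severity minor → major.

**Randomness.** One root seed per run. Scenario `i` (canonical index)
draws from `SeedSequence(root_seed, spawn_key=(i,))`, so results are
invariant to execution order and worker count, and any single scenario
rerun standalone reproduces its grid row bit for bit. Two runs with the
same root seed produce byte-identical tables.

**Allocation.** Treatment is randomized by design; because all
estimators are exchangeable in animal order, cohorts are laid out
deterministically as first-half control / second-half treated, which
guarantees exactly equal arm sizes in every replication.

## Quantile and censoring conventions

Both the censoring threshold and the summary percentiles use the
linear-interpolation sample quantile at index `h = (n−1)q + 1` (R's
default, type 7), and censoring is *strictly below* the threshold. For
continuous welfare the censored count is therefore deterministic:
`floor(h)`, or `h − 1` when `h` is an integer. Two consequences worth
knowing:

* realized attrition can deviate from nominal at small `n`: at
  `n = 10, q = 0.25` exactly 3 animals (30%) are censored, and at
  `n = 50, q = 0.25` exactly 13 (26%); the 10% and 50% levels on the
  grid sizes have no such offset;
* as `q → 0+` the interpolated quantile stays above the sample minimum,
  so the minimal censored count is 1, not 0.

Welfare ties at the threshold are impossible under the continuous model
but can occur with zero noise scales; the generator then censors the
`floor(h)` lowest scores by stable rank and emits a warning.

## Analytic arm-specific attrition

Under balanced allocation, welfare in arm `a` is
`Normal(gamma0 + gamma1·a + gamma2·mu_L, s)` with
`s = sqrt(gamma2²·sigma_L² + sigma_W²)` (`= sqrt(29) ≈ 5.39` at the
defaults). The population analogue of within-dataset percentile
censoring is the `q`-quantile of the equal 50/50 mixture of the two arm
distributions: the cutoff `t` solves `(F0(t) + F1(t))/2 = q`, found by
bracketed Brent root search (absolute tolerance 1e-12, bracket ±10
mixture SDs around the pooled mean, widened by the arm-mean gap). Each
arm's attrition probability is its CDF at `t`; the two average back to
`q` by construction. With major side effects at 10% total attrition this
yields 18% treated / 2% control — a nine-fold asymmetry invisible in the
pooled rate. Rounding for the integer table is half away from zero.

## DAG engine

`Dag` is a thin validated wrapper over a `networkx.DiGraph` (acyclicity,
declared endpoints, no self-loops or duplicates, rollback on violating
insertions). `d_separated` enumerates all simple undirected paths between
the query nodes and applies the standard blocking rules (chain/fork
blocked iff its middle node is conditioned on; collider blocked iff
neither it nor any descendant is). Enumeration is exponential in the
worst case; that is acceptable because the graphs of interest have five
to seven nodes, and it buys something reachability algorithms do not
give: the open paths themselves, returned as witnesses. Tests verify
exact agreement with two independent oracles (a moralized-ancestral-graph
reachability check written in the test, and `networkx.is_d_separator`)
over random DAGs of up to 7 nodes.

`diagnose_selection` conditions on the selection node plus the adjustment
set and reports bias iff some open path is *non-causal*, i.e. not a
directed exposure→outcome route — the direct effect and mediated chains
are the estimand, not bias.

Empirical counterparts: `empirical_association` computes sample partial
correlations by linear residualization, with the large-sample standard
error `1/sqrt(n − k − 3)`. Conditioning on survival is done by
restriction to `S = 1` (matching how a complete-case analysis actually
conditions), not by partialling on the binary indicator.

## What the generator does and does not emulate

The synthetic cohorts reproduce the stated generative model exactly:
balanced arms, Gaussian initial volumes, linear welfare and outcome
equations, deterministic percentile censoring. They deliberately do not
model non-linear infarct growth, longitudinal welfare trajectories,
measurement error in `L`, treatment-effect heterogeneity, or correlated
errors. Passing tests therefore demonstrate the collider-stratification
mechanism and the estimators' behavior *under this model*; the magnitude
and even direction of the bias in any real animal model depend on its own
parameters and functional forms. `L` is kept as drawn even when negative
(probability ≈ 3e-7 at the defaults) to match the stated model exactly.

## Statistical calibration of the checks

Stochastic checks compare Monte Carlo means. The standard error of a
cell mean is estimated from the run itself (`sd/√reps`); comparisons
against the published cell values additionally inflate by √2 because the
reference numbers come from an equally noisy independent 10,000-rep run.
Where *every* cell of the grid is checked simultaneously (54 near-null
means, 27 naive means), the per-cell threshold is Bonferroni-split so the
family-wise error stays at the 3-sigma level (≈0.27%); a per-cell
3-sigma band applied to 54 independent cells would falsely reject a
correct implementation about 13% of the time. Anchor-cell checks keep
plain 3-SE bands, and the near-null adjusted mean uses a fixed ±0.3 mm³
band. Root seed 0 is fixed for the test suite.

At 500,000 replications per cell the simulated naive means agree with
the published anchor values to within 0.07 mm³, confirming that the
generative conventions (including the type-7 censoring quantile) match
the original study; at 10,000 replications individual runs scatter
around those values with SE 0.1–0.35 mm³.

## Problem sizes

The default grid (27 × 10,000, n ≤ 50) runs in a couple of seconds on
one CPU because replications are generated and estimated as stacked
arrays (one QR per grid cell, batched over replications). The
large-sample empirical checks pool 10⁵–10⁶ animals.

## Known limitations

* The naive bias under *within-dataset* percentile censoring is an
  order-statistics functional with no closed form here; it is quantified
  by simulation only. The analytic module covers the population-threshold
  limit, which the empirical rates approach as `n` grows.
* `diagnose_selection` checks validity of a given adjustment set; it does
  not enumerate or minimize adjustment sets.
* No g-methods, inverse-probability weighting, or separable-effects
  estimands; the adjusted approach's validity as a *marginal* effect
  estimate rests on linearity.
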