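# collidersim

Collider stratification bias from animal attrition in preclinical
experiments: simulate it, quantify it, diagnose it, and fix it.

## The problem

In a randomized animal experiment — the motivating case is stroke
surgery (MCAO) in rats — animals are sometimes lost before the outcome
is measured: they die, or are euthanized because their welfare
deteriorates. If the treatment has negative side effects on welfare, and
disease severity also degrades welfare, then analyzing only the
survivors silently conditions on a *collider*: welfare `W` sits on the
path `A → W ← L → Y`, where `A` is the treatment, `L` the initial
infarct volume and `Y` the final infarct volume. Restricting to
survivors (`S = 1`, a child of `W`) opens that non-causal path — among
survivors, treated animals are selectively the milder cases — so the
complete-case contrast looks beneficial **even when the treatment does
nothing**. Randomization does not protect against this: the selection
happens after randomization, and more animals do not help, because the
error is systematic.

`collidersim` is for preclinical researchers and methodologists who want
to understand, teach or quantify this mechanism. It implements:

* a linear-Gaussian structural causal model of the experiment
  (`Y = β0 + β1·A + β2·L + εY`, `W = γ0 + γ1·A + γ2·L + εW`,
  `L ~ N(25, 5)` mm³, null effect `β1 = 0`), with deterministic
  welfare-percentile censoring;
* three estimators per experiment: **oracle** (all animals — the
  unobservable benchmark), **naive** (survivors only) and **adjusted**
  (OLS `Y ~ 1 + A + L` among survivors, which closes the open path);
* a 27-scenario Monte Carlo grid (n ∈ {10, 20, 50} × side-effect
  severity γ1 ∈ {−1, −3, −6} × attrition ∈ {10%, 25%, 50%}), 10,000
  replications per cell;
* closed-form arm-specific attrition probabilities from the
  mixture-of-Gaussians welfare distribution;
* a DAG engine with d-separation (witness paths included) and empirical
  partial-correlation checks on the simulated data.

See `docs/methods.md` for the full model and conventions.

## Worked example

The worst grid cell — 50 animals, major side effects (γ1 = −6), 50%
attrition — with the true effect fixed at zero:

```python
import collidersim as cs

scenario = cs.Scenario(n_total=50, gamma1=-6.0, attrition_q=0.50)
summary = cs.run_scenario(scenario, reps=10_000, rng=cs.scenario_rng(42, 0))
for name in ("oracle", "naive", "adjusted"):
    a = getattr(summary, name)
    print(f"{name:8s} {a.mean:6.1f}  ({a.p2_5:.1f}, {a.p97_5:.1f})")
```

```
oracle     -0.1  (-22.5, 22.9)
naive     -25.7  (-50.9, -0.7)
adjusted    0.0  (-9.7, 9.8)
```

The oracle mean is zero, as it must be. The naive (complete-case) mean
is −25.7 mm³ — a large, apparently beneficial effect that is pure
selection bias; its entire 95% range is below zero, so nearly every
single simulated experiment "finds" the effect. Adjusting for the
initial infarct volume restores an unbiased estimate (0.0 mm³) and is
even tighter than the oracle, because it exploits the outcome's
dependence on `L`.

Why the naive contrast breaks is visible in the attrition itself:

```python
att = cs.population_attrition(cs.default_params(-6.0), 0.10)
print(att.rounded_percent())   # (18, 2)
```

At 10% *total* attrition with major side effects, 18% of treated but
only 2% of control animals are lost — survival itself carries treatment
information. And structurally:

```python
dag = cs.build_study_dag()
print(cs.d_separated(dag, "A", "Y", set()).separated)   # True  — no bias
v = cs.d_separated(dag, "A", "Y", {"S"})
print(v.separated, v.witness_paths)  # False (('A', 'W', 'L', 'Y'),)
print(cs.d_separated(dag, "A", "Y", {"S", "L"}).separated)  # True — fixed
```

The same is available from the shell:

```bash
collidersim simulate --n 50 --severity major --attrition 0.5 --reps 10000 --seed 42 --out table.csv
collidersim attrition-table
collidersim dag --exposure A --outcome Y --condition S
collidersim demo --out cohort.csv
```

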