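# Methods

This document records the mathematical content of each module and the
numerical choices behind it.

## 1. The odds-ratio identity

A normal tissue holds `N0` wild-type stem cells; a focal mutation `z`
arises at per-cell rate `v` and mutant cells follow a linear birth–death
process with division rate `a1` and loss rate `b1` (selective effect
`s = a1 − b1`).  Wild-type cells initiate cancer at baseline rate `r0(t)`
and mutant cells at `r1(t) = w·r0(t)`; `w` is the carcinogenic effect.

Writing `x` for the mutant cell fraction in normal tissue at age `T` and
`y` for the probability that a cancer arising at `T` was founded by a
mutant cell, the identity

```
w = [y/(1−y)] / [x/(1−x)]
```

holds for every `s`, because selection scales the mutant pool — and hence
both odds — by the same factor.  Its inverse,
`y = w·x / (1 − x + w·x)` (`founder_frequency`), drives the synthetic
generators.

## 2. Backward Kolmogorov solver (`branching_process`)

Let `p_k(t, T)` be the probability that no **mutant-founded** cancer
occurs in `(t, T)` given `N1(t) = k` mutant cells.  The backward system is

```
dp0/dt = −N0·v·(p1 − p0)
dp1/dt = (N0·v + a1 + b1 + r1)·p1 − (N0·v + a1)·p1²/p0 − b1·p0
```

with terminal condition `p_k(T,T) = 1`.  The closure `p2 = p1²/p0`
follows from the branching structure: mutant families are independent
conditional on the shared influx background, so `p_k = p0·(p1/p0)^k`.
(A bare `p1²` closure is dimensionally plausible but introduces a
spurious mode growing like `exp(√(N0·v·b1)·t)` in the differentiated
system; with the correct closure the solver matches the closed forms
below to ≤3·10⁻⁴ relative at `dt = 10⁻³`.)

Differentiating in the horizon `T` (`q_k = ∂p_k/∂T`) gives a linear
system solved alongside; `−q0(0,T)` is the age-`T` density of the first
mutant-founded cancer.  The odds a cancer at age `T` carries `z` is
`[−q0/p0] / (N0·r0(T))`; the odds a normal cell carries `z`
(conditional on no cancer) is `[−q0/r1(T)] / (N0·p0)`; their ratio is
exactly `w`, which the solver reproduces to machine precision
(acceptance criterion 1).

Numerics: explicit Euler, backward in `t`, vectorised over `(T, hazard
component)` columns; a guard raises `StepSizeError` if any probability
leaves `[0, 1]`.  Richardson halving of `dt` is used in tests to confirm
discretisation error is far below the stated tolerances.

**Closed forms used as oracles.**  `E N1(T) = N0·v·T` when `s = 0` and
`N0·v·(e^{sT} − 1)/s` otherwise; the Gillespie simulator
(`simulate_trajectories`) provides an exact stochastic oracle for both
the mutant-count trajectory and the founder identity of cancers.

**Cancer-age densities.**  With `S_wt(T) = exp(−N0 ∫₀ᵀ r0)` the survival
against wild-type-founded cancer, the total cancer-age density is
`S_wt·(N0·r0·p0 + (−q0))` and the mutant-founder share is `S_wt·(−q0)`;
integrating both over age yields `P(cancer)` and `P(mutant | cancer)`,
verified against 10⁵ Gillespie trajectories (criterion 2).

**Baseline hazard.**  `r0(t) = 10^u · t^p` with `p = 3` and, in the
population mixture, `u` uniform on `(−16, −13)` integrated by 64-node
midpoint quadrature.  These are the parameters used for the age-profile
figures and the odds-identity grid.

**Growth-curve nulls.**  The null hypothesis of "selection without
causation" for solid-tissue-like dynamics is expressed by deterministic
clone-growth curves (exponential, Gompertz, logistic, polynomial); under
each, a selected neutral mutation's cancers are older than the neutral
reference (positive age shift, CDF dominance), whereas pure causation
(`s = 0`, `w ≫ 1`) produces a slightly *negative* shift via depletion of
at-risk carriers (criterion 4).

## 3. Carcinogenic-effect estimators (`carcino_effect`)

- **Matched odds ratio** (`estimate_matched`): `ŷ` from the cancer
  cohort's gene frequency, `x̂` from normal-tissue cell fractions, `ŵ`
  their odds ratio; percentile bootstrap over samples (donor-level in the
  normal arm) gives the CI.  An optional Haldane pseudo-count handles
  zero cells.
- **Length benchmark** (`estimate_length_benchmark`): `ŵ ∝ f/(1−f)/L`
  with Clopper–Pearson intervals — a scale-free comparator when no
  normal-tissue arm exists.
- **Hybrid Bernoulli/Beta regression** (`fit_hybrid_beta`): cancers
  contribute Bernoulli terms `P(mutated) = w/(w + e^{a+bt})`; normal
  fractions contribute Beta densities with mean `1/(1 + e^{a+bt})` and
  precision `e^φ`, with left-censoring at the detection floor `x0`
  handled by the Beta CDF.  Multi-start L-BFGS-B maximisation; Wald CI on
  `log w`.
- **Logistic colony model** (`fit_logistic_effect`): with single-cell
  colony data in both arms,
  `P(mutated) = w^χ / (w^χ + e^{a + b·t + c·m})` is an ordinary logistic
  regression in which `log w` is the coefficient of the cancer indicator
  `χ`; the CI is profile likelihood at the `χ²₁(0.95)/2` drop.  Complete
  separation is flagged with a warning and infinite endpoints.  Note the
  normal-tissue units must be Bernoulli colonies — thresholding
  continuous bulk fractions breaks the likelihood and badly biases `w`.

All three recover planted `w ∈ {1, 10, 100}` at `n = 2000` with ~95%
coverage and <25% median relative error (criterion 6).

## 4. Age statistics (`age_stats`)

Per-gene mutation-weighted mean ages (optionally cluster-robust on
samples); an age-divergence ratio (between-gene variance of mean ages
over cohort age variance) with a Kruskal–Wallis p-value; and the
permutation test of the no-carcinogenicity age prediction: the statistic
is the gene's functional-mutation mean age minus the exome-wide
synonymous mean age, the null permutes patient ages among samples with
mutation assignments fixed, and p-values are two-sided with BH q-values
across genes.  The null is computed for all genes and permutations in a
single matrix product, which keeps 1000-cohort calibration runs cheap;
calibration at `n_perm = 200` is `2·5/201 ≈ 0.0498` by the discreteness
of attainable p-values (criterion 5).

Rank-biserial age biases (`r = 2U/(n₁n₂) − 1`, midrank ties) compare SCNA
against SNV/indel disruption of the same gene, excluding co-occurring
samples; the implementation is exact against brute-force pair enumeration
(criterion 8).

## 5. Multi-hit model (`multihit`)

Lineages acquire mutations as a rate-`v` Poisson process; each mutation
multiplies the transformation hazard by an independent
`Gamma(shape, rate)` effect.  Between arrivals the hazard is constant,
so transformation times are sampled exactly by competing exponentials —
no time discretisation anywhere.

At the printed parameters (`v = 0.005`, `r_base = 10⁻⁹`, `Gamma(2,1)`,
lifespan 80) transformation is a ~10⁻⁷-per-lifetime event, so direct
simulation observes no cancers.  Two complementary tools handle this:

- `expected_incidence` integrates each lineage's hazard path per age bin,
  removing the shot noise of rare events (the incidence curve is then
  cleanly monotone with 10⁵ lineages — criterion 7, prediction IV).
- `conditional_cancer_table` samples the per-cancer law exactly in the
  rare-event limit, where the tilt factorises: cancer age has density
  ∝ `exp(v(μ−1)t)` with `μ` the mean effect, driver count is
  `Poisson(μ·v·t)` given age, and effects are i.i.d. size-biased
  (`Gamma(shape+1, rate)`).  `conditional_cancer_table_from_outcomes`
  cross-checks this against importance-resampled simulation.

The model's qualitative predictions: driver count rises with age
(Spearman ≈ +0.34); the mean log effect falls weakly with driver count
(≈ −0.03) and with age (≈ −0.004) — the last two are small enough that
~10⁶ conditional draws are needed to resolve their sign; cancers carry
roughly twice the age-matched normal-tissue driver count (`μ·v·t` vs
`v·t`).

## 6. Cohort I/O and cell fractions

TSV dialects with strict validation (sample/mutation column contracts,
mutation-class vocabulary, age and sex checks).  Deterministic rules:
VAF→fraction conversion is `2·VAF` on diploid autosomes (capped by using
`VAF` itself when `2·VAF > 1`, the loss-of-heterozygosity case), `VAF`
on male X; per-gene per-sample fractions combine as sum-or-max (sum when
≤1, else max — mutations in the same cells); burden filters cut at
`factor ×` the lower-median burden; donors contributing identical
variants to both cohorts are excluded (shared-clone contamination).
These rules are pinned by hand-computed fixtures (criterion 9).

## 7. Problem sizes and runtimes

The full test suite (`python -m pytest -o addopts= -p no:cacheprovider
-q tests/`) runs in ~10 minutes on one CPU; the acceptance script
(`python scripts/acceptance.py --seed <s> --out <f>`) in ~3 minutes.
Monte-Carlo scales in tests are chosen so that each statistical assertion
holds with ≥3-SE margins at the stated seeds, and all simulation
tolerances are stated in SE units rather than tuned constants.
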