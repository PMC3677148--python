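# Methods

This note documents the models, the defaults and their rationale, the
numerical choices, and what the synthetic cohorts can and cannot show.

## Stimulus construction

Each arithmetic or memory problem embeds its correct outcome c in a
nine-value series `round(c · 2^(i/4))`, i = −4…+4 — geometrically spaced
candidates from half to double the outcome. Rounding is
half-away-from-zero (12.5 → 13); this is the one tie rule consistent with
the published 25-series, and the 19-series' smallest candidate
(19/2 = 9.5) is the known cell where no single rule can match every
printed value. When integer rounding creates duplicate candidates (only
the 6-series among the session's outcomes), one occurrence of the
smallest duplicated value is decremented by 1 and the list re-scanned
until all values are distinct.

Six of the nine values are shown per trial: positions 1–6 ("low" range,
correct value fifth-smallest) or positions 4–9 ("high" range, correct
value second-smallest). The two ranges share the three middle values.
The 44-trial test session crosses each of the 11 problems (4 addition,
4 subtraction, 3 memory) with range {low, high} × area-control mode
{fixed total area, fixed dot size}; the factorial crossing is an
assumption — only the totals (16/16/12) are fixed by the design. The
cueing session has 40 valid / 10 invalid / 10 neutral trials with target
sides 50/50 and SOAs 200/800 ms balanced within each validity class
(cell counts 3/2/2/3 inside the 10-trial classes, since 10 is not
divisible by 4). Dot arrays are placed by uniform rejection sampling in
a 400×400 abstract-pixel field with a 2-px minimum gap; in
fixed-total-area mode every radius is √(A/(nπ)) with A = 12000 px², in
fixed-dot-size mode every radius is 7 px. Arrays exist as coordinate
lists only; no rendering or animation is modeled.

## Generative observer

The choice model is deliberately parameter-free beyond (w, β_op, lapse):
the internal estimate `X = exp(ln c + β_op ln10 + w Z)` is mapped to the
nearest displayed alternative on the log scale, ties to the smaller
value. A nearest-alternative rule (rather than a softmax) makes the
zero-noise case exactly verifiable and leaves Weber-law behavior fully
determined by w: with unconstrained alternatives the CV of choices is
√(exp(w²) − 1), ≈ 0.201 at w = 0.2. Biases enter additively in log
space, i.e. multiplicatively on the linear scale, matching the log-scale
bias statistic used throughout. Reaction times are log-normal with
additive condition effects applied after exponentiation (a shifted
normal could go negative); the orienting benefit is subtracted on valid
trials and the reorienting cost added on invalid ones.

Two consequences of this model are worth knowing when reading test
output. First, because the smallest (largest) displayed alternative
absorbs the entire lower (upper) estimate tail, the modal choice rank
sits at the correct value's rank only for sufficiently precise
observers: analytically, above w ≈ 0.19 the high-range mode shifts from
rank 2 to rank 1 (and the low-range mode can shift from rank 5 to 6) —
the same below-correct modal shift that high-range choice distributions
show empirically. The rank-peak checks therefore use a w = 0.15
observer. Second, the six-alternative truncation attenuates measured
biases relative to the generating β by roughly a third.

## Cohort defaults

| parameter | adults | children | units / why |
|---|---|---|---|
| β_add, β_sub means | +0.02, −0.05 | 0.00, +0.03 | log10; regular vs inverse momentum, calibration choices (not estimates) |
| between-subject bias SD | 0.05 | 0.08 | log10; children noisier (heteroscedasticity) |
| Weber fraction w (mean ± SD) | 0.15 ± 0.03 | 0.25 ± 0.05 | log-scale SD; adult ANS precision exceeds children's |
| lapse | 0.01 | 0.05 | keeps rank distributions non-degenerate |
| RT base, noise | ln 700 ms, 0.20 | same | log-normal RTs |
| orienting, reorienting (mean ± SD) | 30 ± 12, 60 ± 25 | same | ms; cost ≈ 2 × benefit |
| cueing error rate | 0.02 | 0.02 | calibrated to the observed 2% error total |
| ρ(OM, reorienting cost) | 0 | −0.6 | see below |
| n per group | 32 | 32 | study scale |

These standardized group contrasts land near the published posterior
means (≈ +0.23/−0.51 adults, −0.03/+0.32 children after pooling); they
are generator calibrations, never estimates of any real cohort — no
subject-level generative model exists for the original data.

`rho_om_reorient` is defined as the correlation between a child's OM
parameter (β_add − β_sub) and the reorienting *cost* parameter (positive
ms added to invalid trials). The measured reorienting effect is
neutral − invalid ≈ −cost, so the default ρ = −0.6 produces the positive
measured correlation between OM and (smaller) reorienting cost. Note
that the measured correlation is attenuated well below |ρ| (to ≈ 0.2 at
the defaults) because each child contributes only 10 invalid and 10
neutral trials, so the per-child reorienting estimate carries ~0.45 z
units of trial noise against ~0.18 z units of true between-child spread.
Children are drawn with independent β_add and β_sub (equal variances via
a mean-bias + OM-difference decomposition); a shared positive
across-operation bias component in children is *not* modeled.

## Descriptive statistics

- CV profile: the SD is the across-trial sample SD pooled over subjects
  within each operation × outcome cell (per-subject CVs at 2–4
  trials/cell are noise-dominated); CV = SD/mean.
- Choice ranks: 1-based position of the chosen value among the sorted
  six alternatives; proportions per operation × range with the
  arcsin(√p) variance-stabilizing transform.
- Memory regression: per-subject OLS of chosen on shown numerosity,
  group-level one-sample t-tests on intercepts (vs 0) and slopes (vs a
  selectable null, 0 or 1).
- Cueing effects: correct trials only; each subject's correct-trial RTs
  are z-scored over all their trials (mean 0, SD 1; an all-equal vector
  maps to zeros), then averaged by condition. Orienting =
  neutral − valid, reorienting = neutral − invalid. Z-scoring the three
  condition means themselves (which would force them to mean 0, SD 1)
  is a possible alternative reading of per-child standardization; the
  per-trial interpretation is implemented because the condition-mean
  version destroys between-child effect-size information.
- Classical repeated-measures ANOVA machinery is intentionally absent;
  the cell means/SDs needed to run it elsewhere are all exported.

## Bayesian model and sampler

Scores are standardized before fitting: pooled grand mean subtracted and
pooled grand SD (ddof = 1) divided out over all 2(n₁+n₂) values, with
the transform recorded for back-conversion. Pooling across groups and
measurements is a choice; any affine variant leaves within-group
contrasts' signs and all sign probabilities unchanged.

The inverse-Wishart convention is pinned because libraries differ:
density ∝ |Σ|^−(df+p+1)/2 · exp(−tr(scale·Σ⁻¹)/2) with p = 2,
scale = I, df = 2 (the smallest proper choice; the prior mean does not
exist, which is intended — the prior is weak). The μ prior is an
independent N(0, 100000) per component, so the μ full conditional is
N(P⁻¹ n Σ⁻¹ ȳ, P⁻¹) with P = n Σ⁻¹ + I/100000, and the Σ full
conditional is inverse-Wishart(I + Σᵢ(yᵢ−μ)(yᵢ−μ)ᵀ, 2 + n). Groups are
conditionally independent and run as separate chains.

Numerics: all 2×2 algebra (inverse, Cholesky) is written in closed form
on scalars; inverse-Wishart draws use the Bartlett decomposition with
chi-square degrees of freedom fixed per group, so all randomness is
pre-drawn as arrays and a 600,000-iteration run takes seconds. If a
conditional scale matrix loses positive-definiteness to rounding, its
diagonal is jittered by 1e−10 with a logged warning (never observed in
practice). Default run length 600,000 with 100,000 burn-in; the test
suite uses 60,000/10,000, which agrees with long chains to two decimals
on fixed data. HDIs use the sliding-window shortest-interval rule on
sorted draws (exact for unimodal posteriors); the HDI mass defaults to
0.95, an assumption since no mass is stated with the reference results.
Sign probabilities are the fraction of draws strictly above zero.
Convergence is checked by split-chain rank-normalized R-hat and ESS
(via arviz), warning above 1.01 / below 400 — replacing the visual
inspection used historically.

Sampler validation is dual-route: with the Σ step frozen, μ-draw moments
are compared to the independently coded closed-form conjugate posterior
(3 Monte-Carlo SEs); prior-only runs reproduce the √100000 ≈ 316.2 prior
SD and match scipy's direct inverse-Wishart sampler on marginal medians.

## What the synthetic cohorts do and do not show

Passing tests demonstrate that the pipeline recovers the structure the
generator puts in: Weber-law CV, operation-specific bias signs, group
heteroscedasticity, cueing effects, and the OM–reorienting link. They do
not validate the psychological claims on real children: the generator
has no session-order, fatigue, or strategy effects, no positive
across-operation bias correlation in children, no SOA modulation of
cueing, and its parameter distributions are constructs. Recovery of the
qualitative sign pattern (positive adult effect, positive interaction,
negative child effect) at the 32 + 32 scale is itself probabilistic: the
population child effect (−0.354 standardized) is only ~1.7 cohort-level
standard errors from zero, so a nontrivial fraction of simulated cohorts
genuinely lack it, and the 20-seed recovery suite is expected to sit
near its 15-of-20 threshold.

## Problem sizes

The acceptance script runs the full 600,000/100,000 chain on a 32 + 32
cohort. The test suite runs 60,000/10,000 chains for the recovery suite,
50,000 iid draws for the frozen-Σ oracle, 10⁶ draws for the HDI/sign
analytics, and Monte-Carlo checks at 4,000–60,000 trials; these sizes
make every stochastic tolerance a small multiple of its Monte-Carlo SE.
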