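# opmomentum

Analysis pipeline for **operational momentum (OM)** in non-symbolic
arithmetic: the tendency to overestimate the outcomes of approximate
addition and underestimate those of subtraction when quantities are
presented as dot arrays rather than digits. The package is aimed at
researchers in numerical cognition who want to (a) reconstruct the
stimulus design of a child-friendly non-symbolic calculation task,
(b) simulate child/adult cohorts with a fully specified generative model
of approximate-number-system behavior, (c) compute the standard
descriptive statistics of such experiments, and (d) fit a heteroscedastic
Bayesian repeated-measures model that remains valid when children are
noisier than adults.

## The models

**OM bias.** For each subject and operation the bias is the mean of
log10(chosen) − log10(correct); the OM difference is
bias(addition) − bias(subtraction). Positive values are regular momentum,
negative values inverse momentum.

**Generative observer.** A subject's internal estimate of a trial's
correct outcome c is log-normal, `X = exp(ln c + β_op·ln10 + w·Z)`, with
operation-specific multiplicative bias β_op (log10 units) and a constant
log-scale SD w — Weber's law, implying a constant coefficient of
variation CV = SD/mean ≈ √(exp(w²) − 1) across outcomes. The subject
picks the displayed alternative nearest X on the log scale, lapsing to a
uniform choice with a small probability.

**Heteroscedastic repeated-measures model.** Per-subject
(addition, subtraction) bias pairs y_ik from group k (adults, children)
follow

    y_ik ~ N(μ_k, Σ_k),   μ_jk ~ N(0, 100000),   Σ_k ~ inverse-Wishart(I, 2)

with an unrestricted 2×2 covariance per group, so the operations may
correlate and every variance may differ between groups. A hand-written
Gibbs sampler alternates the conjugate full conditionals (normal for μ_k,
inverse-Wishart for Σ_k) and reports posterior means, 95% highest-density
intervals, and sign probabilities for the group means, (co)variances, the
operation effect in each group (μ_add − μ_sub), and their interaction.

## Worked example

```sh
python analysis/01_build_design.py --seed 1
python analysis/02_simulate_cohort.py --seed 1
python analysis/03_descriptives.py
python analysis/04_fit_bayes.py --seed 1
```

The default cohort is 32 adults (regular momentum, w ≈ 0.15) and 32
children (inverse momentum, noisier, w ≈ 0.25); children also run a
spatial-cueing session. The descriptive stage prints, for seed 1:

```
adult group: measured OM difference +0.0481 (SD 0.0616) -> regular momentum
child group: measured OM difference -0.0090 (SD 0.0819) -> inverse momentum
CV across operation x outcome cells: 0.208-0.244 (Weber's law predicts a flat profile)
memory regression: mean slope 1.046, mean intercept -0.012
cueing (z units): orienting +0.148, reorienting -0.480
OM x reorienting over 32 children: r=0.232, p=0.2019
```

i.e. adults overestimate addition relative to subtraction by ~0.05 log10
units while children show the inverse pattern; response variability
scales with magnitude (flat CV); valid cues speed responses and invalid
cues cost about twice the benefit; and children with smaller reorienting
costs lean toward regular momentum. The Bayesian stage then prints the
13-row posterior summary on the standardized scale, ending with

```
P(adult effect > 0) = 1.000; P(child effect < 0) = 0.730; P(interaction > 0) = 0.999
```

— decisive evidence for regular momentum in adults and for a group
difference, with moderate evidence for inverse momentum in children at
this cohort size.

The same stages are available as a console script
(`opmomentum design|simulate|analyze|fit-bayes|run-all`) and as a single
call, `opmomentum.pipeline.run_pipeline(RunConfig(...))`, which persists
every intermediate (trials.csv, bias.csv, draws.csv, summary.json,
report.json) with byte-stable contents for a fixed configuration.

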