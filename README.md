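# panelkink

Kink (continuous-threshold) panel regression estimated by first-difference
GMM, for two-wave panels in which the threshold variable is endogenous and is
instrumented by time-invariant background variables.

The motivating application is the effect of body-mass index (BMI) on weekly
work hours in a birth-cohort panel observed at ages 34 and 42: work hours may
respond to BMI with one slope in the normal-weight range and a different slope
above an unknown obesity threshold, while BMI itself is correlated with
unobserved determinants of work.  The package provides the panel containers
and sample filters, a synthetic-data generator with the study's dependence
structure (the restricted cohort data cannot be redistributed), the threshold
GMM estimator, linear baselines, instrument diagnostics, and a desk-scale
analysis pipeline.  It is a library: the importable API plus the narrative
scripts in `examples/` are the interface.

## Model

For individual *i* in period *t* ∈ {1, 2}:

    y_it = β₀ + x_it'β + α·q_it + δ·(q_it − γ)·1{q_it ≥ γ} + ω_i + ε_it

where *y* is the outcome (weekly work hours), *q* the threshold variable
(BMI, kg/m²), *x* time-varying covariates, ω_i an individual fixed effect and
γ the unknown threshold.  The kink term changes the slope from α to α + δ at
γ with no jump.  First-differencing removes ω_i:

    Δy_i = Δx_i'β + α·Δq_i + δ·[(q_i2 − γ)⁺ − (q_i1 − γ)⁺] + Δε_i

Because q is endogenous, the differenced equation is estimated by GMM with
instruments (1, Δx_i, z_i), where z_i are four childhood anthropometry
variables (birth weight, own BMI at age 10, each parent's BMI at that time).
The model is linear in (β, α, δ) given γ, so γ is profiled over a grid
spanning the trimmed support of the pooled q distribution (default: total
trim 0.30, i.e. 15% from each tail), with two-step weighting and sandwich
standard errors whose moment Jacobian includes the γ direction.

## Worked example

```
python examples/02_fit_threshold.py
```

simulates the default female study arm (828 individuals, two periods) and
fits the threshold model:

```
               estimate       se       z       p
intercept        0.7488   1.6995  0.4406  0.6595
d_degree        -0.5901   2.6213 -0.2251  0.8219
d_family_size   -1.4202   1.4703 -0.9659  0.3341
d_high_skill     3.3398   4.2913  0.7783  0.4364
alpha            7.1490   6.4265  1.1124  0.2660
delta           -6.9936  11.8783 -0.5888  0.5560
gamma           25.3386   5.3676  4.7207  0.0000

regime slopes: +7.15 h per BMI unit below the threshold, +0.16 above
threshold estimate: 25.34 kg/m^2 (truth used by the generator: 30.021)
J statistic 0.101 on 1 df (p = 0.750)
```

`alpha` is the below-threshold slope (hours per BMI unit), `delta` the slope
change at the kink, `gamma` the estimated threshold.  The gap between the
threshold estimate and the generating value in this single draw is typical:
with instruments explaining ~20% of BMI variance, the threshold location is
weakly identified at this sample size (see `docs/methods.md`), which the
standard errors reflect.  `examples/03_baselines_and_diagnostics.py` adds the
pooled-OLS and fixed-effects benchmarks plus the Cragg–Donald and Sargan
instrument checks, and `examples/04_full_analysis.py` runs the whole pipeline
(filters, summary tables, trim-rate sensitivity, skill subgroups) from one
configuration.

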