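# gformula

Parametric g-formula estimation of the effects of **sustained treatment
strategies** on survival and end-of-follow-up outcomes from longitudinal
data with time-varying confounding.

## The problem

Epidemiologists and biostatisticians often want the counterfactual risk (or
outcome mean) had everyone in a study population followed a time-varying
treatment rule — "always treat", "never treat", "treat whenever the
covariate drops below a threshold".  When a time-varying confounder is
itself affected by past treatment (treatment–confounder feedback, e.g. CD4
count under antiretroviral therapy), conventional regression adjustment is
invalid.  Robins's g-formula still identifies these effects: the
counterfactual mean is a sum over covariate histories of the outcome
model weighted by the covariate distribution under the intervention,

    E[Y^g] = Σ_{l̄} E[Y | L̄ = l̄, Ā = g(l̄)] · Π_k f(l_k | l̄_{k-1}, g(l̄_{k-1})) .

The **parametric g-formula** estimates the pieces with parametric models
and evaluates the sum by Monte Carlo:

1. **Fit**, on the observed person-time data: (a) one conditional model per
   time-varying covariate, factorizing the joint covariate distribution in
   a user-chosen order; (b) a pooled logistic model for the discrete-time
   outcome hazard p_k (survival) or a regression for the end-of-follow-up
   mean; (c) optionally a pooled logistic model for the competing-event
   hazard q_k.
2. **Simulate** s covariate histories forward from a resample of the
   observed baseline, replacing each treatment value with the value the
   strategy prescribes, and average the model-implied risks
   R(k) = Σ_{t≤k} p_t Π_{j<t}(1−p_j) (with (1−q) factors when competing
   events are modelled) or predicted end-of-follow-up means.

Strategies may be static (fixed value vectors), threshold rules on the
*natural value* of treatment (the value that would have been observed had
the intervention stopped just before k), the natural course, or custom
dynamic rules; contrasts (ratios/differences) are reported against a
reference strategy with subject-level bootstrap percentile intervals.
Nonparametric natural-course benchmarks (product-limit risk, per-time
covariate means) are computed for model diagnostics.

## Worked example

The package ships synthetic structural systems with known counterfactual
truth (`gformula.dgp`).  Estimate the risk by seven intervals under "never
treat" and "always treat" for a system with a binary confounder L1, a
continuous confounder L2, a baseline covariate L3, and a binary treatment A
that both responds to and influences L1/L2:

```python
from gformula.dgp import get_dgp, generate_dataset
from gformula.pipeline import run_gformula
from gformula.results import render_summary

dgp = get_dgp("survival_basic")            # n=2500 subjects, K+1=7 intervals
table = generate_dataset(dgp, seed=2026)
config = dgp.analysis_config(nsimul=10000, seed=1)
print(render_summary(run_gformula(table, config)))
```

```
PREDICTED RISK UNDER MULTIPLE INTERVENTIONS

Intervention 	Description
0	Natural course
1	Never treat
2	Always treat

Sample size = 2500, Monte Carlo sample size = 10000
Number of bootstrap samples = 0
Reference intervention = natural course (0)

k  Interv.  NP risk  g-form risk  Risk ratio  Risk difference
6  0  0.5756  0.5759462  1  0
6  1  NA  0.8138444  1.413056  0.2378981
6  2  NA  0.4378804  0.76028  -0.1380658
```

Read: the parametric natural-course risk (0.576) matches the nonparametric
benchmark (0.5756), supporting (not guaranteeing) adequate model
specification; never treating would raise the 7-interval risk to 0.814
(risk ratio 1.41), always treating would lower it to 0.438.  In this
synthetic system the true counterfactual risks are computable exactly
(`gformula.dgp.true_counterfactual`), which is how the estimator is
validated in the test suite.

The same analysis runs from the shell:

```bash
gformula simulate-fixture --dgp survival_basic --seed 2026 --out obs.csv
gformula run --config cfg.yaml --data obs.csv --out results/ --nsimul 10000 --seed 1
```

writing `results.csv`, `models.csv` (coefficients/SEs/RMSEs), `summary.txt`
and natural-course diagnostic plots.

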