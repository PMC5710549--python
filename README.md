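# moodrpe

Momentary mood modelling for risky decision tasks: a recency-weighted
linear model of happiness ratings, task and cohort simulators, per-
participant fitting and model comparison, and nonparametric group
statistics. The package is aimed at computational-psychiatry work that
relates within-task mood dynamics (and especially the baseline mood
parameter) to depression-severity questionnaires such as the HAM-D, PHQ
and BDI-II.

## The model

During a gambling task, participants are asked "How happy are you at
this moment?" every 2–3 trials. Momentary happiness at the probe after
trial *t* is modelled as

```
happiness(t) = w0 + w_CR  Σ_{j≤t} γ^(t−j) CR_j
                  + w_EV  Σ_{j≤t} γ^(t−j) EV_j
                  + w_RPE Σ_{j≤t} γ^(t−j) RPE_j
```

where CR_j is the certain reward when the safe option was chosen, EV_j
the expected value of a chosen gamble, RPE_j = outcome − EV_j the reward
prediction error of a revealed gamble outcome, and 0 ≤ γ ≤ 1 a
forgetting factor that makes recent events exponentially more
influential. Terms for unchosen options are zero, and the RPE is zero
when the outcome is not revealed. `w0` is the intercept — a baseline
mood that persists after task-driven fluctuations are accounted for.

Because the model is linear given γ, fitting is a γ grid search (step
0.01) with the weights solved by ordinary least squares at each grid
point. Alternative forms — dropping the EV term, or splitting the RPE
into its reward and −EV components — are compared by a summed
Gaussian-likelihood BIC (a fixed-effects approximation to Bayesian model
comparison).

Three task variants are simulated: a 160-trial / 66-probe laboratory
session, a 30-trial / 12-probe smartphone session (points, endowment
500, equal-probability spinners), and a 164-trial scanner task with
fully described ±£1 lotteries (win probability 0/25/75/100%) whose
EV and RPE series serve as parametric modulators; participants who miss
the objectively better "observation" lottery on more than 30 trials are
excluded from analysis.

## Worked example

```python
import numpy as np
from moodrpe import (CohortConfig, generate_cohort, fit_mood_model, spearman)

cohort = generate_cohort(CohortConfig.smartphone(n=300, seed=7))
fits = [fit_mood_model(p.session, p.ratings) for p in cohort.participants]
severity = [p.symptom for p in cohort.participants]  # BDI-II

print("mean r2:", round(float(np.mean([f.r2 for f in fits])), 3))
res = spearman([f.params.w0 for f in fits], severity)
print("w0 vs severity: rho=%.3f p=%.2g" % (res.estimate, res.p))
```

prints

```
mean r2: 0.926
w0 vs severity: rho=-0.412 p=1e-13
```

i.e. the model explains most rating variance at the default simulation
noise, and the fitted baseline mood parameter decreases with depression
severity — the structure the generator builds in (weights for CR, EV and
RPE are drawn independently of severity, so their correlations are
null). The same pipeline is available from the shell:

```
moodrpe replicate --out results/run1          # simulate -> fit -> compare -> stats
moodrpe simulate-session --variant lab --seed 1 --out sess.tsv
```

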