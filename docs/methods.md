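# Methods

## The mood model

Happiness at the probe after trial *t* is

    h(t) = w0 + w_CR·S_γ[CR](t) + w_EV·S_γ[EV](t) + w_RPE·S_γ[RPE](t)

with S_γ[x](t) = Σ_{j≤t} γ^(t−j) x_j. The model assumes (i) mood
responds linearly to recent task events, (ii) the influence of an event
decays exponentially with the number of intervening trials (not clock
time), and (iii) events enter only through three channels: the certain
reward obtained when the safe option is chosen (CR), the expected value
of a chosen gamble at choice time (EV), and the surprise at its outcome
(RPE = outcome − EV). Unchosen options contribute nothing, and a hidden
outcome produces no RPE while the expectation (EV) term still stands —
expectations were formed whether or not the outcome is shown.

Two alternative forms support model comparison:

* **no_expectation** — drops the EV term (k = 4 parameters);
* **split_rpe** — keeps CR and EV, and replaces the single RPE weight by
  separate weights on the RPE's two components, the obtained reward R_j
  and the negated expectation −EV_j, both restricted to revealed gamble
  trials (k = 6). Since RPE = R − EV there, the split model nests the
  full model exactly when w_R = w_negEV = w_RPE; the test suite asserts
  this identity to 1e−12.

Ratings and predictions live on the [0, 1] cursor scale and are not
z-scored by default, so that w0 is comparable across participants — a
requirement for correlating baseline mood with symptom severity.
Standardizing per participant would absorb exactly the quantity of
interest.

## Fitting

Given γ, the model is an ordinary least-squares problem in
(w0, weights). The fitter therefore scans γ over a fixed grid (step
0.01 on [0, 1], configurable), solves the weights in closed form at
each grid point (normal equations with an `lstsq` fallback for
rank-deficient designs), and returns the global grid minimum of the
squared error. Ties are broken toward smaller γ, so refitting is
bit-reproducible. On noise-free data whose generating γ lies on the
grid, recovery is exact to numerical precision; the suite verifies the
grid estimator against a dense two-dimensional scan over γ × w_CR with
the remaining weights profiled.

Conventions: fewer probes than parameters raises an error rather than
returning a pseudo-inverse solution; zero rating variance returns
w0 = mean rating, zero weights, and r² defined as 0, flagged as
degenerate. Weights and w0 are unbounded — clipping to [0, 1] happens
only in simulation, never in estimation. r² = 1 − SSE/TSS.

Model evidence is approximated by the Gaussian-likelihood BIC
n·ln(max(SSE, 1e−12)/n) + k·ln(n) (the 1e−12 floor guards exact fits),
summed across participants — a fixed-effects comparison. Residual
variance is not counted in k: it is common to all specs and cannot
affect a ranking. Random-effects selection (exceedance probabilities)
is out of scope; ties in summed IC are reported as ties.

## Task simulators

* **Probe schedules.** "A probe every 2–3 trials" plus the printed
  (trials, probes) pairs pins the gap multiset uniquely
  (a + b = probes, 2a + 3b = trials): 38 gaps of 2 and 28 of 3 in the
  laboratory session, 6 and 6 on the smartphone. Only the gap order is
  randomized (seeded); the first probe follows the first gap and the
  last lands on the final trial.
* **Risky stakes.** The stake distributions of the original tasks are
  not published, so they are configurable with defaults chosen to look
  like a standard gain/loss/mixed design: equal thirds of gain trials
  (certain U(0.2, 0.6) vs {0, U(0.5, 1.5)}), loss trials (mirrored), and
  mixed trials (certain 0 vs {U(0.4, 1.2), −U(0.4, 1.2)}), all at
  p = 0.5. Lab stakes are in pounds; smartphone stakes are the same
  distributions × 80 in points (endowment 500), with weights and choice
  temperature rescaled per point so behaviour is unit-invariant (the
  suite asserts r² invariance under money rescaling).
* **Choices.** The studies measure but do not model risk taking, so any
  generator with realistic gamble shares suffices; the simplest with a
  tunable risk appetite is logistic:
  P(gamble) = expit(bias + β·(EV − CR)), default β = 2 per pound,
  bias 0 (≈ 60% gamble share under the default stakes). In the lab
  variant a seeded ⌊n/2⌋ of the chosen gambles is marked unrevealed with
  RPE 0; smartphone gambles always resolve.
* **Scanner task.** 164 trials, the four ±£1 lotteries
  (p_win ∈ {0, .25, .75, 1}) balanced at 41 each in seeded order. The
  published trial pairing is unavailable, so each observation lottery is
  paired with the same lottery shifted down £0.50 on both outcomes —
  statewise dominated, so the correct choice is belief-free and
  accuracy can sit near 97% in both groups. Per-trial error probability
  defaults to 3%; designated "failure" participants get an exact seeded
  error count drawn uniformly from 31–60, guaranteeing they trip the
  >30-missed-trials exclusion (strict inequality: exactly 30 stays).

## Cohort generator

Questionnaire scores use the published group means/SDs as defaults:
HAM-D 15.6 (4.1) and PHQ 15.8 (4.7) for the depressed laboratory group
(16.6 (2.5) / 16.9 (3.6) with a HAM-D ≥ 14 floor for scanned samples),
0.6 (1.0) / 1.1 (1.7) for controls, drawn jointly with latent
correlation 0.8, rounded and clipped to scale ranges. The smartphone
cohort draws a BDI-II severity continuum from a rounded log-normal
(log-mean 2.2, log-sd 0.8 → median ≈ 9, ≈ quarter of the sample ≥ 15,
which is the high-severity cut used for group labels).

True parameters: weights per pound ~ N(0.25, 0.10) floored at 0.02
(positive mood effects of rewards), γ ~ U(0.25, 0.55) (bracketing the
group-typical forgetting factor ≈ 0.34), and

    w0 = 0.5 + β_s·z(symptom) + ε,  ε ~ N(0, 0.10), β_s = −0.040,

with z the cohort-standardized severity score. β_s is calibrated so the
generating Spearman(w0, severity) is ≈ −0.30 at smartphone scale, the
magnitude the method is meant to detect; the closed-form normal-copula
slope was adjusted once for the skew and rounding of the BDI draw. All
other weights are independent of severity, so their fitted-weight vs
severity correlations are null by construction — the generator mirrors
a study in which depression lowers baseline mood but leaves the
emotional impact of RPEs intact.

Ratings are predictions plus i.i.d. N(0, 0.05) noise clipped to [0, 1];
the clipped fraction is returned and logged (≈ 2% under defaults) and a
warning fires above 10%, since heavy clipping biases fits. Clipping was
chosen over truncated-Gaussian sampling because it is what a bounded
response device actually does to an out-of-range impulse.

What the generator does *not* emulate: rating drift or autocorrelated
noise, reaction times, loss-averse or risk-weighted utilities, learning
or belief updating, attrition, and day-to-day retest dynamics. Passing
recovery tests therefore show the estimator is correct under the
model's own assumptions, not that real raters obey them.

## Statistics

All group-level tests are nonparametric and two-tailed with α = .05 and
no multiple-testing adjustment (deliberately mirroring the analysis
style this package supports; interpret tables accordingly). Spearman ρ
uses average ranks; rank-sum and signed-rank tests report a z that
standardizes the rank statistic by its exact permutation mean and
tie-corrected variance, with p from the normal approximation, or from
exhaustive permutation (combinations / sign flips) when every sample
has n ≤ 8. Zero paired differences are dropped; all-zero differences
are an error, as is a constant input to a correlation.
Covariate-adjusted correlations residualize both variables on an
intercept, sex, a binary university-degree indicator and age by OLS,
then correlate the residuals; rank-deficient covariate sets raise an
error naming the collinear columns. Education is dichotomized as
degree/no-degree because that is the covariate encoding the supported
analyses use, its known coarseness notwithstanding.

## Pipeline and reproducibility

Sessions, fit tables and stats tables are tab-separated text with fixed
6-decimal float formatting and a schema-version header, so identical
configs reproduce byte-identical tables; a JSON manifest records the
config snapshot, seeds, package version and SHA-256 of every output.
Every stochastic stage consumes an explicit seed derived from the
config; there is no hidden global randomness.

## Problem sizes

The shipped verification runs use: 100 replicates for noisy recovery;
20 simulated 50-participant cohorts per model-selection condition;
10 cohorts of n = 1833 smartphone sessions for linkage recovery (3 in
the acceptance script); exhaustive oracles up to n = 8 per sample.
These sizes give Monte-Carlo error comfortably below the tolerances
they are tested against.

## Known limitations

* γ is estimated on a grid; off-grid generating values are recovered
  only to grid resolution, and γ is weakly identified in 12-probe
  smartphone sessions (w0 and the weights remain well determined).
* The BIC comparison is fixed-effects; heterogeneous cohorts in which
  different participants truly use different models are summarized only
  by the per-participant winner counts.
* The smartphone severity continuum is a convenient log-normal, not an
  empirical BDI-II distribution.
* With 12 probes and 5 parameters the full model's fits are optimistic
  (high r²) relative to longer sessions; comparisons across variants
  should use the same session length.
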