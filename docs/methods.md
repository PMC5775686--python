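# Methods

## The problem

Consider a two-arm comparison where membership in the "treated" arm is
revealed over time by an exogenous binary process: the canonical example is
allogeneic stem-cell transplantation, where a patient belongs to the
"donor available" population if a matched donor is identified within a search
window `t_search`, and to the "no donor" population otherwise.  Because donor
search stops when a patient dies or is censored, availability is only partly
observed, and a naive comparison by *observed* donor status suffers from
waiting-time (immortal-time) bias: being classified as "donor available"
requires surviving long enough for the donor to be found.  With strongly
non-proportional hazards (early transplant-related mortality vs long-term
benefit) the usual Cox model with a time-dependent covariate answers the
wrong question; the clinically relevant contrast is between the survival
probabilities `S1(t*)` and `S0(t*)` of the two populations at a long-term
horizon `t*`.

## The compartment model

Each subject follows a three-state process: initial state 0, transient state
1 (entered at the waiting time `W = w` if still at risk), absorbing state 2
(failure).  Before the transition the hazard of failure is `lambda_02(t)`;
afterwards `lambda_12(t, t - w)`.  Exogeneity means donor availability and
the waiting time carry no information about prognosis, so `lambda_02` is the
same in both populations up to `t_search`, and

    S1(t* | w) = exp(-[ int_0^w lambda_02 + int_w^{t*} lambda_12 ]),
    S1(t*)     = sum_w f01(w) S1(t* | w),
    S0(t*)     = exp(- int_0^{t*} lambda_02),

with `f01` the waiting-time law in the donor population.

## Generalised pseudo-values

The ordinary pseudo-value `V_i = n*S_hat(t*) - (n-1)*S_hat^{-i}(t*)`
(jackknife contrast of Kaplan-Meier estimates) turns censored survival at a
fixed time into a regressable per-subject response.  Two generalisations
make it usable here:

* **0->2 pseudo-values** (for `S0`): every subject with an observed
  transition is administratively censored at its `w_i` (censored, not
  dropped -- dropping would over-represent early direct failures) and
  pseudo-values are computed *for all n subjects* on this modified sample.
* **0->1->2 pseudo-values** (for `S1(t*|w)`): for each observed transition,
  a conditional pseudo-value `U_i` of survival at `t*` given alive at `w_i`
  is computed with the Kaplan-Meier clock restarted at `w_i`, then scaled by
  the pre-transition survival factor `S0_hat(w_i)` from the modified-sample
  curve: `V_i,1 = S0_hat(w_i) * U_i`.

Pseudo-values may fall outside [0, 1]; they are never truncated.

### Risk-set convention for the conditional pseudo-value

"All subjects still at risk at `w_i`" is ambiguous when waiting times are
continuous.  The default mode `exact-waiting-time` groups transition
subjects sharing the same waiting time (equal after rounding to 1e-9) --
the natural reading when the waiting-time law is discrete, and the one under
which `E[U_i] = S(t* | T >= w_i, W = w_i)`.  The alternative
`state1-risk-set` mode uses, for each transition subject separately, all
transitioned subjects still at risk at its `w_i`; it remains usable with
continuous waiting times and is reported in the output.  The mode is a
configuration switch (`AnalysisConfig.grouping`).

### Evaluation conventions

Ties are resolved events-before-censorings.  `S0_hat(w_i)` is evaluated
right-continuously on the modified-sample curve: subject i itself is
censored at `w_i` there, so a *different* subject's direct failure at
exactly `w_i` counts.  The observability curve (below) is instead read as
the left limit `G_hat(w_i-)`: the weight is the inverse probability of
*reaching* `w_i` observable, so a subject whose transition is observed
always has positive estimated observability.

### Fast exact jackknife

Leave-one-out Kaplan-Meier values are assembled from risk-set-adjusted
factors rather than n refits.  Up to a size threshold (4e6 factor-matrix
cells, covering every sample the Monte-Carlo studies use) the adjusted
factors are multiplied in the same sequential order a refit would use, so
the fast path is bit-identical to n naive refits; beyond it a prefix/suffix
factorisation of the same product is used, identical up to rounding error.

## IPCW weights

The observed waiting-time distribution `q(w)` over-represents short waits,
because long waits are more often pre-empted by death or censoring.  The
observability probability `G(w)` is estimated by Kaplan-Meier on the *whole*
sample with censorings and direct failures as events and observed
transitions as censorings; each observed transition gets the weight
`gamma_i = p_m / G_hat(w_i-)` with `p_m = m / sum_j 1/G_hat(w_j-)`, so the m
weights sum to m exactly.  The weighted mean of composite pseudo-values then
estimates `S1(t*)` rather than the distorted mixture `sum_w q(w) S1(t*|w)`.
`p_m` is treated purely as the normaliser that fixes the weight sum.

## The weighted GLM

The response stacks the n direct and m composite pseudo-values (a
transition subject contributes one row to each group), with group indicator
x = 0/1 and weights 1 / `gamma_i`.  The mean model is
`E[V] = exp(-exp(beta0 + beta1 x))` -- linear on the cloglog scale
`g(S) = log(-log S)` -- with a homoscedastic normal working model, so the
estimating equations are solved by the weighted group means:
`beta0 = g(V0_bar)`, `beta1 = g(V1_bar) - g(V0_bar)`, and `exp(beta1)` is
the ratio of cumulative hazards at `t*` (cHR < 1 means higher survival with
a donor).  The solver is a damped Newton/IRLS iteration (tolerance 1e-8 on
the coefficient change, at most 100 iterations, step halving on the
estimating-function norm; initialisation at the cloglog of the clipped
overall weighted mean -- clipping is used only to initialise).  If a group's
weighted mean falls outside (0, 1) the link is undefined and the fit is
flagged non-convergent; studies exclude and count such replicates.

Inference uses the HC0 sandwich `B^{-1} M B^{-1}` with
`B = X' diag(w mu'^2) X` and `M = X' diag(w^2 mu'^2 (y - mu)^2) X`: the
analysis weights enter bread and meat as fixed frequency-type weights, and
the sampling variability of the estimated weights themselves is ignored.
No finite-sample correction is applied to the sandwich; the coverage targets
tolerate the difference between HC0 and corrected variants at the sample
sizes studied.  Confidence intervals and p-values are Wald with normal
quantiles on the cloglog scale.

## Standard-error correction by Bernoulli imputation

The factor `S0_hat(w_i)` is shared across transition subjects, so the
composite pseudo-values understate subject-level variability and the
sandwich SEs are too small on average.  The correction replaces
`S0_hat(w_i)` by a random indicator: draw

    p_i ~ Normal( log(-log S0_hat(w_i)),
                  Var_G(S0_hat(w_i)) / [S0_hat(w_i) log S0_hat(w_i)]^2 ),
    B_i ~ Bernoulli( exp(-exp(p_i)) ),

with `Var_G` the Greenwood variance, and use `B_i * U_i`.  The normal is the
asymptotic law of the log(-log) transform of the Kaplan-Meier estimator, so
the imputation is mean-preserving up to the delta-method approximation.
Where `S0_hat(w_i)` is exactly 0 or 1 the transform is degenerate and the
non-imputed value is kept, with a warning.  In a single-dataset analysis
point estimates always come from the non-imputed fit and the SEs are
averaged over repeated imputations (default 1000); inside Monte-Carlo
studies one imputation per replicate suffices because the replication
already averages, and the corrected column's estimates and SEs both come
from the imputed fit.

## The simulator

`simulate.ScenarioSpec` draws three-state data by inversion: piecewise-
constant hazards with optional cure fractions (mixture survival
`pi + (1-pi) exp(-H(t))`, giving the survival plateau typical of paediatric
oncology), a discrete waiting-time law, donor assignment by a Bernoulli
draw, and independent uniform censoring superimposed on everything.  The
waiting time enters the output only when the transition precedes both
failure and censoring, reproducing exactly the partial observability the
method corrects.  Randomness is counter-based (Philox, four variate
streams), so subject j's draws are invariant to the sample size and to other
subjects.

The benchmark scenario (`scenario_I_spec`) fixes the study conditions used
throughout the tests: 75% donors, waiting times equally likely at 0.5, 1 and
3 years, Uniform(0, 6) censoring, `t* = t_search = 5`, and hazards
*calibrated* to the target truths -- a constant pre-transition rate solving
`S0(5) = 0.333` and per-w constant post-transition rates solving
`S1(5|w) = (0.733, 0.681, 0.451)`.  The calibration pins down every derived
truth in closed form: `S1(5) = 0.622`, observable-waiting distortion
`q = (0.47, 0.38, 0.15)` and population weights `(0.71, 0.87, 2.25)`.  The
constant-hazard reconstruction is a deliberate simplification (no cure
fraction, no time-varying shapes); it fixes the survival *levels* and the
observability process but not the full hazard paths, so Monte-Carlo results
that depend on those levels (bias, weight recovery, coverage) are
comparable, while quantities sensitive to the hazard shape within (0, t*)
need not match other generators exactly.  What passing tests show is that
the estimator is unbiased and correctly covered *under this three-state
mechanism*; real registry data add features the generator does not emulate
(covariate-dependent hazards, dependent censoring, misrecorded transition
dates).

## Study sizes and numerical choices

Monte-Carlo studies run 1000 replicates of n = 1000 (about 15 s on one
core thanks to the incremental jackknife); the parameter-recovery check uses
a single dataset of n = 1e5.  Coverage is evaluated against analytic truths
on the cloglog scale.  Degenerate inputs are handled explicitly: empty risk
sets raise with the offending time; conditional risk sets of size one fall
back to the subject's own survival indicator with a warning; evaluation
beyond the last observation returns the last value with a warning.

## Known limitations

* No baseline-covariate adjustment and a single horizon `t*` (single-time
  pseudo-values only).
* Weight-estimation variability is ignored in the sandwich, as in the
  original formulation.
* The `exact-waiting-time` grouping needs replicated waiting times; use
  `state1-risk-set` for continuous waiting-time laws.
* Left truncation, interval censoring and competing-risk cumulative
  incidence are out of scope.
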