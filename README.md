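# gpvreg

Generalised pseudo-value regression for comparing long-term survival
probabilities between two populations whose membership is revealed over time
by a partly unobserved, exogenous, binary time-dependent covariate.

The motivating setting is allogeneic stem-cell transplantation: patients
belong to the "donor available" population if a matched donor is identified
within a search window `t_search`, but donor search stops at death or
censoring, so availability is only partly observed.  Comparing survival by
observed donor status introduces waiting-time (immortal-time) bias, and with
the strongly non-proportional hazards typical of transplant studies a Cox
model with a time-dependent covariate does not answer the clinically
relevant question -- whether the long-term survival probability `S1(t*)`
with a donor exceeds `S0(t*)` without one.

`gpvreg` estimates and compares these probabilities directly:

* **jackknife pseudo-values** `V_i = n*S_hat(t*) - (n-1)*S_hat^{-i}(t*)` of
  the Kaplan-Meier estimator, generalised to the three-state setting:
  0->2 pseudo-values for `S0(t*)` (observed transitions administratively
  censored at their waiting time `w_i`) and composite 0->1->2 pseudo-values
  `S0_hat(w_i) * U_i(t*|w_i)` for `S1(t*|w)`;
* **inverse-probability-of-censoring weights**
  `gamma_i = p_m / G_hat(w_i-)`, which restore the true waiting-time law
  `f01(w)` from the observable one `q(w)`;
* a **weighted GLM with cloglog link** `g(S) = log(-log S)` on the stacked
  pseudo-values, whose group contrast exponentiates to the cumulative hazard
  ratio `cHR = exp(beta1)` at `t*` (cHR < 1 means higher survival with a
  donor), with sandwich standard errors and an optional Bernoulli-imputation
  correction for the variability hidden in the shared `S0_hat(w_i)` factor;
* a **three-state simulator** (piecewise-constant hazards, optional cure
  fractions, discrete waiting-time laws, uniform censoring, counter-based
  randomness) and a **Monte-Carlo study runner** reporting bias, mean
  sandwich SE, Monte-Carlo SD and CI coverage against closed-form truths.

See `docs/methods.md` for the model, estimators and numerical choices.

## Worked example

Simulate a 1000-patient cohort from the benchmark scenario (75% donors,
waiting times 0.5/1/3 years, `S0(5) = 0.333`, `S1(5) = 0.622`, uniform
censoring on 0-6 years) and analyse it:

```python
import gpvreg as g
from gpvreg.io import save_scenario

save_scenario(g.scenario_I_spec(), "scen.yaml")
```

```
$ gpvreg simulate --scenario scen.yaml --n 1000 --seed 7 --out cohort.csv
INFO gpvreg: simulated 1000 subjects (439 observed transitions) -> cohort.csv

$ gpvreg analyze --input cohort.csv --t-star 5 --t-search 5 --imputations 1000 --seed 7
n_response = 1439   converged = True
S0_hat(t*) = 0.3399   S1_hat(t*) = 0.6193
cHR = 0.4440   95% CI (0.3295, 0.5983)   Wald p = 0.0000
beta0 = 0.0763 (se 0.1129)   beta1 = -0.8120 (se 0.1522)
```

Of the 1000 subjects, only 439 transitions are observed (the rest are
pre-empted by death or censoring).  The estimated 5-year survival is 0.34
without and 0.62 with a donor -- both within sampling error of the scenario
truths 0.333 and 0.622 -- and the cumulative hazard ratio 0.44 with CI
(0.33, 0.60) indicates a clear long-term benefit.  The response has
n + m = 1439 rows because each subject with an observed transition
contributes a pseudo-value to both groups.  Standard errors are averaged
over 1000 Bernoulli imputations; point estimates come from the non-imputed
fit.

The same pipeline is available in Python via `g.analyze(df, g.AnalysisConfig(...))`,
and `g.run_study(spec, replicates=1000)` replicates the full Monte-Carlo
experiment (bias, SE, coverage per estimand).

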