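"""Pseudo-values for survival with a partly unobserved time-dependent group.

Four flavours are provided, all built on the jackknife contrast
``V_i = n*S_hat(t*) - (n-1)*S_hat^{-i}(t*)``:

* ``marginal`` -- the ordinary pseudo-value on the whole sample.
* ``direct02`` -- pseudo-value of the direct 0->2 transition: subjects with an
  observed 0->1 transition (e.g. donor found) are administratively censored at
  their waiting time w_i, and a pseudo-value is computed for *all* n subjects
  on that modified sample.  Its mean estimates S0(t*), survival under the
  never-transition regime.
* ``conditional12`` -- pseudo-value of survival at t* conditional on being at
  risk at the transition time w_i, clock restarted at w_i.
* ``composite012`` -- the product S0_hat(w_i) * U_i of the pre-transition
  survival and the conditional pseudo-value; its mean per waiting time
  estimates S1(t*|w).

Pseudo-values may legitimately fall below 0 or above 1 and are never clipped.

The Bernoulli imputation variant replaces the common factor S0_hat(w_i) by a
per-subject random indicator whose mean matches S0_hat(w_i) and whose spread
matches the Greenwood variance (through the log(-log) transform), restoring
the subject-level variability that the shared Kaplan-Meier factor suppresses;
it is used to correct standard errors, not point estimates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .km import KaplanMeierCurve, fit_km, loo_survival_at

logger = logging.getLogger(__name__)

__all__ = [
    "marginal_pseudo_values",
    "direct02_pseudo_values",
    "conditional12_pseudo_values",
    "composite012_pseudo_values",
    "impute_composite012",
]

W_TOL_DECIMALS = 9  # waiting times equal after rounding to 1e-9 share a group


def transition_mask(df: pd.DataFrame) -> np.ndarray:
    """Boolean mask of subjects with an observed 0->1 transition."""
    return df["waiting_time"].notna().to_numpy()


def marginal_pseudo_values(time, event, t_star: float) -> np.ndarray:
    """Ordinary jackknife pseudo-values of S(t*) for every subject."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(time)
    if not np.any(time >= t_star):
        raise ValueError(f"empty risk set at t*={t_star}")
    curve = fit_km(time, event)
    s_full = curve.survival_at(t_star)
    s_loo = loo_survival_at(time, event, t_star)
    return n * s_full - (n - 1) * s_loo


def _modified_sample(df: pd.DataFrame):
    """Censor observed-transition subjects at w_i; everyone else unchanged."""
    trans = transition_mask(df)
    time = np.where(trans, df["waiting_time"].to_numpy(dtype=float),
                    df["time"].to_numpy(dtype=float))
    event = np.where(trans, 0, df["event"].to_numpy())
    return time, event


def direct02_pseudo_values(df: pd.DataFrame, t_star: float):
    """0->2 pseudo-values for all n subjects, plus the modified-sample curve.

    Subjects with an observed transition are censored at w_i (not dropped --
    dropping them would over-represent early direct events); the returned
    curve is the Kaplan-Meier fit of that modified sample, needed later to
    evaluate S0_hat(w_i) and its Greenwood variance.
    """
    time, event = _modified_sample(df)
    values = marginal_pseudo_values(time, event, t_star)
    curve = fit_km(time, event)
    table = pd.DataFrame(
        {"subject_id": df["subject_id"].to_numpy(), "kind": "direct02",
         "value": values},
        index=df.index,
    )
    return table, curve


def conditional12_pseudo_values(
    df: pd.DataFrame, t_star: float, grouping: str = "exact-waiting-time"
) -> pd.DataFrame:
    """1->2 pseudo-values U_i of S(t* | T >= w_i) for transition subjects.

    The Kaplan-Meier clock restarts at w_i and the curve is read at horizon
    t* - w_i.  ``grouping`` fixes the risk set n_i:

    * ``'exact-waiting-time'`` (default): subjects sharing the same waiting
      time (to 1e-9) form the sample -- appropriate when the waiting-time law
      is discrete.
    * ``'state1-risk-set'``: all transitioned subjects still at risk at w_i
      form the sample -- usable with continuous waiting times.
    """
    if grouping not in ("exact-waiting-time", "state1-risk-set"):
        raise ValueError(f"unknown grouping mode {grouping!r}")
    trans = transition_mask(df)
    sub = df.loc[trans]
    w = sub["waiting_time"].to_numpy(dtype=float)
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy()
    if np.any(w > time):
        raise ValueError("transition observed after end of follow-up")

    values = np.empty(len(sub))
    sizes = np.empty(len(sub), dtype=int)

    if grouping == "exact-waiting-time":
        wr = np.round(w, W_TOL_DECIMALS)
        for wv in np.unique(wr):
            idx = np.nonzero(wr == wv)[0]
            values[idx] = _group_pseudo(time[idx] - w[idx], event[idx],
                                        t_star - wv)
            sizes[idx] = len(idx)
    else:
        for i in range(len(sub)):
            at_risk = np.nonzero(time >= w[i])[0]
            pos = int(np.searchsorted(at_risk, i))
            vals = _group_pseudo(time[at_risk] - w[i], event[at_risk],
                                 t_star - w[i])
            values[i] = vals[pos]
            sizes[i] = len(at_risk)

    return pd.DataFrame(
        {"subject_id": sub["subject_id"].to_numpy(), "kind": "conditional12",
         "value": values, "waiting_time": w, "risk_set_size": sizes},
        index=sub.index,
    )


def _group_pseudo(time, event, horizon):
    if len(time) == 0:
        raise ValueError("empty conditional risk set")
    if len(time) == 1:
        logger.warning("conditional risk set of size 1; pseudo-value is the "
                       "subject's own survival indicator")
        return np.array([0.0 if (event[0] == 1 and time[0] <= horizon)
                         else 1.0])
    return marginal_pseudo_values(time, event, horizon)


def composite012_pseudo_values(
    direct_curve: KaplanMeierCurve, cond_values: pd.DataFrame
) -> pd.DataFrame:
    """0->1->2 pseudo-values: S0_hat(w_i) * U_i per transition subject."""
    w = cond_values["waiting_time"].to_numpy(dtype=float)
    s0w = np.array([direct_curve.survival_at(wi) for wi in w])
    out = cond_values.copy()
    out["kind"] = "composite012"
    out["s0_at_w"] = s0w
    out["value"] = s0w * cond_values["value"].to_numpy()
    return out


def impute_composite012(
    direct_curve: KaplanMeierCurve, cond_values: pd.DataFrame, rng
) -> pd.DataFrame:
    """Composite pseudo-values with S0_hat(w_i) replaced by a Bernoulli draw.

    For each transition subject, p_i is drawn from a normal centred at
    log(-log S0_hat(w_i)) with the delta-method variance of that transform
    (Greenwood variance over [S0 * log S0]^2), and B_i ~ Bernoulli(e^{-e^p_i})
    replaces S0_hat(w_i).  Where S0_hat(w_i) is exactly 0 or 1 the transform
    is degenerate and the non-imputed value is kept, with a warning.
    """
    rng = np.random.default_rng(rng)
    w = cond_values["waiting_time"].to_numpy(dtype=float)
    u = cond_values["value"].to_numpy(dtype=float)
    s0w = np.array([direct_curve.survival_at(wi) for wi in w])
    var = np.array([direct_curve.variance_at(wi) for wi in w])

    ok = (s0w > 0.0) & (s0w < 1.0)
    if not np.all(ok):
        logger.warning(
            "S0_hat(w)=0 or 1 for %d transition subject(s); log(-log) "
            "transform degenerate, keeping non-imputed values there",
            int((~ok).sum()),
        )
    out_vals = s0w * u  # fallback for degenerate entries

    mu = np.log(-np.log(s0w[ok]))
    sd = np.sqrt(var[ok]) / np.abs(s0w[ok] * np.log(s0w[ok]))
    p = rng.normal(mu, sd)
    prob = np.exp(-np.exp(p))
    b = rng.random(ok.sum()) < prob
    out_vals[ok] = b.astype(float) * u[ok]

    out = cond_values.copy()
    out["kind"] = "composite012_imputed"
    out["s0_at_w"] = s0w
    out["value"] = out_vals
    return out
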