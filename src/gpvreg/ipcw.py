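"""Inverse-probability-of-censoring weights for observed transition times.

A 0->1 transition (donor identification) at waiting time w is only observed if
the subject is still alive and uncensored at w, so the observed waiting-time
distribution q(w) over-represents short waits relative to the true law
f01(w).  The probability of still being observable at w,
G(w) = P(no 0->2 event and no censoring before w), is estimated by a
Kaplan-Meier fit on the whole sample in which censorings and direct 0->2
events count as events and observed transitions count as censorings.  Each
observed transition is then up-weighted by 1/G_hat(w_i-), normalised so the m
weights sum to m:

    gamma_i = p_hat_m / G_hat(w_i-),   p_hat_m = m / sum_j 1/G_hat(w_j-).

G is read as the left limit G(w-): the weight is the inverse probability of
*reaching* w observable, so a composite event at exactly w never discounts the
subject's own observed transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .km import KaplanMeierCurve, fit_km
from .pseudo import W_TOL_DECIMALS, transition_mask

__all__ = ["WeightTable", "fit_observability_curve", "compute_weights",
           "marginal_survival_donor"]


@dataclass
class WeightTable:
    """Per-transition-subject IPCW weights and implied distributions."""

    table: pd.DataFrame        # subject_id, waiting_time, G_at_w, gamma
    p_m: float                 # common normaliser
    q_hat: pd.Series           # observed waiting-time mass per distinct w
    f01_hat: pd.Series         # weight-corrected mass per distinct w

    @property
    def gamma(self) -> np.ndarray:
        return self.table["gamma"].to_numpy()

    @property
    def m(self) -> int:
        return len(self.table)


def fit_observability_curve(df: pd.DataFrame) -> KaplanMeierCurve:
    """Kaplan-Meier estimate of G(w), the 'still observable' probability.

    Non-transition subjects contribute an event at their follow-up end
    (whether 0->2 event or censoring -- both end observability); transition
    subjects contribute a censored observation at w_i.
    """
    trans = transition_mask(df)
    time = np.where(trans, df["waiting_time"].to_numpy(dtype=float),
                    df["time"].to_numpy(dtype=float))
    event = np.where(trans, 0, 1)
    return fit_km(time, event)


def compute_weights(curve: KaplanMeierCurve, waiting_times) -> WeightTable:
    """IPCW weights gamma_i for the observed transitions.

    ``waiting_times`` may be an array of w_i or a DataFrame of subjects, in
    which case the observed transitions are taken from it.
    """
    if isinstance(waiting_times, pd.DataFrame):
        sub = waiting_times.loc[transition_mask(waiting_times)]
        ids = sub["subject_id"].to_numpy()
        w = sub["waiting_time"].to_numpy(dtype=float)
        index = sub.index
    else:
        w = np.asarray(waiting_times, dtype=float)
        ids = np.arange(len(w))
        index = None
    m = len(w)
    if m == 0:
        raise ValueError("no observed transitions: weights undefined")

    g = np.array([curve.survival_at(wi, side="left") for wi in w])
    if np.any(g <= 0):
        bad = np.unique(np.round(w[g <= 0], W_TOL_DECIMALS))
        raise ValueError(
            f"G_hat(w-) = 0 at waiting time(s) {bad.tolist()}: observability "
            "inestimable in the tail"
        )
    p_m = m / np.sum(1.0 / g)
    gamma = p_m / g

    wr = np.round(w, W_TOL_DECIMALS)
    q_hat = pd.Series(wr).value_counts(normalize=True).sort_index()
    f01_hat = (pd.Series(gamma, index=wr).groupby(level=0).sum() / m
               ).sort_index()

    table = pd.DataFrame(
        {"subject_id": ids, "waiting_time": w, "G_at_w": g, "gamma": gamma},
        index=index,
    )
    return WeightTable(table=table, p_m=float(p_m), q_hat=q_hat,
                       f01_hat=f01_hat)


def marginal_survival_donor(weights: WeightTable,
                            composite: pd.DataFrame) -> float:
    """Weighted mean V1_bar = (1/m) sum gamma_i V_i -- estimates S1(t*)."""
    merged_ok = np.array_equal(
        weights.table["subject_id"].to_numpy(),
        composite["subject_id"].to_numpy(),
    )
    if not merged_ok:
        raise ValueError("weight table and composite pseudo-value table are "
                         "not aligned on subject_id")
    return float(np.mean(weights.gamma * composite["value"].to_numpy()))
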