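"""Three-state survival simulator with waiting-time-dependent hazard switch.

Subjects start in state 0.  A fraction of them (those "with a donor") is
assigned a waiting time W from a waiting-time law on (0, t_search]; at W the
subject moves to the transient state 1 unless it has already reached the
absorbing state 2 (failure) or been censored.  Before the transition the
hazard of failure is lambda_02(t); afterwards it is lambda_12 on the clock
t - w (time since transition), so survival with a fixed waiting time w is

    S1(t | w) = exp(-[ Lam_02(w) + Lam_12(t - w) ])          (t >= w)

and subjects without a donor follow S0(t) = exp(-Lam_02(t)) throughout
(exogeneity: donor availability does not alter the pre-transition hazard).
Hazards are piecewise constant with an optional cure fraction pi, giving
mixture survival pi + (1 - pi) exp(-H(t)) and a plateau of long-term
survivors.  Failure times are drawn by inversion of the cumulative hazard;
uniform censoring is superimposed independently.  The waiting time is
recorded in the output only when the transition happens before failure and
censoring -- exactly the partial observability the analysis corrects for.

Randomness is counter-based (Philox): each of the four variates (donor
status, waiting time, failure, censoring) has its own stream and subject j
always reads position j, so one subject's draws do not depend on n or on the
other subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PiecewiseHazard", "ScenarioSpec", "simulate",
           "calibrate_constant_hazard", "calibrate_post_hazard",
           "scenario_I_spec"]


@dataclass
class PiecewiseHazard:
    """Piecewise-constant hazard with an optional cure fraction.

    ``breaks`` are interval start points (the first must be 0); ``rates`` the
    hazard on each interval, the last extending to infinity.  With a cure
    fraction pi the survival is the mixture pi + (1 - pi) exp(-H(t)) and the
    effective cumulative hazard plateaus at -log(pi).
    """

    breaks: np.ndarray
    rates: np.ndarray
    cure: float = 0.0

    def __post_init__(self):
        self.breaks = np.atleast_1d(np.asarray(self.breaks, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if self.breaks[0] != 0 or np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must start at 0 and increase")
        if len(self.breaks) != len(self.rates):
            raise ValueError("breaks and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("hazard rates must be non-negative")
        if not 0 <= self.cure <= 1:
            raise ValueError("cure fraction must lie in [0, 1]")
        widths = np.diff(self.breaks)
        self._cum = np.concatenate([[0.0],
                                    np.cumsum(self.rates[:-1] * widths)])

    @classmethod
    def constant(cls, rate: float, cure: float = 0.0) -> "PiecewiseHazard":
        return cls(np.array([0.0]), np.array([float(rate)]), cure)

    def plain_cumhaz(self, t):
        """H(t) of the uncured component."""
        t = np.asarray(t, dtype=float)
        k = np.clip(np.searchsorted(self.breaks, t, side="right") - 1,
                    0, len(self.rates) - 1)
        return self._cum[k] + self.rates[k] * (t - self.breaks[k])

    def plain_cumhaz_inv(self, h):
        """Smallest t with H(t) >= h; inf when H plateaus below h."""
        h = np.asarray(h, dtype=float)
        k = np.clip(np.searchsorted(self._cum, h, side="right") - 1,
                    0, len(self.rates) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.breaks[k] + (h - self._cum[k]) / self.rates[k]
        # zero-rate stretch that never accumulates enough hazard
        t = np.where((self.rates[k] == 0) & (h > self._cum[k]), np.inf, t)
        return t

    def survival(self, t):
        """Mixture survival pi + (1 - pi) exp(-H(t))."""
        return self.cure + (1.0 - self.cure) * np.exp(-self.plain_cumhaz(t))

    def cumhaz(self, t):
        """Effective cumulative hazard -log survival of the mixture."""
        return -np.log(self.survival(t))

    def cumhaz_inv(self, e):
        """Invert the mixture cumulative hazard; inf for cured draws."""
        e = np.asarray(e, dtype=float)
        s = np.exp(-e)
        cured = s <= self.cure
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.log((s - self.cure) / (1.0 - self.cure))
        t = np.where(cured, np.inf, self.plain_cumhaz_inv(np.where(cured, 0.0, h)))
        return t


@dataclass
class ScenarioSpec:
    """A complete data-generating configuration for the three-state process.

    ``waiting_support`` / ``waiting_probs`` give a discrete waiting-time law
    on (0, t_search]; ``post_hazards`` maps each support point to the hazard
    after transition (clock = time since transition).  Alternatively a single
    shared post hazard may be given.  Censoring is Uniform(censor_range).
    """

    donor_fraction: float
    waiting_support: np.ndarray
    waiting_probs: np.ndarray
    pre_hazard: PiecewiseHazard
    post_hazards: dict
    censor_range: tuple
    t_star: float = 5.0
    t_search: float = 5.0
    n: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.waiting_support = np.asarray(self.waiting_support, dtype=float)
        self.waiting_probs = np.asarray(self.waiting_probs, dtype=float)
        if not 0 <= self.donor_fraction <= 1:
            raise ValueError("donor_fraction must lie in [0, 1]")
        if not np.isclose(self.waiting_probs.sum(), 1.0):
            raise ValueError("waiting-time masses must sum to 1")
        if np.any(self.waiting_support <= 0) or np.any(
                self.waiting_support > self.t_search):
            raise ValueError("waiting-time support must lie in (0, t_search]")
        if not self.t_search <= self.t_star:
            raise ValueError("t_search must not exceed t_star")
        a, b = self.censor_range
        if not a < b:
            raise ValueError("censor_range must satisfy a < b")
        cures = [self.pre_hazard.cure] + [h.cure for h in
                                          self.post_hazards.values()]
        if any(c > 0 for c in cures) and not np.isfinite(b):
            raise ValueError("a cure fraction requires a finite censoring "
                             "bound (otherwise follow-up is infinite)")
        missing = [w for w in self.waiting_support
                   if w not in self.post_hazards]
        if missing:
            raise ValueError(f"no post-transition hazard for w = {missing}")

    # ---- closed-form truths implied by the spec -------------------------

    def s0(self, t):
        """Survival without donor, S0(t)."""
        return self.pre_hazard.survival(t)

    def s1_given_w(self, t, w):
        """Survival with a donor found at w, S1(t|w) (t >= w)."""
        pre = self.pre_hazard.cumhaz(min(t, w))
        post = self.post_hazards[w].cumhaz(max(t - w, 0.0))
        return float(np.exp(-(pre + post)))

    def s1(self, t):
        """Marginal survival with donor: sum_w f01(w) S1(t|w)."""
        return float(np.sum(self.waiting_probs *
                            [self.s1_given_w(t, w)
                             for w in self.waiting_support]))

    def censoring_survival(self, t):
        a, b = self.censor_range
        return float(np.clip((b - t) / (b - a), 0.0, 1.0)) if t > a else 1.0

    def observability(self, w):
        """G(w): probability of no 0->2 event and no censoring before w."""
        return float(self.s0(w)) * self.censoring_survival(w)

    def q_true(self):
        """Observable waiting-time law q(w) ~ f01(w) G(w), normalised."""
        g = np.array([self.observability(w) for w in self.waiting_support])
        q = self.waiting_probs * g
        return q / q.sum()

    def gamma_true(self):
        """Population IPCW weight per support point: f01(w)/q(w)."""
        return self.waiting_probs / self.q_true()


def _streams(seed: int, n: int) -> np.ndarray:
    """Four counter-based uniform streams of length n (rows)."""
    ss = np.random.SeedSequence(seed)
    out = np.empty((4, n))
    for k, child in enumerate(ss.spawn(4)):
        out[k] = np.random.Generator(np.random.Philox(child)).random(n)
    return out


def simulate(spec: ScenarioSpec, n: int | None = None,
             seed: int | None = None, include_truth: bool = False
             ) -> pd.DataFrame:
    """Draw a subject-level dataset from ``spec``.

    Returns a DataFrame with columns subject_id, time, event, waiting_time
    (NaN when the transition was not observed); with ``include_truth`` the
    latent donor status and waiting time are appended for diagnostics.
    """
    n = spec.n if n is None else int(n)
    seed = spec.seed if seed is None else int(seed)
    u_donor, u_wait, u_fail, u_cens = _streams(seed, n)

    donor = u_donor < spec.donor_fraction
    cum = np.cumsum(spec.waiting_probs)
    w_idx = np.searchsorted(cum, u_wait, side="right")
    w_idx = np.clip(w_idx, 0, len(spec.waiting_support) - 1)
    w = spec.waiting_support[w_idx]

    e = -np.log1p(-u_fail)          # Exp(1) by inversion, one uniform each
    t_fail = spec.pre_hazard.cumhaz_inv(e)   # non-donor path / pre-transition
    for j, wv in enumerate(spec.waiting_support):
        pre_w = float(spec.pre_hazard.cumhaz(wv))
        # donors surviving state 0 up to w switch to the post hazard there
        sel = donor & (w_idx == j) & (e >= pre_w)
        if not np.any(sel):
            continue
        t_fail[sel] = wv + spec.post_hazards[wv].cumhaz_inv(e[sel] - pre_w)

    a, b = spec.censor_range
    t_cens = a + (b - a) * u_cens
    time = np.minimum(t_fail, t_cens)
    event = (t_fail <= t_cens).astype(int)
    observed_w = donor & (w < time)
    waiting = np.where(observed_w, w, np.nan)

    out = pd.DataFrame({
        "subject_id": np.arange(n),
        "time": time,
        "event": event,
        "waiting_time": waiting,
    })
    if include_truth:
        out["true_donor"] = donor
        out["true_waiting_time"] = np.where(donor, w, np.nan)
    return out


def calibrate_constant_hazard(s_target: float, horizon: float) -> float:
    """Constant rate with survival ``s_target`` at ``horizon``."""
    if not 0 < s_target < 1:
        raise ValueError("target survival must lie in (0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return -np.log(s_target) / horizon


def calibrate_post_hazard(s1_target: float, w: float, t_star: float,
                          pre_rate: float) -> float:
    """Constant post-transition rate matching S1(t*|w) given the pre rate.

    Solves s1_target = exp(-pre_rate*w) * exp(-rate*(t_star - w)).
    """
    if not 0 < s1_target < 1:
        raise ValueError("target survival must lie in (0, 1)")
    if not 0 < w < t_star:
        raise ValueError("need 0 < w < t_star")
    rate = (-np.log(s1_target) - pre_rate * w) / (t_star - w)
    if rate < 0:
        raise ValueError(
            "target survival exceeds pre-transition survival at w: "
            "implied post-transition hazard would be negative"
        )
    return float(rate)


def scenario_I_spec(n: int = 1000, seed: int = 0) -> ScenarioSpec:
    """The discrete-waiting-time benchmark scenario.

    75% of subjects have a donor, waiting times equally likely at 0.5, 1 and
    3 years; constant pre-transition hazard calibrated to S0(5) = 0.333 and
    per-w constant post-transition hazards calibrated to S1(5|w) = 0.733,
    0.681 and 0.451; Uniform(0, 6) censoring; t* = t_search = 5.
    """
    support = np.array([0.5, 1.0, 3.0])
    targets = {0.5: 0.733, 1.0: 0.681, 3.0: 0.451}
    pre_rate = calibrate_constant_hazard(0.333, 5.0)
    post = {
        w: PiecewiseHazard.constant(
            calibrate_post_hazard(targets[w], w, 5.0, pre_rate))
        for w in support
    }
    return ScenarioSpec(
        donor_fraction=0.75,
        waiting_support=support,
        waiting_probs=np.full(3, 1.0 / 3.0),
        pre_hazard=PiecewiseHazard.constant(pre_rate),
        post_hazards=post,
        censor_range=(0.0, 6.0),
        t_star=5.0,
        t_search=5.0,
        n=n,
        seed=seed,
    )
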