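import numpy as np
import pandas as pd
import pytest

import gpvreg as g


def naive_loo_survival(time, event, t_star):
    """Independent oracle: refit the Kaplan-Meier curve n times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    out = np.empty(len(time))
    for i in range(len(time)):
        keep = np.ones(len(time), dtype=bool)
        keep[i] = False
        out[i] = g.fit_km(time[keep], event[keep]).survival_at(t_star)
    return out


def random_survival_sample(rng, n=None, ties=True):
    """Small right-censored sample with frequent ties to stress conventions."""
    n = n or rng.integers(2, 51)
    if ties:
        time = rng.integers(1, 8, size=n).astype(float)
    else:
        time = rng.exponential(3.0, size=n)
    event = rng.integers(0, 2, size=n)
    return time, event


def subjects_frame(time, event, waiting=None):
    n = len(time)
    w = np.full(n, np.nan) if waiting is None else np.asarray(waiting, float)
    return pd.DataFrame({
        "subject_id": np.arange(n),
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event),
        "waiting_time": w,
    })


@pytest.fixture(scope="session")
def scenario_I():
    return g.scenario_I_spec(n=1000, seed=0)


@pytest.fixture(scope="session")
def scenario_I_study(scenario_I):
    """The benchmark Monte-Carlo run: 1000 replicates at n = 1000."""
    return g.run_study(scenario_I, replicates=1000, n=1000, seed=1234)
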