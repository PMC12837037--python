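import numpy as np
import pandas as pd
import pytest

from omicox.synthdata import SurvivalOutcome


def weibull_ph_data(seed, n, beta, shape=1.3, scale=None, horizon=10.0,
                    censor_scale=None, target_events=0.5):
    """Weibull proportional-hazards fixture with known coefficients."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.standard_normal((n, p))
    lp = X @ np.asarray(beta, dtype=float)
    if scale is None:
        # crude scale so that roughly target_events of subjects fail by horizon
        scale = horizon / (-np.log(1.0 - target_events)) ** (1.0 / shape)
    T = scale * (-np.log(rng.random(n)) / np.exp(lp)) ** (1.0 / shape)
    C = (
        rng.exponential(censor_scale, n)
        if censor_scale is not None
        else np.full(n, np.inf)
    )
    t = np.minimum(np.minimum(T, C), horizon)
    e = ((T <= C) & (T <= horizon)).astype(int)
    return X, SurvivalOutcome(t, e)


@pytest.fixture
def small_cox_fixture():
    X, out = weibull_ph_data(1, 300, [0.6, -0.4, 0.3], censor_scale=20.0)
    return pd.DataFrame(X, columns=["a", "b", "c"]), out


def brute_force_c(risk, time, event):
    """O(n^2) pair-enumeration oracle for Harrell's C."""
    conc = comp = 0.0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] or (time[i] == time[j] and not event[j]):
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1.0
                elif risk[i] == risk[j]:
                    conc += 0.5
    if comp == 0:
        raise ValueError("no comparable pairs")
    return conc / comp
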