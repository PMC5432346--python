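"""Independent brute-force oracles used to verify the survival primitives.

Everything here is written directly from the defining formulas, without
touching the package's implementation paths: the Cox partial likelihood is
coded explicitly and maximized by scalar golden-section search; the
log-rank observed/expected/variance sums are accumulated time by time; the
Fisher two-sided p enumerates the hypergeometric support with exact integer
binomials; Kaplan-Meier is the textbook product over event times.
"""

import math

import numpy as np
from scipy import optimize


def cox_partial_loglik_1d(beta, time, event, x):
    """Explicit Breslow log partial likelihood, one covariate, no tied events."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        denom = sum(math.exp(beta * x[j]) for j in risk)
        ll += beta * x[i] - math.log(denom)
    return ll


def cox_brute_force_1d(time, event, x, bounds=(-8.0, 8.0)):
    """Golden-section maximizer of the explicit partial likelihood."""
    res = optimize.minimize_scalar(
        lambda b: -cox_partial_loglik_1d(b, time, event, x),
        bounds=bounds, method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def logrank_by_hand(time, event, group):
    """Two-group log-rank chi-squared from per-time O/E/V accumulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = sorted(set(group.tolist()))
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1].tolist())):
        at_risk = time >= t
        n = at_risk.sum()
        n0 = (at_risk & (group == labels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d0 = ((time == t) & (event == 1) & (group == labels[0])).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n0 / n) * (1 - n0 / n)
    return o_minus_e, var, (o_minus_e**2 / var if var > 0 else 0.0)


def fisher_two_sided_by_enumeration(table):
    """Two-sided Fisher p via exact hypergeometric enumeration (math.comb)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    probs = []
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    for k in range(lo, hi + 1):
        probs.append(math.comb(r1, k) * math.comb(r2, c1 - k))
    p_obs = math.comb(r1, a) * math.comb(r2, c)
    total = sum(w for w in probs if w <= p_obs)
    return total / denom


def km_by_hand(time, event):
    """Textbook product-limit estimate at each distinct event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(time[event == 1].tolist())):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
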