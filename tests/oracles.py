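"""Independent brute-force reference implementations used as oracles.

Deliberately written from scratch with the math module and plain loops —
they must stay independent of the package code paths they check.
"""

import math


def egfr_reference(scr: float, age: float, female: bool) -> float:
    kappa = 0.7 if female else 0.9
    alpha = -0.241 if female else -0.302
    r = scr / kappa
    value = 142.0
    value *= (r if r < 1 else 1.0) ** alpha
    value *= (r if r > 1 else 1.0) ** -1.200
    value *= 0.9938**age
    if female:
        value *= 1.012
    return value


def pacr_from_pcr_reference(pcr: float) -> float:
    t1 = 0.3072 * math.log(min(pcr / 50.0, 1.0))
    t2 = 1.5793 * math.log(max(min(pcr / 500.0, 1.0), 0.1))
    t3 = 1.1266 * math.log(max(pcr / 500.0, 1.0))
    return math.exp(5.3920 + t1 + t2 + t3)


_DIP = {"negative": 0.0, "trace": 0.7539, "plus": 1.7243, "plusplus": 3.3475, "above_plusplus": 4.6399}


def pacr_from_dipstick_reference(category: str) -> float:
    return math.exp(2.4738 + _DIP[category])


def km_reference(times, events):
    """Naive O(n²) product-limit estimate.

    Returns (event_times, survival) where survival[i] is S at event_times[i].
    Events precede censorings at tied times.
    """
    data = sorted(zip(times, events))
    event_times = sorted({t for t, e in data if e})
    surv = []
    s = 1.0
    for t in event_times:
        n_at_risk = sum(1 for ti, _ in data if ti >= t)
        d = sum(1 for ti, ei in data if ti == t and ei)
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return event_times, surv


def km_ci_at(t, event_times, surv):
    ci = 0.0
    for et, s in zip(event_times, surv):
        if et <= t:
            ci = 1.0 - s
    return ci
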