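"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain minute-by-minute (or element-by-
element) Python scans, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math


def brute_runs(counts):
    """Run-length scan of a count vector (None/NaN = missing).

    Returns a list of (start, end, kind, censored) with kind in
    {sleep, rest, wake} and end exclusive.
    """

    def code(c):
        if c is None or (isinstance(c, float) and math.isnan(c)):
            return "missing"
        return "active" if c > 0 else "inactive"

    runs = []
    i = 0
    n = len(counts)
    while i < n:
        j = i
        while j < n and code(counts[j]) == code(counts[i]):
            j += 1
        runs.append((i, j, code(counts[i])))
        i = j
    out = []
    for idx, (s, e, c) in enumerate(runs):
        if c == "missing":
            continue
        if c == "active":
            kind = "wake"
        else:
            kind = "sleep" if e - s >= 5 else "rest"
        censored = (
            s == 0 or e == n
            or (idx > 0 and runs[idx - 1][2] == "missing")
            or (idx + 1 < len(runs) and runs[idx + 1][2] == "missing")
        )
        out.append((s, e, kind, censored))
    return out


def brute_total_sleep(counts):
    return sum(e - s for s, e, kind, _ in brute_runs(counts) if kind == "sleep")


def brute_sleep_bout_count(counts):
    return sum(1 for _, _, kind, _ in brute_runs(counts) if kind == "sleep")


def brute_waking_activity(counts):
    sleep_minutes = set()
    for s, e, kind, _ in brute_runs(counts):
        if kind == "sleep":
            sleep_minutes.update(range(s, e))
    num = 0.0
    den = 0
    for i, c in enumerate(counts):
        if c is None or (isinstance(c, float) and math.isnan(c)):
            continue
        if i not in sleep_minutes:
            num += c
            den += 1
    return num / den if den else float("nan")


def brute_latency(counts, t0, horizon=720):
    """Minutes from t0 to the first >=5-min zero run starting in [t0, t0+horizon)."""
    n = len(counts)
    for t in range(t0, min(t0 + horizon, n)):
        if counts[t] == 0 and (t == 0 or counts[t - 1] != 0):
            run = 0
            while t + run < n and counts[t + run] == 0:
                run += 1
            if run >= 5:
                return t - t0
    return None


def brute_death(counts, quiescence=720):
    last_active = None
    for i, c in enumerate(counts):
        if c is not None and not (isinstance(c, float) and math.isnan(c)) and c > 0:
            last_active = i
    candidate = 0 if last_active is None else last_active + 1
    return candidate if len(counts) - candidate >= quiescence else None


def brute_arousal(counts, pulse_start, horizon=180):
    """(eligible, latency, silent_3h) by direct minute scan."""
    # eligible: inside a maximal zero run of length >= 5 covering pulse_start
    s = pulse_start
    if counts[s] != 0:
        eligible = False
    else:
        a = s
        while a > 0 and counts[a - 1] == 0:
            a -= 1
        b = s
        while b < len(counts) and counts[b] == 0:
            b += 1
        eligible = b - a >= 5
    latency = None
    for t in range(pulse_start, min(pulse_start + horizon + 1, len(counts))):
        if counts[t] and counts[t] > 0:
            latency = t - pulse_start
            break
    silent = all(
        not counts[t]
        for t in range(pulse_start + 1, min(pulse_start + 1 + horizon, len(counts)))
    )
    return eligible, latency, silent


def ecdf_sup_distance(a, b):
    """Two-sample sup-|ECDF difference| by direct evaluation at all points."""
    points = sorted(set(a) | set(b))
    best = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


def fisher_exact_two_sided(table):
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small
    relative tolerance for ties, matching the conventional definition).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_choose(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    def log_p(x):
        return (
            log_choose(r1, x) + log_choose(r2, c1 - x) - log_choose(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    lp_obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def pairwise_distances(xs, ys):
    return [
        math.hypot(x1 - x0, y1 - y0)
        for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:]))
    ]
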