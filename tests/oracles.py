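"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and dict tallies,
deliberately sharing no code path with the package, so agreement between
the two routes is a meaningful check.
"""

from __future__ import annotations

import math


def brute_pattern_probs(x, m=3, tau=1, ddof=1):
    """Weighted ordinal-pattern probabilities by explicit enumeration.

    Returns a dict pattern-tuple -> probability.
    """
    x = [float(v) for v in x]
    T = len(x)
    n = T - (m - 1) * tau
    assert n >= 1, "series too short"
    span = max(x) - min(x)
    eps = 1e-12 * (span if span > 0 else 1.0)
    pats, ws = [], []
    for i in range(n):
        y = [x[i + j * tau] for j in range(m)]
        mean = sum(y) / m
        var = sum((v - mean) ** 2 for v in y) / (m - ddof)
        w = math.sqrt(var) / max(abs(mean), eps)
        pat = tuple(sorted(range(m), key=lambda j: (y[j], j)))
        pats.append(pat)
        ws.append(w)
    total = sum(ws)
    tally: dict = {}
    if total > 0:
        for pat, w in zip(pats, ws):
            tally[pat] = tally.get(pat, 0.0) + w
        return {pat: w / total for pat, w in tally.items()}
    for pat in pats:
        tally[pat] = tally.get(pat, 0.0) + 1.0
    return {pat: c / n for pat, c in tally.items()}


def entropy_of_probs(probs_by_pattern, m):
    h = -sum(p * math.log2(p) for p in probs_by_pattern.values() if p > 0)
    return h / math.log2(math.factorial(m))


def brute_aspe(x, m=3, tau=1, ddof=1):
    """Normalized amplitude-weighted permutation entropy, loop version."""
    return entropy_of_probs(brute_pattern_probs(x, m, tau, ddof), m)


def brute_coarse_grain(x, s):
    """Phase-shifted window averages, 1-based index algebra spelled out."""
    x = [float(v) for v in x]
    T = len(x)
    subs = []
    for k in range(1, s + 1):
        sub = []
        j = 1
        while j * s + k - 1 <= T:
            window = x[(j - 1) * s + k - 1 : j * s + k - 1]
            sub.append(sum(window) / s)
            j += 1
        subs.append(sub)
    return subs


def brute_rcmaspe_at_scale(x, s, m=3, tau=1):
    """Average the per-subsequence pattern distributions, then entropy."""
    subs = brute_coarse_grain(x, s)
    avg: dict = {}
    for sub in subs:
        for pat, p in brute_pattern_probs(sub, m, tau).items():
            avg[pat] = avg.get(pat, 0.0) + p / s
    return entropy_of_probs(avg, m)


def brute_tsmaspe_at_lag(x, k, m=3, tau=1):
    """Average ASPE over the k interleaved subsequences."""
    x = [float(v) for v in x]
    subs = [x[j::k] for j in range(k)]
    return sum(brute_aspe(sub, m, tau) for sub in subs) / k
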