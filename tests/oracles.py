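"""Independent brute-force oracles used only by the tests.

Each oracle re-states the documented rule in the most naive way possible
(per-sample loops, full enumeration), deliberately sharing no code with the
package implementation.
"""

from itertools import permutations, product

import numpy as np


def naive_threshold_scan(x, pos_thr, neg_thr, dead_samples):
    """Per-sample re-statement of the detection rule.

    Walk the trace one sample at a time; on the first sample strictly
    outside the thresholds (and past any dead time) look at the next
    ``dead_samples`` samples, take the first largest-|v| sample as the
    extremum, then skip everything within ``dead_samples`` of the extremum.
    Returns a list of (extremum_index, polarity, amplitude).
    """
    events = []
    n = len(x)
    i = 0
    while i < n:
        v = x[i]
        if v > pos_thr or v < neg_thr:
            best = i
            for j in range(i, min(i + dead_samples, n)):
                if abs(x[j]) > abs(x[best]):
                    best = j
            amp = x[best]
            events.append((best, 1 if amp > 0 else -1, amp))
            i = best + dead_samples
        else:
            i += 1
    return events


def naive_isi_list(times_by_electrode, max_isi_s):
    """All consecutive-pair ISIs per electrode, <= max, pooled."""
    isis = []
    for times in times_by_electrode.values():
        ts = sorted(times)
        for a, b in zip(ts, ts[1:]):
            if b - a <= max_isi_s:
                isis.append(b - a)
    return isis


def mann_whitney_exact_p(x, y, tails="two-sided"):
    """Two-sided exact Mann-Whitney p by enumerating label permutations."""
    x, y = list(x), list(y)
    m, n = len(x), len(y)
    pooled = np.asarray(x + y, dtype=float)

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    ranks = midranks(pooled)

    def u_of(label_pattern):
        r1 = sum(r for r, lab in zip(ranks, label_pattern) if lab)
        return r1 - m * (m + 1) / 2.0

    obs = u_of([1] * m + [0] * n)
    mu = m * n / 2.0
    pats = sorted(set(permutations([1] * m + [0] * n)))
    us = [u_of(p) for p in pats]
    if tails == "two-sided":
        return sum(1 for u in us if abs(u - mu) >= abs(obs - mu) - 1e-12) / len(us)
    raise ValueError(tails)


def wilcoxon_exact_p(diffs, tails="two-sided"):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    mags = np.abs(np.asarray(d, dtype=float))
    order = np.argsort(mags, kind="stable")
    ranks = np.empty(n)
    i = 0
    sm = mags[order]
    while i < n:
        j = i
        while j < n and sm[j] == sm[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    w_minus = sum(ranks) - w_plus
    obs = min(w_plus, w_minus)
    count = 0
    total = 0
    for signs in product([1, -1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        wm = sum(ranks) - wp
        total += 1
        if min(wp, wm) <= obs + 1e-12:
            count += 1
    if tails == "two-sided":
        return count / total
    raise ValueError(tails)


def pearson_chi2_closed_form(a, b, c, d):
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
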