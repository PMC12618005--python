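"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately uses a different algorithmic route than the
implementation it checks (scan-based run-length encoding vs vectorised
diffs, explicit step-up loop vs library BH, python running sum vs vectorised
cumulative sums, per-epoch chain stepping vs geometric dwell times).
"""

from __future__ import annotations

from itertools import groupby

import numpy as np


def rle_bouts(immobile, frame_rate, min_bout_s, max_gap_s=0.0, t0=0.0):
    """Run-length-encoding sleep-bout oracle.

    Scans the flag sequence element by element with groupby, merges immobile
    runs across mobile gaps <= max_gap_s, and keeps runs >= min_bout_s.
    Returns a list of (start_s, end_s) tuples.
    """
    runs = []
    pos = 0
    for val, grp in groupby(immobile):
        n = sum(1 for _ in grp)
        if val:
            runs.append([pos, pos + n])
        pos += n
    if max_gap_s > 0 and len(runs) > 1:
        merged = [runs[0]]
        for r in runs[1:]:
            if (r[0] - merged[-1][1]) / frame_rate <= max_gap_s + 1e-12:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    period = 1.0 / frame_rate
    return [
        (t0 + i0 * period, t0 + i1 * period)
        for i0, i1 in runs
        if (i1 - i0) * period >= min_bout_s - 1e-9
    ]


def bh_stepup(p):
    """Explicit Benjamini–Hochberg step-up loop."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def gsea_es(scores, hits, weight=1.0):
    """Plain-python running-sum enrichment-score oracle.

    scores sorted descending; hits a boolean sequence.  Walks the list
    accumulating the weighted hit CDF minus the miss CDF and returns the
    extreme (signed) deviation.
    """
    n = len(scores)
    k = sum(bool(h) for h in hits)
    if k == n:
        return 1.0
    total_w = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    running = 0.0
    best = 0.0
    for s, h in zip(scores, hits):
        if h:
            running += abs(s) ** weight / total_w
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def step_two_state_chain(n_epochs, p_doze, p_wake, rng, initial_quiescent=False):
    """Per-epoch two-state chain stepping (independent of the dwell-time route)."""
    states = np.empty(n_epochs, dtype=bool)
    q = initial_quiescent
    u = rng.random(n_epochs)
    for i in range(n_epochs):
        states[i] = q
        if q:
            if u[i] < p_wake:
                q = False
        else:
            if u[i] < p_doze:
                q = True
    return states
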