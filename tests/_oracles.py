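"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops / direct sums, deliberately
separate from the optimized implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# direct-sum time-domain features


def time_domain_reference(x, zc_thr=0.0, ssc_thr=0.0, wamp_thr=0.05,
                          myop_thr=0.05):
    x = [float(v) for v in x]
    n = len(x)
    out = {}
    out["IEMG"] = sum(abs(v) for v in x)
    out["MAV"] = out["IEMG"] / n
    w1 = [1.0 if 0.25 * n <= i <= 0.75 * n else 0.5 for i in range(n)]
    out["MAV1"] = sum(w * abs(v) for w, v in zip(w1, x)) / n
    w2 = []
    for i in range(n):
        if i < 0.25 * n:
            w2.append(4.0 * i / n)
        elif i > 0.75 * n:
            w2.append(4.0 * (n - i) / n)
        else:
            w2.append(1.0)
    out["MAV2"] = sum(w * abs(v) for w, v in zip(w2, x)) / n
    half = n // 2
    out["MAVS"] = (sum(abs(v) for v in x[half:]) / (n - half)
                   - sum(abs(v) for v in x[:half]) / half)
    out["RMS"] = math.sqrt(sum(v * v for v in x) / n)
    out["VAR"] = sum(v * v for v in x) / (n - 1)
    out["SSI"] = sum(v * v for v in x)
    d = [x[i + 1] - x[i] for i in range(n - 1)]
    out["WL"] = sum(abs(v) for v in d)
    out["DAMV"] = out["WL"] / (n - 1)
    out["DASDV"] = math.sqrt(sum(v * v for v in d) / (n - 1))
    nz = [abs(v) for v in x if v != 0]
    out["LD"] = math.exp(sum(math.log(v) for v in nz) / n) if len(nz) == n \
        else (0.0 if not nz else math.exp(
            sum(math.log(v) for v in nz) / len(nz)))
    out["TM"] = abs(sum(v ** 3 for v in x) / n)
    out["V"] = abs(sum(v ** 3 for v in x) / n) ** (1.0 / 3.0)
    out["M2"] = sum(v * v for v in d)
    out["ZC"] = sum(1 for i in range(n - 1)
                    if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= zc_thr)
    out["SSC"] = sum(1 for i in range(1, n - 1)
                     if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= ssc_thr)
    out["WAMP"] = sum(1 for v in d if abs(v) >= wamp_thr)
    out["MYOP"] = sum(1 for v in x if abs(v) >= myop_thr) / n
    out["MFL"] = math.log10(math.sqrt(sum(v * v for v in d)))
    return out


def tdpsd_reference(x):
    """Straight-line recomputation of the six spectral-moment descriptors."""
    x = [float(v) for v in x]
    d1 = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    d2 = [d1[i + 1] - d1[i] for i in range(len(d1) - 1)]
    m0 = math.sqrt(sum(v * v for v in x)) ** 0.1 / 0.1
    m2 = math.sqrt(sum(v * v for v in d1)) ** 0.1 / 0.1
    m4 = math.sqrt(sum(v * v for v in d2)) ** 0.1 / 0.1

    def slog(v):
        return math.log(max(abs(v), 1e-300))

    f1 = slog(m0)
    f2 = slog(m0 - m2)
    f3 = slog(m0 - m4)
    f4 = slog(m0 / max(math.sqrt(abs((m0 - m2) * (m0 - m4))), 1e-300))
    f5 = slog(m2 / max(math.sqrt(abs(m0 * m4)), 1e-300))
    f6 = slog(sum(abs(v) for v in d1) / max(sum(abs(v) for v in d2), 1e-300))
    return [f1, f2, f3, f4, f5, f6]


# ---------------------------------------------------------------------------
# naive Ward agglomeration (Lance-Williams on squared distances)


def naive_ward(points):
    """Greedy Ward agglomeration; returns merge heights (ascending order of
    execution) and the list of cluster-membership frozensets after each
    merge level, so any cut can be reconstructed."""
    pts = np.asarray(points, float)
    n = len(pts)
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((pts[i] - pts[j]) ** 2))
    heights = []
    merges = []
    next_id = n
    while len(clusters) > 1:
        (a, b), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(math.sqrt(best))
        new = clusters[a] | clusters[b]
        na, nb = sizes[a], sizes[b]
        merges.append(new)
        for k in list(clusters):
            if k in (a, b):
                continue
            nk = sizes[k]
            dka = d2[tuple(sorted((k, a)))]
            dkb = d2[tuple(sorted((k, b)))]
            dab = best
            upd = ((na + nk) * dka + (nb + nk) * dkb - nk * dab) / (
                na + nb + nk)
            d2[tuple(sorted((k, next_id)))] = upd
        for key in [key for key in d2 if a in key or b in key]:
            del d2[key]
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[next_id] = new
        sizes[next_id] = na + nb
        next_id += 1
    return np.array(heights), merges


def naive_gap_partition(points, gap_sd=2.0, gap_ratio=3.0):
    """Partition of point indices after cutting the naive Ward tree at the
    largest qualifying gap (same dual rule as the implementation, derived
    independently from the Lance-Williams recursion above)."""
    pts = np.asarray(points, float)
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [frozenset([0])]
    heights, merges = naive_ward(pts)
    best_i, best_ratio = None, 0.0
    for i in range(2, len(heights)):
        prev = heights[:i]
        pmax = prev.max()
        if pmax <= 0:
            continue
        ratio = heights[i] / pmax
        if (heights[i] > prev.mean() + gap_sd * prev.std()
                and ratio > gap_ratio and ratio > best_ratio):
            best_i, best_ratio = i, ratio
    if best_i is None:
        return [frozenset(range(n))]
    # apply merges with height strictly below the cut
    cut = (heights[best_i - 1] + heights[best_i]) / 2.0
    parts = {i: frozenset([i]) for i in range(n)}
    for h, group in zip(heights, merges):
        if h <= cut:
            for i in group:
                parts[i] = group
    # resolve to maximal groups
    out = []
    seen = set()
    for i in range(n):
        g = parts[i]
        # grow to the largest applied merge containing i
        for h, group in zip(heights, merges):
            if h <= cut and i in group and len(group) > len(g):
                g = group
        if g not in seen:
            out.append(g)
            seen.add(g)
    return out


# ---------------------------------------------------------------------------
# brute-force Mapper


def brute_mapper(X, k=2, n_intervals=3, overlap_pct=50.0,
                 gap_sd=2.0, gap_ratio=3.0):
    """Enumerate interval membership and cluster with the naive Ward oracle;
    returns (nodes, edges): nodes as (interval, frozenset of point indices),
    edges as frozenset pairs of node positions with shared counts."""
    X = np.asarray(X, float)
    n = len(X)
    fv = np.empty(n)
    for i in range(n):
        dists = sorted(math.dist(X[i], X[j]) for j in range(n) if j != i)
        fv[i] = dists[k - 2] if k >= 2 else 0.0
    lo, hi = fv.min(), fv.max()
    if hi <= lo:
        intervals = [(lo, lo)]
    else:
        frac = 1.0 - overlap_pct / 100.0
        length = (hi - lo) / (1.0 + (n_intervals - 1) * frac)
        stride = length * frac
        intervals = [(lo + i * stride, lo + i * stride + length)
                     for i in range(n_intervals)]
        intervals[-1] = (intervals[-1][0], hi)
    nodes = []
    for idx, (a, b) in enumerate(intervals):
        members = [i for i in range(n) if a <= fv[i] <= b]
        if not members:
            continue
        for part in naive_gap_partition(X[members], gap_sd, gap_ratio):
            nodes.append((idx, frozenset(members[i] for i in part)))
    edges = {}
    for u in range(len(nodes)):
        for v in range(u + 1, len(nodes)):
            if abs(nodes[u][0] - nodes[v][0]) != 1:
                continue
            shared = nodes[u][1] & nodes[v][1]
            if shared:
                edges[(u, v)] = len(shared)
    return fv, nodes, edges
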