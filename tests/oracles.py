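"""Independent brute-force oracles used by the test suite.

Everything here is written as plain enumeration, deliberately sharing no
code with the package implementations it checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def all_offsets(ndim):
    """One representative per +/- offset pair (13 in 3D, 4 in 2D)."""
    out = set()
    for off in product((-1, 0, 1), repeat=ndim):
        if off == (0,) * ndim:
            continue
        neg = tuple(-o for o in off)
        out.add(max(off, neg))
    return sorted(out)


def naive_glcm(levels, mask, n_levels, offset):
    """Symmetric normalized GLCM by looping over every voxel."""
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb = tuple(i + o for i, o in zip(idx, offset))
        if any(j < 0 or j >= s for j, s in zip(nb, shape)):
            continue
        if not mask[nb]:
            continue
        a, b = levels[idx] - 1, levels[nb] - 1
        counts[a, b] += 1
        counts[b, a] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def naive_glrlm(levels, mask, n_levels, offset, max_len):
    """Run-length counts by walking every line in the given direction."""
    counts = np.zeros((n_levels, max_len))
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(shape):
        if not mask[idx] or visited[idx]:
            continue
        prev = tuple(i - o for i, o in zip(idx, offset))
        if (
            all(0 <= j < s for j, s in zip(prev, shape))
            and mask[prev]
            and levels[prev] == levels[idx]
        ):
            continue  # not a run start
        # walk forward
        length = 0
        cur = idx
        while (
            all(0 <= j < s for j, s in zip(cur, shape))
            and mask[cur]
            and levels[cur] == levels[idx]
        ):
            visited[cur] = True
            length += 1
            cur = tuple(i + o for i, o in zip(cur, offset))
        counts[levels[idx] - 1, length - 1] += 1
    return counts


def naive_glszm(levels, mask, n_levels, max_size):
    """Zone counts via flood fill with full diagonal connectivity."""
    shape = levels.shape
    counts = np.zeros((n_levels, max_size))
    visited = np.zeros(shape, dtype=bool)
    nbrs = [off for off in product((-1, 0, 1), repeat=levels.ndim) if any(off)]
    for idx in np.ndindex(shape):
        if not mask[idx] or visited[idx]:
            continue
        lev = levels[idx]
        stack = [idx]
        visited[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in nbrs:
                nb = tuple(i + o for i, o in zip(cur, off))
                if any(j < 0 or j >= s for j, s in zip(nb, shape)):
                    continue
                if mask[nb] and not visited[nb] and levels[nb] == lev:
                    visited[nb] = True
                    stack.append(nb)
        counts[lev - 1, size - 1] += 1
    return counts


def naive_ngtdm(levels, mask, n_levels):
    """Per-level (n_i, p_i, s_i) by looping over voxels and neighborhoods."""
    shape = levels.shape
    nbrs = [off for off in product((-1, 0, 1), repeat=levels.ndim) if any(off)]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        vals = []
        for off in nbrs:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(j < 0 or j >= s for j, s in zip(nb, shape)):
                continue
            if mask[nb]:
                vals.append(levels[nb])
        if not vals:
            continue
        lev = levels[idx]
        n_i[lev - 1] += 1
        s_i[lev - 1] += abs(lev - np.mean(vals))
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


def naive_icc11(x):
    """One-way random single-measure ICC from explicit ANOVA sums."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_between = 0.0
    ss_within = 0.0
    for i in range(n):
        row_mean = x[i].sum() / k
        ss_between += k * (row_mean - grand) ** 2
        for j in range(k):
            ss_within += (x[i, j] - row_mean) ** 2
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return (msb - msw) / denom


def naive_c_index(scores, times, events):
    """Harrell's C by looping over ordered pairs.

    A pair is usable when the earlier time is an event (at tied times: one
    event and one censored subject). Higher score with earlier event is
    concordant; score ties count 0.5.
    """
    n = len(scores)
    usable = 0.0
    concordant = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or events[i] != 1:
                continue
            if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                usable += 1
                if scores[i] > scores[j]:
                    concordant += 1
                elif scores[i] == scores[j]:
                    concordant += 0.5
    if usable == 0:
        raise ValueError("no usable pairs")
    return concordant / usable


def naive_logrank_chi2(times, events, group):
    """Two-sample log-rank chi-square from explicit O-E sums."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
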