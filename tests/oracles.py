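"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, per-base counting,
neighbourhood expansion) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def canonical_motif_oracle(motif: str) -> str:
    """Exhaustive enumeration of rotations and reverse-complement rotations."""
    rc = "".join(_COMP[c] for c in reversed(motif))
    forms = []
    for s in (motif, rc):
        for i in range(len(s)):
            forms.append(s[i:] + s[:i])
    return min(forms)


def dbscan_oracle(values, eps, min_samples):
    """Brute-force DBSCAN with the deterministic border tie rule.

    Core = >= min_samples neighbours within eps (self included); clusters =
    connected components of cores; border joins its nearest core's cluster,
    lower-valued core on ties.  Returns labels with clusters numbered by
    ascending cluster minimum so labelings are comparable.
    """
    v = list(map(float, values))
    n = len(v)
    neigh = [
        [j for j in range(n) if abs(v[i] - v[j]) <= eps] for i in range(n)
    ]
    core = [len(neigh[i]) >= min_samples for i in range(n)]
    labels = [None] * n
    cid = 0
    for i in range(n):
        if core[i] and labels[i] is None:
            stack = [i]
            labels[i] = cid
            while stack:
                u = stack.pop()
                for w in neigh[u]:
                    if core[w] and labels[w] is None:
                        labels[w] = cid
                        stack.append(w)
            cid += 1
    for i in range(n):
        if core[i] or labels[i] is not None:
            continue
        cores_near = [j for j in neigh[i] if core[j]]
        if cores_near:
            best = min(cores_near, key=lambda j: (abs(v[i] - v[j]), v[j]))
            labels[i] = labels[best]
    out = [-1 if l is None else l for l in labels]
    return relabel_by_position(out, v)


def relabel_by_position(labels, values):
    """Renumber clusters by ascending minimum member value (noise stays -1)."""
    order = {}
    mins = {}
    for l, x in zip(labels, values):
        if l != -1:
            mins[l] = min(mins.get(l, math.inf), x)
    for rank, l in enumerate(sorted(mins, key=mins.get)):
        order[l] = rank
    return [(-1 if l == -1 else order[l]) for l in labels]


def rank_sum_exact_p(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumeration of all group assignments."""
    pooled = sorted(list(x) + list(y))
    nx = len(x)

    def midrank(val):
        lo = sum(1 for p in pooled if p < val)
        t = sum(1 for p in pooled if p == val)
        return lo + (t + 1) / 2

    obs_u = sum(midrank(v) for v in x) - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = sum(midrank(pooled[i]) for i in combo) - nx * (nx + 1) / 2
        us.append(u)
    us = np.array(us)
    if alternative == "less":
        return float(np.mean(us <= obs_u))
    if alternative == "greater":
        return float(np.mean(us >= obs_u))
    lo = np.mean(us <= obs_u)
    hi = np.mean(us >= obs_u)
    return float(min(1.0, 2 * min(lo, hi)))


def conserved_bp_per_base(start, end, conserved, coding):
    """Per-base count of (total, coding, noncoding) conserved overlap."""
    total = cod = 0
    for b in range(start, end):
        in_cons = any(s <= b < e for s, e in conserved)
        if in_cons:
            total += 1
            if any(s <= b < e for s, e in coding):
                cod += 1
    return total, cod, total - cod


def merge_intervals_oracle(intervals):
    """Transitive >=1 bp (strict) overlap merge via union-find components.

    Abutting half-open intervals share 0 bp and stay separate, unlike a
    per-base painting merge.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 < e2 and s2 < e1:  # strict overlap, >=1 bp
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(intervals[i])
    spans = [
        (min(s for s, _ in group), max(e for _, e in group))
        for group in comps.values()
    ]
    return sorted(spans)
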