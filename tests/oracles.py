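"""Independent brute-force oracles used by the tests.

Deliberately naive implementations — O(n^3) hull, full enumeration,
direct sums — kept separate from the package code they check.
"""

from itertools import combinations, permutations

import numpy as np


def brute_force_hull_area(pts: np.ndarray) -> float:
    """Convex-hull area by exclusion of interior points + shoelace."""

    def in_triangle(p, a, b, c):
        def cross(o, u, v):
            return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        has_neg = min(d1, d2, d3) < -1e-12
        has_pos = max(d1, d2, d3) > 1e-12
        return not (has_neg and has_pos)

    hull = []
    for i, p in enumerate(pts):
        others = np.delete(pts, i, axis=0)
        if not any(in_triangle(p, a, b, c) for a, b, c in combinations(others, 3)):
            hull.append(p)
    hull = np.array(hull)
    centre = hull.mean(axis=0)
    order = np.argsort(np.arctan2(hull[:, 1] - centre[1], hull[:, 0] - centre[0]))
    hull = hull[order]
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def pseudo_f(dist: np.ndarray, codes) -> float:
    """Direct within/between sums-of-squared-distances pseudo-F."""
    n = len(codes)
    groups = sorted(set(codes))
    a = len(groups)
    ss_total = sum(dist[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if codes[i] == g]
        ss_within += sum(dist[i, j] ** 2 for i, j in combinations(idx, 2)) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def exhaustive_permanova_p(dist: np.ndarray, codes) -> float:
    """Exact p over every distinct arrangement of the label multiset."""
    observed = pseudo_f(dist, codes)
    all_f = [pseudo_f(dist, perm) for perm in sorted(set(permutations(codes)))]
    return sum(f >= observed - 1e-12 for f in all_f) / len(all_f)
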