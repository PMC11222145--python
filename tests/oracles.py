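"""Independent brute-force oracles the implementation is checked against."""

from itertools import combinations

import numpy as np

from viralhist.domains import ResolutionConfig, overlap_fraction


def _conflict(a, b, threshold):
    return overlap_fraction(a.ali_from, a.ali_to, b.ali_from, b.ali_to) > threshold


def exhaustive_resolution(hits, cfg: ResolutionConfig):
    """All conflict-free subsets, enumerated; pick the one greedy would.

    Among *maximal* conflict-free subsets of the coverage-passing hits,
    the greedy-by-E-value solution is the lexicographically smallest by
    the sorted tuple of priority ranks.  Enumeration is exponential and
    only used on small instances.
    """
    passing = [h for h in hits if h.coverage >= cfg.min_coverage]
    order = sorted(passing, key=lambda h: (h.c_evalue, -h.bit_score,
                                           -h.ali_length, h.ali_from, h.family))
    rank = {id(h): i for i, h in enumerate(order)}

    best_key, best_subset = None, []
    n = len(passing)
    for r in range(n, -1, -1):
        for combo in combinations(passing, r):
            if any(_conflict(a, b, cfg.overlap_threshold)
                   for a, b in combinations(combo, 2)):
                continue
            # maximality: no remaining hit can be added
            rest = [h for h in passing if h not in combo]
            if any(all(not _conflict(h, c, cfg.overlap_threshold)
                       for c in combo) for h in rest):
                continue
            key = tuple(sorted(rank[id(h)] for h in combo))
            if best_key is None or key < best_key:
                best_key, best_subset = key, list(combo)
    return sorted(best_subset, key=lambda h: (h.ali_from, h.ali_to))


def ecdf_sup_distance(a, b):
    """sup |ECDF_a − ECDF_b| evaluated over the pooled values."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def local_maxima_with_prominence(y, prominence):
    """Direct O(n²) local-maxima scan with the textbook prominence rule."""
    y = np.asarray(y, float)
    peaks = []
    for i in range(1, y.size - 1):
        if not (y[i] > y[i - 1] and y[i] >= y[i + 1]):
            continue
        # prominence: height above the higher of the two valley minima
        # between this peak and the nearest higher ground on each side
        left = y[:i][::-1]
        higher = np.where(left > y[i])[0]
        lmin = left[:higher[0]].min() if higher.size else left.min()
        right = y[i + 1:]
        higher = np.where(right > y[i])[0]
        rmin = right[:higher[0]].min() if higher.size else right.min()
        if y[i] - max(lmin, rmin) >= prominence:
            peaks.append(i)
    return peaks
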