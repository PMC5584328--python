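"""Independent oracle implementations used by several test modules.

Each oracle recomputes a quantity from first principles, sharing no code
path with the package implementation it checks.
"""

import itertools

import numpy as np


def brute_force_cheapest_path(index, log_values, raw_values, config):
    """Exhaustive enumeration over all monotone source-to-target paths.

    Returns (reward-adjusted objective, 0-based node tuple) of the optimum;
    feasible only for small n (2^(n-2) candidate paths).
    """
    n = index.n
    n_s = log_values.shape[1]
    b = np.where(index.is_known_reference, -config.r, 0.0)
    centered = log_values - log_values.mean(axis=1, keepdims=True)

    def cost(i, j):
        d = np.sqrt(((centered[i] - centered[j]) ** 2).sum() / n_s)
        k = int((raw_values[j] < raw_values[i]).sum())
        return d + (j - i - 1) * config.m + k * config.h

    best_obj, best_path = None, None
    for size in range(n - 1):
        for interior in itertools.combinations(range(1, n - 1), size):
            path = (0,) + interior + (n - 1,)
            z = sum(cost(i, j) for i, j in zip(path[:-1], path[1:]))
            obj = z + sum(b[p] for p in path)
            if best_obj is None or obj < best_obj - 1e-15:
                best_obj, best_path = obj, path
    return best_obj, best_path


def quadratic_ols_normal_equations(x, y):
    """Closed-form normal equations via explicit power sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = [np.sum(x**p) for p in range(5)]
    A = np.array([[s[0], s[1], s[2]], [s[1], s[2], s[3]], [s[2], s[3], s[4]]])
    rhs = np.array([np.sum(y), np.sum(x * y), np.sum(x * x * y)])
    return np.linalg.inv(A) @ rhs


def naive_ward_d2(points):
    """O(n^3) Ward agglomeration recomputing every merge cost from scratch.

    The Ward distance between clusters A, B is computed directly from the
    increase in within-cluster sum of squares:
    height = sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||.
    Ties broken toward the smallest cluster index pair.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pa, pb = pts[clusters[a]], pts[clusters[b]]
            ca, cb = pa.mean(axis=0), pb.mean(axis=0)
            na, nb = len(pa), len(pb)
            h = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            key = (h, (a, b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (h, _), a, b = best
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)
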