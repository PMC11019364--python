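"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive (explicit loops, no shared code with
the package implementation beyond the published seeding conventions), so it
can serve as an independent reference for the fast paths it checks.
"""

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive changepoint search
# ---------------------------------------------------------------------------

def naive_t_stat(values, i, j):
    """Two-sample t-like statistic of arc [i, j) vs the rest, from scratch."""
    inside = np.asarray(values[i:j], dtype=float)
    outside = np.concatenate([values[:i], values[j:]]).astype(float)
    n_in, n_out = len(inside), len(outside)
    mean_in, mean_out = inside.mean(), outside.mean()
    dev = ((inside - mean_in) ** 2).sum() + ((outside - mean_out) ** 2).sum()
    s2 = dev / max(n_in + n_out - 2, 1)
    se = np.sqrt(s2 * (1.0 / n_in + 1.0 / n_out))
    diff = abs(mean_in - mean_out)
    if se == 0:
        return np.inf if diff > 0 else 0.0
    return diff / se


def naive_best_arc_definitional(values, min_width):
    """Exhaustive max over every admissible arc, via the definitional
    statistic (slow; used to self-check the fast oracle)."""
    n = len(values)
    best = (0.0, 0, n)
    for i in range(0, n + 1):
        if i != 0 and i < min_width:
            continue
        for j in range(i + min_width, n + 1):
            if j != n and n - j < min_width:
                continue
            if i == 0 and j == n:
                continue
            t = naive_t_stat(values, i, j)
            if t > best[0]:
                best = (t, i, j)
    return best


def naive_best_arc(values, min_width):
    """Exhaustive max over every admissible arc (each piece >= min_width).

    Pure-Python double loop over all (i, j) with prefix sums; no code shared
    with the vectorised implementation under test.
    """
    n = len(values)
    import math
    cs = [0.0] * (n + 1)
    css = [0.0] * (n + 1)
    for k, v in enumerate(values):
        cs[k + 1] = cs[k] + v
        css[k + 1] = css[k] + v * v
    total, total_sq = cs[n], css[n]
    best = (0.0, 0, n)
    for i in range(0, n + 1):
        if i != 0 and i < min_width:
            continue
        for j in range(i + min_width, n + 1):
            if j != n and n - j < min_width:
                continue
            if i == 0 and j == n:
                continue
            d = j - i
            n_out = n - d
            sum_in = cs[j] - cs[i]
            ss_in = css[j] - css[i]
            sum_out = total - sum_in
            mean_in = sum_in / d
            mean_out = sum_out / n_out
            dev = (ss_in - sum_in * sum_in / d) + \
                  (total_sq - ss_in - sum_out * sum_out / n_out)
            s2 = dev / max(n - 2, 1)
            se2 = s2 * (1.0 / d + 1.0 / n_out)
            diff = abs(mean_in - mean_out)
            if se2 <= 0:
                t = math.inf if diff > 0 else 0.0
            else:
                t = diff / math.sqrt(se2)
            if t > best[0]:
                best = (t, i, j)
    return best


def naive_cbs(values, positions, min_width, alpha, n_perm, seed):
    """Recursive exhaustive-search segmentation with seeded permutations.

    Mirrors the published convention that each interval's permutation
    generator is seeded from (seed, interval start, interval end), so the
    draws are shared with the implementation under test.
    """
    values = np.asarray(values, dtype=float)
    final = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        seg = values[lo:hi]
        n = hi - lo
        split = None
        if n >= 2 * min_width and not np.all(seg == seg[0]):
            stat, i, j = naive_best_arc(seg, min_width)
            if stat > 0:
                rng = np.random.default_rng(
                    np.random.SeedSequence((int(seed), int(lo), int(hi))))
                exceed = 0
                significant = True
                for _ in range(n_perm):
                    s, _, _ = naive_best_arc(rng.permutation(seg), min_width)
                    if s >= stat:
                        exceed += 1
                        if (exceed + 1) / (n_perm + 1) >= alpha:
                            significant = False
                            break
                if significant and (exceed + 1) / (n_perm + 1) < alpha:
                    split = (i, j)
        if split is None:
            final.append((lo, hi))
        else:
            i, j = split
            for piece in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                if piece[1] > piece[0]:
                    stack.append(piece)
    return sorted(final)


# ---------------------------------------------------------------------------
# UPGMA / average linkage
# ---------------------------------------------------------------------------

def naive_upgma(ids, dist):
    """Average-linkage clustering tracked on leaf sets.

    Cluster distance is the plain average of all leaf-pair distances; ties
    broken by the lexicographically smallest (min-label, max-label) pair.
    Returns a nested tuple topology plus heights: (left, right, height).
    """
    dist = np.asarray(dist, dtype=float)
    clusters = {i: frozenset([i]) for i in range(len(ids))}
    trees = {i: ids[i] for i in range(len(ids))}
    heights = {i: 0.0 for i in range(len(ids))}
    next_id = len(ids)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[x, y] for x in clusters[a]
                             for y in clusters[b]])
                la = min(ids[x] for x in clusters[a])
                lb = min(ids[x] for x in clusters[b])
                key = (d, min(la, lb), max(la, lb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        left, right = sorted([trees[a], trees[b]], key=_min_label)
        trees[next_id] = (left, right, d / 2.0)
        heights[next_id] = d / 2.0
        clusters[next_id] = clusters[a] | clusters[b]
        del clusters[a], clusters[b], trees[a], trees[b]
        next_id += 1
    return trees[next_id - 1]


def _min_label(t):
    return t if isinstance(t, str) else min(_min_label(t[0]), _min_label(t[1]))


def tree_to_tuple(node):
    """Package TreeNode -> the oracle's nested-tuple form."""
    if not node.children:
        return node.name
    left, right = sorted((tree_to_tuple(c) for c in node.children),
                         key=_min_label)
    return (left, right, node.height)


def tuples_equal(a, b, tol=1e-9):
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    return (abs(a[2] - b[2]) < tol and tuples_equal(a[0], b[0], tol)
            and tuples_equal(a[1], b[1], tol))
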