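"""A minimal extremely-randomized-trees regressor for feature importances.

The shadow-feature selection loop refits a fresh tree ensemble at every
iteration of every run, tens of thousands of times per stability study, on
matrices of a few dozen samples and features.  Only the impurity-based
importances are ever consumed, so this module grows the forest in a single
numba-jitted pass (explicit node stack, in-place index partitioning) instead
of paying a general-purpose estimator's per-fit overhead.

Algorithm (Extra-Trees): each tree sees the full sample (no bootstrap); at
each node ``max_features`` candidate features are drawn and each is assigned
one uniformly random split threshold between its node-local min and max; the
best candidate by variance reduction splits the node.  A feature's importance
is the total variance reduction it achieves, weighted by node size, averaged
over trees.

Equivalence with sklearn's ``ExtraTreesRegressor`` importances (up to Monte
Carlo noise) is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _grow_tree(X, y, idx, max_features, min_leaf, seed, importances):
    n_total, p = X.shape
    np.random.seed(seed)
    # explicit stack of (start, end) ranges into idx
    stack = np.empty((4 * n_total + 8, 2), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n_total
    top = 1
    while top > 0:
        top -= 1
        start = stack[top, 0]
        end = stack[top, 1]
        n_node = end - start
        if n_node < 2 * min_leaf or n_node < 2:
            continue
        s = 0.0
        s2 = 0.0
        for k in range(start, end):
            v = y[idx[k]]
            s += v
            s2 += v * v
        var_node = s2 / n_node - (s / n_node) ** 2
        if var_node <= 1e-12:
            continue

        best_score = -1.0
        best_feat = -1
        best_thr = 0.0
        for _ in range(max_features):
            f = np.random.randint(0, p)
            lo = X[idx[start], f]
            hi = lo
            for k in range(start + 1, end):
                v = X[idx[k], f]
                if v < lo:
                    lo = v
                elif v > hi:
                    hi = v
            if hi <= lo:
                continue
            thr = np.random.uniform(lo, hi)
            nl = 0
            sl = 0.0
            sl2 = 0.0
            for k in range(start, end):
                v = X[idx[k], f]
                if v <= thr:
                    w = y[idx[k]]
                    nl += 1
                    sl += w
                    sl2 += w * w
            nr = n_node - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            var_l = sl2 / nl - (sl / nl) ** 2
            sr = s - sl
            sr2 = s2 - sl2
            var_r = sr2 / nr - (sr / nr) ** 2
            score = var_node - (nl * var_l + nr * var_r) / n_node
            if score > best_score:
                best_score = score
                best_feat = f
                best_thr = thr
        if best_feat < 0:
            continue

        # partition idx[start:end] in place around the chosen split
        i = start
        j = end - 1
        while i <= j:
            if X[idx[i], best_feat] <= best_thr:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        mid = i
        importances[best_feat] += (n_node / n_total) * best_score
        stack[top, 0] = start
        stack[top, 1] = mid
        top += 1
        stack[top, 0] = mid
        stack[top, 1] = end
        top += 1


@njit(cache=True)
def _forest_importances(X, y, n_trees, max_features, min_leaf, tree_seeds):
    n, p = X.shape
    importances = np.zeros(p)
    idx = np.empty(n, dtype=np.int64)
    for t in range(n_trees):
        for k in range(n):
            idx[k] = k
        _grow_tree(X, y, idx, max_features, min_leaf, tree_seeds[t], importances)
    return importances / n_trees


@njit(cache=True)
def _grow_tree_stored(
    X, y, idx, n_active, max_features, min_leaf, seed,
    feat, thr, left, right, value,
):
    """Grow one tree on ``idx[:n_active]`` storing its structure; returns node count."""
    n_total, p = X.shape
    np.random.seed(seed)
    n_nodes = 1
    feat[0] = -1
    value[0] = 0.0
    stack = np.empty((4 * n_active + 8, 3), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n_active
    stack[0, 2] = 0  # node id
    top = 1
    while top > 0:
        top -= 1
        start = stack[top, 0]
        end = stack[top, 1]
        node = stack[top, 2]
        n_node = end - start
        s = 0.0
        s2 = 0.0
        for k in range(start, end):
            v = y[idx[k]]
            s += v
            s2 += v * v
        feat[node] = -1
        value[node] = s / n_node
        if n_node < 2 * min_leaf or n_node < 2:
            continue
        var_node = s2 / n_node - (s / n_node) ** 2
        if var_node <= 1e-12:
            continue

        best_score = -1.0
        best_feat = -1
        best_thr = 0.0
        for _ in range(max_features):
            f = np.random.randint(0, p)
            lo = X[idx[start], f]
            hi = lo
            for k in range(start + 1, end):
                v = X[idx[k], f]
                if v < lo:
                    lo = v
                elif v > hi:
                    hi = v
            if hi <= lo:
                continue
            t = np.random.uniform(lo, hi)
            nl = 0
            sl = 0.0
            sl2 = 0.0
            for k in range(start, end):
                v = X[idx[k], f]
                if v <= t:
                    w = y[idx[k]]
                    nl += 1
                    sl += w
                    sl2 += w * w
            nr = n_node - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            var_l = sl2 / nl - (sl / nl) ** 2
            sr = s - sl
            sr2 = s2 - sl2
            var_r = sr2 / nr - (sr / nr) ** 2
            score = var_node - (nl * var_l + nr * var_r) / n_node
            if score > best_score:
                best_score = score
                best_feat = f
                best_thr = t
        if best_feat < 0:
            continue

        i = start
        j = end - 1
        while i <= j:
            if X[idx[i], best_feat] <= best_thr:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        mid = i
        feat[node] = best_feat
        thr[node] = best_thr
        left[node] = n_nodes
        right[node] = n_nodes + 1
        n_nodes += 2
        stack[top, 0] = start
        stack[top, 1] = mid
        stack[top, 2] = left[node]
        top += 1
        stack[top, 0] = mid
        stack[top, 1] = end
        stack[top, 2] = right[node]
        top += 1
    return n_nodes


@njit(cache=True)
def _tree_predict_sse(X, y, rows, col_perm, perm_feat, feat, thr, left, right, value):
    """SSE of one tree over ``rows``; feature ``perm_feat`` (if >= 0) is read
    through the row permutation ``col_perm`` instead of in order."""
    sse = 0.0
    for r in range(len(rows)):
        node = 0
        while feat[node] >= 0:
            f = feat[node]
            if f == perm_feat:
                v = X[rows[col_perm[r]], f]
            else:
                v = X[rows[r], f]
            if v <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        d = y[rows[r]] - value[node]
        sse += d * d
    return sse


@njit(cache=True)
def _forest_permutation_importances(X, y, n_trees, max_features, min_leaf, tree_seeds):
    n, p = X.shape
    imp = np.zeros(p)
    imp2 = np.zeros(p)
    max_nodes = 4 * n + 8
    feat = np.empty(max_nodes, dtype=np.int64)
    thr = np.empty(max_nodes)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    value = np.empty(max_nodes)
    inbag = np.empty(n, dtype=np.int64)
    used = np.empty(n, dtype=np.bool_)
    n_used_trees = 0
    for t in range(n_trees):
        np.random.seed(tree_seeds[t])
        for k in range(n):
            used[k] = False
        for k in range(n):
            j = np.random.randint(0, n)
            inbag[k] = j
            used[j] = True
        n_oob = 0
        for k in range(n):
            if not used[k]:
                n_oob += 1
        if n_oob == 0:
            continue
        oob = np.empty(n_oob, dtype=np.int64)
        m = 0
        for k in range(n):
            if not used[k]:
                oob[m] = k
                m += 1
        _grow_tree_stored(
            X, y, inbag, n, max_features, min_leaf,
            np.random.randint(0, 2**31 - 1), feat, thr, left, right, value,
        )
        ident = np.arange(n_oob)
        base = _tree_predict_sse(X, y, oob, ident, -1, feat, thr, left, right, value)
        perm = np.arange(n_oob)
        for f in range(p):
            # fresh shuffle per feature
            for k in range(n_oob - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = perm[k]
                perm[k] = perm[j]
                perm[j] = tmp
            sse = _tree_predict_sse(X, y, oob, perm, f, feat, thr, left, right, value)
            delta = (sse - base) / n_oob
            imp[f] += delta
            imp2[f] += delta * delta
        n_used_trees += 1
    # Z-score over trees: mean decrease accuracy / its standard error
    z = np.zeros(p)
    if n_used_trees > 1:
        for f in range(p):
            mean = imp[f] / n_used_trees
            var = imp2[f] / n_used_trees - mean * mean
            if var < 1e-300:
                z[f] = 0.0
            else:
                z[f] = mean / np.sqrt(var / n_used_trees)
    return z


def permutation_importances(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    max_features: int | None = None,
    min_leaf: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-bag permutation importances of a bootstrapped randomized forest.

    Each tree is grown on a bootstrap resample; a feature's importance is the
    mean increase in out-of-bag squared error when that feature's OOB values
    are shuffled.  This is the mean-decrease-accuracy measure of the original
    shadow-feature algorithm, and unlike impurity importance it is anchored to
    held-out points, so in-sample chance correlation earns no credit.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if max_features is None:
        max_features = max(1, p // 3)
    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees).astype(np.int64)
    return _forest_permutation_importances(
        X, y, n_trees, max_features, min_leaf, tree_seeds
    )


def extra_trees_importances(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    max_features: int | None = None,
    min_leaf: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Impurity importances of an Extra-Trees regression forest.

    ``max_features`` defaults to ``max(1, p // 3)``, the usual regression
    heuristic.  Deterministic given ``seed``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if max_features is None:
        max_features = max(1, p // 3)
    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees).astype(np.int64)
    return _forest_importances(
        X, y, n_trees, max_features, min_leaf, tree_seeds
    )
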