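"""Shapley-additive attributions for tree ensembles.

Implements the exact path-dependent tree-Shapley algorithm (polynomial in
tree size), attributing each sample's predicted case-probability additively
across features: ``base_value + sum(phi) == prediction`` to numerical
precision.  Conditional expectations under a feature coalition follow the
tree's own training cover: a split on a feature outside the coalition
averages both children weighted by the fraction of training samples routed
to each.

``exhaustive_shap`` is a direct Shapley-formula evaluation over all
coalitions of the features a tree uses — exponential, intended only for
small trees as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np

__all__ = ["TreeArrays", "tree_shap", "forest_shap", "exhaustive_shap",
           "tree_expected_value"]


@dataclass
class TreeArrays:
    """Flat arrays describing one fitted decision tree.

    ``value`` is the scalar output at each node (for classification, the
    fraction of the positive class among training samples at that node);
    ``cover`` is the (weighted) number of training samples reaching the node.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray

    @classmethod
    def from_sklearn(cls, estimator, class_index: int = 1) -> "TreeArrays":
        t = estimator.tree_
        raw = t.value[:, 0, :]  # (n_nodes, n_classes) class fractions
        if raw.shape[1] == 1:
            value = raw[:, 0]
        else:
            norm = raw.sum(axis=1, keepdims=True)
            value = (raw / norm)[:, class_index]
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=np.asarray(value, dtype=float),
            cover=t.weighted_n_node_samples.copy(),
        )

    def is_leaf(self, node: int) -> bool:
        return self.children_left[node] < 0


def tree_expected_value(tree: TreeArrays) -> float:
    """Cover-weighted mean leaf value (the tree's base prediction)."""
    total = tree.cover[0]
    acc = 0.0
    stack = [0]
    while stack:
        node = stack.pop()
        if tree.is_leaf(node):
            acc += tree.cover[node] / total * tree.value[node]
        else:
            stack.append(tree.children_left[node])
            stack.append(tree.children_right[node])
    return acc


def _extend(d, z, o, w, pz, po, pi):
    l = len(w)
    d.append(pi)
    z.append(pz)
    o.append(po)
    w.append(1.0 if l == 0 else 0.0)
    for j in range(l - 1, -1, -1):
        w[j + 1] += po * w[j] * (j + 1) / (l + 1)
        w[j] = pz * w[j] * (l - j) / (l + 1)


def _unwind(d, z, o, w, i):
    l = len(w)
    oi, zi = o[i], z[i]
    n = w[l - 1]
    if oi != 0:
        for j in range(l - 2, -1, -1):
            t = w[j]
            w[j] = n * l / ((j + 1) * oi)
            n = t - w[j] * zi * (l - 1 - j) / l
    else:
        for j in range(l - 2, -1, -1):
            w[j] = w[j] * l / (zi * (l - 1 - j))
    for j in range(i, l - 1):
        d[j], z[j], o[j] = d[j + 1], z[j + 1], o[j + 1]
    d.pop(), z.pop(), o.pop(), w.pop()


def _unwound_sum(d, z, o, w, i):
    l = len(w)
    oi, zi = o[i], z[i]
    total = 0.0
    if oi != 0:
        n = w[l - 1]
        for j in range(l - 2, -1, -1):
            t = n * l / ((j + 1) * oi)
            total += t
            n = w[j] - t * zi * (l - 1 - j) / l
    else:
        for j in range(l - 2, -1, -1):
            total += w[j] * l / (zi * (l - 1 - j))
    return total


def tree_shap(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact path-dependent Shapley attributions of one tree's prediction."""
    phi = np.zeros(n_features)

    def recurse(node, d, z, o, w, pz, po, pi):
        d, z, o, w = list(d), list(z), list(o), list(w)
        _extend(d, z, o, w, pz, po, pi)
        if tree.is_leaf(node):
            v = tree.value[node]
            for i in range(1, len(w)):
                s = _unwound_sum(d, z, o, w, i)
                phi[d[i]] += s * (o[i] - z[i]) * v
            return
        f = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if x[f] <= tree.threshold[node]:
            hot, cold = left, right
        else:
            hot, cold = right, left
        iz = io = 1.0
        k = next((ii for ii in range(1, len(w)) if d[ii] == f), None)
        if k is not None:
            iz, io = z[k], o[k]
            _unwind(d, z, o, w, k)
        rj = tree.cover[node]
        recurse(hot, d, z, o, w, iz * tree.cover[hot] / rj, io, f)
        recurse(cold, d, z, o, w, iz * tree.cover[cold] / rj, 0.0, f)

    recurse(0, [], [], [], [], 1.0, 1.0, -1)
    return phi


def forest_shap(model, X: np.ndarray, class_index: int = 1
                ) -> tuple[np.ndarray, float]:
    """SHAP values for a fitted sklearn random forest's case probability.

    Returns ``(phi, base)`` where ``phi`` is (n_samples, n_features) and
    ``base + phi.sum(axis=1)`` reconstructs ``predict_proba[:, class_index]``.
    Per-sample attributions are averaged over the ensemble's trees.
    """
    X = np.asarray(X, dtype=float)
    n_samples, n_features = X.shape
    trees = [TreeArrays.from_sklearn(est, class_index)
             for est in model.estimators_]
    phi = np.zeros((n_samples, n_features))
    base = 0.0
    for tree in trees:
        base += tree_expected_value(tree)
        # Samples sharing identical split-test outcomes at every internal
        # node get identical attributions; cache on that decision pattern.
        internal = np.flatnonzero(tree.feature >= 0)
        if internal.size == 0:
            continue
        tests = (X[:, tree.feature[internal]] <=
                 tree.threshold[internal][None, :])
        _, first, inverse = np.unique(tests, axis=0, return_index=True,
                                      return_inverse=True)
        reps = {}
        for u, row in enumerate(first):
            reps[u] = tree_shap(tree, X[row], n_features)
        for s in range(n_samples):
            phi[s] += reps[inverse[s]]
    n_trees = len(trees)
    return phi / n_trees, base / n_trees


def _conditional_expectation(tree: TreeArrays, x: np.ndarray,
                             coalition: frozenset) -> float:
    def walk(node: int) -> float:
        if tree.is_leaf(node):
            return tree.value[node]
        f = tree.feature[node]
        left, right = tree.children_left[node], tree.children_right[node]
        if f in coalition:
            child = left if x[f] <= tree.threshold[node] else right
            return walk(child)
        wl = tree.cover[left] / tree.cover[node]
        wr = tree.cover[right] / tree.cover[node]
        return wl * walk(left) + wr * walk(right)

    return walk(0)


def exhaustive_shap(tree: TreeArrays, x: np.ndarray, n_features: int
                    ) -> np.ndarray:
    """Shapley values by brute-force enumeration of feature coalitions.

    Only features the tree actually splits on participate (others have zero
    attribution by construction).  Exponential in the number of used
    features; reference implementation for small trees.
    """
    used = sorted({int(f) for f in tree.feature if f >= 0})
    m = len(used)
    phi = np.zeros(n_features)
    if m == 0:
        return phi
    for i in used:
        others = [f for f in used if f != i]
        total = 0.0
        for size in range(m):
            weight = factorial(size) * factorial(m - size - 1) / factorial(m)
            for subset in combinations(others, size):
                s = frozenset(subset)
                v_with = _conditional_expectation(tree, x, s | {i})
                v_without = _conditional_expectation(tree, x, s)
                total += weight * (v_with - v_without)
        phi[i] = total
    return phi
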