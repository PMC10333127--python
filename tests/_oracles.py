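"""Independent brute-force oracles used to validate the dynamic-programming
engines: exhaustive enumeration over internal-node state assignments for both
the pruning likelihood/marginals and the Sankoff minimal cost."""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from paleoparity import TimeTree


def enum_loglik_and_marginals(tree: TimeTree, tips: dict, q: np.ndarray,
                              prior: np.ndarray):
    """Likelihood and node marginals by summing over every internal assignment."""
    n = q.shape[0]
    internals = [nd for nd in tree.dtree.postorder_node_iter() if not nd.is_leaf()]
    pmats = {nd: expm(q * nd.edge.length)
             for nd in tree.dtree.preorder_node_iter() if nd.parent_node is not None}
    total = 0.0
    marg = {nd: np.zeros(n) for nd in internals}
    for assign in itertools.product(range(n), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        w = prior[amap[tree.dtree.seed_node]]
        for nd in tree.dtree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            ps = amap[nd.parent_node]
            if nd.is_leaf():
                w *= pmats[nd][ps] @ np.asarray(tips[nd.taxon.label])
            else:
                w *= pmats[nd][ps, amap[nd]]
        total += w
        for nd in internals:
            marg[nd][amap[nd]] += w
    return np.log(total), {tree.clade_of(nd): m / total for nd, m in marg.items()}


def enum_min_cost(tree: TimeTree, rows: dict, costs: np.ndarray):
    """Minimal Sankoff cost and per-node minimal-state sets by enumeration."""
    n = costs.shape[0]
    internals = [nd for nd in tree.dtree.postorder_node_iter() if not nd.is_leaf()]
    best = np.inf
    minstates: dict = {}
    for assign in itertools.product(range(n), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        tot = 0.0
        for nd in tree.dtree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            ps = amap[nd.parent_node]
            if nd.is_leaf():
                allowed = np.flatnonzero(rows[nd.taxon.label])
                tot += min(costs[ps, a] for a in allowed)
            else:
                tot += costs[ps, amap[nd]]
        if tot < best - 1e-9:
            best = tot
            minstates = {nd: {amap[nd]} for nd in internals}
        elif tot <= best + 1e-9:
            for nd in internals:
                minstates[nd].add(amap[nd])
    return best, {tree.clade_of(nd): frozenset(s) for nd, s in minstates.items()}


def random_timetree(n_tips: int, rng: np.random.Generator,
                    min_len: float = 0.05, max_len: float = 1.0) -> TimeTree:
    """Random rooted bifurcating tree with uniform branch lengths."""
    labels = [chr(65 + i) for i in range(n_tips)]
    parts = list(labels)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    tree = TimeTree.from_newick(parts[0] + ";")
    for nd in tree.dtree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.uniform(min_len, max_len))
    return tree
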