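"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives an expected value from its mathematical definition by
a route independent of the package implementation (explicit enumeration,
O(n^2) definitional loops, hand-built trees), so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def rank_pearson(x, y) -> float:
    """Spearman rho as the textbook Pearson formula applied to mid-ranks."""
    rx = rankdata(x)
    ry = rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def permutation_pvalue(x, y) -> float:
    """Exact two-sided permutation p-value of Spearman rho over all n! orderings."""
    rx = rankdata(x)
    ry = rankdata(y)
    obs = abs(rank_pearson(x, y))
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    dx = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    num = pc @ dx
    den = np.sqrt((pc**2).sum(axis=1) * (dx**2).sum())
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= obs - 1e-12))


def bh_step_up(p_values) -> np.ndarray:
    """BH q-values straight from the step-up definition, O(n^2)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(min(candidates), 1.0)
    return q


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths; returns (skbio tree, labels, D).

    D is the matrix of path-length distances between tips — additive by
    construction.
    """
    from skbio import TreeNode

    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=name) for name in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
    tree = TreeNode(children=nodes)
    dm = tree.tip_tip_distances()
    ids = [str(x) for x in dm.ids]
    order = [ids.index(lbl) for lbl in labels]
    d = np.asarray(dm.data)[np.ix_(order, order)]
    return tree, labels, d


def graph_density(nodes, edge_keys) -> float:
    """Edge density by brute-force enumeration over all node pairs."""
    nodes = list(nodes)
    if len(nodes) < 2:
        return 0.0
    present = {frozenset(e) for e in edge_keys}
    hits = sum(1 for pair in itertools.combinations(nodes, 2) if frozenset(pair) in present)
    return hits / (len(nodes) * (len(nodes) - 1) / 2)
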