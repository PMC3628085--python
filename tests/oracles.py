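"""Independent brute-force oracles used by the test suite.

Tree handling here deliberately goes through dendropy (the package under
test uses scikit-bio) and every metric is computed by explicit per-edge
set enumeration, so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import dendropy
import numpy as np


def _edges_with_tipsets(newick: str):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        tips = frozenset(leaf.taxon.label.replace(" ", "_")
                         for leaf in node.leaf_iter())
        edges.append((length, tips))
    return edges


def brute_unweighted_unifrac(newick: str, tips_i: set[str], tips_j: set[str]) -> float:
    unique = shared = 0.0
    for length, tips in _edges_with_tipsets(newick):
        in_i = bool(tips & tips_i)
        in_j = bool(tips & tips_j)
        if in_i and in_j:
            shared += length
        elif in_i or in_j:
            unique += length
    total = unique + shared
    if total == 0:
        raise ValueError("no observed branches")
    return unique / total


def brute_weighted_unifrac(newick: str, counts_i: dict[str, int],
                           counts_j: dict[str, int],
                           normalized: bool = False) -> float:
    ni = sum(counts_i.values())
    nj = sum(counts_j.values())
    raw = 0.0
    for length, tips in _edges_with_tipsets(newick):
        pi = sum(counts_i.get(t, 0) for t in tips) / ni
        pj = sum(counts_j.get(t, 0) for t in tips) / nj
        raw += length * abs(pi - pj)
    if not normalized:
        return raw
    denom = 0.0
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label.replace(" ", "_")
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        denom += depth * (counts_i.get(name, 0) / ni + counts_j.get(name, 0) / nj)
    return raw / denom


def brute_faith_pd(newick: str, tips_present: set[str]) -> float:
    return sum(length for length, tips in _edges_with_tipsets(newick)
               if tips & tips_present)


def naive_permanova_f(d: np.ndarray, groups) -> float:
    """Double-loop pseudo-F, straight from the definition."""
    groups = list(groups)
    n = d.shape[0]
    labels = sorted(set(groups))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in labels:
        members = [i for i in range(n) if groups[i] == g]
        acc = 0.0
        for ai in range(len(members)):
            for aj in range(ai + 1, len(members)):
                acc += d[members[ai], members[aj]] ** 2
        ss_within += acc / len(members)
    ss_between = ss_total - ss_within
    a = len(labels)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary newick over tips T1..Tn with U(0.1, 2) branch lengths."""
    nodes = [f"T{i + 1}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    inner = nodes[0]
    k = inner.rfind(":")
    return inner[:k] + ";" if inner.startswith("(") else f"({inner});"
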