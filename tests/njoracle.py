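"""Shared oracles for neighbor-joining tests: random additive metrics from
edge-weighted trees, and path lengths read back via Biopython."""

import io as _io
import itertools

import numpy as np


def tree_path_lengths(newick, names):
    """Leaf-to-leaf path lengths of a Newick tree (Biopython traversal)."""
    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(newick), "newick")
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = tree.distance(a, b)
    return out


def random_additive_matrix(rng, n_leaves):
    """Distances from a random edge-weighted binary tree (additive metric)."""
    import networkx as nx

    next_node = [n_leaves]

    def new_internal():
        next_node[0] += 1
        return next_node[0] - 1

    root = new_internal()
    tree_edges = [(root, 0, rng.uniform(0.5, 3)), (root, 1, rng.uniform(0.5, 3))]
    for leaf in range(2, n_leaves):
        idx = rng.integers(len(tree_edges))
        parent, child, w = tree_edges.pop(idx)
        mid = new_internal()
        f = rng.uniform(0.2, 0.8)
        tree_edges += [
            (parent, mid, w * f),
            (mid, child, w * (1 - f)),
            (mid, leaf, rng.uniform(0.5, 3)),
        ]
    g = nx.Graph()
    for a, b, w in tree_edges:
        g.add_edge(a, b, weight=w)
    d = np.zeros((n_leaves, n_leaves))
    for a, b in itertools.combinations(range(n_leaves), 2):
        d[a, b] = d[b, a] = nx.shortest_path_length(g, a, b, weight="weight")
    return d
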