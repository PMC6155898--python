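"""Independent brute-force tree utilities used as oracles in the test suite."""

import random

import numpy as np

from tdckit.phylo import DistanceMatrix, Node, Tree


def tree_path_lengths(tree: Tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths by summing branch lengths (brute force)."""
    parents = {}

    def walk(node, parent):
        parents[id(node)] = (node, parent)
        for ch in node.children:
            walk(ch, node)

    walk(tree.root, None)
    leaves = tree.root.leaves()

    def path_to_root(leaf):
        out = []
        node = leaf
        while True:
            _, parent = parents[id(node)]
            if parent is None:
                break
            out.append(node)
            node = parent
        return out

    dists = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            pa, pb = path_to_root(a), path_to_root(b)
            sa, sb = set(map(id, pa)), set(map(id, pb))
            total = sum(n.length for n in pa if id(n) not in sb)
            total += sum(n.length for n in pb if id(n) not in sa)
            dists[frozenset((a.name, b.name))] = total
    return dists


def random_additive_matrix(n_taxa: int, rng: random.Random):
    """Distances realised by a random binary tree with positive branch lengths."""
    nodes = [Node(name=f"t{i}", length=rng.uniform(0.05, 1.0)) for i in range(n_taxa)]
    while len(nodes) > 3:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(Node(length=rng.uniform(0.05, 1.0), children=[a, b]))
    tree = Tree(Node(children=nodes))
    paths = tree_path_lengths(tree)
    ids = sorted(leaf.name for leaf in tree.root.leaves())
    m = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                m[i, j] = paths[frozenset((a, b))]
    return DistanceMatrix(ids, m), paths
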