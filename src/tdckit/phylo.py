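"""Distance-based dendrograms with bootstrap supports.

Distances come from pairwise comparison of alignment rows: the p-distance
(fraction of differing residues over columns where both rows are non-gap)
optionally passed through the Dayhoff-style correction
``d = -ln(1 - p - 0.2 p^2)``, which linearises multiple substitutions under
an empirical amino-acid model.  Trees are built by neighbor-joining, which
is exact on additive distance matrices; bootstrap supports are percentages
of column-resampled replicates containing the same leaf bipartition.

Using NJ on corrected distances is a deliberate lightweight substitute for
full maximum-likelihood inference: the claims this package tests (two
clusters, one per enzyme class) are topological, and NJ recovers them from
the same alignments at a fraction of the cost.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import Phylo

from .msa import Alignment

logger = logging.getLogger(__name__)

#: p-distance beyond which the Dayhoff correction's log argument is <= 0.
DAYHOFF_P_LIMIT = (math.sqrt(1.8) - 1.0) / 0.4


class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    def __init__(self, ids: Iterable[str], matrix: np.ndarray) -> None:
        self.ids = list(ids)
        matrix = np.asarray(matrix, dtype=float)
        n = len(self.ids)
        if matrix.shape != (n, n):
            raise ValueError(f"matrix shape {matrix.shape} does not fit {n} ids")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(matrix), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (matrix < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = matrix

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class Node:
    """A tree node; ``support`` is a bootstrap percentage on the parent edge."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class Tree:
    root: Node

    @property
    def taxa(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> dict[frozenset[str], Node]:
        """Non-trivial leaf bipartitions, canonicalised; maps to the child node."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out: dict[frozenset[str], Node] = {}

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_taxa) - 2:
                side = below if ref not in below else all_taxa - below
                out[side] = node
            return below

        walk(self.root)
        return out


def _pair_p_distance(row_i: np.ndarray, row_j: np.ndarray) -> float:
    shared = (row_i >= 0) & (row_j >= 0)
    n = int(shared.sum())
    if n == 0:
        raise ValueError("no shared non-gap columns")
    return float((row_i[shared] != row_j[shared]).sum()) / n


def dayhoff_correct(p: float) -> float:
    """Dayhoff-style corrected distance ``-ln(1 - p - 0.2 p^2)``."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        raise ValueError(
            f"p-distance {p:.4f} >= {DAYHOFF_P_LIMIT:.4f}, outside the Dayhoff "
            "correction's domain; use model='p'"
        )
    return -math.log(arg)


def distance_from_alignment(aln: Alignment, model: str = "dayhoff") -> DistanceMatrix:
    """Pairwise distances between alignment rows under ``p`` or ``dayhoff``."""
    if model not in ("p", "dayhoff"):
        raise ValueError(f"unknown model {model!r}")
    enc = aln.matrix()
    n = len(aln.records)
    if n < 2:
        raise ValueError("need at least 2 rows")
    ids = [r.id for r in aln.records]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                p = _pair_p_distance(enc[i], enc[j])
            except ValueError as exc:
                raise ValueError(f"pair ({ids[i]!r}, {ids[j]!r}): {exc}") from exc
            if model == "dayhoff":
                try:
                    val = dayhoff_correct(p)
                except ValueError as exc:
                    raise ValueError(f"pair ({ids[i]!r}, {ids[j]!r}): {exc}") from exc
            else:
                val = p
            d[i, j] = d[j, i] = val
    return DistanceMatrix(ids, d)


def _clamp(x: float) -> float:
    if x < 0.0:
        logger.debug("clamping negative branch length %.6g to 0", x)
        return 0.0
    return x


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard neighbor-joining; negative branch lengths are clamped to zero."""
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[Node] = [Node(name=t) for t in dm.ids]
    if n == 2:
        d = dm.matrix[0, 1]
        nodes[0].length = d / 2.0
        nodes[1].length = d / 2.0
        return Tree(Node(children=nodes))
    D = dm.matrix.copy()
    active = list(range(n))
    grown: dict[int, Node] = dict(enumerate(nodes))
    next_id = n
    # grow D as nodes join; index into a dict-of-rows is simpler than resizing
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i < j else dist[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = grown[i], grown[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        new = Node(children=[child_i, child_j])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = 0.5 * (
                get(i, k) + get(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        grown[next_id] = new
        next_id += 1
    # final three-way join via the three-point formulas
    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    for k, lk in ((a, la), (b, lb), (c, lc)):
        grown[k].length = _clamp(lk)
    return Tree(Node(children=[grown[a], grown[b], grown[c]]))


def bootstrap_tree(
    aln: Alignment,
    model: str = "dayhoff",
    n_reps: int = 100,
    seed: int = 0,
    max_retries_factor: int = 10,
) -> Tree:
    """NJ tree from the full alignment with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement; an internal
    edge's support is the percentage of replicates whose tree contains the
    same leaf bipartition.  Replicates whose distances are incomputable
    (e.g. a resampled pair sharing no non-gap column) are redrawn, up to
    ``max_retries_factor * n_reps`` draws in total.
    """
    main = neighbor_joining(distance_from_alignment(aln, model))
    bip = main.bipartitions()
    counts = {key: 0 for key in bip}
    rng = np.random.default_rng(seed)
    done = 0
    attempts = 0
    enc = aln.matrix()
    n, width = enc.shape
    ids = [r.id for r in aln.records]
    while done < n_reps:
        if attempts >= max_retries_factor * n_reps:
            raise RuntimeError("too many failed bootstrap replicates")
        attempts += 1
        cols = rng.integers(0, width, size=width)
        sub = enc[:, cols]
        try:
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    p = _pair_p_distance(sub[i], sub[j])
                    d[i, j] = d[j, i] = dayhoff_correct(p) if model == "dayhoff" else p
        except ValueError as exc:
            logger.debug("redrawing bootstrap replicate: %s", exc)
            continue
        rep_tree = neighbor_joining(DistanceMatrix(ids, d))
        rep_bips = rep_tree.bipartitions()
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
        done += 1
    for key, node in bip.items():
        node.support = round(100.0 * counts[key] / n_reps)
    return main


def write_newick(tree: Tree) -> str:
    """Serialize with branch lengths to 6 decimals; supports as internal labels."""

    def render(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            inner = ",".join(render(ch, False) for ch in node.children)
            label = "" if node.support is None else str(node.support)
            body = f"({inner}){label}"
        if is_root:
            return body
        return f"{body}:{node.length:.6f}"

    return render(tree.root, True) + ";"


def read_newick(text: str) -> Tree:
    """Parse a Newick string; internal numeric labels become supports."""
    try:
        btree = Phylo.read(io.StringIO(text), "newick")
    except Exception as exc:  # Bio.Phylo raises its own parser errors
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(clade) -> Node:
        node = Node(
            name=clade.name,
            length=float(clade.branch_length) if clade.branch_length is not None else 0.0,
            support=int(clade.confidence) if clade.confidence is not None else None,
        )
        node.children = [convert(ch) for ch in clade.clades]
        return node

    return Tree(convert(btree.root))


def write_phylip(dm: DistanceMatrix) -> str:
    """Square PHYLIP rendering of a distance matrix."""
    lines = [f"{len(dm)}"]
    for i, name in enumerate(dm.ids):
        row = " ".join(f"{x:.6f}" for x in dm.matrix[i])
        lines.append(f"{name[:10]:<10} {row}")
    return "\n".join(lines) + "\n"
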