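"""Progressive multiple sequence alignment for desk-scale protein families.

The aligner is a classic three-stage progressive scheme: optimal pairwise
global alignments under affine gap penalties (Gotoh), a UPGMA guide tree on
``1 - fractional identity`` distances, and profile-profile merges up the
guide tree where a column pair is scored by the expectation of the
substitution score under the two columns' residue frequencies.  There is no
iterative refinement; the goal is faithful conserved-column structure on
families of tens of ~500-residue sequences, not byte-level agreement with
any particular aligner.

Tie-breaking in the DP traceback is fixed (substitution preferred over a gap
in the first argument, preferred over a gap in the second) so every alignment
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seq_core import AMINO_ACIDS, GAP, SequenceRecord, SequenceSet, percent_identity

#: Residue order used for all numeric encodings (20 standard + X).
RESIDUE_ORDER = AMINO_ACIDS + "X"
_RES_INDEX = {ch: i for i, ch in enumerate(RESIDUE_ORDER)}

_NEG = -1e30


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    A gap run of length *k* costs ``gap_open + (k - 1) * gap_extend``.
    Defaults (BLOSUM62, 10/1) are the standard protein choices.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def matrix_array(self) -> np.ndarray:
        """The substitution matrix as a (21, 21) array over :data:`RESIDUE_ORDER`."""
        mat = substitution_matrices.load(self.matrix)
        arr = np.zeros((len(RESIDUE_ORDER), len(RESIDUE_ORDER)))
        for i, a in enumerate(RESIDUE_ORDER):
            for j, b in enumerate(RESIDUE_ORDER):
                arr[i, j] = mat[a, b]
        return arr

    def score(self, a: str, b: str) -> float:
        return float(substitution_matrices.load(self.matrix)[a, b])


def encode(residues: str) -> np.ndarray:
    """Encode residues as integer indices into :data:`RESIDUE_ORDER`; gap = -1."""
    return np.array([-1 if ch == GAP else _RES_INDEX[ch] for ch in residues], dtype=np.int64)


def _gotoh_matrices(sm: np.ndarray, go: float, ge: float):
    """Fill Gotoh DP matrices for a column-score matrix ``sm`` (m x n).

    M: column i aligned to column j.  E: gap in the first profile (consumes a
    column of the second).  F: gap in the second profile.
    """
    m, n = sm.shape
    M = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, n + 1, dtype=float)
    E[0, 1:] = -go - (j - 1) * ge
    i = np.arange(1, m + 1, dtype=float)
    F[1:, 0] = -go - (i - 1) * ge
    jext = j * ge
    for ii in range(1, m + 1):
        vprev = np.maximum(np.maximum(M[ii - 1], E[ii - 1]), F[ii - 1])
        M[ii, 1:] = sm[ii - 1] + vprev[:-1]
        F[ii, 1:] = np.maximum(
            np.maximum(M[ii - 1, 1:], E[ii - 1, 1:]) - go, F[ii - 1, 1:] - ge
        )
        # E has an intra-row recurrence E[j] = max(G[j-1]-go, E[j-1]-ge); solved
        # as a running max after the substitution ge * j, which linearises the
        # extension decay.
        g_row = np.maximum(M[ii], F[ii])
        acc = np.maximum.accumulate(g_row[:-1] - go + jext)
        E[ii, 1:] = acc - jext
    return M, E, F


def _pick(candidates: list[tuple[str, float]]) -> str:
    """First state attaining the maximum value; list order encodes preference."""
    best = max(v for _, v in candidates)
    for state, v in candidates:
        if v >= best - 1e-9:
            return state
    return candidates[0][0]


def _traceback(M, E, F, sm, go, ge):
    """Recover one optimal path as a list of (i, j) with None marking a gap.

    Predecessors are chosen by re-maximising the recurrence at each step
    (ties broken by the fixed preference M > E > F), which stays on an
    optimal path without relying on bit-exact float comparisons.
    """
    m, n = sm.shape
    ii, jj = m, n
    st = _pick([("M", M[ii, jj]), ("E", E[ii, jj]), ("F", F[ii, jj])])
    path: list[tuple[int | None, int | None]] = []
    while ii > 0 or jj > 0:
        if ii == 0:
            path.append((None, jj - 1))
            jj -= 1
            continue
        if jj == 0:
            path.append((ii - 1, None))
            ii -= 1
            continue
        if st == "M":
            path.append((ii - 1, jj - 1))
            ii -= 1
            jj -= 1
            st = _pick([("M", M[ii, jj]), ("E", E[ii, jj]), ("F", F[ii, jj])])
        elif st == "E":
            path.append((None, jj - 1))
            st = _pick(
                [
                    ("M", M[ii, jj - 1] - go),
                    ("E", E[ii, jj - 1] - ge),
                    ("F", F[ii, jj - 1] - go),
                ]
            )
            jj -= 1
        else:
            path.append((ii - 1, None))
            st = _pick(
                [
                    ("M", M[ii - 1, jj] - go),
                    ("E", E[ii - 1, jj] - go),
                    ("F", F[ii - 1, jj] - ge),
                ]
            )
            ii -= 1
    path.reverse()
    return path


def _align_score_matrix(sm: np.ndarray, scheme: ScoringScheme):
    M, E, F = _gotoh_matrices(sm, scheme.gap_open, scheme.gap_extend)
    m, n = sm.shape
    score = float(max(M[m, n], E[m, n], F[m, n]))
    path = _traceback(M, E, F, sm, scheme.gap_open, scheme.gap_extend)
    return path, score


def pairwise_global_align(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> tuple[SequenceRecord, SequenceRecord, float]:
    """Optimal global alignment of two sequences under affine gap penalties.

    Returns the two gapped records and the optimal score.
    """
    scheme = scheme or ScoringScheme()
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    mat = scheme.matrix_array()
    ea, eb = encode(a.ungapped), encode(b.ungapped)
    sm = mat[np.ix_(ea, eb)]
    path, score = _align_score_matrix(sm, scheme)
    ra, rb = [], []
    sa, sb = a.ungapped, b.ungapped
    for i, j in path:
        ra.append(sa[i] if i is not None else GAP)
        rb.append(sb[j] if j is not None else GAP)
    return (
        replace(a, residues="".join(ra)),
        replace(b, residues="".join(rb)),
        score,
    )


class Alignment:
    """Equal-length gapped sequence records; degapping any row recovers its input."""

    def __init__(self, records: Iterable[SequenceRecord]) -> None:
        self.records: list[SequenceRecord] = list(records)
        if not self.records:
            raise ValueError("alignment needs at least one record")
        widths = {len(r.residues) for r in self.records}
        if len(widths) != 1:
            raise ValueError(f"rows have differing widths: {sorted(widths)}")
        (self.width,) = widths
        cols = np.array([list(r.residues) for r in self.records])
        if ((cols == GAP).all(axis=0)).any():
            raise ValueError("alignment contains an all-gap column")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def row(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def column(self, col: int) -> str:
        """Column ``col`` (1-based) as a string, one character per row."""
        if not 1 <= col <= self.width:
            raise IndexError(f"column {col} outside 1..{self.width}")
        return "".join(r.residues[col - 1] for r in self.records)

    def matrix(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_rows, width); gap = -1."""
        return np.stack([encode(r.residues) for r in self.records])


@dataclass
class _GuideNode:
    members: tuple[int, ...]
    height: float = 0.0
    children: tuple["_GuideNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _pairwise_identity_distances(records: Sequence[SequenceRecord], scheme: ScoringScheme) -> np.ndarray:
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = pairwise_global_align(records[i], records[j], scheme)
            pid = percent_identity(ga.residues, gb.residues)
            d[i, j] = d[j, i] = 1.0 - pid / 100.0
    return d


def guide_tree(seqs: SequenceSet, scheme: ScoringScheme | None = None) -> _GuideNode:
    """UPGMA tree on 1 - identity distances from all pairwise alignments.

    Ties are broken by merging the lexicographically smallest index pair, so
    the tree (and hence the progressive alignment) is deterministic.
    """
    scheme = scheme or ScoringScheme()
    records = list(seqs)
    if len(records) < 2:
        raise ValueError("guide tree needs at least 2 sequences")
    d = _pairwise_identity_distances(records, scheme)
    nodes: dict[int, _GuideNode] = {i: _GuideNode(members=(i,)) for i in range(len(records))}
    sizes = {i: 1 for i in nodes}
    dist = {(i, j): d[i, j] for i in nodes for j in nodes if i < j}
    next_id = len(records)
    while len(nodes) > 1:
        (i, j), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = _GuideNode(
            members=nodes[i].members + nodes[j].members,
            height=dist[(i, j)] / 2.0,
            children=(nodes[i], nodes[j]),
        )
        si, sj = sizes[i], sizes[j]
        new_dist = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[k] = (si * dik + sj * djk) / (si + sj)
        del nodes[i], nodes[j], sizes[i], sizes[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        nodes[next_id] = merged
        sizes[next_id] = si + sj
        for k, v in new_dist.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return next(iter(nodes.values()))


def _profile(rows: list[np.ndarray]) -> np.ndarray:
    """Residue-frequency profile, shape (width, 21); gaps contribute zero mass."""
    width = len(rows[0])
    prof = np.zeros((width, len(RESIDUE_ORDER)))
    for row in rows:
        nz = row >= 0
        prof[np.nonzero(nz)[0], row[nz]] += 1.0
    return prof / len(rows)


def _merge(rows_a: list[np.ndarray], rows_b: list[np.ndarray], mat: np.ndarray, scheme: ScoringScheme):
    pa, pb = _profile(rows_a), _profile(rows_b)
    sm = pa @ mat @ pb.T
    path, _ = _align_score_matrix(sm, scheme)
    gap_col = -1
    out_a = []
    out_b = []
    ia = np.array([i if i is not None else -1 for i, _ in path])
    ib = np.array([j if j is not None else -1 for _, j in path])
    for row in rows_a:
        new = np.full(len(path), gap_col, dtype=np.int64)
        sel = ia >= 0
        new[sel] = row[ia[sel]]
        out_a.append(new)
    for row in rows_b:
        new = np.full(len(path), gap_col, dtype=np.int64)
        sel = ib >= 0
        new[sel] = row[ib[sel]]
        out_b.append(new)
    return out_a + out_b


def progressive_align(seqs: SequenceSet, scheme: ScoringScheme | None = None) -> Alignment:
    """Profile-profile progressive alignment following the UPGMA guide tree."""
    scheme = scheme or ScoringScheme()
    records = list(seqs)
    if len(records) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    mat = scheme.matrix_array()
    tree = guide_tree(seqs, scheme)

    def align_node(node: _GuideNode) -> tuple[list[int], list[np.ndarray]]:
        if node.is_leaf:
            (idx,) = node.members
            return [idx], [encode(records[idx].ungapped)]
        left, right = node.children
        order_a, rows_a = align_node(left)
        order_b, rows_b = align_node(right)
        merged = _merge(rows_a, rows_b, mat, scheme)
        return order_a + order_b, merged

    order, rows = align_node(tree)
    by_index = dict(zip(order, rows))
    gapped = []
    for idx, rec in enumerate(records):
        row = by_index[idx]
        chars = [GAP if v < 0 else RESIDUE_ORDER[v] for v in row]
        gapped.append(replace(rec, residues="".join(chars)))
    return Alignment(gapped)
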