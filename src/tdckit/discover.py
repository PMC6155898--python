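"""Discovery of group-discriminative motifs from a class-labeled alignment.

Given an alignment whose rows carry exactly two class labels, each column is
summarised per class by the smallest residue set (greedy, by descending
frequency, ties alphabetical) that covers at least ``1 - epsilon`` of that
class's non-gap residues.  A column is *conserved* in a class when that set
has at most ``k_max`` residues and the class's gap fraction is at most
``max_gap_fraction``; it is *diagnostic* when it is conserved in both
classes and the two covering sets are disjoint.  Maximal runs of columns
conserved in both classes (bridging short non-conserved stretches) that
contain at least one diagnostic column become motif pairs, rendered in the
same ``[X/Y]`` dialect the scanner consumes — so discovered signatures can
be fed straight back into classification.

Conservation is defined by covering-set size rather than entropy because the
covering set *is* the degenerate pattern being reported; there is no extra
translation step between statistic and output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .msa import Alignment
from .seq_core import GAP, SequenceRecord
from .signatures import DegenerateMotif, SignaturePair, motif_to_string


@dataclass(frozen=True)
class DiscoveryConfig:
    """Knobs of the conserved/diagnostic column definitions.

    k_max: maximum covering-set size for a conserved column.
    epsilon: fraction of a class's non-gap residues the set may fail to
        cover (0 demands every member be covered; raise for noisy inputs).
    max_gap_fraction: columns gappier than this in either class are ignored.
    merge_gap: longest non-conserved stretch bridged inside one motif.
    min_length: minimum motif span in columns.
    """

    k_max: int = 3
    epsilon: float = 0.0
    max_gap_fraction: float = 0.1
    merge_gap: int = 1
    min_length: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.merge_gap < 0 or self.min_length < 1:
            raise ValueError("merge_gap >= 0 and min_length >= 1 required")


class LabeledAlignment:
    """An :class:`~tdckit.msa.Alignment` whose rows carry exactly two class labels."""

    def __init__(self, alignment: Alignment) -> None:
        self.alignment = alignment
        labels = [r.class_label for r in alignment]
        self.classes = tuple(sorted(set(labels)))
        if len(self.classes) != 2:
            raise ValueError(
                f"labeled alignment needs exactly two classes, got {self.classes}"
            )
        for cls in self.classes:
            if labels.count(cls) < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 rows")
        self.labels = labels

    @property
    def width(self) -> int:
        return self.alignment.width

    def rows_of(self, cls: str) -> list[SequenceRecord]:
        return [r for r, lab in zip(self.alignment, self.labels) if lab == cls]


@dataclass(frozen=True)
class ColumnProfile:
    """Per-class residue frequencies and gap fraction of one column."""

    column: int  # 1-based
    frequencies: dict[str, dict[str, float]]  # class -> residue -> freq (non-gap part)
    gap_fraction: dict[str, float]


def column_profiles(la: LabeledAlignment) -> list[ColumnProfile]:
    """Residue frequencies (over non-gap residues) per column per class."""
    out = []
    for col in range(1, la.width + 1):
        freqs: dict[str, dict[str, float]] = {}
        gaps: dict[str, float] = {}
        for cls in la.classes:
            chars = [r.residues[col - 1] for r in la.rows_of(cls)]
            n_gap = chars.count(GAP)
            gaps[cls] = n_gap / len(chars)
            nongap = [c for c in chars if c != GAP]
            counts = Counter(nongap)
            freqs[cls] = (
                {c: counts[c] / len(nongap) for c in sorted(counts)} if nongap else {}
            )
        out.append(ColumnProfile(column=col, frequencies=freqs, gap_fraction=gaps))
    return out


def _covering_set(chars: list[str], epsilon: float) -> tuple[str, ...] | None:
    """Greedy minimal residue set covering >= 1 - epsilon of ``chars``.

    ``X`` is never admitted to a set (it is an ambiguity code, not evidence of
    conservation) but still counts in the denominator.  Returns residues in
    descending-frequency order (ties alphabetical), or None when no such set
    exists.
    """
    if not chars:
        return None
    needed = (1.0 - epsilon) * len(chars)
    counts = Counter(c for c in chars if c != "X")
    covered = 0
    chosen: list[str] = []
    for res, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        chosen.append(res)
        covered += cnt
        if covered >= needed - 1e-9:
            return tuple(chosen)
    return None  # X residues made full coverage impossible


def _column_state(la: LabeledAlignment, cfg: DiscoveryConfig):
    """Per column and class: (covering set or None, conserved flag)."""
    width = la.width
    class_rows = {cls: [r.residues for r in la.rows_of(cls)] for cls in la.classes}
    states = []
    for col in range(width):
        per_class = {}
        for cls in la.classes:
            chars = [row[col] for row in class_rows[cls]]
            n_gap = chars.count(GAP)
            gap_frac = n_gap / len(chars)
            nongap = [c for c in chars if c != GAP]
            cov = _covering_set(nongap, cfg.epsilon)
            conserved = (
                gap_frac <= cfg.max_gap_fraction
                and cov is not None
                and len(cov) <= cfg.k_max
            )
            per_class[cls] = (cov, conserved)
        states.append(per_class)
    return states


def find_diagnostic_columns(la: LabeledAlignment, cfg: DiscoveryConfig | None = None) -> list[int]:
    """1-based columns conserved in both classes with disjoint covering sets."""
    cfg = cfg or DiscoveryConfig()
    states = _column_state(la, cfg)
    a, b = la.classes
    out = []
    for col0, st in enumerate(states):
        (cov_a, ok_a), (cov_b, ok_b) = st[a], st[b]
        if ok_a and ok_b and not set(cov_a) & set(cov_b):
            out.append(col0 + 1)
    return out


@dataclass(frozen=True)
class DiscoveredMotifPair:
    """One conserved region with class-specific degenerate patterns."""

    span: tuple[int, int]  # 1-based inclusive alignment columns
    patterns: dict[str, str]  # class label -> pattern string
    diagnostic_columns: tuple[int, ...]
    reference_positions: dict[str, int | None]  # class -> ungapped position of span start

    def as_signature_pair(self, tdc_class: str, tydc_class: str, name: str | None = None):
        """View as a scannable :class:`~tdckit.signatures.SignaturePair`."""
        from .signatures import parse_motif

        nm = name or f"cols{self.span[0]}-{self.span[1]}"
        return SignaturePair(
            name=nm,
            tdc_motif=parse_motif(
                self.patterns[tdc_class],
                name=f"{nm}/{tdc_class}",
                reference_position=self.reference_positions.get(tdc_class),
            ),
            tydc_motif=parse_motif(
                self.patterns[tydc_class],
                name=f"{nm}/{tydc_class}",
                reference_position=self.reference_positions.get(tydc_class),
            ),
        )


def column_to_reference_position(alignment: Alignment, row_id: str, column: int) -> int:
    """Map an alignment column (1-based) to the row's ungapped residue number."""
    row = alignment.row(row_id)
    if not 1 <= column <= alignment.width:
        raise IndexError(f"column {column} outside 1..{alignment.width}")
    if row.residues[column - 1] == GAP:
        raise ValueError(f"row {row_id!r} has a gap at column {column}")
    return sum(1 for ch in row.residues[:column] if ch != GAP)


def _class_reference_position(la: LabeledAlignment, cls: str, column: int) -> int | None:
    for rec in la.rows_of(cls):
        if rec.residues[column - 1] != GAP:
            return column_to_reference_position(la.alignment, rec.id, column)
    return None


def extract_motif_pairs(
    la: LabeledAlignment, cfg: DiscoveryConfig | None = None
) -> list[DiscoveredMotifPair]:
    """Motif pairs: runs of doubly conserved columns containing a diagnostic one."""
    cfg = cfg or DiscoveryConfig()
    states = _column_state(la, cfg)
    a, b = la.classes
    both = [st[a][1] and st[b][1] for st in states]
    diagnostic = set(find_diagnostic_columns(la, cfg))

    # a non-conserved column can only be bridged if each class still has
    # residues there to render into the pattern
    class_rows = {cls: [r.residues for r in la.rows_of(cls)] for cls in la.classes}
    def bridgeable(col0: int) -> bool:
        for cls in la.classes:
            chars = {row[col0] for row in class_rows[cls]} - {GAP, "X"}
            if not chars:
                return False
        return True

    runs: list[tuple[int, int]] = []  # 0-based inclusive
    cols = [i for i, flag in enumerate(both) if flag]
    for col in cols:
        if (
            runs
            and col - runs[-1][1] - 1 <= cfg.merge_gap
            and all(bridgeable(c) for c in range(runs[-1][1] + 1, col))
        ):
            runs[-1] = (runs[-1][0], col)
        else:
            runs.append((col, col))

    pairs = []
    for start0, end0 in runs:
        span = (start0 + 1, end0 + 1)
        length = end0 - start0 + 1
        diag_in = tuple(c for c in sorted(diagnostic) if span[0] <= c <= span[1])
        if length < cfg.min_length or not diag_in:
            continue
        patterns = {}
        for cls in (a, b):
            rendered = []
            for col0 in range(start0, end0 + 1):
                cov, ok = states[col0][cls]
                if cov is None:
                    # bridged column too noisy to summarise: fall back to the
                    # full residue inventory of the class
                    chars = sorted(
                        {r.residues[col0] for r in la.rows_of(cls)} - {GAP, "X"}
                    )
                    cov = tuple(chars)
                rendered.append(cov)
            motif = DegenerateMotif(name=f"{cls}:{span[0]}-{span[1]}", positions=tuple(rendered))
            patterns[cls] = motif_to_string(motif)
        pairs.append(
            DiscoveredMotifPair(
                span=span,
                patterns=patterns,
                diagnostic_columns=diag_in,
                reference_positions={
                    cls: _class_reference_position(la, cls, span[0]) for cls in (a, b)
                },
            )
        )
    return pairs


def motif_pairs_to_json(pairs: list[DiscoveredMotifPair], tdc_class: str, tydc_class: str) -> list[dict]:
    """Serialize discovered pairs in the packaged signature-fixture schema."""
    out = []
    for p in pairs:
        sp = p.as_signature_pair(tdc_class, tydc_class)
        from .signatures import diagnostic_positions as _diag

        out.append(
            {
                "name": sp.name,
                "tdc_pattern": p.patterns[tdc_class],
                "tydc_pattern": p.patterns[tydc_class],
                "tdc_position": p.reference_positions.get(tdc_class),
                "tydc_position": p.reference_positions.get(tydc_class),
                "binding": None,
                "diagnostic_hint": sorted(_diag(sp)),
            }
        )
    return out
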