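"""Degenerate signature motifs discriminating TDC from TYDC.

A degenerate motif is an ordered list of allowed-residue sets written in the
``T[H/N]W[L/M]SP`` dialect: a bare letter is a singleton position, a
bracketed slash-separated group lists alternatives.  A *signature pair*
couples the TDC and TYDC variants of the same conserved region; its
*diagnostic positions* are the offsets where the two variants' allowed sets
are disjoint, i.e. where a single residue suffices to tell the classes
apart (e.g. the Q of THWQSP, or the SP/NA doublet in front of the
PLP-region HKW triplet).

The packaged signature set contains the four discriminative region pairs
identified from labeled alignments of 14 plant TDC and 28 plant TYDC
sequences.  The fixture stores the printed diagnostic offsets only as a
hint; the code always recomputes disjointness from the patterns, and a test
asserts the two agree.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seq_core import AMINO_ACIDS, GAP, SequenceRecord

_AA_SET = frozenset(AMINO_ACIDS)


class MotifParseError(ValueError):
    """Raised for malformed motif patterns; carries the offending offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class DegenerateMotif:
    """Ordered allowed-residue sets, optionally anchored at a printed position.

    ``positions`` keeps the residues of each allowed set in their written
    order so patterns round-trip; set semantics apply for matching.
    ``reference_position`` is the 1-based residue number printed with the
    motif in its source alignment and is metadata only — it is never used
    for matching.
    """

    name: str
    positions: tuple[tuple[str, ...], ...]
    reference_position: int | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"motif {self.name!r}: length must be >= 3")
        for off, allowed in enumerate(self.positions, start=1):
            if not allowed:
                raise ValueError(f"motif {self.name!r}: empty set at offset {off}")
            bad = set(allowed) - _AA_SET
            if bad:
                raise ValueError(
                    f"motif {self.name!r}: illegal residues {sorted(bad)} at offset {off}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def allowed_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(frozenset(p) for p in self.positions)

    def pattern(self) -> str:
        return motif_to_string(self)


def parse_motif(
    pattern: str,
    name: str = "",
    reference_position: int | None = None,
    annotation: str | None = None,
) -> DegenerateMotif:
    """Parse a pattern like ``"T[H/N]W[L/M]SP"`` into a :class:`DegenerateMotif`."""
    positions: list[tuple[str, ...]] = []
    i = 0
    n = len(pattern)
    while i < n:
        ch = pattern[i]
        if ch == "[":
            end = pattern.find("]", i)
            if end < 0:
                raise MotifParseError("unbalanced '['", i + 1)
            group = pattern[i + 1 : end]
            alts = group.split("/")
            if any(len(a) != 1 for a in alts):
                raise MotifParseError(f"bad alternative group {group!r}", i + 1)
            seen: list[str] = []
            for a in alts:
                if a not in _AA_SET:
                    raise MotifParseError(f"illegal residue {a!r}", i + 1)
                if a not in seen:
                    seen.append(a)
            positions.append(tuple(seen))
            i = end + 1
        elif ch == "]":
            raise MotifParseError("unmatched ']'", i + 1)
        elif ch in _AA_SET:
            positions.append((ch,))
            i += 1
        else:
            raise MotifParseError(f"illegal character {ch!r}", i + 1)
    return DegenerateMotif(
        name=name or pattern,
        positions=tuple(positions),
        reference_position=reference_position,
        annotation=annotation,
    )


def motif_to_string(motif: DegenerateMotif) -> str:
    """Render a motif back into the bracketed-alternatives dialect."""
    parts = []
    for allowed in motif.positions:
        if len(allowed) == 1:
            parts.append(allowed[0])
        else:
            parts.append("[" + "/".join(allowed) + "]")
    return "".join(parts)


@dataclass(frozen=True)
class SignaturePair:
    """The TDC and TYDC variants of one conserved discriminative region."""

    name: str
    tdc_motif: DegenerateMotif
    tydc_motif: DegenerateMotif

    def __post_init__(self) -> None:
        if len(self.tdc_motif) != len(self.tydc_motif):
            raise ValueError(
                f"pair {self.name!r}: motif lengths differ "
                f"({len(self.tdc_motif)} vs {len(self.tydc_motif)})"
            )


def diagnostic_positions(pair: SignaturePair) -> frozenset[int]:
    """1-based motif offsets where the two variants' allowed sets are disjoint."""
    out = set()
    for off, (sa, sb) in enumerate(
        zip(pair.tdc_motif.allowed_sets, pair.tydc_motif.allowed_sets), start=1
    ):
        if not sa & sb:
            out.add(off)
    return frozenset(out)


class SignatureSet:
    """An ordered collection of signature pairs (the packaged set has four)."""

    def __init__(self, pairs: Iterable[SignaturePair]) -> None:
        self.pairs: list[SignaturePair] = list(pairs)
        if not self.pairs:
            raise ValueError("signature set must not be empty")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i: int) -> SignaturePair:
        return self.pairs[i]


def load_signatures() -> SignatureSet:
    """Load the packaged four-pair TDC/TYDC signature set."""
    raw = json.loads(
        importlib.resources.files("tdckit.data").joinpath("signatures.json").read_text()
    )
    pairs = []
    for row in raw:
        pairs.append(
            SignaturePair(
                name=row["name"],
                tdc_motif=parse_motif(
                    row["tdc_pattern"],
                    name=f"{row['name']}/TDC",
                    reference_position=row.get("tdc_position"),
                    annotation=row.get("binding"),
                ),
                tydc_motif=parse_motif(
                    row["tydc_pattern"],
                    name=f"{row['name']}/TYDC",
                    reference_position=row.get("tydc_position"),
                    annotation=row.get("binding"),
                ),
            )
        )
    return SignatureSet(pairs)


def load_signature_hints() -> list[frozenset[int]]:
    """The fixture's printed diagnostic offsets (hints; code recomputes them)."""
    raw = json.loads(
        importlib.resources.files("tdckit.data").joinpath("signatures.json").read_text()
    )
    return [frozenset(row.get("diagnostic_hint", [])) for row in raw]


@dataclass(frozen=True)
class Match:
    """One ungapped window of a sequence matching a motif."""

    start: int  # 1-based offset in the scanned sequence
    matched: str
    n_mismatch: int
    mismatch_offsets: frozenset[int]  # 1-based offsets within the motif


def scan(
    seq: SequenceRecord | str,
    motif: DegenerateMotif,
    max_mismatch: int = 0,
    diagnostic_strict: Iterable[int] = (),
) -> list[Match]:
    """All ungapped windows of ``seq`` matching ``motif``.

    Offsets listed in ``diagnostic_strict`` (1-based, within the motif) must
    match their allowed set exactly; the remaining offsets may mismatch at up
    to ``max_mismatch`` positions.  ``X`` and gap characters never satisfy an
    allowed set.  Results are sorted by (mismatch count, start).  A sequence
    shorter than the motif yields an empty list.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    L = len(motif)
    S = len(residues)
    if S < L:
        return []
    strict = frozenset(diagnostic_strict)
    if strict and not strict <= set(range(1, L + 1)):
        raise ValueError(f"strict offsets {sorted(strict)} outside motif 1..{L}")
    # boolean membership table: allowed[k, c] for motif offset k, character c
    chars = sorted(set(residues))
    char_idx = {c: i for i, c in enumerate(chars)}
    allowed = np.zeros((L, len(chars)), dtype=bool)
    for k, allowed_set in enumerate(motif.allowed_sets):
        for c in allowed_set:
            if c in char_idx:
                allowed[k, char_idx[c]] = True
    enc = np.array([char_idx[c] for c in residues], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    hit = allowed[np.arange(L)[None, :], windows]  # (n_windows, L)
    miss = ~hit
    strict_mask = np.zeros(L, dtype=bool)
    for off in strict:
        strict_mask[off - 1] = True
    ok = (~miss[:, strict_mask].any(axis=1)) & (
        miss[:, ~strict_mask].sum(axis=1) <= max_mismatch
    )
    matches = []
    for w in np.nonzero(ok)[0]:
        offs = frozenset(int(k) + 1 for k in np.nonzero(miss[w])[0])
        matches.append(
            Match(
                start=int(w) + 1,
                matched=residues[w : w + L],
                n_mismatch=len(offs),
                mismatch_offsets=offs,
            )
        )
    matches.sort(key=lambda m: (m.n_mismatch, m.start))
    return matches
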