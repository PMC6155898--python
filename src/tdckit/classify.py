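"""Signature-based TDC/TYDC classification.

Each of the four signature pairs casts at most one vote: both variants are
scanned against the (degapped) query, and the class whose variant achieves
the better best match — fewer mismatches, with diagnostic offsets required
to match exactly — wins the pair's vote.  Equal best matches, or no match
for either variant, give no vote.  A class label is called when the winning
side reaches ``min_votes`` and beats the other side by at least ``margin``;
a query matching nothing is UNCLASSIFIED, anything else AMBIGUOUS.

The default of 3-of-4 votes reflects that one of the four packaged pairs
has no disjoint column at all (its two variants overlap at every offset),
so demanding all four would be fragile, while the strongly diagnostic
SP/NA pair plus two others remain decisive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq_core import TDC, TYDC, SequenceRecord, SequenceSet
from .signatures import Match, SignaturePair, SignatureSet, diagnostic_positions, scan

AMBIGUOUS = "AMBIGUOUS"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassificationConfig:
    """Tolerances of the vote rule.

    max_mismatch: allowed mismatches per motif at non-diagnostic offsets.
    strict_diagnostic: when true, diagnostic offsets must match exactly.
    min_votes: winning-class votes needed to call a label.
    margin: minimum lead of the winner over the loser.
    """

    max_mismatch: int = 1
    strict_diagnostic: bool = True
    min_votes: int = 3
    margin: int = 1

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.margin < 0:
            raise ValueError("max_mismatch and margin must be >= 0")
        if not 1 <= self.min_votes <= 4:
            raise ValueError("min_votes must be in 1..4")


@dataclass(frozen=True)
class PairEvidence:
    """Best match of each variant of one signature pair, and the vote cast."""

    pair_name: str
    tdc_best: Match | None
    tydc_best: Match | None
    vote: str | None  # TDC, TYDC or None


@dataclass(frozen=True)
class ClassificationResult:
    record_id: str
    label: str
    votes_tdc: int
    votes_tydc: int
    evidence: tuple[PairEvidence, ...] = field(default=())


def _best_match(
    seq: SequenceRecord, pair_motif, cfg: ClassificationConfig, strict: frozenset[int]
) -> Match | None:
    hits = scan(
        seq,
        pair_motif,
        max_mismatch=cfg.max_mismatch,
        diagnostic_strict=strict if cfg.strict_diagnostic else (),
    )
    return hits[0] if hits else None


def classify_sequence(
    seq: SequenceRecord,
    sigs: SignatureSet,
    cfg: ClassificationConfig | None = None,
) -> ClassificationResult:
    """Classify one sequence from its signature-motif evidence."""
    cfg = cfg or ClassificationConfig()
    seq = seq.degapped()
    votes = {TDC: 0, TYDC: 0}
    evidence = []
    for pair in sigs:
        strict = diagnostic_positions(pair)
        best_t = _best_match(seq, pair.tdc_motif, cfg, strict)
        best_y = _best_match(seq, pair.tydc_motif, cfg, strict)
        vote: str | None = None
        if best_t is not None and (best_y is None or best_t.n_mismatch < best_y.n_mismatch):
            vote = TDC
        elif best_y is not None and (best_t is None or best_y.n_mismatch < best_t.n_mismatch):
            vote = TYDC
        if vote:
            votes[vote] += 1
        evidence.append(
            PairEvidence(pair_name=pair.name, tdc_best=best_t, tydc_best=best_y, vote=vote)
        )
    vt, vy = votes[TDC], votes[TYDC]
    if vt == 0 and vy == 0:
        label = UNCLASSIFIED
    elif vt == vy:
        # exact vote ties are never called, whatever the margin
        label = AMBIGUOUS
    else:
        winner, lead = (TDC, vt - vy) if vt > vy else (TYDC, vy - vt)
        if max(vt, vy) >= cfg.min_votes and lead >= cfg.margin:
            label = winner
        else:
            label = AMBIGUOUS
    return ClassificationResult(
        record_id=seq.id,
        label=label,
        votes_tdc=vt,
        votes_tydc=vy,
        evidence=tuple(evidence),
    )


def classify_set(
    seqs: SequenceSet,
    sigs: SignatureSet,
    cfg: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Classify every record; one row per record, with per-pair evidence columns."""
    cfg = cfg or ClassificationConfig()
    rows = []
    for rec in seqs:
        res = classify_sequence(rec, sigs, cfg)
        row: dict = {
            "id": res.record_id,
            "label": res.label,
            "votes_tdc": res.votes_tdc,
            "votes_tydc": res.votes_tydc,
        }
        for ev in res.evidence:
            for side, best in (("tdc", ev.tdc_best), ("tydc", ev.tydc_best)):
                prefix = f"{ev.pair_name}_{side}"
                row[f"{prefix}_start"] = best.start if best else pd.NA
                row[f"{prefix}_mismatches"] = best.n_mismatch if best else pd.NA
            row[f"{ev.pair_name}_vote"] = ev.vote or ""
        rows.append(row)
    columns = list(rows[0].keys()) if rows else ["id", "label", "votes_tdc", "votes_tydc"]
    return pd.DataFrame(rows, columns=columns)


def summarize_labels(table: pd.DataFrame) -> dict[str, int]:
    """Counts per assigned label for a :func:`classify_set` table."""
    if table.empty:
        return {}
    return table["label"].value_counts().to_dict()
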