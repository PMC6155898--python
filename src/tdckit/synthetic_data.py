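"""Synthetic two-class protein families with planted signature motifs.

The generator emulates the statistical structure the signature analysis
assumes: a single random ~500-residue backbone shared by both classes,
class-specific degenerate motifs written at fixed anchor positions (each
degenerate position sampled per record from its allowed set), and
independent per-site substitution noise outside the motif windows.  Noise
is never applied inside a motif window: the class signal is exact,
mirroring the premise that the signature regions are conserved within each
class, and within-class motif variability is exactly the allowed-set
variability that the per-record sampling already provides.

Defaults follow the real study conditions: 14 TDC and 28 TYDC sequences of
500 residues, the four packaged signature pairs planted at their printed
anchors (TDC 92/103/167/318, TYDC 137/148/217/369), and 5% per-site noise.

Because the two classes share the backbone, between-class divergence is
attributable entirely to the planted motifs plus noise, which makes the
two-cluster tree property a direct read-out of the planted signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seq_core import AMINO_ACIDS, TDC, TYDC, SequenceRecord, SequenceSet
from .signatures import DegenerateMotif, SignatureSet, load_signatures

_AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class MotifLayout:
    """Where each class's motif variants sit (1-based anchor positions)."""

    signatures: SignatureSet
    tdc_anchors: tuple[int, ...] = (92, 103, 167, 318)
    tydc_anchors: tuple[int, ...] = (137, 148, 217, 369)

    def __post_init__(self) -> None:
        if len(self.tdc_anchors) != len(self.signatures) or len(
            self.tydc_anchors
        ) != len(self.signatures):
            raise ValueError("need one anchor per signature pair and class")

    def windows(self, label: str) -> list[tuple[int, DegenerateMotif]]:
        anchors = self.tdc_anchors if label == TDC else self.tydc_anchors
        out = []
        for anchor, pair in zip(anchors, self.signatures):
            motif = pair.tdc_motif if label == TDC else pair.tydc_motif
            out.append((anchor, motif))
        return out


def default_layout() -> MotifLayout:
    return MotifLayout(signatures=load_signatures())


@dataclass(frozen=True)
class FamilyConfig:
    """Study-scale defaults: 14 + 28 sequences of 500 residues, 5% noise."""

    n_tdc: int = 14
    n_tydc: int = 28
    length: int = 500
    mu: float = 0.05
    seed: int = 0
    motif_layout: MotifLayout = field(default_factory=default_layout)

    def __post_init__(self) -> None:
        if self.n_tdc < 2 or self.n_tydc < 2:
            raise ValueError("need at least 2 sequences per class")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")
        for label in (TDC, TYDC):
            covered: set[int] = set()
            for anchor, motif in self.motif_layout.windows(label):
                window = set(range(anchor, anchor + len(motif)))
                if anchor < 1 or anchor + len(motif) - 1 > self.length:
                    raise ValueError(
                        f"{label} motif at {anchor} does not fit length {self.length}"
                    )
                if covered & window:
                    raise ValueError(f"{label} motif windows overlap at anchor {anchor}")
                covered |= window


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: per-record classes, motif starts, diagnostic columns."""

    labels: dict[str, str]
    motif_starts: dict[str, tuple[int, ...]]  # record id -> anchors of its class
    diagnostic_columns: tuple[int, ...]  # 1-based; disjoint class-ancestor columns
    backbone: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "motif_starts": {k: list(v) for k, v in self.motif_starts.items()},
                "diagnostic_columns": list(self.diagnostic_columns),
                "backbone": self.backbone,
            },
            indent=1,
        )


def _ancestor_sets(cfg: FamilyConfig, backbone: str, label: str) -> list[frozenset[str]]:
    """Per-position allowed sets of the class ancestor (motif set or backbone)."""
    sets = [frozenset([ch]) for ch in backbone]
    for anchor, motif in cfg.motif_layout.windows(label):
        for k, allowed in enumerate(motif.allowed_sets):
            sets[anchor - 1 + k] = allowed
    return sets


def _planted_diagnostic_columns(cfg: FamilyConfig, backbone: str) -> tuple[int, ...]:
    tdc_sets = _ancestor_sets(cfg, backbone, TDC)
    tydc_sets = _ancestor_sets(cfg, backbone, TYDC)
    return tuple(
        col
        for col, (sa, sb) in enumerate(zip(tdc_sets, tydc_sets), start=1)
        if not sa & sb
    )


def generate_family(cfg: FamilyConfig | None = None) -> tuple[SequenceSet, GroundTruth]:
    """Sample a labeled two-class family; deterministic for a given seed."""
    cfg = cfg or FamilyConfig()
    rng = np.random.default_rng(cfg.seed)
    backbone = "".join(rng.choice(_AA, size=cfg.length))
    records = SequenceSet()
    labels: dict[str, str] = {}
    starts: dict[str, tuple[int, ...]] = {}
    for label, count in ((TDC, cfg.n_tdc), (TYDC, cfg.n_tydc)):
        windows = cfg.motif_layout.windows(label)
        motif_mask = np.zeros(cfg.length, dtype=bool)
        for anchor, motif in windows:
            motif_mask[anchor - 1 : anchor - 1 + len(motif)] = True
        anchors = tuple(anchor for anchor, _ in windows)
        for k in range(count):
            seq = np.array(list(backbone))
            # plant this record's motif variants (each degenerate position is
            # drawn per record, so within-class motif variability is exactly
            # the allowed-set variability and nothing else)
            for anchor, motif in windows:
                for off, allowed in enumerate(motif.positions):
                    choices = list(allowed)
                    seq[anchor - 1 + off] = choices[rng.integers(len(choices))]
            # per-site substitution noise outside motif windows
            hit = (rng.random(cfg.length) < cfg.mu) & ~motif_mask
            for pos in np.nonzero(hit)[0]:
                current = seq[pos]
                alternatives = [a for a in AMINO_ACIDS if a != current]
                seq[pos] = alternatives[rng.integers(19)]
            rec_id = f"{label}_{k + 1:02d}"
            records.add(
                SequenceRecord(
                    id=rec_id, residues="".join(seq), class_label=label
                )
            )
            labels[rec_id] = label
            starts[rec_id] = anchors
    truth = GroundTruth(
        labels=labels,
        motif_starts=starts,
        diagnostic_columns=_planted_diagnostic_columns(cfg, backbone),
        backbone=backbone,
    )
    return records, truth


#: Position (1-based) of the single difference between the two Citrus-like sequences.
CITRUS_DIFF_POSITION = 463


def generate_citrus_like_pair(seed: int = 0) -> SequenceSet:
    """Two synthetic TDC-planted 500-mers differing at a single position.

    Emulates the clementine / sweet orange putative-TDC pair: identical
    sequences except for one residue at position 463, i.e. 99.80% identity
    over 500 columns.  Both carry the full TDC signature complement.
    """
    cfg = FamilyConfig(n_tdc=2, n_tydc=2, mu=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    seq = rng.choice(_AA, size=cfg.length)
    for anchor, motif in cfg.motif_layout.windows(TDC):
        for off, allowed in enumerate(motif.positions):
            choices = list(allowed)
            seq[anchor - 1 + off] = choices[rng.integers(len(choices))]
    first = "".join(seq)
    pos0 = CITRUS_DIFF_POSITION - 1
    current = seq[pos0]
    alternatives = [a for a in AMINO_ACIDS if a != current]
    seq[pos0] = alternatives[rng.integers(19)]
    second = "".join(seq)
    out = SequenceSet()
    out.add(
        SequenceRecord(
            id="clementine_pTDC_synthetic",
            residues=first,
            description="synthetic stand-in for the clementine putative TDC",
        )
    )
    out.add(
        SequenceRecord(
            id="sweet_orange_pTDC_synthetic",
            residues=second,
            description="synthetic stand-in for the sweet orange putative TDC",
        )
    )
    return out
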