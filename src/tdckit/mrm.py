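"""MRM transition arithmetic for the tryptamine N-methylation series.

The analytes are tryptamine (C10H12N2) and its mono-, di- and tri-N-methyl
derivatives, each in unlabeled and indole-ring-d5 form.  The mono- and
di-methyl species ionize as [M+H]+; N,N,N-trimethyltryptamine is a
quaternary ammonium cation (C13H19N2+) detected at its own m/z with no
added proton.  Fragmentation proceeds by neutral loss of the amine —
ammonia, methylamine, dimethylamine or trimethylamine depending on the
methylation count — leaving protonated vinylindole (C10H10N+, m/z 144) for
every unlabeled member and its d5 analogue (m/z 149) for every labeled one.

Printed m/z convention: precursor values are *truncated* (floored) to one
decimal and product values to the integer, not rounded.  This matters: the
exact trimethyl precursors are 203.154 and 208.186, reported as 203.1 and
208.1; rounding would give 203.2 and 208.2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator

#: Monoisotopic atomic masses (Da).
ATOMIC_MASS = {
    "H": 1.0078250319,
    "D": 2.0141017780,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
}
#: Proton mass (electron already subtracted from the H atom mass).
PROTON = 1.00727646
#: Electron mass implied by the two constants above.
ELECTRON = ATOMIC_MASS["H"] - PROTON

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaParseError(ValueError):
    pass


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts over C/H/D/N/O plus an integer charge (0 or +1)."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        if self.charge not in (0, 1):
            raise ValueError("charge must be 0 or +1")
        total = sum(n for _, n in self.counts)
        if total <= 0:
            raise ValueError("formula must contain at least one atom")
        for el, n in self.counts:
            if el not in ATOMIC_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")

    def count(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(_canon(merged), charge=self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(f"cannot remove {n} {el} atoms")
        return MolecularFormula(_canon(merged), charge=self.charge - other.charge)


def _canon(counts: dict[str, int]) -> tuple[tuple[str, int], ...]:
    order = {el: i for i, el in enumerate("CHDNO")}
    return tuple(
        sorted(((el, n) for el, n in counts.items() if n > 0), key=lambda x: order[x[0]])
    )


def parse_formula(text: str, charge: int = 0) -> MolecularFormula:
    """Parse ``"C10H12N2"``-style formulas (supported elements: C H D N O)."""
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _FORMULA_RE.match(text, pos)
        if not m or not m.group(1):
            raise FormulaParseError(f"cannot parse formula {text!r} at offset {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise FormulaParseError(f"unsupported element {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaParseError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if not counts:
        raise FormulaParseError(f"empty formula {text!r}")
    return MolecularFormula(_canon(counts), charge=charge)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of monoisotopic atomic masses (the charge is ignored here)."""
    return sum(ATOMIC_MASS[el] * n for el, n in f.counts)


def mz(f: MolecularFormula) -> float:
    """m/z of a singly charged cation: atom-mass sum minus one electron."""
    if f.charge != 1:
        raise ValueError("m/z defined here for +1 cations only")
    return monoisotopic_mass(f) - ELECTRON


@dataclass(frozen=True)
class AnalyteSpec:
    """One member of the methylation series: methyl count and d5 labeling."""

    n_methyl: int
    labeled_d5: bool = False

    def __post_init__(self) -> None:
        if self.n_methyl not in (0, 1, 2, 3):
            raise ValueError("n_methyl must be 0..3")

    @property
    def name(self) -> str:
        base = {
            0: "tryptamine",
            1: "N-methyltryptamine",
            2: "N,N-dimethyltryptamine",
            3: "N,N,N-trimethyltryptamine",
        }[self.n_methyl]
        return f"[d5]{base}" if self.labeled_d5 else base


_TRYPTAMINE = parse_formula("C10H12N2")
_CH2 = parse_formula("CH2")
_H = parse_formula("H")

#: Neutral losses by methylation count.
NEUTRAL_LOSSES = {
    0: ("ammonia", parse_formula("NH3")),
    1: ("methylamine", parse_formula("CH5N")),
    2: ("dimethylamine", parse_formula("C2H7N")),
    3: ("trimethylamine", parse_formula("C3H9N")),
}


def analyte_formula(a: AnalyteSpec) -> MolecularFormula:
    """The detected cation's composition.

    n_methyl 0-2 are protonated molecules [M+H]+; n_methyl 3 is the intact
    quaternary trimethyltryptammonium cation C13H19N2+ (permanently charged —
    no proton is added in the source, but compositionally the cation equals
    tryptamine + 3 CH2 + H just like the protonated members).  d5 labeling
    swaps the five indole-ring hydrogens for deuterium.
    """
    f = _TRYPTAMINE + _H
    for _ in range(a.n_methyl):
        f = f + _CH2
    cation = MolecularFormula(f.counts, charge=1)
    if a.labeled_d5:
        counts = dict(cation.counts)
        counts["H"] -= 5
        counts["D"] = counts.get("D", 0) + 5
        cation = MolecularFormula(_canon(counts), charge=1)
    return cation


def _truncate(value: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(value * scale + 1e-9) / scale


def precursor_mz(a: AnalyteSpec) -> float:
    """Precursor m/z truncated (floored) to one decimal, as reported."""
    return _truncate(mz(analyte_formula(a)), 1)


def precursor_mz_exact(a: AnalyteSpec) -> float:
    return mz(analyte_formula(a))


def product_mz(a: AnalyteSpec) -> tuple[int, str]:
    """Product-ion m/z (floored to integer) and the neutral loss name."""
    loss_name, loss = NEUTRAL_LOSSES[a.n_methyl]
    value = mz(analyte_formula(a)) - monoisotopic_mass(loss)
    return int(_truncate(value, 0)), loss_name


@dataclass(frozen=True)
class Transition:
    """One MRM precursor-to-product transition with its neutral-loss provenance."""

    analyte: str
    n_methyl: int
    labeled_d5: bool
    precursor_mz: float
    product_mz: int
    neutral_loss: str

    def __post_init__(self) -> None:
        if not self.precursor_mz > self.product_mz:
            raise ValueError("precursor m/z must exceed product m/z")


def transition_table() -> list[Transition]:
    """The eight monitored transitions: unlabeled then d5, by methyl count."""
    out = []
    for labeled in (False, True):
        for n in range(4):
            spec = AnalyteSpec(n_methyl=n, labeled_d5=labeled)
            prod, loss = product_mz(spec)
            out.append(
                Transition(
                    analyte=spec.name,
                    n_methyl=n,
                    labeled_d5=labeled,
                    precursor_mz=precursor_mz(spec),
                    product_mz=prod,
                    neutral_loss=loss,
                )
            )
    return out


def protonated_amine_mz(n_methyl: int) -> int:
    """m/z (floored) of the protonated neutral-loss amine itself.

    The trimethylamine case (n_methyl = 3) is the diagnostic m/z 60 ion seen
    in trimethyltryptamine spectra.
    """
    _, loss = NEUTRAL_LOSSES[n_methyl]
    cation = MolecularFormula((loss + _H).counts, charge=1)
    return int(_truncate(mz(cation), 0))
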