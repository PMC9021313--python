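"""Per-formula indices and rule-based classification of CHNOS molecular formulae.

Ultra-high-resolution mass spectrometry of dissolved organic matter (DOM)
yields, per sample, thousands of assigned neutral elemental compositions
C\\ :sub:`c`\\ H\\ :sub:`h`\\ N\\ :sub:`n`\\ O\\ :sub:`o`\\ S\\ :sub:`s`.
This module computes the standard per-formula descriptors used to interpret
such lists:

* **DBE** — double-bond equivalents, ``c − h/2 + n/2 + 1`` (rings plus double
  bonds to carbon).
* **AI_mod** — modified aromaticity index,
  ``(1 + c − o/2 − s − h/2) / (c − o/2 − s − n)``, clamped to ``[0, 1]``
  (0 when the numerator is negative or the denominator non-positive).
* **NOSC** — nominal oxidation state of carbon,
  ``4 − (4c + h − 3n − 2o − 2s)/c``, a thermodynamic proxy for
  biodegradability under anoxic conditions.
* **Kendrick mass / mass defect** — the IUPAC→Kendrick rescaling by
  ``14 / 14.01565`` that collapses CH2 homologous series onto a shared mass
  defect.
* **CRAM** — carboxylic-rich alicyclic molecules, defined by the three
  inclusive ratio windows DBE/C ∈ [0.30, 0.68], DBE/H ∈ [0.20, 0.95],
  DBE/O ∈ [0.77, 1.75].
* **Compound class** — a mutually exclusive van Krevelen label per formula
  (condensed aromatic, polyphenolic, sugar-like, aliphatic, peptide-like,
  highly unsaturated & phenolic, other), resolved by a documented precedence.

Formulae are neutral: negative-mode electrospray deprotonation bookkeeping is
assumed to be handled by upstream assignment.  Isomers are indistinguishable
at the formula level and no attempt is made to resolve them.

Scalar functions operate on :class:`MolecularFormula`; the vectorised
:func:`indices_table` computes every index for a collection at once and is
the work-horse behind sample-level summaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MolecularFormula",
    "FormulaIndices",
    "FormulaError",
    "NitrogenRuleWarning",
    "parse_formula",
    "dbe",
    "ai_mod",
    "nosc",
    "neutral_mass",
    "kendrick",
    "is_cram",
    "compound_class",
    "heteroatom_class",
    "indices",
    "indices_table",
    "indices_from_counts",
    "CLASS_LABELS",
    "CRAM_BOUNDS",
]

#: Monoisotopic atomic masses (Da) of the CHNOS elements.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Exact mass of a CH2 repeat unit as used in the Kendrick rescaling.
CH2_EXACT_MASS = 14.01565

#: Inclusive CRAM ratio windows: DBE/C, DBE/H, DBE/O.
CRAM_BOUNDS = {
    "dbe_c": (0.30, 0.68),
    "dbe_h": (0.20, 0.95),
    "dbe_o": (0.77, 1.75),
}

# AI_mod class thresholds
_AI_CONDENSED = 0.66
_AI_POLYPHENOLIC = 0.5

CONDENSED_AROMATIC = "condensed_aromatic"
POLYPHENOLIC = "polyphenolic"
HIGHLY_UNSATURATED_PHENOLIC = "highly_unsaturated_phenolic"
ALIPHATIC = "aliphatic"
PEPTIDE_LIKE = "peptide_like"
SUGAR_LIKE = "sugar_like"
OTHER = "other"

#: All mutually exclusive compound-class labels, in precedence order.
CLASS_LABELS = (
    CONDENSED_AROMATIC,
    POLYPHENOLIC,
    SUGAR_LIKE,
    ALIPHATIC,
    PEPTIDE_LIKE,
    HIGHLY_UNSATURATED_PHENOLIC,
    OTHER,
)


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula input."""


class NitrogenRuleWarning(UserWarning):
    """Emitted when h + n is odd (non-integer DBE); assignments are trusted."""


_TOKEN = re.compile(r"([A-Za-z])(\d*)")  # CHNOS only: every symbol is one letter


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """A neutral CHNOS elemental composition.

    Instances are immutable, hashable and usable as table keys; two formulae
    with equal element counts compare equal.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise FormulaError(f"element count {name!r} must be an integer, got {value!r}")
            if value < 0:
                raise FormulaError(f"element count {name!r} must be >= 0, got {value}")
        if self.c < 1:
            raise FormulaError("a molecular formula must contain at least one carbon atom")

    def to_string(self) -> str:
        """Canonical writer: C, H, N, O, S order, count suppressed when 1."""
        parts = []
        for symbol, count in (("C", self.c), ("H", self.h), ("N", self.n),
                              ("O", self.o), ("S", self.s)):
            if count == 0:
                continue
            parts.append(symbol if count == 1 else f"{symbol}{count}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a formula string such as ``"C15H20O7"`` or ``"C15 H21 O8 N1"``.

    Element symbols are restricted to C, H, N, O, S, each appearing at most
    once, with an optional count (absent count means 1).  Whitespace between
    tokens is ignored.  The result round-trips through
    :meth:`MolecularFormula.to_string`.

    Raises
    ------
    FormulaError
        For unknown element symbols, repeated elements, zero carbon, or
        trailing garbage.
    """
    compact = re.sub(r"\s+", "", text)
    if not compact:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(compact):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula {text!r} at position {pos}")
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {text!r}")
        if symbol in counts:
            raise FormulaError(f"element {symbol!r} appears more than once in {text!r}")
        counts[symbol] = int(digits) if digits else 1
        pos = match.end()
    if pos != len(compact):
        raise FormulaError(f"unparseable formula {text!r} at position {pos}")
    f = MolecularFormula(
        c=counts.get("C", 0),
        h=counts.get("H", 0),
        n=counts.get("N", 0),
        o=counts.get("O", 0),
        s=counts.get("S", 0),
    )
    if (f.h + f.n) % 2 == 1:
        warnings.warn(
            f"formula {f} violates the nitrogen rule (h + n odd, non-integer DBE)",
            NitrogenRuleWarning,
            stacklevel=2,
        )
    return f


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents: ``c − h/2 + n/2 + 1``.

    May be negative for chemically impossible compositions; callers that
    care should validate.
    """
    return f.c - f.h / 2.0 + f.n / 2.0 + 1.0


def ai_mod(f: MolecularFormula) -> float:
    """Modified aromaticity index, clamped to ``[0, 1]``.

    ``(1 + c − o/2 − s − h/2) / (c − o/2 − s − n)``; returns 0 when the
    numerator is negative or the denominator is non-positive.
    """
    numerator = 1.0 + f.c - f.o / 2.0 - f.s - f.h / 2.0
    denominator = f.c - f.o / 2.0 - f.s - f.n
    if numerator < 0.0 or denominator <= 0.0:
        return 0.0
    return min(numerator / denominator, 1.0)


def nosc(f: MolecularFormula) -> float:
    """Nominal oxidation state of carbon: ``4 − (4c + h − 3n − 2o − 2s)/c``."""
    return 4.0 - (4.0 * f.c + f.h - 3.0 * f.n - 2.0 * f.o - 2.0 * f.s) / f.c


def neutral_mass(f: MolecularFormula) -> float:
    """Monoisotopic neutral mass in Da."""
    return (
        f.c * MONOISOTOPIC_MASS["C"]
        + f.h * MONOISOTOPIC_MASS["H"]
        + f.n * MONOISOTOPIC_MASS["N"]
        + f.o * MONOISOTOPIC_MASS["O"]
        + f.s * MONOISOTOPIC_MASS["S"]
    )


def kendrick(iupac_mass: float) -> tuple[float, float]:
    """Convert an IUPAC-scale mass to ``(kendrick_mass, kendrick_mass_defect)``.

    ``kendrick_mass = iupac_mass × 14 / 14.01565``;
    ``kmd = round(kendrick_mass) − kendrick_mass``.  Members of a CH2
    homologous series share the same mass defect.

    Raises
    ------
    ValueError
        If ``iupac_mass`` is not strictly positive.
    """
    if iupac_mass <= 0:
        raise ValueError(f"iupac_mass must be > 0, got {iupac_mass}")
    km = iupac_mass * 14.0 / CH2_EXACT_MASS
    kmd = round(km) - km
    return km, kmd


def is_cram(f: MolecularFormula) -> bool:
    """Carboxylic-rich alicyclic molecule test (three inclusive ratio windows).

    Formulae with ``o == 0`` or ``h == 0`` are classified not-CRAM (the
    corresponding ratio is undefined; the CRAM definition presumes
    oxygenated molecules).
    """
    if f.o == 0 or f.h == 0:
        return False
    d = dbe(f)
    lo, hi = CRAM_BOUNDS["dbe_c"]
    if not lo <= d / f.c <= hi:
        return False
    lo, hi = CRAM_BOUNDS["dbe_h"]
    if not lo <= d / f.h <= hi:
        return False
    lo, hi = CRAM_BOUNDS["dbe_o"]
    return CRAM_BOUNDS["dbe_o"][0] <= d / f.o <= CRAM_BOUNDS["dbe_o"][1]


def compound_class(f: MolecularFormula) -> str:
    """Assign the single van Krevelen compound-class label for a formula.

    Rules, evaluated in precedence order so every formula gets exactly one
    label:

    1. ``AI_mod > 0.66`` → condensed aromatic
    2. ``0.5 < AI_mod ≤ 0.66`` → polyphenolic
    3. ``O/C > 0.9`` → sugar-like
    4. ``1.5 ≤ H/C ≤ 2.0``, ``O/C ≤ 0.9``, ``n = 0`` → aliphatic
    5. ``1.5 ≤ H/C ≤ 2.0``, ``n > 0`` → peptide-like
    6. ``AI_mod ≤ 0.5`` and ``H/C < 1.5`` → highly unsaturated & phenolic
    7. otherwise → other

    The extra ``H/C < 1.5`` condition on rule 6 keeps the aliphatic /
    peptide-like band from being swallowed by the aromaticity-index band.
    """
    ai = ai_mod(f)
    hc = f.h / f.c
    oc = f.o / f.c
    if ai > _AI_CONDENSED:
        return CONDENSED_AROMATIC
    if ai > _AI_POLYPHENOLIC:
        return POLYPHENOLIC
    if oc > 0.9:
        return SUGAR_LIKE
    if 1.5 <= hc <= 2.0 and oc <= 0.9 and f.n == 0:
        return ALIPHATIC
    if 1.5 <= hc <= 2.0 and f.n > 0:
        return PEPTIDE_LIKE
    if ai <= _AI_POLYPHENOLIC and hc < 1.5:
        return HIGHLY_UNSATURATED_PHENOLIC
    return OTHER


def heteroatom_class(f: MolecularFormula) -> str:
    """Heteroatom class: CHO, CHON, CHOS or CHONS."""
    if f.n > 0 and f.s > 0:
        return "CHONS"
    if f.n > 0:
        return "CHON"
    if f.s > 0:
        return "CHOS"
    return "CHO"


@dataclass(frozen=True)
class FormulaIndices:
    """Bundle of the derived per-formula quantities."""

    dbe: float
    hc: float
    oc: float
    ai_mod: float
    nosc: float
    neutral_mass: float
    kendrick_mass: float
    kmd: float
    label: str
    is_cram: bool
    heteroatom_class: str


def indices(f: MolecularFormula) -> FormulaIndices:
    """Compute every per-formula index for one formula."""
    mass = neutral_mass(f)
    km, kmd = kendrick(mass)
    return FormulaIndices(
        dbe=dbe(f),
        hc=f.h / f.c,
        oc=f.o / f.c,
        ai_mod=ai_mod(f),
        nosc=nosc(f),
        neutral_mass=mass,
        kendrick_mass=km,
        kmd=kmd,
        label=compound_class(f),
        is_cram=is_cram(f),
        heteroatom_class=heteroatom_class(f),
    )


def _counts_frame(formulae: Iterable[MolecularFormula | str]) -> pd.DataFrame:
    parsed = [parse_formula(f) if isinstance(f, str) else f for f in formulae]
    return pd.DataFrame(
        {
            "c": [f.c for f in parsed],
            "h": [f.h for f in parsed],
            "n": [f.n for f in parsed],
            "o": [f.o for f in parsed],
            "s": [f.s for f in parsed],
        },
        index=pd.Index([f.to_string() for f in parsed], name="formula"),
    )


def indices_table(formulae: Iterable[MolecularFormula | str]) -> pd.DataFrame:
    """Vectorised per-formula index table.

    Accepts formulae or formula strings and returns a DataFrame indexed by
    canonical formula string with columns ``c h n o s dbe hc oc ai_mod nosc
    neutral_mass kendrick_mass kmd label is_cram heteroatom_class``.
    Agrees elementwise with the scalar functions.
    """
    return indices_from_counts(_counts_frame(formulae))


def indices_from_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised index computation from a ``c h n o s`` counts DataFrame.

    Lower-level entry point for callers that already hold element counts
    (e.g. exhaustive enumerations); :func:`indices_table` delegates here.
    """
    if (table["c"] < 1).any():
        raise FormulaError("all formulae must contain at least one carbon atom")
    c = table["c"].to_numpy(float)
    h = table["h"].to_numpy(float)
    n = table["n"].to_numpy(float)
    o = table["o"].to_numpy(float)
    s = table["s"].to_numpy(float)

    d = c - h / 2.0 + n / 2.0 + 1.0
    hc = h / c
    oc = o / c

    ai_num = 1.0 + c - o / 2.0 - s - h / 2.0
    ai_den = c - o / 2.0 - s - n
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where((ai_num < 0) | (ai_den <= 0), 0.0, ai_num / np.where(ai_den == 0, 1.0, ai_den))
    ai = np.clip(ai, 0.0, 1.0)

    nosc_v = 4.0 - (4.0 * c + h - 3.0 * n - 2.0 * o - 2.0 * s) / c
    mass = (
        c * MONOISOTOPIC_MASS["C"]
        + h * MONOISOTOPIC_MASS["H"]
        + n * MONOISOTOPIC_MASS["N"]
        + o * MONOISOTOPIC_MASS["O"]
        + s * MONOISOTOPIC_MASS["S"]
    )
    km = mass * 14.0 / CH2_EXACT_MASS
    kmd = np.round(km) - km

    with np.errstate(divide="ignore", invalid="ignore"):
        ok_co = (d / c >= CRAM_BOUNDS["dbe_c"][0]) & (d / c <= CRAM_BOUNDS["dbe_c"][1])
        ok_h = np.where(h > 0, (d / np.where(h == 0, 1, h) >= CRAM_BOUNDS["dbe_h"][0])
                        & (d / np.where(h == 0, 1, h) <= CRAM_BOUNDS["dbe_h"][1]), False)
        ok_o = np.where(o > 0, (d / np.where(o == 0, 1, o) >= CRAM_BOUNDS["dbe_o"][0])
                        & (d / np.where(o == 0, 1, o) <= CRAM_BOUNDS["dbe_o"][1]), False)
    cram = ok_co & ok_h & ok_o & (h > 0) & (o > 0)

    in_ali_band = (hc >= 1.5) & (hc <= 2.0)
    label = np.select(
        [
            ai > _AI_CONDENSED,
            ai > _AI_POLYPHENOLIC,
            oc > 0.9,
            in_ali_band & (oc <= 0.9) & (n == 0),
            in_ali_band & (n > 0),
            (ai <= _AI_POLYPHENOLIC) & (hc < 1.5),
        ],
        [
            CONDENSED_AROMATIC,
            POLYPHENOLIC,
            SUGAR_LIKE,
            ALIPHATIC,
            PEPTIDE_LIKE,
            HIGHLY_UNSATURATED_PHENOLIC,
        ],
        default=OTHER,
    )

    het = np.select(
        [(n > 0) & (s > 0), n > 0, s > 0],
        ["CHONS", "CHON", "CHOS"],
        default="CHO",
    )

    table = table.assign(
        dbe=d, hc=hc, oc=oc, ai_mod=ai, nosc=nosc_v, neutral_mass=mass,
        kendrick_mass=km, kmd=kmd, label=label, is_cram=cram,
        heteroatom_class=het,
    )
    return table
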