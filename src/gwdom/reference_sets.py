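"""Reference formula sets: Island of Stability (IOS) and degradation index (I_DEG).

The IOS is a published collection of carboxylic-rich alicyclic formulae whose
relative abundance increases in aging oxic-water DOM; the degradation index
I_DEG is an intensity ratio over ten reference formulae (five whose intensity
rises and five whose intensity falls with marine DOC age).

Both sets come from appendices of the literature, so they are shipped as
editable delimited text files rather than hard-coded: users holding the
original appendices can drop in their own files.  The packaged defaults are
synthetic stand-ins (see ``data/ios_reference_synthetic.csv`` and
``data/ideg_reference_synthetic.csv``) constructed to have the right
chemistry (CRAM-type compositions at intermediate H/C and O/C) without
reproducing the published lists.

Membership can alternatively be tested against the published H/C–O/C
rectangle of the IOS (``mode="bounds"``); this must be selected explicitly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .formula import MolecularFormula, parse_formula

__all__ = [
    "load_ios_reference",
    "load_ideg_reference",
    "is_ios",
    "ios_membership",
    "IOS_HC_BOUNDS",
    "IOS_OC_BOUNDS",
]

#: Approximate H/C window of the Island of Stability (bounds mode).
IOS_HC_BOUNDS = (1.0, 1.5)
#: Approximate O/C window of the Island of Stability (bounds mode).
IOS_OC_BOUNDS = (0.42, 0.70)


def _packaged(name: str) -> Path:
    return Path(str(resources.files("gwdom").joinpath("data", name)))


def load_ios_reference(path: str | Path | None = None) -> frozenset[MolecularFormula]:
    """Load an IOS reference set from a one-column ``formula`` file.

    Without ``path`` the packaged synthetic stand-in list is used.

    Raises
    ------
    ValueError
        If the file holds no formulae.
    """
    source = Path(path) if path is not None else _packaged("ios_reference_synthetic.csv")
    table = pd.read_csv(source, comment="#")
    if "formula" not in table.columns:
        raise ValueError(f"IOS reference {source} lacks a 'formula' column")
    members = frozenset(parse_formula(text) for text in table["formula"])
    if not members:
        raise ValueError(f"IOS reference {source} is empty")
    return members


def load_ideg_reference(
    path: str | Path | None = None,
) -> tuple[tuple[MolecularFormula, ...], tuple[MolecularFormula, ...]]:
    """Load the ten I_DEG formulae as ``(neg_set, pos_set)``.

    The file has columns ``formula, role`` with role ``neg`` (intensity
    falls with age) or ``pos`` (intensity rises with age); five of each.
    """
    source = Path(path) if path is not None else _packaged("ideg_reference_synthetic.csv")
    table = pd.read_csv(source, comment="#")
    missing = {"formula", "role"} - set(table.columns)
    if missing:
        raise ValueError(f"I_DEG reference {source} lacks columns {sorted(missing)}")
    roles = set(table["role"])
    if not roles <= {"neg", "pos"}:
        raise ValueError(f"I_DEG roles must be 'neg'/'pos', got {sorted(roles)}")
    neg = tuple(parse_formula(t) for t in table.loc[table["role"] == "neg", "formula"])
    pos = tuple(parse_formula(t) for t in table.loc[table["role"] == "pos", "formula"])
    if len(neg) != 5 or len(pos) != 5:
        raise ValueError(
            f"I_DEG reference must hold 5 neg and 5 pos formulae, got {len(neg)}/{len(pos)}"
        )
    return neg, pos


def is_ios(
    f: MolecularFormula,
    reference: frozenset[MolecularFormula] | set[MolecularFormula],
    mode: str = "exact",
) -> bool:
    """Island-of-Stability membership for one formula.

    ``mode="exact"`` (default) tests exact element-count membership in
    ``reference``; ``mode="bounds"`` tests the H/C–O/C rectangle instead and
    ignores the reference set contents (it must still be non-empty in exact
    mode).
    """
    if mode == "exact":
        if not reference:
            raise ValueError("empty IOS reference set")
        return f in reference
    if mode == "bounds":
        hc, oc = f.h / f.c, f.o / f.c
        return IOS_HC_BOUNDS[0] <= hc <= IOS_HC_BOUNDS[1] and IOS_OC_BOUNDS[0] <= oc <= IOS_OC_BOUNDS[1]
    raise ValueError(f"unknown IOS mode {mode!r}")


def ios_membership(
    formulae: Iterable[MolecularFormula | str],
    reference: frozenset[MolecularFormula] | None = None,
    mode: str = "exact",
) -> pd.Series:
    """Vectorised IOS membership over a collection of formulae."""
    if reference is None and mode == "exact":
        reference = load_ios_reference()
    parsed = [parse_formula(f) if isinstance(f, str) else f for f in formulae]
    values = [is_ios(f, reference or frozenset(), mode=mode) for f in parsed]
    return pd.Series(values, index=[f.to_string() for f in parsed], name="is_ios")
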