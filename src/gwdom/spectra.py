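"""Per-sample peak lists, study alignment, and intensity-weighted summaries.

A *sample spectrum* is one FT-ICR MS peak list after formula assignment: a
mapping formula → signal magnitude, plus sample metadata (environment group,
radiocarbon content, DOC concentration).  An *aligned study* stacks several
samples over the union of their formulae, zero-filling absences exactly
(detection below the noise floor is represented as 0, never imputed).

Sample-level summaries are intensity-weighted: a weighted mean of any
per-formula property, percent relative abundance (% RA, 0–100 scale) of
compound classes or arbitrary flag sets, and the degradation index I_DEG
(ratio of five age-negative reference formulae over all ten reference
formulae present).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import formula as fc
from .formula import MolecularFormula, parse_formula

__all__ = [
    "PeakRecord",
    "SampleSpectrum",
    "AlignedStudy",
    "align",
    "relative_intensity",
    "weighted_mean",
    "class_relative_abundance",
    "i_deg",
    "GROUPS",
]

#: Recognised environment groups.
GROUPS = ("stream", "shallow_groundwater", "deep_groundwater", "other")


@dataclass(frozen=True)
class PeakRecord:
    """One assigned peak: formula, signal magnitude, optional measured m/z."""

    formula: MolecularFormula
    intensity: float
    mz: float | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass
class SampleSpectrum:
    """One sample's peak list plus metadata.

    ``pmc`` / ``delta14c`` are the radiocarbon content of the sample's DOC
    (percent modern carbon / per-mille deviation from the 1950 standard);
    ``doc_conc`` is in mg C L⁻¹.  All metadata are optional; operations that
    need a missing field fail loudly for that sample.
    """

    sample_id: str
    group: str
    peaks: list[PeakRecord] = field(default_factory=list)
    pmc: float | None = None
    delta14c: float | None = None
    doc_conc: float | None = None
    collection_year: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        seen: set[MolecularFormula] = set()
        for p in self.peaks:
            if p.formula in seen:
                raise ValueError(
                    f"sample {self.sample_id!r} contains duplicate formula {p.formula}"
                )
            seen.add(p.formula)
        if not self.peaks:
            raise ValueError(f"sample {self.sample_id!r} has no peaks")

    @classmethod
    def from_table(
        cls,
        sample_id: str,
        group: str,
        table: pd.DataFrame,
        **metadata,
    ) -> "SampleSpectrum":
        """Build from a DataFrame with columns ``formula, intensity[, mz]``."""
        peaks = []
        has_mz = "mz" in table.columns
        for row in table.itertuples(index=False):
            f = parse_formula(row.formula) if isinstance(row.formula, str) else row.formula
            peaks.append(
                PeakRecord(f, float(row.intensity), float(row.mz) if has_mz else None)
            )
        return cls(sample_id=sample_id, group=group, peaks=peaks, **metadata)

    def to_table(self) -> pd.DataFrame:
        """Long table ``formula, intensity[, mz]`` with canonical formula strings."""
        data = {
            "formula": [p.formula.to_string() for p in self.peaks],
            "intensity": [p.intensity for p in self.peaks],
        }
        if any(p.mz is not None for p in self.peaks):
            data["mz"] = [p.mz if p.mz is not None else np.nan for p in self.peaks]
        return pd.DataFrame(data)


class AlignedStudy:
    """Formula × sample intensity table over the union of formulae.

    ``intensities`` is a DataFrame indexed by canonical formula string with
    one column per sample; absences are exactly 0.  ``groups`` maps
    sample_id → group; ``metadata`` carries per-sample pmc/delta14c/doc_conc/
    collection_year.  ``formula_table`` (cached) is the per-formula index
    table from :func:`gwdom.formula.indices_table`.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        groups: pd.Series,
        metadata: pd.DataFrame | None = None,
    ) -> None:
        if intensities.empty:
            raise ValueError("empty intensity table")
        if (intensities.sum(axis=0) <= 0).any():
            bad = intensities.columns[intensities.sum(axis=0) <= 0].tolist()
            raise ValueError(f"samples with zero total intensity: {bad}")
        if not intensities.columns.equals(groups.index):
            groups = groups.reindex(intensities.columns)
            if groups.isna().any():
                raise ValueError("groups missing for some samples")
        self.intensities = intensities
        self.groups = groups
        self.metadata = (
            metadata.reindex(intensities.columns)
            if metadata is not None
            else pd.DataFrame(index=intensities.columns)
        )
        self._formula_table: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def formulae(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def formula_table(self) -> pd.DataFrame:
        if self._formula_table is None:
            self._formula_table = fc.indices_table(self.intensities.index)
        return self._formula_table

    def samples_in(self, group: str) -> list[str]:
        ids = [s for s in self.sample_ids if self.groups[s] == group]
        if not ids:
            raise KeyError(f"no samples in group {group!r}")
        return ids


def align(samples: Sequence[SampleSpectrum]) -> AlignedStudy:
    """Align samples over the union of their formulae, zero-filling absences.

    Raises for an empty study or duplicate sample ids; original intensities
    are preserved exactly.
    """
    if not samples:
        raise ValueError("cannot align an empty study")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    columns = {}
    for s in samples:
        columns[s.sample_id] = pd.Series(
            {p.formula.to_string(): p.intensity for p in s.peaks}, dtype=float
        )
    table = pd.DataFrame(columns).fillna(0.0)
    table = table.sort_index()
    groups = pd.Series({s.sample_id: s.group for s in samples}).reindex(table.columns)
    metadata = pd.DataFrame(
        {
            "pmc": {s.sample_id: s.pmc for s in samples},
            "delta14c": {s.sample_id: s.delta14c for s in samples},
            "doc_conc": {s.sample_id: s.doc_conc for s in samples},
            "collection_year": {s.sample_id: s.collection_year for s in samples},
        }
    ).reindex(table.columns)
    return AlignedStudy(table, groups, metadata)


def relative_intensity(study: AlignedStudy) -> AlignedStudy:
    """Rescale every sample column to sum to 1 (idempotent)."""
    sums = study.intensities.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    out = AlignedStudy(study.intensities / sums, study.groups, study.metadata)
    out._formula_table = study._formula_table
    return out


def weighted_mean(intensity: pd.Series, prop: pd.Series) -> float:
    """Intensity-weighted average of a per-formula property for one sample.

    ``Σ(intensity_i × property_i) / Σ(intensity_i)``; the property series is
    aligned to the intensity index.
    """
    total = float(intensity.sum())
    if total <= 0:
        raise ValueError("zero total intensity")
    prop = prop.reindex(intensity.index)
    if prop.isna().any():
        missing = prop.index[prop.isna()].tolist()[:3]
        raise ValueError(f"property missing for formulae such as {missing}")
    return float((intensity * prop).sum() / total)


def weighted_means(study: AlignedStudy, prop: str | pd.Series) -> pd.Series:
    """Weighted mean of a property (name in ``formula_table`` or a Series) per sample."""
    series = study.formula_table[prop] if isinstance(prop, str) else prop
    return pd.Series(
        {sid: weighted_mean(study.intensities[sid], series) for sid in study.sample_ids},
        name=prop if isinstance(prop, str) else getattr(prop, "name", "property"),
    )


def class_relative_abundance(
    intensity: pd.Series,
    membership: pd.Series | pd.DataFrame,
) -> pd.Series | float:
    """% RA of one or several classes for one sample column (0–100 scale).

    ``membership`` is a boolean Series (→ scalar) or a label Series /
    boolean DataFrame (→ Series per class).  Percentages over a mutually
    exclusive label partition sum to 100.
    """
    total = float(intensity.sum())
    if total <= 0:
        raise ValueError("zero total intensity")
    if isinstance(membership, pd.DataFrame):
        member = membership.reindex(intensity.index).fillna(False).astype(bool)
        return 100.0 * member.mul(intensity, axis=0).sum(axis=0) / total
    member = membership.reindex(intensity.index)
    if member.dtype == bool or member.dtype == object and set(member.unique()) <= {True, False}:
        return float(100.0 * intensity[member.astype(bool)].sum() / total)
    # label series → one % per label
    out = {}
    for label in pd.unique(member):
        out[label] = float(100.0 * intensity[member == label].sum() / total)
    return pd.Series(out)


def class_relative_abundances(study: AlignedStudy) -> pd.DataFrame:
    """% RA of every mutually exclusive compound-class label, per sample.

    Returns a class × sample DataFrame; each column sums to 100.
    """
    labels = study.formula_table["label"]
    out = {}
    for sid in study.sample_ids:
        ra = class_relative_abundance(study.intensities[sid], labels)
        out[sid] = ra.reindex(list(fc.CLASS_LABELS)).fillna(0.0)
    return pd.DataFrame(out)


def i_deg(
    intensity: pd.Series,
    neg_set: Sequence[MolecularFormula],
    pos_set: Sequence[MolecularFormula],
) -> tuple[float, int]:
    """Degradation index for one sample column.

    ``Σ(magnitudes of neg_set members present) / Σ(magnitudes of all ten
    present)``, in ``[0, 1]``, together with the count of reference formulae
    missing from the sample.  When none of the ten is present the index is
    undefined and NaN is returned (distinct from 0).  Scale-invariant under
    uniform rescaling of the sample.
    """
    if len(neg_set) != 5 or len(pos_set) != 5:
        raise ValueError("I_DEG requires exactly 5 neg and 5 pos reference formulae")
    keys_neg = [f.to_string() for f in neg_set]
    keys_all = keys_neg + [f.to_string() for f in pos_set]
    present = [k for k in keys_all if k in intensity.index and intensity[k] > 0]
    missing = len(keys_all) - len(present)
    denom = float(intensity.reindex(present).sum()) if present else 0.0
    if denom == 0.0:
        return math.nan, missing
    num = float(intensity.reindex([k for k in keys_neg if k in present]).sum())
    return num / denom, missing


def sample_summary(
    study: AlignedStudy,
    neg_set: Sequence[MolecularFormula] | None = None,
    pos_set: Sequence[MolecularFormula] | None = None,
    ios_reference=None,
    ios_mode: str = "exact",
) -> pd.DataFrame:
    """Tidy per-sample summary table.

    One row per sample with weighted-mean H/C, O/C, NOSC and DBE, % RA per
    compound class, CRAM and IOS % RA, and (when reference sets are given)
    I_DEG.  Uses each sample's own intensities; within one sample the
    summaries are identical for raw and relative intensities.
    """
    from .reference_sets import ios_membership, load_ideg_reference, load_ios_reference

    table = study.formula_table
    rows = {}
    if ios_reference is None and ios_mode == "exact":
        ios_reference = load_ios_reference()
    ios_flags = ios_membership(study.formulae, reference=ios_reference, mode=ios_mode)
    if neg_set is None and pos_set is None:
        neg_set, pos_set = load_ideg_reference()
    for sid in study.sample_ids:
        col = study.intensities[sid]
        row = {
            "group": study.groups[sid],
            "weighted_hc": weighted_mean(col, table["hc"]),
            "weighted_oc": weighted_mean(col, table["oc"]),
            "weighted_nosc": weighted_mean(col, table["nosc"]),
            "weighted_dbe": weighted_mean(col, table["dbe"]),
            "cram_ra": class_relative_abundance(col, table["is_cram"]),
        }
        ra = class_relative_abundance(col, table["label"]).reindex(list(fc.CLASS_LABELS)).fillna(0.0)
        for label in fc.CLASS_LABELS:
            row[f"ra_{label}"] = ra[label]
        if ios_flags is not None:
            row["ios_ra"] = class_relative_abundance(col, ios_flags)
        value, missing = i_deg(col, neg_set, pos_set)
        row["i_deg"] = value
        row["i_deg_missing"] = missing
        rows[sid] = row
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    for column in out.columns:
        if column != "group":
            out[column] = pd.to_numeric(out[column])
    return out
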