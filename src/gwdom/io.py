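"""Readers and writers for the delimited interchange formats.

All formats are comma-separated UTF-8 text with a mandatory header row and
"." decimal separator:

* peak list: ``formula, intensity[, mz]`` (one file per sample)
* study metadata: ``sample_id, group, pmc, delta14c, doc_conc,
  collection_year``
* EEM: wide matrix, first row = emission axis, first column = excitation
  axis (see :mod:`gwdom.fluor`)

A *study directory* holds ``metadata.csv`` plus ``peaks/<sample_id>.csv``.
Output tables written through :func:`write_table` carry ``#``-prefixed
provenance header lines (tool version, seed, configuration hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .formula import FormulaError, parse_formula
from .spectra import GROUPS, PeakRecord, SampleSpectrum

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_metadata",
    "read_study",
    "write_study",
    "write_table",
    "read_table",
    "RunConfig",
    "config_hash",
]

_METADATA_COLUMNS = ("sample_id", "group")
_OPTIONAL_METADATA = ("pmc", "delta14c", "doc_conc", "collection_year")


class SchemaError(ValueError):
    """A required column is missing or a row cannot be parsed."""


def read_peaklist(path: str | Path, sample_id: str | None = None,
                  group: str = "other", **metadata) -> SampleSpectrum:
    """Read one peak list; the sample id defaults to the file stem.

    Unparseable formulae are reported with their line number; duplicate
    formulae reject the load.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty peak list file") from exc
    missing = {"formula", "intensity"} - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    peaks = []
    has_mz = "mz" in table.columns
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            f = parse_formula(str(row.formula))
        except FormulaError as exc:
            raise SchemaError(f"{path}, data row {i + 1}: {exc}") from exc
        mz = float(row.mz) if has_mz and pd.notna(row.mz) else None
        peaks.append(PeakRecord(f, float(row.intensity), mz))
    return SampleSpectrum(
        sample_id=sample_id or path.stem, group=group, peaks=peaks, **metadata
    )


def write_peaklist(spectrum: SampleSpectrum, path: str | Path) -> None:
    spectrum.to_table().to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read study metadata, indexed by sample_id; groups are validated."""
    path = Path(path)
    table = pd.read_csv(path, comment="#")
    missing = set(_METADATA_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"{path}: duplicate sample_id(s) {dup}")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise SchemaError(f"{path}: unknown group(s) {sorted(bad)}; expected {GROUPS}")
    return table.set_index("sample_id")


def write_study(samples: list[SampleSpectrum], directory: str | Path) -> None:
    """Write ``metadata.csv`` plus ``peaks/<sample_id>.csv``."""
    directory = Path(directory)
    (directory / "peaks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "pmc": s.pmc,
                "delta14c": s.delta14c,
                "doc_conc": s.doc_conc,
                "collection_year": s.collection_year,
            }
        )
        write_peaklist(s, directory / "peaks" / f"{s.sample_id}.csv")
    pd.DataFrame(rows).to_csv(directory / "metadata.csv", index=False)


def read_study(directory: str | Path) -> list[SampleSpectrum]:
    """Read a study directory back into sample spectra (round-trips write_study)."""
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.csv")
    samples = []
    for sample_id, row in meta.iterrows():
        extras = {}
        for key in _OPTIONAL_METADATA:
            if key in meta.columns and pd.notna(row[key]):
                value = row[key]
                extras[key] = int(value) if key == "collection_year" else float(value)
        samples.append(
            read_peaklist(
                directory / "peaks" / f"{sample_id}.csv",
                sample_id=str(sample_id),
                group=row["group"],
                **extras,
            )
        )
    return samples


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping, for provenance headers."""
    payload = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path: str | Path,
                meta: dict | None = None, index: bool = False) -> None:
    """Write a CSV with ``#`` provenance header lines (version, seed, config hash)."""
    from . import __version__

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gwdom {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Paths are checked at validation time; the seed is recorded in every
    output header.  ``column_map`` renames deposit-specific column names to
    the expected schema at read time.
    """

    study_dir: str | None = None
    output_dir: str = "."
    seed: int = 0
    ios_reference: str | None = None
    ideg_reference: str | None = None
    ios_mode: str = "exact"
    no_range: tuple[int, int] = (2, 21)
    column_map: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "no_range" in raw:
            raw["no_range"] = tuple(raw["no_range"])
        return cls(**raw)

    def validate(self) -> None:
        for label, value in (
            ("study_dir", self.study_dir),
            ("ios_reference", self.ios_reference),
            ("ideg_reference", self.ideg_reference),
        ):
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{label} path does not exist: {value}")
        if self.ios_mode not in ("exact", "bounds"):
            raise ValueError(f"ios_mode must be 'exact' or 'bounds', got {self.ios_mode!r}")
        if len(self.no_range) != 2 or self.no_range[0] > self.no_range[1]:
            raise ValueError(f"invalid no_range {self.no_range}")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
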