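"""Fluorescence indices from corrected excitation–emission matrices (EEMs).

Inputs are assumed already corrected for inner-filter effects and Rayleigh
scattering and normalised to Raman Units; this module only evaluates the
corrected surface.  Index wavelengths rarely fall exactly on the instrument
grid, so values are read off by bilinear interpolation between the four
surrounding grid nodes (exact at nodes, robust to grid resolution).

Indices:

* **BIX** = F(ex 310, em 380) / F(ex 310, em 430) — biological index;
  values > 1 indicate a larger share of recent microbially derived material.
* **FI**  = F(ex 370, em 450) / F(ex 370, em 500) — fluorescence index;
  ~1.9 indicates microbially derived fulvic acids, ~1.4–1.5 terrestrial.
* **Peak T** = F(ex 275, em 340) — tryptophan-like (protein) intensity in
  Raman Units.

Zero denominators yield NaN (undefined index), never an exception.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EEM", "bix", "fi", "peak_t", "index_report"]


@dataclass
class EEM:
    """A corrected fluorescence excitation–emission matrix.

    ``values[i, j]`` is the intensity at ``excitation[i]``, ``emission[j]``,
    in Raman Units.  Axes must be strictly increasing and match the grid.
    """

    excitation: np.ndarray
    emission: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.excitation = np.asarray(self.excitation, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, axis in (("excitation", self.excitation), ("emission", self.emission)):
            if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
                raise ValueError(f"{name} axis must be 1-D, length >= 2, strictly increasing")
        if self.values.shape != (self.excitation.size, self.emission.size):
            raise ValueError(
                f"grid shape {self.values.shape} does not match axes "
                f"({self.excitation.size}, {self.emission.size})"
            )

    def value(self, ex: float, em: float) -> float:
        """Bilinear interpolation at (excitation, emission) in nm.

        Exact grid nodes return the stored value; queries outside either
        axis raise naming the offending axis.
        """
        for name, axis, q in (("excitation", self.excitation, ex), ("emission", self.emission, em)):
            if q < axis[0] or q > axis[-1]:
                raise ValueError(
                    f"{name} {q} nm outside the grid range [{axis[0]}, {axis[-1]}] nm"
                )
        i = int(np.clip(np.searchsorted(self.excitation, ex, side="right") - 1, 0,
                        self.excitation.size - 2))
        j = int(np.clip(np.searchsorted(self.emission, em, side="right") - 1, 0,
                        self.emission.size - 2))
        x0, x1 = self.excitation[i], self.excitation[i + 1]
        y0, y1 = self.emission[j], self.emission[j + 1]
        tx = (ex - x0) / (x1 - x0)
        ty = (em - y0) / (y1 - y0)
        v = self.values
        return float(
            v[i, j] * (1 - tx) * (1 - ty)
            + v[i + 1, j] * tx * (1 - ty)
            + v[i, j + 1] * (1 - tx) * ty
            + v[i + 1, j + 1] * tx * ty
        )

    @classmethod
    def from_wide_csv(cls, path: str | Path) -> "EEM":
        """Read the wide dialect: first row emission axis, first column excitation axis."""
        frame = pd.read_csv(path, index_col=0, comment="#")
        return cls(
            excitation=frame.index.to_numpy(float),
            emission=frame.columns.to_numpy(float),
            values=frame.to_numpy(float),
        )

    def to_wide_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.excitation, columns=self.emission)
        frame.index.name = "excitation_nm"
        frame.to_csv(path)


def _ratio(eem: EEM, ex: float, em_num: float, em_den: float) -> float:
    denominator = eem.value(ex, em_den)
    if denominator == 0:
        return math.nan
    return eem.value(ex, em_num) / denominator


def bix(eem: EEM) -> float:
    """Biological index: F(310, 380) / F(310, 430); NaN when undefined."""
    return _ratio(eem, 310.0, 380.0, 430.0)


def fi(eem: EEM) -> float:
    """Fluorescence index: F(370, 450) / F(370, 500); NaN when undefined."""
    return _ratio(eem, 370.0, 450.0, 500.0)


def peak_t(eem: EEM) -> float:
    """Tryptophan-like peak intensity F(275, 340), Raman Units."""
    return eem.value(275.0, 340.0)


def index_report(eems: dict[str, EEM]) -> pd.DataFrame:
    """Tidy index table ``sample_id, bix, fi, peak_t`` for several samples."""
    rows = [
        {"sample_id": sid, "bix": bix(e), "fi": fi(e), "peak_t": peak_t(e)}
        for sid, e in eems.items()
    ]
    return pd.DataFrame(rows)
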