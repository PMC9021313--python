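"""Between-group molecular comparison.

Implements the enrichment analysis behind median-difference van Krevelen
diagrams: per-group median intensities over a common formula axis,
enrichment sets by sign of the median difference, per-group unique and
universally common formula sets, and the intensity-difference-weighted
DBE-per-oxygen profile whose ordinary-least-squares slope diagnoses the
functional-group character of the enriched material (a DBE/O slope near 0.5
indicates carboxyl-dominated DOM — one double bond per two oxygens — while
steeper slopes indicate additional rings or C=C bonds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import AlignedStudy

__all__ = [
    "median_by_group",
    "enrichment",
    "unique_and_common",
    "weighted_dbe_profile",
    "dbe_o_slope",
    "RegressionResult",
    "vkd_table",
]

#: Default oxygen-number range entering the DBE–O regression.
DEFAULT_NO_RANGE = (2, 21)


def median_by_group(study: AlignedStudy, group: str) -> pd.Series:
    """Per-formula median intensity over the samples of one group.

    Zero-filled absences count as observations (value 0): the aligned table
    puts every formula on a common axis, and medians are taken over that
    axis to damp the influence of extreme single-sample intensities.  Even
    sample counts use the midpoint of the two central values.
    """
    ids = study.samples_in(group)  # raises KeyError for an unknown group
    return study.intensities[ids].median(axis=1)


def enrichment(
    study: AlignedStudy, group_a: str, group_b: str, threshold: float = 0.0
) -> pd.DataFrame:
    """Median-difference enrichment between two groups.

    Returns a DataFrame indexed by formula with columns ``median_a,
    median_b, diff, enriched_in`` where ``diff = median_b − median_a``.
    ``diff < 0`` → enriched in ``group_a``; ``diff > 0`` → enriched in
    ``group_b``; ties belong to neither set (``enriched_in`` empty).  By
    default only exact ties (``diff == 0``) are excluded; a positive
    ``threshold`` additionally treats ``|diff| ≤ threshold`` as a tie, which
    is useful for suppressing noise-level differences.
    """
    if group_a == group_b:
        raise ValueError(f"group_a and group_b are both {group_a!r}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    med_a = median_by_group(study, group_a)
    med_b = median_by_group(study, group_b)
    diff = med_b - med_a
    enriched_in = np.select(
        [diff < -threshold, diff > threshold], [group_a, group_b], default=""
    )
    return pd.DataFrame(
        {"median_a": med_a, "median_b": med_b, "diff": diff, "enriched_in": enriched_in}
    )


def unique_and_common(study: AlignedStudy) -> dict[str, set[str]]:
    """Per-group unique formula sets plus the universally common set.

    A formula is *unique to a group* when it is detected (nonzero) in at
    least one sample of that group and in no sample of any other group, and
    *common* when it is nonzero in every sample of the study.
    """
    groups = pd.unique(study.groups)
    if len(groups) < 2:
        raise ValueError("unique/common sets need at least two groups")
    detected = study.intensities > 0
    out: dict[str, set[str]] = {}
    for g in groups:
        ids = study.samples_in(g)
        others = [s for s in study.sample_ids if s not in ids]
        mask = detected[ids].any(axis=1) & ~detected[others].any(axis=1)
        out[g] = set(study.intensities.index[mask])
    out["common"] = set(study.intensities.index[detected.all(axis=1)])
    return out


def weighted_dbe_profile(
    enriched: pd.DataFrame,
    formula_table: pd.DataFrame,
) -> pd.DataFrame:
    """Intensity-difference-weighted average DBE per oxygen number.

    ``enriched`` is the subset of an :func:`enrichment` result restricted to
    one enriched set.  For each oxygen count ``n_o`` the weighted DBE is
    ``Σ(dbe_i × |diff_i|) / Σ|diff_i|`` over the formulae with that many
    oxygens; absolute differences are used (within one enriched set the raw
    differences are single-signed anyway).  Rows are returned for every
    populated ``n_o``; range restriction happens at regression time.
    """
    if enriched.empty:
        raise ValueError("empty enriched set")
    sub = formula_table.reindex(enriched.index)
    weights = enriched["diff"].abs()
    frame = pd.DataFrame({"n_o": sub["o"].astype(int), "dbe": sub["dbe"], "w": weights})
    frame = frame[frame["w"] > 0]
    if frame.empty:
        raise ValueError("all intensity differences are zero")
    grouped = frame.groupby("n_o")
    profile = pd.DataFrame(
        {
            "weighted_dbe": grouped.apply(
                lambda g: float((g["dbe"] * g["w"]).sum() / g["w"].sum()),
                include_groups=False,
            ),
            "total_weight": grouped["w"].sum(),
        }
    )
    profile.index.name = "n_o"
    return profile.reset_index()


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares fit of weighted DBE on oxygen number."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_points": self.n_points,
        }


def dbe_o_slope(
    profile: pd.DataFrame,
    no_range: tuple[int, int] | None = DEFAULT_NO_RANGE,
) -> RegressionResult:
    """OLS regression of weighted DBE on oxygen number.

    Categories outside ``no_range`` (default 2–21) are excluded; pass
    ``no_range=None`` to use every populated category.  Two-sided p-value
    for the zero-slope null.
    """
    frame = profile
    if no_range is not None:
        frame = profile[(profile["n_o"] >= no_range[0]) & (profile["n_o"] <= no_range[1])]
    if len(frame) < 3:
        raise ValueError(f"need >= 3 populated n_o categories, got {len(frame)}")
    x = frame["n_o"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in n_o")
    fit = stats.linregress(x, frame["weighted_dbe"].to_numpy(float))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_points=len(frame),
    )


def vkd_table(
    study: AlignedStudy,
    group_a: str,
    group_b: str,
    enriched_in: str | None = None,
) -> pd.DataFrame:
    """Export table behind a median-difference van Krevelen panel.

    Columns ``formula, hc, oc, diff, class, heteroatom_class, is_cram``; when
    ``enriched_in`` names one of the two groups only that enriched set is
    returned.
    """
    enr = enrichment(study, group_a, group_b)
    if enriched_in is not None:
        if enriched_in not in (group_a, group_b):
            raise ValueError(f"enriched_in must be {group_a!r} or {group_b!r}")
        enr = enr[enr["enriched_in"] == enriched_in]
    table = study.formula_table.reindex(enr.index)
    return pd.DataFrame(
        {
            "formula": enr.index,
            "hc": table["hc"],
            "oc": table["oc"],
            "diff": enr["diff"],
            "class": table["label"],
            "heteroatom_class": table["heteroatom_class"],
            "is_cram": table["is_cram"],
        }
    ).reset_index(drop=True)
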