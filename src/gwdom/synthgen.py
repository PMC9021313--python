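"""Seeded synthetic studies with the compositional structure the pipeline assumes.

The generator emulates the three-environment design the analysis is built
for — a few stream samples, a larger set of shallow-groundwater samples and
a few deep confined-groundwater samples — with the canonical aging
trajectory: intensity mass shifting toward lower O/C and higher H/C, more
heteroatom-bearing formulae, and increasingly negative Δ14C from stream to
shallow to deep.

Mechanism: a shared pool of chemically plausible CHNOS formulae is drawn
once; each group weights the pool with a Gaussian kernel in (H/C, O/C)
space around its compositional centre (optionally also around a target
DBE-per-oxygen band), and each sample multiplies those weights by
independent lognormal magnitudes.  Intensities below a per-sample detection
quantile are zeroed, producing realistic present/absent structure.  Ground
truth (profiles and per-sample Δ14C) is always returned next to the data so
tests never re-derive it.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import formula as fc
from .agestats import delta14c_to_pmc
from .fluor import EEM
from .formula import MolecularFormula
from .spectra import PeakRecord, SampleSpectrum

__all__ = [
    "GroupProfile",
    "default_profiles",
    "generate_formula_pool",
    "generate_study",
    "generate_eem",
    "eem_closed_form",
]


@dataclass(frozen=True)
class GroupProfile:
    """Target composition of one environment group.

    ``hc_center``/``oc_center`` position the group's intensity mass in van
    Krevelen space with Gaussian spreads; ``heteroatom_prob`` tilts intensity
    toward N/S-bearing formulae (0.5 is neutral); ``dbe_o_slope`` optionally
    concentrates mass near the band DBE ≈ slope · nO (width ``dbe_o_width``
    in DBE units); ``delta14c_range`` is the ‰ interval samples are assigned
    uniformly from.
    """

    name: str
    n_samples: int
    hc_center: float
    hc_spread: float
    oc_center: float
    oc_spread: float
    heteroatom_prob: float = 0.5
    intensity_sigma: float = 0.8
    intensity_scale: float = 1e6
    delta14c_range: tuple[float, float] = (-100.0, 0.0)
    doc_conc_range: tuple[float, float] = (0.5, 2.0)
    dbe_o_slope: float | None = None
    dbe_o_width: float = 2.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.hc_spread <= 0 or self.oc_spread <= 0:
            raise ValueError("spreads must be > 0")
        if not 0.0 <= self.heteroatom_prob <= 1.0:
            raise ValueError("heteroatom_prob must be in [0, 1]")


def default_profiles() -> tuple[GroupProfile, GroupProfile, GroupProfile]:
    """The 3 / 9 / 3 stream → shallow → deep study design.

    Centres encode the aging trajectory (O/C falling, H/C rising, heteroatom
    share and DBE/O band steepness growing with age); Δ14C ranges span
    modern stream water to ~20,000-year-old deep groundwater.
    """
    return (
        GroupProfile(
            name="stream", n_samples=3,
            hc_center=1.10, hc_spread=0.28, oc_center=0.55, oc_spread=0.14,
            heteroatom_prob=0.35, delta14c_range=(-30.0, 40.0),
            doc_conc_range=(1.3, 8.3), dbe_o_slope=0.75,
        ),
        GroupProfile(
            name="shallow_groundwater", n_samples=9,
            hc_center=1.25, hc_spread=0.28, oc_center=0.47, oc_spread=0.14,
            heteroatom_prob=0.40, delta14c_range=(-350.0, -60.0),
            doc_conc_range=(0.5, 1.6), dbe_o_slope=0.5,
        ),
        GroupProfile(
            name="deep_groundwater", n_samples=3,
            hc_center=1.50, hc_spread=0.28, oc_center=0.33, oc_spread=0.14,
            heteroatom_prob=0.65, delta14c_range=(-955.0, -890.0),
            doc_conc_range=(0.75, 1.1), dbe_o_slope=1.0,
        ),
    )


def generate_formula_pool(
    n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> list[MolecularFormula]:
    """Draw ``n`` distinct chemically plausible CHNOS formulae.

    Coverage targets H/C ∈ (0.3, 2.2), O/C ∈ (0, 1.2), c ∈ [8, 40], with
    nitrogen-rule-consistent hydrogen parity and non-negative DBE.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    pool: dict[MolecularFormula, None] = {}
    while len(pool) < n:
        c = int(rng.integers(8, 41))
        n_atoms = int(rng.choice([0, 1, 2], p=[0.70, 0.20, 0.10]))
        s_atoms = int(rng.choice([0, 1], p=[0.90, 0.10]))
        h = int(round(c * rng.uniform(0.3, 2.2)))
        h_max = 2 * c + 2 + n_atoms  # DBE >= 0
        h = min(h, h_max)
        if (h + n_atoms) % 2 == 1:  # nitrogen rule: integer DBE
            h = h - 1 if h > 1 else h + 1
        if h < 1:
            continue
        o = int(np.clip(round(c * rng.uniform(0.0, 1.2)), 0, 30))
        f = MolecularFormula(c=c, h=h, n=n_atoms, o=o, s=s_atoms)
        if f.c - f.h / 2 + f.n / 2 + 1 < 0:
            continue
        pool.setdefault(f, None)
    return list(pool)


def _group_weights(table, profile: GroupProfile) -> np.ndarray:
    hc = table["hc"].to_numpy(float)
    oc = table["oc"].to_numpy(float)
    w = np.exp(
        -0.5 * ((hc - profile.hc_center) / profile.hc_spread) ** 2
        - 0.5 * ((oc - profile.oc_center) / profile.oc_spread) ** 2
    )
    if profile.dbe_o_slope is not None:
        d = table["dbe"].to_numpy(float)
        o = table["o"].to_numpy(float)
        w = w * np.exp(
            -0.5 * ((d - profile.dbe_o_slope * o) / profile.dbe_o_width) ** 2
        )
    het = (table["n"].to_numpy(int) > 0) | (table["s"].to_numpy(int) > 0)
    w = w * np.where(het, 2.0 * profile.heteroatom_prob, 2.0 * (1.0 - profile.heteroatom_prob))
    return w


def generate_study(
    profiles: Sequence[GroupProfile] | None = None,
    pool: Sequence[MolecularFormula] | None = None,
    seed: int | None = None,
    pool_size: int = 1500,
    detection_quantile: float = 0.3,
    collection_year: int = 2017,
    include_reference_sets: bool = True,
) -> tuple[list[SampleSpectrum], dict]:
    """Generate a seeded multi-group study plus its ground truth.

    Returns ``(samples, ground_truth)`` where ``ground_truth`` records the
    seed, the full group profiles, each sample's assigned Δ14C and DOC
    concentration, and each group's *expected* intensity-weighted H/C, O/C
    and CRAM % RA computed analytically from the kernel weights (the
    quantities the pipeline should recover).  Intensities below the
    per-sample ``detection_quantile`` are dropped, so samples carry
    distinct (overlapping) formula sets.

    When the pool is drawn internally and ``include_reference_sets`` is
    true, the packaged IOS and I_DEG reference formulae are appended to the
    pool so that reference-set metrics are defined on synthetic studies
    (in real peak lists these ubiquitous compositions are routinely
    detected).
    """
    if profiles is None:
        profiles = default_profiles()
    if len(profiles) < 2:
        raise ValueError("need at least two group profiles")
    rng = np.random.default_rng(seed)
    if pool is None:
        pool = generate_formula_pool(pool_size, rng=rng)
        if include_reference_sets:
            from .reference_sets import load_ideg_reference, load_ios_reference

            neg, pos = load_ideg_reference()
            extras = list(load_ios_reference()) + list(neg) + list(pos)
            known = set(pool)
            pool = list(pool) + [f for f in sorted(extras) if f not in known]
    if not pool:
        raise ValueError("empty formula pool")
    table = fc.indices_table(pool)
    samples: list[SampleSpectrum] = []
    profile_dicts = [
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(p).items()}
        for p in profiles
    ]
    truth: dict = {"seed": seed, "profiles": profile_dicts, "samples": {}, "expected": {}}
    for profile in profiles:
        weights = _group_weights(table, profile)
        cram = table["is_cram"].to_numpy(bool)
        truth["expected"][profile.name] = {
            "weighted_hc": float((weights * table["hc"].to_numpy(float)).sum() / weights.sum()),
            "weighted_oc": float((weights * table["oc"].to_numpy(float)).sum() / weights.sum()),
            "cram_ra": float(100.0 * weights[cram].sum() / weights.sum()),
        }
        for k in range(profile.n_samples):
            sid = f"{profile.name}_{k + 1:02d}"
            noise = rng.lognormal(mean=0.0, sigma=profile.intensity_sigma, size=len(pool))
            intensity = weights * noise * profile.intensity_scale
            cut = np.quantile(intensity, detection_quantile)
            intensity = np.where(intensity >= cut, intensity, 0.0)
            delta14c = float(rng.uniform(*profile.delta14c_range))
            doc_conc = float(rng.uniform(*profile.doc_conc_range))
            peaks = [
                PeakRecord(f, float(v))
                for f, v in zip(pool, intensity)
                if v > 0
            ]
            samples.append(
                SampleSpectrum(
                    sample_id=sid,
                    group=profile.name,
                    peaks=peaks,
                    delta14c=delta14c,
                    pmc=delta14c_to_pmc(delta14c, collection_year),
                    doc_conc=doc_conc,
                    collection_year=collection_year,
                )
            )
            truth["samples"][sid] = {
                "group": profile.name,
                "delta14c": delta14c,
                "doc_conc": doc_conc,
            }
    return samples, truth


def eem_closed_form(
    ex: float, em: float, peaks: Sequence[tuple[float, float, float, float]]
) -> float:
    """Analytic value of a Gaussian-peak EEM at one point (the oracle).

    Each peak is ``(ex_center, em_center, amplitude, width)`` with a shared
    isotropic width in nm.
    """
    total = 0.0
    for ex_c, em_c, amp, width in peaks:
        total += amp * np.exp(
            -0.5 * ((ex - ex_c) / width) ** 2 - 0.5 * ((em - em_c) / width) ** 2
        )
    return float(total)


def generate_eem(
    peaks: Sequence[tuple[float, float, float, float]],
    excitation: np.ndarray | None = None,
    emission: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> EEM:
    """Synthetic EEM: a sum of bivariate Gaussian peaks plus optional noise.

    Default axes are 240–450 nm excitation and 300–600 nm emission at 5 nm
    steps.  Peak centres outside the axes trigger a warning (not an error).
    The noise-free surface matches :func:`eem_closed_form` at every node.
    """
    if excitation is None:
        excitation = np.arange(240.0, 451.0, 5.0)
    if emission is None:
        emission = np.arange(300.0, 601.0, 5.0)
    excitation = np.asarray(excitation, float)
    emission = np.asarray(emission, float)
    for ex_c, em_c, _, _ in peaks:
        if not (excitation[0] <= ex_c <= excitation[-1]) or not (
            emission[0] <= em_c <= emission[-1]
        ):
            warnings.warn(
                f"peak centre ({ex_c}, {em_c}) nm lies outside the EEM axes",
                UserWarning,
                stacklevel=2,
            )
    ex_grid = excitation[:, None]
    em_grid = emission[None, :]
    values = np.zeros((excitation.size, emission.size))
    for ex_c, em_c, amp, width in peaks:
        values += amp * np.exp(
            -0.5 * ((ex_grid - ex_c) / width) ** 2 - 0.5 * ((em_grid - em_c) / width) ** 2
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, values.shape)
    return EEM(excitation=excitation, emission=emission, values=values)
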