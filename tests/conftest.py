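import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from gwdom import spectra, synthgen
from gwdom.formula import MolecularFormula
from gwdom.spectra import PeakRecord, SampleSpectrum


def make_sample(sample_id, group, peaks, **meta):
    """Build a SampleSpectrum from {formula_string_or_obj: intensity}."""
    from gwdom.formula import parse_formula

    records = [
        PeakRecord(parse_formula(f) if isinstance(f, str) else f, float(v))
        for f, v in peaks.items()
    ]
    return SampleSpectrum(sample_id=sample_id, group=group, peaks=records, **meta)


@pytest.fixture
def toy_study():
    """Two groups x two samples over four formulae with partial overlap."""
    samples = [
        make_sample("s1", "stream", {"C10H12O6": 10.0, "C12H16O6": 4.0, "C20H30O10": 2.0}),
        make_sample("s2", "stream", {"C10H12O6": 8.0, "C12H16O6": 6.0, "C15H20O7": 1.0}),
        make_sample("g1", "shallow_groundwater", {"C10H12O6": 1.0, "C15H20O7": 9.0, "C20H30O10": 5.0}),
        make_sample("g2", "shallow_groundwater", {"C10H12O6": 2.0, "C15H20O7": 7.0, "C20H30O10": 3.0}),
    ]
    return spectra.align(samples)


@pytest.fixture(scope="session")
def synthetic_study():
    """One default-profile synthetic study, fixed seed, with ground truth."""
    samples, truth = synthgen.generate_study(seed=7, pool_size=800)
    return spectra.align(samples), truth


def random_formulae(n, seed):
    """n random (not necessarily chemically sensible) CHNOS formulae."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            MolecularFormula(
                c=int(rng.integers(1, 41)),
                h=int(rng.integers(0, 81)),
                n=int(rng.integers(0, 3)),
                o=int(rng.integers(0, 31)),
                s=int(rng.integers(0, 2)),
            )
        )
    return out
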