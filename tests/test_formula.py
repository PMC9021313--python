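"""Per-formula indices: parsing, DBE, AI_mod, NOSC, Kendrick, CRAM, classes."""

import warnings

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from conftest import random_formulae
from gwdom.formula import (
    CLASS_LABELS,
    CRAM_BOUNDS,
    FormulaError,
    MolecularFormula,
    NitrogenRuleWarning,
    ai_mod,
    compound_class,
    dbe,
    heteroatom_class,
    indices_table,
    is_cram,
    kendrick,
    neutral_mass,
    nosc,
    parse_formula,
)

# hydrogen bounded so DBE >= 0 and oxygen bounded by carbon valence (CO2 limit)
valid_formulae = st.integers(1, 40).flatmap(
    lambda c: st.builds(
        MolecularFormula,
        c=st.just(c),
        h=st.integers(0, 2 * c + 2),
        n=st.integers(0, 2),
        o=st.integers(0, 2 * c),
        s=st.integers(0, 1),
    )
)


class TestParsing:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("CH4", MolecularFormula(1, 4)),
            ("C6H12O6", MolecularFormula(6, 12, o=6)),
            ("C15H21O8N", MolecularFormula(15, 21, n=1, o=8)),
            ("C15 H21 O8 N1", MolecularFormula(15, 21, n=1, o=8)),
            ("C15H20O7", MolecularFormula(15, 20, o=7)),
        ],
    )
    def test_examples(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("C6H6P1", "'P'"),
            ("H12O6", "carbon"),
            ("C6H6C2", "more than once"),
            ("", "empty"),
            ("C6H6-O2", "unparseable"),
        ],
    )
    def test_errors_name_the_problem(self, text, fragment):
        with pytest.raises(FormulaError, match=fragment):
            parse_formula(text)

    def test_nitrogen_rule_is_warning_not_error(self):
        with pytest.warns(NitrogenRuleWarning):
            f = parse_formula("C6H7O2")  # h + n odd
        assert f.h == 7

    @given(valid_formulae)
    @settings(max_examples=200)
    def test_round_trip_through_canonical_writer(self, f):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NitrogenRuleWarning)
            assert parse_formula(f.to_string()) == f

    def test_equal_counts_hash_equal(self):
        a = parse_formula("C6H12O6")
        b = MolecularFormula(6, 12, 0, 6, 0)
        assert a == b and hash(a) == hash(b)
        assert len({a, b}) == 1

    def test_zero_carbon_rejected(self):
        with pytest.raises(FormulaError):
            MolecularFormula(0, 4)


class TestIndices:
    @pytest.mark.parametrize(
        "text, expected",
        [("CH4", 0.0), ("C6H6", 4.0), ("C15H20O7", 6.0)],
    )
    def test_dbe_examples(self, text, expected):
        assert dbe(parse_formula(text)) == expected

    @given(st.integers(1, 40))
    def test_dbe_zero_for_alkanes(self, n):
        assert dbe(MolecularFormula(n, 2 * n + 2)) == 0.0

    @given(valid_formulae)
    @settings(max_examples=200)
    def test_dbe_increments_when_h_drops_by_two(self, f):
        if f.h < 2:
            return
        less = MolecularFormula(f.c, f.h - 2, f.n, f.o, f.s)
        assert dbe(less) == dbe(f) + 1.0

    @pytest.mark.parametrize(
        "text, expected",
        [("C6H12O6", 0.0), ("CH4", 0.0), ("C6H6", 4.0 / 6.0)],
    )
    def test_ai_mod_examples(self, text, expected):
        assert ai_mod(parse_formula(text)) == pytest.approx(expected)

    def test_ai_mod_clamped_to_unit_interval(self):
        for f in random_formulae(500, seed=11):
            assert 0.0 <= ai_mod(f) <= 1.0

    def test_ai_mod_never_increases_under_ch2_homologation(self):
        # adding CH2 (fixed o, s, n) lowers aromaticity, checked exhaustively
        # on small formulae with a positive denominator (c - o/2 > 0; the
        # clamped zero-denominator region has no defined aromaticity)
        for c in range(1, 25):
            for h in range(0, 2 * c + 3, 2):
                for o in (0, 2, 5):
                    if c - o / 2 <= 0:
                        continue
                    f = MolecularFormula(c, h, 0, o, 0)
                    bigger = MolecularFormula(c + 1, h + 2, 0, o, 0)
                    assert ai_mod(bigger) <= ai_mod(f) + 1e-12

    @pytest.mark.parametrize(
        "text, expected",
        [("C6H12O6", 0.0), ("CH4", -4.0), ("C15H20O7", -0.4)],
    )
    def test_nosc_examples(self, text, expected):
        assert nosc(parse_formula(text)) == pytest.approx(expected)

    @given(valid_formulae)
    @settings(max_examples=300)
    def test_nosc_within_carbon_oxidation_limits(self, f):
        # valence feasibility: heteroatom bonds must fit the C-H skeleton
        assume(3 * f.n + 2 * f.o + 2 * f.s <= 4 * f.c + f.h)
        assert -4.0 - 1e-12 <= nosc(f) <= 4.0 + 1e-12

    def test_kendrick_scale_definition(self):
        km, kmd = kendrick(14.01565)
        assert km == pytest.approx(14.0, abs=1e-9)
        assert kmd == pytest.approx(0.0, abs=1e-9)
        km10, _ = kendrick(280.3130)
        assert km10 == pytest.approx(280.0, abs=1e-9)

    def test_ch2_homologues_share_kendrick_mass_defect(self):
        f = parse_formula("C15H20O7")
        g = MolecularFormula(f.c + 1, f.h + 2, f.n, f.o, f.s)
        _, kmd_f = kendrick(neutral_mass(f))
        _, kmd_g = kendrick(neutral_mass(g))
        assert abs(kmd_f - kmd_g) < 1e-6

    def test_kendrick_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            kendrick(0.0)


class TestCram:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("C15H20O7", True),   # ratios 0.40, 0.30, 0.857: all inside
            ("C16H22O8", False),  # dbe/o = 0.75 just below the window
            ("C6H6", False),      # o = 0: DBE/O undefined
        ],
    )
    def test_examples(self, text, expected):
        assert is_cram(parse_formula(text)) is expected

    def test_bounds_inclusive(self):
        # C10H20O4: dbe 1... construct a formula sitting exactly on a bound:
        # dbe/c = 0.30 with c=10 -> dbe=3 -> h = 2(10+1-3) = 16
        f = MolecularFormula(10, 16, 0, 4, 0)
        assert dbe(f) / f.c == pytest.approx(CRAM_BOUNDS["dbe_c"][0])
        # dbe/h = 3/16 = 0.1875 < 0.20 -> not CRAM despite boundary dbe/c
        assert is_cram(f) is False

    def test_agrees_with_interval_oracle_on_random_formulae(self):
        def oracle(f):
            d = f.c - f.h / 2 + f.n / 2 + 1
            if f.o == 0 or f.h == 0:
                return False
            return (
                0.30 <= d / f.c <= 0.68
                and 0.20 <= d / f.h <= 0.95
                and 0.77 <= d / f.o <= 1.75
            )

        formulae = random_formulae(10_000, seed=42)
        mismatches = [f for f in formulae if is_cram(f) != oracle(f)]
        assert mismatches == []


class TestCompoundClass:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("C6H6", "condensed_aromatic"),
            ("C16H32O2", "aliphatic"),
            ("C6H12O6", "sugar_like"),
            ("C10H17NO4", "peptide_like"),
            ("C15H20O7", "highly_unsaturated_phenolic"),
            ("C14H12O3", "polyphenolic"),  # ai = (1+14-1.5-6)/(14-1.5) = 0.60
        ],
    )
    def test_label_examples(self, text, expected):
        assert compound_class(parse_formula(text)) == expected

    def test_every_label_is_known(self):
        for f in random_formulae(2000, seed=3):
            assert compound_class(f) in CLASS_LABELS

    def test_vectorised_table_matches_scalar_functions(self):
        formulae = random_formulae(400, seed=9)
        table = indices_table(formulae)
        # indices_table dedupes nothing but random dupes collapse on index;
        # iterate positionally instead
        for f, (_, row) in zip(formulae, table.iterrows()):
            assert row["dbe"] == pytest.approx(dbe(f))
            assert row["ai_mod"] == pytest.approx(ai_mod(f))
            assert row["nosc"] == pytest.approx(nosc(f))
            assert row["label"] == compound_class(f)
            assert bool(row["is_cram"]) == is_cram(f)
            assert row["heteroatom_class"] == heteroatom_class(f)

    def test_aliphatic_band_not_swallowed_by_hup(self):
        f = parse_formula("C16H32O2")  # H/C = 2.0, AI_mod = 0
        assert compound_class(f) == "aliphatic"

    def test_heteroatom_classes(self):
        assert heteroatom_class(parse_formula("C6H12O6")) == "CHO"
        assert heteroatom_class(parse_formula("C6H13NO2")) == "CHON"
        assert heteroatom_class(parse_formula("C6H12O3S")) == "CHOS"
        assert heteroatom_class(parse_formula("C6H13NO3S")) == "CHONS"
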