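"""Group medians, enrichment sets, unique/common sets and DBE–O regression."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sample
from gwdom import compare, spectra
from gwdom.compare import (
    dbe_o_slope,
    enrichment,
    median_by_group,
    unique_and_common,
    vkd_table,
    weighted_dbe_profile,
)


@pytest.fixture
def two_group_study():
    # 4 formulae, 2 samples per group, hand-checkable medians
    samples = [
        make_sample("a1", "stream", {"C10H12O6": 4.0, "C12H16O6": 1.0, "C15H20O7": 2.0}),
        make_sample("a2", "stream", {"C10H12O6": 10.0, "C12H16O6": 1.0}),
        make_sample("b1", "shallow_groundwater", {"C10H12O6": 1.0, "C15H20O7": 8.0, "C20H30O10": 6.0}),
        make_sample("b2", "shallow_groundwater", {"C15H20O7": 6.0, "C20H30O10": 4.0}),
    ]
    return spectra.align(samples)


class TestMedianByGroup:
    def test_single_sample_group_identity(self):
        samples = [
            make_sample("x", "stream", {"C10H12O6": 5.0}),
            make_sample("y", "deep_groundwater", {"C10H12O6": 1.0}),
        ]
        study = spectra.align(samples)
        med = median_by_group(study, "stream")
        assert med["C10H12O6"] == 5.0

    def test_even_count_midpoint_with_zero_fill(self, two_group_study):
        med = median_by_group(two_group_study, "stream")
        # C15H20O7 present in a1 (2.0), absent (0.0) in a2 -> midpoint 1.0
        assert med["C15H20O7"] == 1.0
        assert med["C10H12O6"] == 7.0

    def test_unknown_group_raises(self, two_group_study):
        with pytest.raises(KeyError):
            median_by_group(two_group_study, "lake")


class TestEnrichment:
    def test_sign_convention_and_sets(self, two_group_study):
        enr = enrichment(two_group_study, "stream", "shallow_groundwater")
        # hand evaluation: medians stream = {C10:7, C12:1, C15:1, C20:0}
        #                  shallow        = {C10:0.5, C12:0, C15:7, C20:5}
        assert enr.loc["C10H12O6", "diff"] == pytest.approx(-6.5)
        assert enr.loc["C10H12O6", "enriched_in"] == "stream"
        assert enr.loc["C15H20O7", "enriched_in"] == "shallow_groundwater"
        assert enr.loc["C20H30O10", "enriched_in"] == "shallow_groundwater"
        assert enr.loc["C12H16O6", "enriched_in"] == "stream"

    def test_identical_groups_all_ties(self):
        peaks = {"C10H12O6": 3.0, "C15H20O7": 5.0}
        samples = [
            make_sample("a1", "stream", peaks),
            make_sample("b1", "shallow_groundwater", peaks),
        ]
        study = spectra.align(samples)
        enr = enrichment(study, "stream", "shallow_groundwater")
        assert (enr["enriched_in"] == "").all()

    def test_formula_only_in_b_enriched_in_b(self, two_group_study):
        enr = enrichment(two_group_study, "stream", "shallow_groundwater")
        assert enr.loc["C20H30O10", "enriched_in"] == "shallow_groundwater"

    def test_swap_symmetry(self, two_group_study):
        ab = enrichment(two_group_study, "stream", "shallow_groundwater")
        ba = enrichment(two_group_study, "shallow_groundwater", "stream")
        assert np.allclose(ab["diff"], -ba["diff"])
        set_a_in_ab = set(ab.index[ab["enriched_in"] == "stream"])
        set_a_in_ba = set(ba.index[ba["enriched_in"] == "stream"])
        assert set_a_in_ab == set_a_in_ba

    def test_same_group_rejected(self, two_group_study):
        with pytest.raises(ValueError):
            enrichment(two_group_study, "stream", "stream")

    def test_threshold_suppresses_small_differences(self, two_group_study):
        enr = enrichment(two_group_study, "stream", "shallow_groundwater", threshold=1.0)
        assert enr.loc["C12H16O6", "enriched_in"] == ""  # |diff| = 1.0 <= threshold


class TestUniqueAndCommon:
    def test_three_group_set_algebra(self):
        samples = [
            make_sample("s1", "stream", {"C10H12O6": 1.0, "C12H16O6": 1.0}),
            make_sample("g1", "shallow_groundwater", {"C10H12O6": 1.0, "C15H20O7": 1.0}),
            make_sample("d1", "deep_groundwater", {"C10H12O6": 1.0, "C20H30O10": 1.0}),
        ]
        study = spectra.align(samples)
        sets = unique_and_common(study)
        assert sets["stream"] == {"C12H16O6"}
        assert sets["shallow_groundwater"] == {"C15H20O7"}
        assert sets["deep_groundwater"] == {"C20H30O10"}
        assert sets["common"] == {"C10H12O6"}

    def test_brute_force_oracle_on_synthetic(self, synthetic_study):
        study, _ = synthetic_study
        sets = unique_and_common(study)
        detected = study.intensities > 0
        groups = study.groups
        for formula in study.formulae[:200]:
            row = detected.loc[formula]
            present_groups = set(groups[row[row].index])
            for g in ("stream", "shallow_groundwater", "deep_groundwater"):
                expected = present_groups == {g}
                assert (formula in sets[g]) == expected
            assert (formula in sets["common"]) == bool(row.all())

    def test_needs_two_groups(self):
        study = spectra.align([make_sample("a", "stream", {"C10H12O6": 1.0})])
        with pytest.raises(ValueError):
            unique_and_common(study)


class TestWeightedDbeProfile:
    def _enriched_frame(self, rows):
        # rows: list of (formula, diff)
        return pd.DataFrame(
            {"diff": [d for _, d in rows]}, index=[f for f, _ in rows]
        )

    def test_single_formula_per_category_identity(self, two_group_study):
        table = two_group_study.formula_table
        enr = self._enriched_frame([("C15H20O7", 2.0)])
        profile = weighted_dbe_profile(enr, table)
        assert len(profile) == 1
        assert profile.iloc[0]["n_o"] == 7
        assert profile.iloc[0]["weighted_dbe"] == pytest.approx(table.loc["C15H20O7", "dbe"])

    def test_hand_arithmetic_two_formulae_one_category(self):
        # two formulae with 6 oxygens: dbe 4 (weight 1) and dbe 8 (weight 3) -> 7
        table = pd.DataFrame(
            {"o": [6, 6], "dbe": [4.0, 8.0]}, index=["C10H14O6", "C14H14O6"]
        )
        enr = self._enriched_frame([("C10H14O6", -1.0), ("C14H14O6", -3.0)])
        profile = weighted_dbe_profile(enr, table)
        assert profile.iloc[0]["weighted_dbe"] == pytest.approx(7.0)
        assert profile.iloc[0]["total_weight"] == pytest.approx(4.0)

    def test_scale_invariance(self, synthetic_study):
        study, _ = synthetic_study
        enr = enrichment(study, "stream", "deep_groundwater")
        deep = enr[enr["enriched_in"] == "deep_groundwater"]
        p1 = weighted_dbe_profile(deep, study.formula_table)
        scaled = deep.assign(diff=deep["diff"] * 1e3)
        p2 = weighted_dbe_profile(scaled, study.formula_table)
        assert np.allclose(p1["weighted_dbe"], p2["weighted_dbe"])

    def test_empty_set_rejected(self, synthetic_study):
        study, _ = synthetic_study
        with pytest.raises(ValueError, match="empty"):
            weighted_dbe_profile(pd.DataFrame(columns=["diff"]), study.formula_table)


class TestDbeOSlope:
    def _line_profile(self, slope, intercept, n_o=None):
        n_o = np.arange(2, 22) if n_o is None else np.asarray(n_o)
        return pd.DataFrame(
            {"n_o": n_o, "weighted_dbe": slope * n_o + intercept,
             "total_weight": np.ones_like(n_o, dtype=float)}
        )

    def test_carboxyl_line_exact(self):
        fit = dbe_o_slope(self._line_profile(0.5, 0.0))
        assert fit.slope == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_unit_slope_with_intercept(self):
        fit = dbe_o_slope(self._line_profile(1.0, 2.0))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self):
        x = np.array([2.0, 5.0, 9.0, 13.0, 20.0])
        y = np.array([1.8, 3.1, 5.4, 6.2, 10.9])
        profile = pd.DataFrame({"n_o": x, "weighted_dbe": y, "total_weight": 1.0})
        fit = dbe_o_slope(profile)
        # closed-form least squares
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        r = np.corrcoef(x, y)[0, 1]
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(r**2)

    def test_range_restriction_default_2_21(self):
        profile = self._line_profile(0.5, 0.0, n_o=np.arange(1, 30))
        fit = dbe_o_slope(profile)
        assert fit.n_points == 20
        fit_all = dbe_o_slope(profile, no_range=None)
        assert fit_all.n_points == 29

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            dbe_o_slope(self._line_profile(0.5, 0.0, n_o=[3, 4]))

    def test_zero_variance_rejected(self):
        profile = pd.DataFrame(
            {"n_o": [5, 5, 5], "weighted_dbe": [1.0, 2.0, 3.0], "total_weight": 1.0}
        )
        with pytest.raises(ValueError, match="variance"):
            dbe_o_slope(profile)


def test_vkd_table_columns_and_restriction(synthetic_study):
    study, _ = synthetic_study
    table = vkd_table(study, "stream", "deep_groundwater", enriched_in="deep_groundwater")
    assert set(table.columns) == {"formula", "hc", "oc", "diff", "class",
                                  "heteroatom_class", "is_cram"}
    assert (table["diff"] > 0).all()
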