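"""Metabolomics computations: normalization, fractions, methylation index,
remethylation threshold, recycling fraction, group statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samtrace import isotopologue as iso


def peak_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "metabolite",
                                       "isotopologue", "peak_area",
                                       "detected"])


class TestNormalization:
    def test_reference_factor_is_one(self, toy_peak_table):
        nf = iso.normalization_factors(toy_peak_table, "s1")
        assert nf["s1"] == 1.0

    def test_uniform_scaling_gives_that_factor(self, toy_peak_table):
        nf = iso.normalization_factors(toy_peak_table, "s1")
        assert nf["s2"] == pytest.approx(2.0)

    def test_mixed_ratios_use_arithmetic_mean(self):
        table = peak_table([
            ("ref", "g", "A", "m+0", 10.0, True),
            ("ref", "g", "B", "m+0", 10.0, True),
            ("s", "g", "A", "m+0", 20.0, True),
            ("s", "g", "B", "m+0", 40.0, True),
        ])
        nf = iso.normalization_factors(table, "ref")
        assert nf["s"] == pytest.approx(3.0)

    def test_zero_reference_area_names_metabolite(self):
        table = peak_table([
            ("ref", "g", "A", "m+0", 0.0, True),
            ("s", "g", "A", "m+0", 5.0, True),
        ])
        with pytest.raises(ValueError, match="'A'"):
            iso.normalization_factors(table, "ref")

    def test_normalize_makes_uniform_sample_match_reference(
            self, toy_peak_table):
        nf = iso.normalization_factors(toy_peak_table, "s1")
        out = iso.normalize(toy_peak_table, nf)
        wide = out.pivot(index="metabolite", columns="sample_id",
                         values="peak_area")
        assert np.allclose(wide["s1"], wide["s2"])

    def test_renormalization_is_identity(self, toy_peak_table):
        nf = iso.normalization_factors(toy_peak_table, "s1")
        once = iso.normalize(toy_peak_table, nf)
        nf2 = iso.normalization_factors(once, "s1")
        twice = iso.normalize(once, nf2)
        assert np.allclose(nf2.to_numpy(), 1.0)
        assert np.allclose(once["peak_area"], twice["peak_area"])

    def test_missing_factor_rejected(self, toy_peak_table):
        with pytest.raises(ValueError, match="s2"):
            iso.normalize(toy_peak_table, pd.Series({"s1": 1.0}))

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_of_normalized_areas(self, scale):
        """Scaling one sample's areas by c scales NF_s by c and leaves the
        normalized areas unchanged."""
        table = peak_table([
            ("ref", "g", "A", "m+0", 10.0, True),
            ("ref", "g", "B", "m+0", 4.0, True),
            ("s", "g", "A", "m+0", 12.0, True),
            ("s", "g", "B", "m+0", 6.0, True),
        ])
        scaled = table.copy()
        mask = scaled["sample_id"] == "s"
        scaled.loc[mask, "peak_area"] *= scale
        nf, nf_scaled = (iso.normalization_factors(t, "ref")
                         for t in (table, scaled))
        assert nf_scaled["s"] == pytest.approx(scale * nf["s"])
        a = iso.normalize(table, nf)
        b = iso.normalize(scaled, nf_scaled)
        assert np.allclose(a["peak_area"], b["peak_area"])


class TestFractions:
    def test_simple_fraction(self):
        table = peak_table([("s", "g", "M", "m+0", 30.0, True),
                            ("s", "g", "M", "m+5", 70.0, True)])
        fr = iso.isotopologue_fractions(table)
        assert fr.loc[fr["isotopologue"] == "m+5", "fraction"].iloc[0] \
            == pytest.approx(0.70)

    def test_unlabeled_only(self):
        table = peak_table([("s", "g", "M", "m+0", 100.0, True)])
        fr = iso.isotopologue_fractions(table)
        assert (fr["fraction"] == 1.0).all()

    def test_all_zero_flagged_missing_not_zero_division(self):
        table = peak_table([("s", "g", "M", "m+0", 0.0, True),
                            ("s", "g", "M", "m+5", 0.0, True)])
        fr = iso.isotopologue_fractions(table)
        assert fr["fraction"].isna().all()

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_fraction_scale_invariance(self, scale):
        table = peak_table([("s", "g", "M", "m+0", 3.0, True),
                            ("s", "g", "M", "m+4", 1.0, True),
                            ("s", "g", "M", "m+5", 6.0, True)])
        scaled = table.copy()
        scaled["peak_area"] *= scale
        a = iso.isotopologue_fractions(table)["fraction"]
        b = iso.isotopologue_fractions(scaled)["fraction"]
        assert np.allclose(a, b)


class TestMethylationIndex:
    @pytest.mark.parametrize("sam,sah,expected", [(10.0, 5.0, 2.0),
                                                  (5.0, 5.0, 1.0)])
    def test_ratio(self, sam, sah, expected):
        table = peak_table([("s", "g", "SAM", "m+0", sam, True),
                            ("s", "g", "SAH", "m+0", sah, True)])
        mi = iso.methylation_index(table)
        assert mi["methylation_index"].iloc[0] == pytest.approx(expected)

    def test_zero_sah_reported_missing(self):
        table = peak_table([("s", "g", "SAM", "m+0", 10.0, True),
                            ("s", "g", "SAH", "m+0", 0.0, True)])
        mi = iso.methylation_index(table)
        assert np.isnan(mi["methylation_index"].iloc[0])


class TestRemethylation:
    def test_cell_below_medium_threshold(self):
        v = iso.remethylation_test({"m+4": 0.029, "m+5": 0.971},
                                   {"m+4": 0.03, "m+5": 0.97})
        assert not v.remethylation_detected

    def test_cell_above_medium_threshold(self):
        v = iso.remethylation_test({"m+4": 0.10, "m+5": 0.90},
                                   {"m+4": 0.03, "m+5": 0.97})
        assert v.remethylation_detected

    def test_equal_statistic_is_no_detection(self):
        v = iso.remethylation_test({"m+4": 0.03, "m+5": 0.97},
                                   {"m+4": 0.03, "m+5": 0.97})
        assert not v.remethylation_detected

    def test_no_labeled_methionine_rejected(self):
        with pytest.raises(ValueError, match="m\\+4"):
            iso.remethylation_test({"m+4": 0.0, "m+5": 0.0},
                                   {"m+4": 0.03, "m+5": 0.97})


class TestRecyclingFraction:
    def test_arithmetic(self):
        assert iso.recycling_fraction(0.013, 0.10) == pytest.approx(0.13)

    def test_zero_sam(self):
        assert iso.recycling_fraction(0.0, 0.10) == 0.0

    def test_zero_atp_undefined(self):
        assert np.isnan(iso.recycling_fraction(0.013, 0.0))


class TestExtracellularPurines:
    def test_per_protein_normalization(self):
        sup = pd.DataFrame({
            "sample_id": ["s", "s"], "group": ["g", "g"],
            "metabolite": ["adenosine", "inosine"],
            "peak_area": [4.0, 6.0], "detected": [True, True]})
        out = iso.extracellular_purines(sup, {"s": 2.0})
        row = out.iloc[0]
        assert (row["adenosine"], row["inosine"], row["ado_plus_ino"]) \
            == (2.0, 3.0, 5.0)

    def test_missing_protein_excluded(self):
        sup = pd.DataFrame({
            "sample_id": ["a", "b"], "group": ["g", "g"],
            "metabolite": ["adenosine", "adenosine"],
            "peak_area": [4.0, 4.0], "detected": [True, True]})
        out = iso.extracellular_purines(sup, {"a": 2.0})
        assert list(out["sample_id"]) == ["a"]


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10)
        res = iso.group_compare({"a": x, "b": x})
        assert res["p_value"] == pytest.approx(1.0)
        assert res["pairwise"][0][3] == "ns"

    def test_huge_separation_is_four_stars(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        res = iso.group_compare({"a": a, "b": b})
        assert res["p_value"] < 1e-4
        assert res["pairwise"][0][3] == "****"

    def test_multigroup_uses_anova_and_tukey(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(m, 1, 8)
                  for k, m in (("a", 0), ("b", 0), ("c", 4))}
        res = iso.group_compare(groups)
        assert res["design"] == "multi-group"
        assert len(res["pairwise"]) == 3
        pmap = {(x, y): p for x, y, p, _ in res["pairwise"]}
        assert pmap[("a", "c")] < 0.001
        assert pmap[("a", "b")] > 0.05

    def test_degenerate_design_fails(self):
        with pytest.raises(ValueError):
            iso.group_compare({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            iso.group_compare({"a": [2.0, 2.0], "b": [2.0, 2.0]})

    @pytest.mark.parametrize("p,stars", [
        (0.2, "ns"), (0.04, "*"), (0.004, "**"), (4e-4, "***"),
        (4e-5, "****")])
    def test_star_buckets(self, p, stars):
        assert iso.significance_stars(p) == stars
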