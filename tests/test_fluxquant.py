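from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hubscope import fluxquant
from hubscope.synthdata import gen_cell_table, gen_facs_table


def exact_ranksum_oracle(x, y):
    """Full enumeration of the rank-sum null (tie-free data).

    Two-sided p = P(U <= u_low or U >= n1*n2 - u_low) over all
    C(n1+n2, n1) equally likely group assignments.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2
    u_low = min(u_obs, n1 * n2 - u_obs)
    hits = total = 0
    for subset in combinations(range(n1 + n2), n1):
        u = sum(i + 1 for i in subset) - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_low or u >= n1 * n2 - u_low:
            hits += 1
    return hits / total


def cells_fixture():
    design = [
        {"condition": "UT", "genotype": "WT", "n_cells": 40, "replicate": r,
         "features": {"surface_intensity": (50.0, 8.0),
                      "total_intensity": (100.0, 10.0)}}
        for r in (1, 2)
    ] + [
        {"condition": "EBSS", "genotype": "WT", "n_cells": 40, "replicate": r,
         "features": {"surface_intensity": (75.0, 8.0),
                      "total_intensity": (100.0, 10.0)}}
        for r in (1, 2)
    ]
    table, truth = gen_cell_table(design, seed=100)
    return table


class TestRatioMetric:
    def test_per_cell_ratio(self):
        t = pd.DataFrame({"surface": [50.0], "total": [100.0]})
        out, n_excl = fluxquant.ratio_metric(t, "surface", "total", name="m")
        assert out["m"].iloc[0] == 0.5 and n_excl == 0

    def test_zero_denominator_excluded_and_counted(self):
        t = pd.DataFrame({"surface": [50.0, 10.0], "total": [100.0, 0.0]})
        out, n_excl = fluxquant.ratio_metric(t, "surface", "total")
        assert len(out) == 1 and n_excl == 1

    def test_scale_invariance(self):
        t = pd.DataFrame({"a": [3.0, 5.0], "b": [6.0, 8.0]})
        r1, _ = fluxquant.ratio_metric(t, "a", "b", name="m")
        t2 = t * 2
        r2, _ = fluxquant.ratio_metric(t2, "a", "b", name="m")
        np.testing.assert_allclose(r1["m"], r2["m"])

    def test_missing_column_errors(self):
        with pytest.raises(KeyError):
            fluxquant.ratio_metric(pd.DataFrame({"a": [1.0]}), "a", "zz")


class TestNormalize:
    def test_reference_mean_becomes_one(self):
        t = pd.DataFrame({"v": [4.0, 4.0, 6.0], "condition": ["UT", "UT", "X"],
                          "genotype": ["WT"] * 3})
        out = fluxquant.normalize_to_reference(t, "v", {"condition": "UT"})
        assert out["v_normalized"].tolist() == [1.0, 1.0, 1.5]

    def test_per_stratum_reference_identity(self):
        t = pd.DataFrame({
            "v": [2.0, 2.0, 5.0, 8.0, 8.0, 4.0],
            "condition": ["UT", "UT", "X", "UT", "UT", "X"],
            "rep": [1, 1, 1, 2, 2, 2]})
        out = fluxquant.normalize_to_reference(t, "v", {"condition": "UT"},
                                               stratum_col="rep")
        for rep in (1, 2):
            ref = out[(out.rep == rep) & (out.condition == "UT")]["v_normalized"]
            assert ref.mean() == pytest.approx(1.0, abs=1e-12)

    def test_missing_reference_names_stratum(self):
        t = pd.DataFrame({"v": [1.0, 2.0], "condition": ["UT", "X"],
                          "rep": [1, 2]})
        with pytest.raises(ValueError, match="2"):
            fluxquant.normalize_to_reference(t, "v", {"condition": "UT"},
                                             stratum_col="rep")

    def test_idempotence(self):
        table = cells_fixture()
        kept, _ = fluxquant.ratio_metric(table, "surface_intensity",
                                         "total_intensity", name="m")
        once = fluxquant.normalize_to_reference(kept, "m", {"condition": "UT"},
                                                stratum_col="replicate")
        twice = fluxquant.normalize_to_reference(once, "m_normalized",
                                                 {"condition": "UT"},
                                                 stratum_col="replicate",
                                                 out_col="again")
        np.testing.assert_allclose(twice["again"], once["m_normalized"],
                                   atol=1e-12)


class TestWellAggregate:
    def test_well_means_and_counts(self):
        t = pd.DataFrame({"well_id": ["w1"] * 3 + ["w2"] * 2,
                          "m": [1.0, 2.0, 3.0, 4.0, 6.0]})
        out = fluxquant.well_aggregate(t, "m")
        assert out.set_index("well_id")["m"].to_dict() == {"w1": 2.0, "w2": 5.0}
        assert out["n_cells"].tolist() == [3, 2]

    def test_empty_well_dropped(self):
        t = pd.DataFrame({"well_id": ["w1", "w2"], "m": [1.0, np.nan]})
        out = fluxquant.well_aggregate(t, "m")
        assert out["well_id"].tolist() == ["w1"]
        assert out.attrs["dropped_wells"] == ["w2"]


class TestOneSampleTest:
    def test_closed_form(self):
        res = fluxquant.one_sample_test([1.1, 1.2, 1.3], mu=1)
        assert res["t"] == pytest.approx(3.4641, abs=1e-4)
        assert res["df"] == 2
        assert res["p_two_sided"] == pytest.approx(0.0742, abs=1e-4)

    def test_constant_at_mu_untestable(self):
        res = fluxquant.one_sample_test([1.0, 1.0, 1.0], mu=1)
        assert res["untestable"]

    def test_negating_deviations_negates_t(self):
        a = fluxquant.one_sample_test([1.1, 1.3, 1.2], mu=1)
        b = fluxquant.one_sample_test([0.9, 0.7, 0.8], mu=1)
        assert b["t"] == pytest.approx(-a["t"], abs=1e-12)

    def test_n_below_two_errors(self):
        with pytest.raises(ValueError):
            fluxquant.one_sample_test([1.0])


class TestGroupCompare:
    def as_table(self, groups):
        return pd.DataFrame({
            "v": np.concatenate(list(groups.values())),
            "g": sum([[k] * len(v) for k, v in groups.items()], []),
        })

    def test_fully_separated_exact_p(self):
        t = self.as_table({"lo": [1, 2, 3, 4, 5], "hi": [6, 7, 8, 9, 10]})
        out = fluxquant.group_compare(t, "v", "g", [("lo", "hi")])
        assert out["method"].iloc[0] == "exact"
        assert out["p"].iloc[0] == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_multisets_p_one(self):
        t = self.as_table({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        out = fluxquant.group_compare(t, "v", "g", [("a", "b")])
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for n1 in range(1, 7):
            for n2 in range(1, 13 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                t = self.as_table({"x": x, "y": y})
                out = fluxquant.group_compare(t, "v", "g", [("x", "y")])
                assert out["method"].iloc[0] == "exact"
                assert out["p"].iloc[0] == pytest.approx(
                    exact_ranksum_oracle(x, y), abs=1e-12), (n1, n2)

    def test_bh_family_matches_oracle(self, rng):
        from conftest import bh_oracle
        groups = {k: rng.normal(loc, 1, size=8)
                  for k, loc in [("a", 0), ("b", 0.5), ("c", 2), ("d", 3)]}
        t = self.as_table(groups)
        comps = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")]
        out = fluxquant.group_compare(t, "v", "g", comps)
        np.testing.assert_allclose(out["q"], bh_oracle(out["p"]), atol=1e-15)

    def test_unknown_group_errors(self):
        t = self.as_table({"a": [1.0, 2.0]})
        with pytest.raises(KeyError):
            fluxquant.group_compare(t, "v", "g", [("a", "zz")])


class TestBoxSummary:
    def test_one_to_nine(self):
        s = fluxquant.box_summary(range(1, 10))
        assert s == {"median": 5.0, "q25": 3.0, "q75": 7.0,
                     "whisker_lo": 1.0, "whisker_hi": 9.0, "outlier_count": 0}

    def test_single_value(self):
        s = fluxquant.box_summary([4.2])
        assert all(s[k] == 4.2 for k in
                   ("median", "q25", "q75", "whisker_lo", "whisker_hi"))

    def test_outlier_moves_whisker_to_fence_point(self):
        s = fluxquant.box_summary(list(range(1, 10)) + [100])
        assert s["outlier_count"] == 1
        assert s["whisker_hi"] == 9.0


class TestMfiFoldChange:
    def test_untreated_mean_is_one_per_line(self):
        facs, _ = gen_facs_table(["WT", "KO"], ["UT", "EBSS"], 1.0,
                                 {"UT": 1.0, "EBSS": 2.0}, 0.05, seed=4)
        out = fluxquant.mfi_fold_change(facs)
        for line in ("WT", "KO"):
            ut = out[(out.cell_line == line) & (out.condition == "UT")]
            assert ut["fold_change"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_doubling_ratio_doubles_fold_change(self):
        facs = pd.DataFrame({
            "cell_line": ["WT"] * 3, "condition": ["UT", "UT", "EBSS"],
            "replicate": [1, 2, 1],
            "mfi_mcherry": [100.0, 100.0, 200.0], "mfi_gfp": [100.0] * 3})
        out = fluxquant.mfi_fold_change(facs)
        assert out.loc[out.condition == "EBSS", "fold_change"].iloc[0] == \
            pytest.approx(2.0, abs=1e-12)

    def test_missing_untreated_names_line(self):
        facs = pd.DataFrame({"cell_line": ["X"], "condition": ["EBSS"],
                             "replicate": [1], "mfi_mcherry": [1.0],
                             "mfi_gfp": [1.0]})
        with pytest.raises(ValueError, match="X"):
            fluxquant.mfi_fold_change(facs)


class TestScatterAndStars:
    def test_log2_pairs_and_exclusions(self):
        t = pd.DataFrame({"x": [1024.0, 0.0], "y": [2.0, 4.0],
                          "puncta_count": [3, 5]})
        out, n_excl = fluxquant.log2_intensity_scatter(t, "x", "y")
        assert n_excl == 1 and len(out) == 1
        assert out["log2_x"].iloc[0] == pytest.approx(10.0)

    @pytest.mark.parametrize("p, stars", [
        (0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"),
        (0.00005, "****")])
    def test_star_conventions(self, p, stars):
        assert fluxquant.p_to_stars(p) == stars
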