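import io

import numpy as np
import pandas as pd
import pytest

from _oracles import welch_p
from crossdiff.data import InputError, InsufficientDataError
from crossdiff.qpcr import (
    anova_bonferroni,
    ddct,
    efficiency_check,
    group_tests,
    percent_of_max,
    read_ct_table,
    significance_tier,
    welch_test,
)


def ct_frame(rows):
    df = pd.DataFrame(rows, columns=["animal", "group", "gene", "ct"])
    df["detected"] = df["ct"].notna()
    return df


class TestDdct:
    def test_equal_target_and_reference_everywhere(self):
        rows = [(f"a{i}", g, gene, 20.0)
                for i, g in enumerate(["ctl", "ctl", "trt", "trt"])
                for gene in ("Tgt", "Ref")]
        out = ddct(ct_frame(rows), "Tgt", "Ref", "ctl")
        np.testing.assert_allclose(out["expression"], 1.0)

    def test_three_cycle_shift_is_eightfold(self):
        rows = [
            ("a1", "ctl", "Tgt", 25.0), ("a1", "ctl", "Ref", 20.0),
            ("a2", "ctl", "Tgt", 25.0), ("a2", "ctl", "Ref", 20.0),
            ("a3", "trt", "Tgt", 22.0), ("a3", "trt", "Ref", 20.0),
            ("a4", "trt", "Tgt", 22.0), ("a4", "trt", "Ref", 20.0),
        ]
        out = ddct(ct_frame(rows), "Tgt", "Ref", "ctl")
        assert out.loc["a3", "expression"] == pytest.approx(8.0)
        assert out.loc["a1", "expression"] == pytest.approx(1.0)

    def test_matches_log_space_oracle(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(12):
            grp = "ctl" if i < 6 else "trt"
            rows.append((f"a{i}", grp, "Tgt", rng.uniform(18, 30)))
            rows.append((f"a{i}", grp, "Ref", rng.uniform(15, 25)))
        table = ct_frame(rows)
        out = ddct(table, "Tgt", "Ref", "ctl")
        tgt = table[table["gene"] == "Tgt"].set_index("animal")
        ref = table[table["gene"] == "Ref"].set_index("animal")
        delta = tgt["ct"] - ref["ct"]
        dd = delta - delta[tgt["group"] == "ctl"].mean()
        np.testing.assert_allclose(out["expression"],
                                   np.exp2(-dd), rtol=1e-12)

    def test_invariant_to_per_animal_ct_offset(self):
        rng = np.random.default_rng(1)
        rows, shifted = [], []
        offsets = rng.uniform(-2, 2, size=6)
        for i in range(6):
            grp = "ctl" if i < 3 else "trt"
            t, r = rng.uniform(20, 28), rng.uniform(16, 22)
            rows += [(f"a{i}", grp, "Tgt", t), (f"a{i}", grp, "Ref", r)]
            shifted += [(f"a{i}", grp, "Tgt", t + offsets[i]),
                        (f"a{i}", grp, "Ref", r + offsets[i])]
        out1 = ddct(ct_frame(rows), "Tgt", "Ref", "ctl")
        out2 = ddct(ct_frame(shifted), "Tgt", "Ref", "ctl")
        np.testing.assert_allclose(out1["expression"], out2["expression"],
                                   rtol=1e-12)

    def test_nd_propagates_and_missing_reference_raises(self):
        rows = [
            ("a1", "ctl", "Tgt", np.nan), ("a1", "ctl", "Ref", 20.0),
            ("a2", "ctl", "Tgt", 24.0), ("a2", "ctl", "Ref", 20.0),
        ]
        out = ddct(ct_frame(rows), "Tgt", "Ref", "ctl")
        assert np.isnan(out.loc["a1", "expression"])
        assert not out.loc["a1", "detected"]
        rows_bad = [("a1", "ctl", "Tgt", 24.0)]
        with pytest.raises(InputError, match="reference"):
            ddct(ct_frame(rows_bad), "Tgt", "Ref", "ctl")

    def test_read_ct_table_parses_nd(self):
        tsv = "animal\tgroup\tgene\tct\na1\tctl\tTgt\tND\na1\tctl\tRef\t19.5\n"
        df = read_ct_table(io.StringIO(tsv))
        assert np.isnan(df.loc[0, "ct"]) and not df.loc[0, "detected"]
        assert df.loc[1, "ct"] == 19.5


class TestPercentOfMax:
    def test_single_group_is_hundred(self):
        df = pd.DataFrame({"group": ["a"] * 3, "expression": [1.0, 2.0, 3.0]})
        out = percent_of_max(df)
        assert out.loc["a", "pct_mean"] == pytest.approx(100.0)

    def test_group_ratio_preserved(self):
        df = pd.DataFrame({"group": ["a"] * 2 + ["b"] * 2,
                           "expression": [2.0, 2.0, 8.0, 8.0]})
        out = percent_of_max(df)
        assert out.loc["a", "pct_mean"] == pytest.approx(25.0)
        assert out.loc["b", "pct_mean"] == pytest.approx(100.0)

    def test_random_ratios_preserved(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "group": np.repeat([f"grp{i}" for i in range(4)], 5),
            "expression": rng.uniform(0.5, 10, size=20),
        })
        out = percent_of_max(df)
        ratio_in = out["mean"] / out["mean"].max()
        np.testing.assert_allclose(out["pct_mean"] / 100.0, ratio_in,
                                   rtol=1e-12)
        assert (out["pct_mean"] <= 100 + 1e-12).all()

    def test_all_nd_raises(self):
        df = pd.DataFrame({"group": ["a", "a"],
                           "expression": [np.nan, np.nan]})
        with pytest.raises(InputError):
            percent_of_max(df)


class TestGroupTests:
    def test_identical_groups_p_one(self):
        t, p = welch_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_welch_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0, 1, size=5)
            b = rng.normal(0.5, 2, size=7)
            _, p = welch_test(a, b)
            assert p == pytest.approx(welch_p(a, b), abs=1e-10)

    def test_welch_symmetric_in_group_order(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=5), rng.normal(size=5)
        ta, pa = welch_test(a, b)
        tb, pb = welch_test(b, a)
        assert ta == pytest.approx(-tb) and pa == pytest.approx(pb)

    def test_anova_null_calibration(self):
        """Three equal-mean groups: the ANOVA stays non-significant in at
        least 94% of null replicates."""
        rng = np.random.default_rng(5)
        keep = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = {g: rng.normal(0, 1, size=4) for g in "abc"}
            if anova_bonferroni(groups)["anova_p"] > 0.05:
                keep += 1
        assert keep / n_rep >= 0.94

    def test_rat_mode_per_strain(self):
        rng = np.random.default_rng(6)
        rows = []
        for strain in ("HW", "LE"):
            shift = 3.0 if strain == "LE" else 0.0
            for t, n in (("control", 4), ("exposed", 4)):
                for i in range(n):
                    rows.append({"gene": "Cyp", "strain": strain,
                                 "treatment": t,
                                 "expression": rng.normal(
                                     shift if t == "exposed" else 0.0, 0.3)})
        res = group_tests(pd.DataFrame(rows), mode="rat")
        le = res[res["strain"] == "LE"].iloc[0]
        hw = res[res["strain"] == "HW"].iloc[0]
        assert le["p"] < 0.001 and le["tier"] == "***"
        assert hw["p"] > 0.05

    def test_mouse_mode_bonferroni(self):
        rng = np.random.default_rng(7)
        rows = []
        for g, shift in (("wt_ctl", 0), ("wt_tcdd", 4),
                         ("ko_ctl", 0), ("ko_tcdd", 0)):
            for i in range(4):
                rows.append({"gene": "Cyp", "group": g,
                             "expression": rng.normal(shift, 0.4)})
        res = group_tests(pd.DataFrame(rows), mode="mouse")
        assert (res["anova_p"] < 0.001).all()
        sig = res[res["comparison"] == "wt_ctl vs wt_tcdd"].iloc[0]
        assert sig["p_bonferroni"] < 0.001
        null = res[res["comparison"] == "ko_ctl vs ko_tcdd"].iloc[0]
        assert null["p_bonferroni"] > 0.05

    def test_degenerate_group_raises(self):
        with pytest.raises(InsufficientDataError):
            welch_test([1.0], [1.0, 2.0])

    def test_tiers(self):
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.009) == "**"
        assert significance_tier(0.0009) == "***"
        assert significance_tier(0.2) == ""


class TestEfficiency:
    def test_perfect_doubling(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        ct = 20.0 - np.log2(10.0) * x  # slope = -log2(10) = -3.3219
        res = efficiency_check(ct, x)
        assert res["efficiency_pct"] == pytest.approx(100.0, abs=0.01)
        assert res["ok"]

    def test_slow_amplification_flagged(self):
        x = np.array([0.0, -1.0, -2.0])
        ct = 20.0 + 3.6 * (-x)
        res = efficiency_check(ct, x)
        assert res["efficiency_pct"] == pytest.approx(89.57, abs=0.05)
        assert not res["ok"]

    def test_two_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            efficiency_check([20.0, 23.3], [0.0, -1.0])
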