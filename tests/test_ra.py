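"""Tests of RA computation, the zero-input filter, the Welch test and
the DRA screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ribodra import call_dra, compute_ra, direction_summary, welch_t_test
from ribodra.ra import DesignError

from .conftest import matrices_from
from .oracles import exhaustive_permutation_p, t_two_tailed_p, welch_by_hand


class TestComputeRA:
    def test_per_animal_ratio_arithmetic(self, tiny_design):
        inp, ip = matrices_from(
            tiny_design,
            {"g1": {"wt1_input": 10, "wt2_input": 5, "mut1_input": 2,
                    "mut2_input": 4, "wt1_IP": 30, "wt2_IP": 5,
                    "mut1_IP": 1, "mut2_IP": 0}},
        )
        table = compute_ra(inp, ip, tiny_design)
        assert table.ra.loc["g1", "wt1"] == 3.0
        assert table.ra.loc["g1", "wt2"] == 1.0
        assert table.ra.loc["g1", "mut1"] == 0.5
        # IP=0 with positive input is a valid RA of zero, retained
        assert table.ra.loc["g1", "mut2"] == 0.0
        assert table.n_filtered_genes == 0

    def test_any_zero_input_removes_gene(self, tiny_design):
        vals = {s: 1.0 for s in tiny_design["sample_id"]}
        bad = dict(vals)
        bad["mut2_input"] = 0.0
        inp, ip = matrices_from(tiny_design, {"ok": vals, "bad": bad})
        table = compute_ra(inp, ip, tiny_design)
        assert list(table.ra.index) == ["ok"]
        assert table.n_filtered_genes == 1

    def test_identical_matrices_give_unit_ra_and_no_calls(self, tiny_design):
        rng = np.random.default_rng(0)
        genes = {f"g{i}": dict.fromkeys(tiny_design["sample_id"], 0)
                 for i in range(20)}
        for g in genes:
            for a in tiny_design["animal_id"].unique():
                v = rng.uniform(1, 100)
                genes[g][f"{a}_input"] = v
                genes[g][f"{a}_IP"] = v
        inp, ip = matrices_from(tiny_design, genes)
        table = compute_ra(inp, ip, tiny_design)
        assert np.allclose(table.ra.to_numpy(), 1.0)
        dra = call_dra(table)
        assert (dra["p_value"] == 1.0).all()
        assert not dra["is_dra"].any()

    def test_scaling_one_ip_column_scales_that_animals_ra(self, tiny_design):
        rng = np.random.default_rng(1)
        genes = {}
        for i in range(10):
            genes[f"g{i}"] = {s: rng.uniform(1, 50)
                              for s in tiny_design["sample_id"]}
        inp, ip = matrices_from(tiny_design, genes)
        base = compute_ra(inp, ip, tiny_design)
        ip2 = ip.copy()
        ip2["wt1_IP"] = ip2["wt1_IP"] * 3.0
        scaled = compute_ra(inp, ip2, tiny_design)
        np.testing.assert_allclose(scaled.ra["wt1"], base.ra["wt1"] * 3.0)
        others = [c for c in base.ra.columns if c != "wt1"]
        pd.testing.assert_frame_equal(scaled.ra[others], base.ra[others])

    def test_adding_a_sample_only_removes_genes(self, tiny_design):
        rng = np.random.default_rng(2)
        genes = {}
        for i in range(50):
            vals = {s: rng.uniform(0.0, 5.0) for s in tiny_design["sample_id"]}
            if rng.random() < 0.3:
                vals[rng.choice([s for s in vals if s.endswith("_input")])] = 0.0
            genes[f"g{i}"] = vals
        inp, ip = matrices_from(tiny_design, genes)
        before = set(compute_ra(inp, ip, tiny_design).ra.index)
        extra = pd.DataFrame([
            {"sample_id": "mut3_input", "animal_id": "mut3",
             "genotype": "MUT", "fraction": "input"},
            {"sample_id": "mut3_IP", "animal_id": "mut3",
             "genotype": "MUT", "fraction": "IP"},
        ])
        design2 = pd.concat([tiny_design, extra], ignore_index=True)
        inp2 = inp.copy()
        ip2 = ip.copy()
        inp2["mut3_input"] = rng.choice([0.0, 1.0], size=len(inp))
        ip2["mut3_IP"] = 1.0
        after = set(compute_ra(inp2, ip2, design2).ra.index)
        assert after <= before

    def test_bad_designs_rejected(self, tiny_design):
        inp, ip = matrices_from(
            tiny_design, {"g1": dict.fromkeys(tiny_design["sample_id"], 1.0)})
        missing_ip = tiny_design[tiny_design["sample_id"] != "wt1_IP"]
        with pytest.raises(DesignError):
            compute_ra(inp, ip, missing_ip)
        one_wt = tiny_design[tiny_design["animal_id"] != "wt2"]
        with pytest.raises(DesignError):
            compute_ra(inp, ip, one_wt)

    def test_mismatched_gene_sets_rejected(self, tiny_design):
        inp, ip = matrices_from(
            tiny_design, {"g1": dict.fromkeys(tiny_design["sample_id"], 1.0)})
        with pytest.raises(ValueError, match="gene sets"):
            compute_ra(inp, ip.rename(index={"g1": "g2"}), tiny_design)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # means 2 vs 5, each variance 1: t = -3/sqrt(2/3), df = 4
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
        assert df == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(t_two_tailed_p(t, 4.0), abs=1e-10)
        assert p == pytest.approx(0.0214, abs=5e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
    )
    def test_antisymmetry(self, a, b):
        t1, df1, p1 = welch_t_test(a, b)
        t2, df2, p2 = welch_t_test(b, a)
        assert t1 == -t2 and df1 == df2 and p1 == p2

    def test_degenerate_conventions(self):
        t, df, p = welch_t_test([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)
        t, df, p = welch_t_test([3, 3], [2, 2])
        assert np.isinf(t) and t > 0 and p == 0.0
        with pytest.raises(ValueError):
            welch_t_test([1], [1, 2])

    def test_matches_independent_t_cdf_on_random_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            na, nb = rng.integers(2, 7, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.normal(), rng.uniform(0.5, 2), nb)
            t, df, p = welch_t_test(a, b)
            th, dfh = welch_by_hand(a, b)
            assert t == pytest.approx(th, rel=1e-12)
            assert df == pytest.approx(dfh, rel=1e-12)
            assert p == pytest.approx(t_two_tailed_p(t, df), abs=1e-9)

    def test_rank_agreement_with_exhaustive_permutation(self):
        rng = np.random.default_rng(5)
        cases = []
        for _ in range(12):
            a = rng.normal(0, 1, 4)
            b = rng.normal(rng.uniform(0, 2), 1, 4)
            _, _, p_welch = welch_t_test(a, b)
            p_perm = exhaustive_permutation_p(a, b)
            cases.append((p_welch, p_perm))
        welch_order = np.argsort([c[0] for c in cases])
        perm_order = np.argsort([c[1] for c in cases])
        # ordering should agree strongly, though not necessarily exactly
        rho = stats.spearmanr([c[0] for c in cases],
                              [c[1] for c in cases]).statistic
        assert rho > 0.9


class TestCallDRA:
    def test_strong_shift_called_up_in_mut(self, tiny_design):
        extra = pd.DataFrame([
            {"sample_id": f"mut3_{f}", "animal_id": "mut3",
             "genotype": "MUT", "fraction": f} for f in ("input", "IP")
        ])
        design = pd.concat([tiny_design, extra], ignore_index=True)
        wt = {"wt1": 1.0, "wt2": 1.1}
        # 3 WT animals needed: reuse tiny design plus one more WT
        extra_wt = pd.DataFrame([
            {"sample_id": f"wt3_{f}", "animal_id": "wt3",
             "genotype": "WT", "fraction": f} for f in ("input", "IP")
        ])
        design = pd.concat([design, extra_wt], ignore_index=True)
        ra_vals = {"wt1": 1.0, "wt2": 1.1, "wt3": 0.9,
                   "mut1": 4.0, "mut2": 4.1, "mut3": 3.9}
        genes = {"g1": {}}
        for a, r in ra_vals.items():
            genes["g1"][f"{a}_input"] = 10.0
            genes["g1"][f"{a}_IP"] = 10.0 * r
        inp, ip = matrices_from(design, genes)
        table = compute_ra(inp, ip, design)
        dra = call_dra(table)
        row = dra.loc["g1"]
        t_ref, df_ref = welch_by_hand([4.0, 4.1, 3.9], [1.0, 1.1, 0.9])
        assert row["t_stat"] == pytest.approx(t_ref, rel=1e-9)
        assert row["p_value"] == pytest.approx(
            t_two_tailed_p(t_ref, df_ref), abs=1e-9)
        assert row["is_dra"] and row["direction"] == "up_in_mut"

    def test_rowwise_matches_scalar_welch(self, small_dataset):
        inp, ip, design, _, _ = small_dataset
        table = compute_ra(inp, ip, design)
        dra = call_dra(table)
        geno = table.genotype
        wt = table.ra[geno.index[geno == "WT"]]
        mut = table.ra[geno.index[geno == "MUT"]]
        rng = np.random.default_rng(0)
        for g in rng.choice(table.ra.index, size=25, replace=False):
            t, df, p = welch_t_test(mut.loc[g], wt.loc[g])
            assert dra.loc[g, "t_stat"] == pytest.approx(t, rel=1e-9, abs=1e-12)
            assert dra.loc[g, "p_value"] == pytest.approx(p, abs=1e-12)

    def test_alpha_validation(self, small_dataset):
        inp, ip, design, _, _ = small_dataset
        table = compute_ra(inp, ip, design)
        with pytest.raises(ValueError):
            call_dra(table, alpha=1.5)


class TestDirectionSummary:
    def test_percentages(self):
        dra = pd.DataFrame({
            "is_dra": [True] * 10 + [False] * 5,
            "direction": ["up_in_mut"] * 7 + ["up_in_wt"] * 3 + ["none"] * 5,
        })
        n, up_mut, up_wt = direction_summary(dra)
        assert n == 10 and up_mut == 70.0 and up_wt == 30.0

    def test_no_calls_returns_nan_sentinels(self):
        dra = pd.DataFrame({"is_dra": [False, False],
                            "direction": ["none", "none"]})
        n, up_mut, up_wt = direction_summary(dra)
        assert n == 0 and np.isnan(up_mut) and np.isnan(up_wt)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            direction_summary(pd.DataFrame(columns=["is_dra", "direction"]))
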