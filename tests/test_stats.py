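"""Group comparisons, Dunn post-hoc, ΔΔCt, suppression statistic, report."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cellmech import (
    InvalidParameterError,
    build_report,
    compare_groups,
    ddct_expression,
    dunn_test,
    simulate_expression_tables,
    target_suppression,
)
from cellmech.stats import comparison_from_dict


class TestCompareGroups:
    def test_lognormal_routes_to_kruskal_dunn(self):
        rng = np.random.default_rng(1)
        g = {k: rng.lognormal(0, 1, 30) for k in "ABC"}
        comp = compare_groups(g, control_group="A")
        assert comp.test_name == "kruskal_dunn"
        assert {p[:2] for p in comp.pairwise} == {("A", "B"), ("A", "C")}

    def test_normal_routes_to_anova(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(0, 1, 30) for k in "ABC"}
        assert compare_groups(g).test_name == "anova_tukey"
        assert compare_groups(g, control_group="A").test_name == "anova_dunnett"

    def test_two_nonnormal_groups_without_control_use_mann_whitney(self):
        rng = np.random.default_rng(3)
        g = {"A": rng.lognormal(0, 1, 25), "B": rng.lognormal(0.8, 1, 25)}
        comp = compare_groups(g)
        assert comp.test_name == "mann_whitney"
        assert comp.global_p < 0.05

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(50):
            g = {"A": rng.normal(0, 1, 60), "B": rng.normal(1, 1, 60)}
            hits += compare_groups(g).global_p < 0.05
        assert hits >= 49  # power > 99% at d = 1, n = 60

    def test_small_group_error_names_group(self):
        g = {"A": [1.0, 2.0, 3.0], "tiny": [1.0, 2.0]}
        with pytest.raises(InvalidParameterError, match="tiny"):
            compare_groups(g)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        g = {k: rng.lognormal(0, 1, 20) for k in "ABC"}
        c1 = compare_groups(g)
        c2 = compare_groups(dict(reversed(list(g.items()))))
        assert c1.global_p == pytest.approx(c2.global_p)
        p1 = {frozenset(p[:2]): p[2] for p in c1.pairwise}
        p2 = {frozenset(p[:2]): p[2] for p in c2.pairwise}
        for key in p1:
            assert p1[key] == pytest.approx(p2[key])

    def test_descriptives_quantile_rule(self):
        rng = np.random.default_rng(6)
        g = {"A": np.array([1.0, 2.0, 3.0]), "B": rng.normal(0, 1, 10)}
        comp = compare_groups(g)
        d = comp.descriptives["A"]
        assert d["median"] == 2.0
        assert d["q25"] == pytest.approx(1.5)  # linear interpolation
        assert d["q75"] == pytest.approx(2.5)


class TestDunn:
    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        g = {k: rng.lognormal(0, 1, 25) for k in "ABCD"}
        adj = {p[:2]: p[2] for p in dunn_test(g)}
        raw = {p[:2]: p[2] for p in dunn_test(g, adjust="none")}
        for pair in adj:
            assert adj[pair] >= raw[pair] - 1e-15

    def test_two_group_dunn_agrees_with_normal_rank_test(self):
        # with two groups and no ties, Dunn's z equals the standardized
        # rank-sum statistic; cross-check p against the normal approximation
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        p_dunn = dunn_test({"A": a, "B": b}, adjust="none")[0][2]
        n, m = len(a), len(b)
        ranks = sps.rankdata(np.concatenate([a, b]))
        ra = ranks[:n].mean()
        rb = ranks[n:].mean()
        se = np.sqrt((n + m) * (n + m + 1) / 12.0 * (1 / n + 1 / m))
        p_ref = 2 * sps.norm.sf(abs(ra - rb) / se)
        assert p_dunn == pytest.approx(p_ref, rel=1e-9)


class TestDDCt:
    def test_control_fold_is_one(self):
        ct, _ = simulate_expression_tables(
            {"groups": {"WT": {}, "KD": {"target_shift": 1.0}}, "ct_sd": 0.0},
            {"n_targets": 10}, seed=1,
        )
        res = ddct_expression(ct, "Itga1", "Rpl37", "WT")
        assert res["WT"].fold_change == pytest.approx(1.0)

    def test_one_cycle_lower_doubles_fold(self):
        ct, _ = simulate_expression_tables(
            {"groups": {"WT": {}, "UP": {"target_shift": -1.0}}, "ct_sd": 0.0},
            {"n_targets": 10}, seed=1,
        )
        res = ddct_expression(ct, "Itga1", "Rpl37", "WT")
        assert res["UP"].fold_change == pytest.approx(2.0)

    def test_noisy_knockdown_recovery(self):
        # 4-fold knockdown = +2 cycles, 0.2-cycle noise, n = 4
        folds = []
        for seed in range(20):
            ct, _ = simulate_expression_tables(
                {"groups": {"WT": {}, "KD": {"target_shift": 2.0}}, "ct_sd": 0.2},
                {"n_targets": 5}, seed=seed,
            )
            res = ddct_expression(ct, "Itga1", "Rpl37", "WT")
            folds.append(res["KD"].fold_change)
        # knockdown factor 1/fold concentrates around 4 (error propagation
        # of 0.2-cycle noise at n = 4: SE(ddCt) ~ 0.2 cycles)
        assert 1 / 5.0 <= float(np.median(folds)) <= 1 / 3.2
        assert sum(1 / 5.0 <= f <= 1 / 3.2 for f in folds) >= 14

    def test_missing_reference_raises(self):
        ct = pd.DataFrame(
            {"group": ["WT"] * 3, "replicate": range(3),
             "gene": ["Itga1"] * 3, "ct": [24.0] * 3}
        )
        with pytest.raises(InvalidParameterError, match="Rpl37"):
            ddct_expression(ct, "Itga1", "Rpl37", "WT")


class TestSuppression:
    def test_printed_counts(self):
        _, deg = simulate_expression_tables(
            {"groups": {"WT": {}}}, {"n_targets": 816, "n_down": 560}, seed=1
        )
        res = target_suppression(deg)
        assert res.fraction_down == pytest.approx(560 / 816)
        assert res.p_value < 0.001

    def test_balanced_split_p_one(self):
        _, deg = simulate_expression_tables(
            {"groups": {"WT": {}}}, {"n_targets": 100, "n_down": 50}, seed=2
        )
        assert target_suppression(deg).p_value == pytest.approx(1.0)

    def test_all_down_exact_binomial(self):
        _, deg = simulate_expression_tables(
            {"groups": {"WT": {}}}, {"n_targets": 10, "n_down": 10}, seed=3
        )
        assert target_suppression(deg).p_value == pytest.approx(2 * 0.5**10)

    def test_no_targets_error(self):
        deg = pd.DataFrame({"log2_fold_change": [1.0], "is_target": [False]})
        with pytest.raises(InvalidParameterError):
            target_suppression(deg)


class TestReport:
    def test_round_trip_and_descriptives(self, tmp_path):
        rng = np.random.default_rng(9)
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(40)],
                "group": ["WT"] * 20 + ["KD"] * 20,
                "E_Pa": np.concatenate([rng.normal(1500, 200, 20),
                                        rng.normal(1000, 200, 20)]),
            }
        )
        comp = compare_groups(
            {g: sub["E_Pa"].to_numpy() for g, sub in cells.groupby("group")}
        )
        written = build_report(cells, {"E_Pa": comp}, tmp_path)
        assert written["descriptives"].exists()
        reloaded = comparison_from_dict(
            json.loads(written["tests"].read_text())["E_Pa"]
        )
        assert reloaded.global_p == comp.global_p
        for a, b in zip(reloaded.pairwise, comp.pairwise):
            assert a[2] == b[2]
        assert written["plot_E_Pa"].exists()

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(InvalidParameterError):
            build_report(pd.DataFrame(), {}, tmp_path)
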