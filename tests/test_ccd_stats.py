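"""CCD extraction, summary tables, fate proportions, and group tests."""

import math
from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats

from clonekinetics import (
    ColonyClass,
    ColonyDataset,
    DegenerateDataError,
    DivisionRecord,
    DivisionType,
    LineageTree,
    classify_dataset,
    compare_groups,
    compute_ccds,
    fate_proportions_by_generation,
    growth_curve,
    median_ci,
    summarize_ccd,
)
from clonekinetics.ccd_stats import _ranksum_exact

from conftest import make_cell


def _record(ccd, division_type=DivisionType.PP, colony_class=ColonyClass.EXPANDING,
            forward_gen=2, td=None, fo=None, colony="c1", cell="x"):
    return DivisionRecord(
        colony_id=colony, cell_id=cell, ccd=ccd, division_type=division_type,
        forward_gen=forward_gen, td_aligned=td, fo_aligned=fo,
        colony_class=colony_class,
    )


class TestComputeCcds:
    def test_ccd_is_interval_between_consecutive_mitoses(self, expanding_tree):
        dataset = ColonyDataset(trees=(expanding_tree,))
        records = compute_ccds(dataset, classify_dataset(dataset))
        by_cell = {r.cell_id: r for r in records}
        assert by_cell["c2"].ccd == pytest.approx(20.0)
        assert by_cell["c4"].ccd == pytest.approx(40.0)

    def test_founder_division_has_no_ccd(self, expanding_tree):
        dataset = ColonyDataset(trees=(expanding_tree,))
        records = compute_ccds(dataset, classify_dataset(dataset))
        founder = next(r for r in records if r.cell_id == "f")
        assert founder.ccd is None

    def test_nondividing_cells_produce_no_record(self, differentiating_tree):
        dataset = ColonyDataset(trees=(differentiating_tree,))
        records = compute_ccds(dataset, classify_dataset(dataset))
        assert [r.cell_id for r in records] == ["f"]

    def test_division_type_counts_partition_divisions(self, demo_dataset):
        records = compute_ccds(demo_dataset, classify_dataset(demo_dataset))
        assert len(records) == demo_dataset.n_divisions
        by_type = {t: 0 for t in DivisionType}
        for r in records:
            by_type[r.division_type] += 1
        assert sum(by_type.values()) == demo_dataset.n_divisions


class TestSummarize:
    def test_group_medians(self):
        records = [
            _record(19.0), _record(19.0), _record(19.0),
            _record(30.0, colony_class=ColonyClass.DIFFERENTIATING),
            _record(30.0, colony_class=ColonyClass.DIFFERENTIATING),
            _record(30.0, colony_class=ColonyClass.DIFFERENTIATING),
        ]
        table = summarize_ccd(records, "colony_class").set_index("colony_class")
        assert table.loc["EXPANDING", "median"] == 19.0
        assert table.loc["DIFFERENTIATING", "median"] == 30.0
        assert int(table["n"].sum()) == 6

    def test_single_record_has_no_ci(self):
        table = summarize_ccd([_record(21.0)], "colony_class")
        assert table.loc[0, "median"] == 21.0
        assert math.isnan(table.loc[0, "ci_low"])

    def test_first_k_generations_filter(self):
        records = [_record(19.0, forward_gen=g) for g in (1, 2, 3, 4)]
        table = summarize_ccd(records, "first_k_generations", k=3)
        assert int(table.loc[0, "n"]) == 3

    def test_unknown_divisions_and_founders_excluded(self):
        records = [
            _record(19.0),
            _record(19.0, division_type=DivisionType.UNKNOWN),
            _record(None),
        ]
        table = summarize_ccd(records, "colony_class")
        assert int(table["n"].sum()) == 1

    def test_group_sizes_sum_to_qualifying_records(self):
        rng = np.random.default_rng(0)
        types = [DivisionType.PP, DivisionType.PD, DivisionType.DD]
        classes = [ColonyClass.EXPANDING, ColonyClass.DIFFERENTIATING]
        records = [
            _record(float(rng.uniform(10, 40)),
                    division_type=types[rng.integers(3)],
                    colony_class=classes[rng.integers(2)])
            for _ in range(60)
        ]
        table = summarize_ccd(records, "division_type")
        assert int(table["n"].sum()) == 60


class TestMedianCi:
    def test_order_statistic_interval_n10(self):
        # Binomial(10, 1/2): P(X <= 1) = 0.0107 <= 0.025 < P(X <= 2)
        assert median_ci(range(1, 11)) == (2.0, 9.0)

    def test_too_small_sample_has_no_interval(self):
        assert median_ci([1.0, 2.0, 3.0, 4.0, 5.0]) is None

    def test_interval_brackets_the_median_and_has_coverage(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(3.0, 0.3, size=101)
        lo, hi = median_ci(x)
        assert lo <= np.median(x) <= hi
        # exact coverage of the chosen order statistics is >= 95%
        n = x.size
        ranks = (np.searchsorted(np.sort(x), lo), np.searchsorted(np.sort(x), hi))
        cover = stats.binom.cdf(ranks[1], n, 0.5) - stats.binom.cdf(ranks[0], n, 0.5)
        assert cover >= 0.95


class TestFateProportions:
    def test_pooled_proportions_exclude_unknowns(self, demo_dataset):
        cls = classify_dataset(demo_dataset)
        table = fate_proportions_by_generation(demo_dataset, cls, "forward")
        by_gen = table.set_index("generation")
        # generation 1: exp1 gives (P, D), dif1 gives (D, D) -> P prop 0.25
        assert by_gen.loc[1, "prop_p"] == pytest.approx(0.25)
        # generation 3: both daughters U -> no row
        assert 3 not in by_gen.index

    def test_terminal_generation_of_differentiating_colony_is_all_d(
        self, demo_dataset
    ):
        cls = classify_dataset(demo_dataset)
        table = fate_proportions_by_generation(
            demo_dataset, cls, "td", ColonyClass.DIFFERENTIATING
        )
        td_row = table.set_index("generation").loc[0]
        assert td_row["prop_p"] == 0.0
        assert td_row["prop_d"] == 1.0

    def test_proportions_sum_to_one(self, demo_dataset):
        cls = classify_dataset(demo_dataset)
        table = fate_proportions_by_generation(demo_dataset, cls, "forward")
        assert np.allclose(table["prop_p"] + table["prop_d"], 1.0)


class TestGrowthCurve:
    def test_founder_only(self, unclassified_tree):
        curve = growth_curve(unclassified_tree)
        assert curve.to_dict(orient="list") == {"generation": [0], "n_cells": [1]}

    def test_doubling_tree(self):
        from clonekinetics.simulate import SC, SimulationConfig, StemParams, \
            simulate_colony
        config = SimulationConfig(
            seed=0, window=100.0, founder_first_division_delay=0.0,
            offscreen_rate=0.0, tracking_capacity=None,
            sc_params=StemParams(p_pp=1.0, p_pd=0.0, p_dd=0.0, ccd_log_sd=0.0),
        )
        tree = simulate_colony(config, SC, np.random.default_rng(0))
        curve = growth_curve(tree).set_index("generation")["n_cells"]
        assert list(curve) == [2 ** g for g in range(6)]

    def test_pd_chain_has_two_cells_per_generation(self, expanding_tree):
        curve = growth_curve(expanding_tree).set_index("generation")["n_cells"]
        assert curve.loc[0] == 1
        assert (curve.loc[1:] == 2).all()

    def test_at_most_doubling_between_generations(self, demo_dataset):
        for tree in demo_dataset:
            counts = growth_curve(tree)["n_cells"].to_numpy()
            assert (counts[1:] <= 2 * counts[:-1]).all()


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _oracle_ranksum(x, y):
    """Independent exact Mann-Whitney oracle.

    U from pair counts (ties count half); two-sided p by enumerating
    every assignment of the pooled values to the two groups.
    """
    def u_stat(a, b):
        return sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0)
            for xi in a for yj in b
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestCompareGroups:
    def test_ranksum_separated_groups_exact_p(self):
        result = compare_groups([[1, 2, 3], [4, 5, 6]], "ranksum")
        assert result.method == "ranksum_exact"
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(0.1)

    def test_ranksum_identical_groups_is_symmetric(self):
        result = compare_groups([[1, 2], [1, 2]], "ranksum")
        assert result.statistic == pytest.approx(2.0)  # the null mean n1*n2/2
        assert result.p_value == 1.0

    def test_exact_branch_matches_oracle_on_small_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.integers(0, 6, size=4).tolist()
            y = rng.integers(0, 6, size=5).tolist()
            u_mine, p_mine = _ranksum_exact(np.array(x, float), np.array(y, float))
            u_ref, p_ref = _oracle_ranksum(x, y)
            assert u_mine == pytest.approx(u_ref)
            assert p_mine == pytest.approx(p_ref)

    def test_exact_branch_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.choice(60, size=5, replace=False)
            y = rng.choice(np.arange(60, 120), size=5, replace=False)
            perm = rng.permutation(np.concatenate([x, y]))
            a, b = perm[:5].astype(float), perm[5:].astype(float)
            _, p_mine = _ranksum_exact(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p_mine == pytest.approx(ref.pvalue)

    def test_exact_and_normal_branches_agree_on_6v6(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            _, p_exact = _ranksum_exact(x, y)
            p_norm = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_norm) <= 0.05

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(7)
        result = compare_groups([rng.normal(0, 1, 30), rng.normal(1, 1, 30)],
                                "ranksum")
        assert result.method == "ranksum_normal"
        assert result.p_value < 0.05

    def test_anova_identical_groups(self):
        result = compare_groups([[1, 2, 3]] * 3, "anova")
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_kruskal_dunn_reports_pairwise(self):
        groups = [[18, 19, 20, 19], [21, 22, 23, 22], [25, 26, 27, 26]]
        result = compare_groups(groups, "kruskal_dunn", labels=["PP", "PD", "DD"])
        assert result.method == "kruskal_wallis"
        assert len(result.pairwise) == 3
        for pair in result.pairwise:
            assert pair.details["p_bonferroni"] >= pair.p_value

    def test_paired_t_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compare_groups([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]], "t_paired")

    def test_paired_t_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0, 2.0], [1.0, 2.0, 3.0]], "t_paired")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0], []], "ranksum")
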