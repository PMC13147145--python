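"""Patristic distances, nearest-relative pairs and inflation statistics."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from speclock.inflation_clock import (
    PairRecord,
    compare_group_ages,
    inflation_increase,
    interval_series,
    nearest_relative_pairs,
    patristic_distances,
    prune_to_year,
    threshold_report,
    validate_ultrametric,
)
from speclock.records import SpeclockError, ValidationError
from speclock.synthetic_data import simulate_yule_tree

from conftest import FIXTURE_NEWICKS


def brute_force_patristic(tree: dendropy.Tree) -> pd.DataFrame:
    """Independent oracle: sum edge lengths along the path via the MRCA."""
    tree.is_rooted = True
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)

    def depth_to(node, ancestor):
        d = 0.0
        while node is not ancestor:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    labels = [l.taxon.label for l in leaves]
    m = np.zeros((len(leaves), len(leaves)))
    for i, j in itertools.combinations(range(len(leaves)), 2):
        mrca = tree.mrca(taxa=[leaves[i].taxon, leaves[j].taxon])
        d = depth_to(leaves[i], mrca) + depth_to(leaves[j], mrca)
        m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=labels, columns=labels)


class TestPatristicDistances:
    def test_cherry(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        dm = patristic_distances(tree)
        assert dm.at["A", "B"] == 2.0

    def test_three_tip_path_sums(self, three_tip_tree):
        dm = patristic_distances(three_tip_tree)
        assert dm.at["A", "C"] == 4.0
        assert dm.at["B", "C"] == 4.0
        assert dm.at["A", "B"] == 2.0

    @pytest.mark.parametrize("newick", FIXTURE_NEWICKS)
    def test_matches_brute_force_oracle_on_fixture_suite(self, newick):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        dm = patristic_distances(tree)
        oracle = brute_force_patristic(tree)
        assert np.allclose(dm.to_numpy(), oracle.to_numpy())
        assert list(dm.index) == list(oracle.index)

    def test_triangle_inequality_and_symmetry(self):
        tree = simulate_yule_tree(20, 1.0, seed=5)
        m = patristic_distances(tree).to_numpy()
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
        for i, j, k in itertools.combinations(range(20), 3):
            assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_non_ultrametric_rejected_with_depths(self):
        tree = dendropy.Tree.get(data="((A:1,B:3):1,C:2);", schema="newick")
        with pytest.raises(ValidationError, match="B"):
            patristic_distances(tree)

    def test_duplicate_labels_rejected(self, three_tip_tree):
        for lf in three_tip_tree.leaf_node_iter():
            lf.taxon.label = "A"  # force a label clash past the parser
        with pytest.raises(ValidationError, match="duplicate"):
            validate_ultrametric(three_tip_tree)


class TestNearestRelativePairs:
    def test_cherry_yields_two_records(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        recs = nearest_relative_pairs(tree)
        assert [(r.species, r.partner, r.divergence_ma) for r in recs] == [
            ("A", "B", 1.0),
            ("B", "A", 1.0),
        ]

    def test_alphabetical_tie_break(self, three_tip_tree):
        recs = {r.species: r for r in nearest_relative_pairs(three_tip_tree)}
        assert recs["C"].partner == "A"  # A and B both at patristic 4

    def test_mutual_neighbors_symmetric_divergence(self):
        tree = simulate_yule_tree(30, 1.0, seed=3)
        recs = {r.species: r for r in nearest_relative_pairs(tree)}
        for r in recs.values():
            if recs[r.partner].partner == r.species:
                assert recs[r.partner].divergence_ma == pytest.approx(r.divergence_ma)

    def test_minima_match_exhaustive_matrix_scan(self):
        tree = simulate_yule_tree(50, 1.0, seed=11)
        dm = patristic_distances(tree)
        recs = {r.species: r for r in nearest_relative_pairs(dm)}
        arr = dm.to_numpy()
        np.fill_diagonal(arr, np.inf)
        for i, sp in enumerate(dm.index):
            assert recs[sp].patristic_ma == pytest.approx(arr[i].min())

    def test_unique_pairs_collapses_mutual(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        assert len(nearest_relative_pairs(tree, unique_pairs=True)) == 1


class TestPruneToYear:
    def test_three_tip_distance_preserved(self, three_tip_tree):
        years = {"A": 1800, "B": 1900, "C": 1800}
        pruned = prune_to_year(three_tip_tree, years, 1850)
        dm = patristic_distances(pruned)
        assert list(dm.index) == ["A", "C"]
        assert dm.at["A", "C"] == 4.0

    def test_empty_interval_marker(self, three_tip_tree):
        years = {"A": 1900, "B": 1900, "C": 1900}
        assert prune_to_year(three_tip_tree, years, 1850) is None

    def test_survivor_submatrix_preserved_exactly(self):
        tree = simulate_yule_tree(100, 1.0, seed=7)
        full = patristic_distances(tree)
        rng = np.random.default_rng(0)
        years = {l: int(rng.integers(1758, 2011)) for l in full.index}
        pruned = prune_to_year(tree, years, 1900)
        sub = patristic_distances(pruned)
        keep = [l for l in full.index if years[l] <= 1900]
        assert list(sub.index) == keep
        assert np.allclose(sub.to_numpy(), full.loc[keep, keep].to_numpy())

    def test_species_missing_from_tree_warned(self, three_tip_tree):
        years = {"A": 1800, "B": 1800, "C": 1800, "Zz": 1800}
        with pytest.warns(UserWarning, match="absent"):
            pruned = prune_to_year(three_tip_tree, years, 1850)
        assert len(pruned.taxon_namespace) == 3


class TestIntervalSeries:
    def test_single_description_year_constant_afterwards(self, three_tip_tree):
        years = {"A": 1800, "B": 1800, "C": 1800}
        s = interval_series(three_tip_tree, years, interval_length=100)
        nonempty = s[s.n_pairs > 0]
        assert nonempty.mean_patristic_ma.nunique() == 1

    def test_species_counts_nondecreasing(self):
        tree = simulate_yule_tree(40, 1.0, seed=9)
        rng = np.random.default_rng(1)
        years = {t.label: int(rng.integers(1758, 2011)) for t in tree.taxon_namespace}
        s = interval_series(tree, years, interval_length=25)
        assert (s.n_species.diff().dropna() >= 0).all()
        assert (s.loc[s.n_pairs > 0, "min_patristic_ma"]
                <= s.loc[s.n_pairs > 0, "mean_patristic_ma"]).all()

    def test_final_cutoff_reproduces_full_tree_pairs(self):
        tree = simulate_yule_tree(30, 1.0, seed=2)
        rng = np.random.default_rng(4)
        years = {t.label: int(rng.integers(1758, 2011)) for t in tree.taxon_namespace}
        s = interval_series(tree, years, interval_length=10)
        recs = nearest_relative_pairs(tree)
        assert s.iloc[-1].n_pairs == len(recs)
        assert s.iloc[-1].mean_patristic_ma == pytest.approx(
            np.mean([r.patristic_ma for r in recs])
        )

    def test_mean_matches_hand_computation_on_fixture(self, tmp_path):
        tree = dendropy.Tree.get(
            data="(((A:1,B:1):1,C:2):2,(D:3,E:3):1);", schema="newick"
        )
        years = {"A": 1760, "B": 1765, "C": 1800, "D": 1805, "E": 1900}
        s = interval_series(tree, years, interval_length=10, out_dir=tmp_path)
        # cutoff 1768: {A,B} -> both at patristic 2
        row = s[s.cutoff_year == 1768].iloc[0]
        assert row.mean_patristic_ma == pytest.approx(2.0)
        # cutoff 1808: {A,B,C,D}: A-B 2, C->A or B 4, D->nearest is A/B/C at 8
        row = s[s.cutoff_year == 1808].iloc[0]
        assert row.mean_patristic_ma == pytest.approx((2 + 2 + 4 + 8) / 4)
        assert (tmp_path / "summary.tsv").exists()
        assert (tmp_path / "tree_1808.nwk").exists()
        assert (tmp_path / "pairs_1808.tsv").exists()


class TestThresholdReport:
    def _recs(self, divs):
        return [PairRecord(f"s{i}", f"s{i + 1}", 2 * d, d) for i, d in enumerate(divs)]

    def test_strict_inequality_count(self):
        rep = threshold_report(self._recs([0.5, 1.5, 3.0]), 2.0)
        assert rep.count_below == 2
        assert rep.proportion == pytest.approx(2 / 3)
        assert threshold_report(self._recs([0.5, 1.5, 2.0]), 2.0).count_below == 2

    def test_published_amphibian_arithmetic(self):
        # 216 of 2523 species pairs below threshold -> 8.6% at 1 decimal
        divs = [1.0] * 216 + [10.0] * (2523 - 216)
        rep = threshold_report(self._recs(divs), 2.6)
        assert rep.count_below == 216
        assert round(100 * rep.proportion, 1) == 8.6

    def test_threshold_below_minimum(self):
        assert threshold_report(self._recs([3.0, 4.0]), 0.5).count_below == 0

    def test_proportion_monotone_in_threshold(self):
        recs = self._recs(list(np.random.default_rng(0).uniform(0.1, 10, 50)))
        props = [threshold_report(recs, t).proportion for t in (0.5, 1, 2, 5, 10)]
        assert props == sorted(props)


class TestInflationIncrease:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((2887, 629, 237, 114), 120.78),
            ((100, 10, 50, 20), 300.0),
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert inflation_increase(*counts) == pytest.approx(expected, abs=0.005)

    def test_equal_proportions_zero(self):
        assert inflation_increase(1000, 100, 200, 20) == 0.0

    def test_no_young_pairs_undefined(self):
        assert inflation_increase(100, 0, 10, 0) is None

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(SpeclockError):
            inflation_increase(100, 200, 10, 5)
        with pytest.raises(SpeclockError):
            inflation_increase(100, 10, 10, 20)


class TestCompareGroupAges:
    def test_self_comparison_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        df = compare_group_ages({"a": x, "b": list(x)})
        assert df.iloc[0].t == pytest.approx(0.0)
        assert df.iloc[0].p_bonferroni == 1.0

    def test_three_groups_three_comparisons(self):
        rng = np.random.default_rng(0)
        df = compare_group_ages({g: rng.normal(size=10) for g in "abc"})
        assert len(df) == 3
        assert (df.p_bonferroni <= 1).all()
        assert np.allclose(df.p_bonferroni, np.minimum(1.0, df.p_raw * 3))

    def test_null_simulation_rarely_significant(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(30):
            df = compare_group_ages(
                {"a": rng.normal(5, 1, 100), "b": rng.normal(5, 1, 100)}
            )
            hits += df.iloc[0].p_bonferroni <= 0.05
        assert hits <= 3

    def test_letters_separate_distant_groups(self):
        rng = np.random.default_rng(1)
        df = compare_group_ages(
            {
                "low": rng.normal(0, 1, 50),
                "mid": rng.normal(0.2, 1, 50),
                "high": rng.normal(10, 1, 50),
            }
        )
        letters = df.attrs["letters"]
        assert set(letters["low"]) & set(letters["mid"])
        assert not set(letters["low"]) & set(letters["high"])

    def test_zero_variance_flagged(self):
        df = compare_group_ages({"a": [1.0, 1.0, 1.0], "b": [2.0, 3.0, 4.0]})
        assert df.iloc[0].zero_variance
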