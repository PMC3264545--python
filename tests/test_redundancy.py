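import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multicent.centrality import INDEX_LABELS
from multicent.redundancy import (
    association_matrix,
    evaluate_subset,
    gk_gamma,
    gk_lambda,
    index_dendrogram,
)


class TestGamma:
    def test_self_concordance(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert gk_gamma(x, x) == 1.0

    def test_reversal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert gk_gamma(x, x[::-1]) == -1.0

    def test_single_swap(self):
        # pairs: 5 concordant, 1 discordant -> 4/6
        assert gk_gamma([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(4 / 6)

    def test_tied_pairs_excluded(self):
        # the (a, b) pair is tied in x and dropped; remaining pairs concordant
        assert gk_gamma([1, 1, 2], [1, 2, 3]) == 1.0

    def test_all_tied_is_nan(self):
        assert math.isnan(gk_gamma([1.0, 1.0, 1.0], [5.0, 5.0, 5.0]))

    def test_mismatched_series_rejected(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        b = pd.Series([1.0, 2.0], index=["x", "z"])
        with pytest.raises(ValueError, match="different protein sets"):
            gk_gamma(a, b)

    def test_series_aligned_by_id(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
        b = pd.Series([3.0, 2.0, 1.0], index=["z", "y", "x"])
        assert gk_gamma(a, b) == 1.0

    def test_lambda_alias(self):
        assert gk_lambda is gk_gamma

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(-1000, 1000), min_size=4, max_size=25, unique=True
        ),
        st.lists(
            st.integers(-1000, 1000), min_size=25, max_size=25, unique=True
        ),
    )
    def test_monotone_transform_and_antisymmetry(self, xs, ys):
        x = np.array(xs, dtype=float)
        y = np.array(ys, dtype=float)[: len(x)]
        g = gk_gamma(x, y)
        # strictly monotone transform of either argument changes nothing
        # (cubing is exact and order-preserving on these integers)
        assert gk_gamma(x**3, y) == pytest.approx(g, abs=1e-12)
        # reversing one ranking flips the sign
        assert gk_gamma(x, -y) == pytest.approx(-g, abs=1e-12)


class TestAssociationMatrix:
    def _table(self, cols):
        return pd.DataFrame(cols, index=[f"p{i}" for i in range(len(next(iter(cols.values()))))])

    def test_identical_columns_give_ones(self):
        base = np.arange(10.0)
        table = self._table({c: base for c in INDEX_LABELS})
        mat = association_matrix(table)
        assert np.allclose(mat.to_numpy(), 1.0)

    def test_reversed_column_gives_minus_one(self):
        base = np.arange(10.0)
        cols = {c: base for c in INDEX_LABELS}
        cols["B"] = -base
        mat = association_matrix(self._table(cols))
        assert mat.loc["D", "B"] == -1.0
        assert mat.loc["B", "D"] == -1.0

    def test_symmetric_unit_diagonal(self, toy_table):
        mat = association_matrix(toy_table)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diagonal(mat.to_numpy()), 1.0)
        assert ((mat.to_numpy() >= -1) & (mat.to_numpy() <= 1)).all()

    def test_protein_permutation_invariance(self, toy_table):
        shuffled = toy_table.sample(frac=1.0, random_state=5)
        pd.testing.assert_frame_equal(
            association_matrix(toy_table), association_matrix(shuffled)
        )


class TestDendrogram:
    def test_all_ones_merges_at_zero(self):
        mat = pd.DataFrame(1.0, index=list(INDEX_LABELS), columns=list(INDEX_LABELS))
        d = index_dendrogram(mat)
        assert np.allclose(d.linkage[:, 2], 0.0)
        assert len(d.merge_order()) == 5

    def test_perfect_blocks_merge_first(self):
        labels = list(INDEX_LABELS)
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        np.fill_diagonal(mat.values, 1.0)
        for a, b in [("D", "B"), ("EC", "C")]:
            mat.loc[a, b] = mat.loc[b, a] = 0.95
        first_two = index_dendrogram(mat).merge_order()[:2]
        assert frozenset({"D", "B"}) in first_two
        assert frozenset({"EC", "C"}) in first_two

    def test_label_order_invariance(self, toy_table):
        mat = association_matrix(toy_table)
        perm = ["C", "D", "TI4", "B", "EC", "TI1"]
        merged_a = {frozenset(m) for m in index_dendrogram(mat).merge_order()}
        merged_b = {
            frozenset(m)
            for m in index_dendrogram(mat.loc[perm, perm]).merge_order()
        }
        assert merged_a == merged_b

    def test_unknown_linkage_rejected(self, toy_table):
        with pytest.raises(ValueError, match="linkage"):
            index_dendrogram(association_matrix(toy_table), linkage="median")

    def test_newick_wellformed(self, toy_table):
        import dendropy

        newick = index_dendrogram(association_matrix(toy_table)).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(
            INDEX_LABELS
        )


class TestSubsetEvaluation:
    def test_self_consistency_full_profile(self, small_scenario, small_hub_result):
        _, _, _, table = small_scenario
        ev = evaluate_subset(
            table, ["D", "EC", "TI1"], small_hub_result.hubs, seed=3
        )
        assert ev.overlap_1cluster[0] <= ev.reference_size

    def test_top_two_contains_top_one(self, small_scenario, small_hub_result):
        _, _, _, table = small_scenario
        ev = evaluate_subset(
            table, ["TI1", "TI4", "B", "C"], small_hub_result.hubs, seed=3
        )
        assert ev.overlap_2clusters[0] >= ev.overlap_1cluster[0]
        assert ev.overlap_2clusters[1] >= ev.overlap_1cluster[1]

    def test_four_index_subsets_recover_hubs(self, small_scenario):
        _, _, truth, table = small_scenario
        ev = evaluate_subset(
            table, ["D", "EC", "TI1", "TI4"], truth.hub_ids, seed=3
        )
        assert ev.overlap_2clusters[0] >= 0.8 * len(truth.hub_ids)

    def test_unknown_label_rejected(self, small_scenario, small_hub_result):
        _, _, _, table = small_scenario
        with pytest.raises(ValueError, match="unknown"):
            evaluate_subset(table, ["D", "XX"], small_hub_result.hubs)

    def test_empty_reference_rejected(self, small_scenario):
        _, _, _, table = small_scenario
        with pytest.raises(ValueError, match="empty"):
            evaluate_subset(table, ["D", "B"], set())
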