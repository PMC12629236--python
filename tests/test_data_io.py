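import io

import numpy as np
import pandas as pd
import pytest

from tcvs.data_io import (
    CountTable,
    CompositionMatrix,
    clr_transform,
    close_counts,
    newick_to_tree,
    read_counts,
    taxonomy_to_tree,
)


def table(rows, taxa=None):
    rows = np.asarray(rows)
    return CountTable(
        samples=[f"s{i}" for i in range(rows.shape[0])],
        taxa=taxa or [f"t{j}" for j in range(rows.shape[1])],
        counts=rows,
    )


class TestCloseCounts:
    @pytest.mark.parametrize(
        "row,pseudo,expected",
        [
            ([1, 1, 2], 0.5, np.array([1.5, 1.5, 2.5]) / 5.5),
            ([0, 0, 0], 0.5, np.array([1, 1, 1]) / 3),
            ([2, 3, 5], 0.0, np.array([0.2, 0.3, 0.5])),
        ],
    )
    def test_closure_formula(self, row, pseudo, expected):
        comp = close_counts(table([row]), pseudo_count=pseudo)
        np.testing.assert_allclose(comp.values[0], expected, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        comp = close_counts(table(rng.integers(0, 50, (20, 7))))
        np.testing.assert_allclose(comp.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_counts_require_pseudo(self):
        with pytest.raises(ValueError, match="pseudo"):
            close_counts(table([[0, 1, 2]]), pseudo_count=0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            table([[-1, 2, 3]])

    def test_default_pseudo_count_is_half(self):
        comp = close_counts(table([[0, 1, 2]]))
        assert comp.pseudo_count == 0.5
        np.testing.assert_allclose(comp.values[0], np.array([0.5, 1.5, 2.5]) / 4.5)


class TestClrTransform:
    def test_uniform_composition_maps_to_zero(self):
        comp = CompositionMatrix(values=np.full((1, 4), 0.25))
        np.testing.assert_allclose(clr_transform(comp).values, 0.0, atol=1e-14)

    def test_hand_computed_row(self):
        # log(x / geometric mean) for (1/2, 1/4, 1/4)
        comp = CompositionMatrix(values=np.array([[0.5, 0.25, 0.25]]))
        z = clr_transform(comp).values[0]
        np.testing.assert_allclose(z, [0.4621, -0.2310, -0.2310], atol=5e-5)
        assert abs(z.sum()) < 1e-12

    def test_rows_sum_to_zero_after_closure(self):
        rng = np.random.default_rng(1)
        z = clr_transform(close_counts(table(rng.integers(0, 100, (30, 9)))))
        np.testing.assert_allclose(z.values.sum(axis=1), 0.0, atol=1e-8)

    def test_scale_invariance_of_count_rows(self):
        # compositional data carry only relative information: scaling a
        # positive count row must not change its CLR representation
        base = np.array([[3, 7, 11, 19]])
        z1 = clr_transform(close_counts(table(base), pseudo_count=0.0)).values
        z2 = clr_transform(close_counts(table(base * 13), pseudo_count=0.0)).values
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_non_positive_entry_named_in_error(self):
        comp = CompositionMatrix.__new__(CompositionMatrix)
        comp.values = np.array([[0.5, 0.5, 0.0]])
        with pytest.raises(ValueError, match="row 0, column 2"):
            clr_transform(comp)


class TestTaxonomyParsing:
    def test_two_family_toy(self):
        tax = pd.DataFrame(
            {"Family": ["F1", "F1", "F2"], "Genus": ["G1", "G2", "G3"]},
            index=["t1", "t2", "t3"],
        )
        tree = taxonomy_to_tree(tax, ["t1", "t2", "t3"], ("Family", "Genus"))
        sets = set(tree.internal_nodes.values())
        assert frozenset({0, 1}) in sets          # family F1
        assert frozenset({0, 1, 2}) in sets       # root
        # unary tails (one-leaf genera / F2) add no internal node
        assert all(len(s) > 1 for s in sets)

    def test_single_rank_degenerate_tree(self):
        tax = pd.DataFrame({"Family": ["F", "F", "F"]}, index=["a", "b", "c"])
        tree = taxonomy_to_tree(tax, ["a", "b", "c"], ("Family",))
        assert set(tree.internal_nodes.values()) == {frozenset({0, 1, 2})}

    def test_missing_taxon_rejected(self):
        tax = pd.DataFrame({"Family": ["F"]}, index=["a"])
        with pytest.raises(ValueError, match="absent in taxonomy"):
            taxonomy_to_tree(tax, ["a", "b"], ("Family",))

    def test_duplicate_leaf_ids_rejected(self):
        tax = pd.DataFrame({"Family": ["F", "F"]}, index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            taxonomy_to_tree(tax, ["a"], ("Family",))

    def test_blank_labels_not_merged_across_families(self):
        # a blank genus under F1 and a blank genus under F2 must become
        # distinct placeholder nodes, never one biologically absurd group
        tax = pd.DataFrame(
            {"Family": ["F1", "F1", "F2", "F2"],
             "Genus": ["", "", "", ""],
             "Species": ["x1", "x2", "x3", "x4"]},
            index=["t1", "t2", "t3", "t4"],
        )
        tree = taxonomy_to_tree(tax, ["t1", "t2", "t3", "t4"],
                                ("Family", "Genus", "Species"))
        assert frozenset({0, 1}) in set(tree.internal_nodes.values())
        assert frozenset({2, 3}) in set(tree.internal_nodes.values())
        assert frozenset({0, 1, 2, 3}) in set(tree.internal_nodes.values())


class TestNewickParsing:
    def test_cherry_plus_outgroup(self):
        tree = newick_to_tree("((A,B),C);", ["A", "B", "C"])
        sets = set(tree.internal_nodes.values())
        assert sets == {frozenset({0, 1}), frozenset({0, 1, 2})}

    def test_star_tree_only_root(self):
        tree = newick_to_tree("(A,B,C);", ["A", "B", "C"])
        assert set(tree.internal_nodes.values()) == {frozenset({0, 1, 2})}

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="do not match"):
            newick_to_tree("((A,B),C);", ["A", "B", "D"])

    def test_membership_invariant_to_leaf_order(self):
        nwk = "((A,B),(C,D));"
        t1 = newick_to_tree(nwk, ["A", "B", "C", "D"])
        t2 = newick_to_tree(nwk, ["D", "C", "B", "A"])
        sets1 = {frozenset(t1.leaves[i] for i in s) for s in t1.internal_nodes.values()}
        sets2 = {frozenset(t2.leaves[i] for i in s) for s in t2.internal_nodes.values()}
        assert sets1 == sets2

    def test_matches_taxonomy_parse_of_same_topology(self):
        tax = pd.DataFrame(
            {"Family": ["L", "L", "R", "R"]}, index=["A", "B", "C", "D"]
        )
        from_tax = taxonomy_to_tree(tax, ["A", "B", "C", "D"], ("Family",))
        from_nwk = newick_to_tree("((A,B),(C,D));", ["A", "B", "C", "D"])
        assert set(from_tax.internal_nodes.values()) == set(from_nwk.internal_nodes.values())


def test_read_counts_round_trip(tmp_path):
    df = pd.DataFrame([[1, 2, 3], [4, 0, 6]], index=["s1", "s2"],
                      columns=["tA", "tB", "tC"])
    path = tmp_path / "counts.tsv"
    df.to_csv(path, sep="\t")
    ct = read_counts(path)
    assert ct.samples == ["s1", "s2"] and ct.taxa == ["tA", "tB", "tC"]
    np.testing.assert_array_equal(ct.counts, df.to_numpy())
    ct_t = read_counts(path, transpose=False)
    np.testing.assert_array_equal(ct_t.counts, ct.counts)


def test_read_counts_transpose(tmp_path):
    df = pd.DataFrame([[1, 4], [2, 0], [3, 6]], index=["tA", "tB", "tC"],
                      columns=["s1", "s2"])
    path = tmp_path / "counts_t.csv"
    df.to_csv(path)
    ct = read_counts(path, transpose=True)
    assert ct.samples == ["s1", "s2"]
    np.testing.assert_array_equal(ct.counts, df.T.to_numpy())
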