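import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from epifootprint import tree_concordance as tc
from epifootprint.slicing import DataSlice


def make_slice(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return DataSlice("H3K4me1", "enhancer", [f"r{i}" for i in range(arr.shape[0])], samples, arr)


class TestCorrelationDistance:
    def test_identical_columns_distance_zero(self):
        d = tc.correlation_distance(make_slice([[1, 1], [2, 2], [5, 5]]))
        assert d[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_columns_distance_two(self):
        d = tc.correlation_distance(make_slice([[1, -1], [2, -2], [5, -5]]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=(4, 3))
        d = tc.correlation_distance(make_slice(x))
        for i in range(3):
            for j in range(3):
                xi, xj = x[:, i], x[:, j]
                r = np.cov(xi, xj)[0, 1] / (xi.std(ddof=1) * xj.std(ddof=1))
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_column_names_sample(self):
        x = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
        with pytest.raises(ValueError, match="sB"):
            tc.correlation_distance(make_slice(x, samples=["sA", "sB"]))

    def test_entries_within_zero_two(self, rng):
        d = tc.correlation_distance(make_slice(rng.normal(size=(10, 6))))
        assert (d >= 0).all() and (d <= 2).all()


class TestAverageLinkage:
    def test_two_samples_single_merge(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = tc.average_linkage_tree(d, ["a", "b"])
        assert tree.root.height == pytest.approx(0.7)
        assert tree.leaves() == frozenset(["a", "b"])

    def test_two_tight_pairs(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.2
        tree = tc.average_linkage_tree(d, list("ABCD"))
        assert tree.clades() == {frozenset("AB"), frozenset("CD")}

    def test_manual_upgma_trace_five_samples(self):
        # merge A,B at 2; then {AB},C at mean(3,4)=3.5; D,E at 5;
        # final root at mean of cross distances
        labels = list("ABCDE")
        d = np.array(
            [
                [0, 2, 3, 9, 9],
                [2, 0, 4, 9, 9],
                [3, 4, 0, 9, 9],
                [9, 9, 9, 0, 5],
                [9, 9, 9, 5, 0],
            ],
            dtype=float,
        )
        tree = tc.average_linkage_tree(d, labels)
        assert tree.clades() == {frozenset("AB"), frozenset("ABC"), frozenset("DE")}
        heights = {frozenset("AB"): 2.0, frozenset("ABC"): 3.5, frozenset("DE"): 5.0}

        def walk(node):
            if node.is_leaf():
                return
            ls = node.leafset()
            if ls in heights:
                assert node.height == pytest.approx(heights[ls])
            for c in node.children:
                walk(c)

        walk(tree.root)
        assert tree.root.height == pytest.approx(9.0)

    def test_agrees_with_scipy_on_distinct_distances(self, rng):
        # cross-check against the reference implementation when no ties exist
        n = 8
        x = rng.normal(size=(n, 5))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(n)]
        ours = tc.average_linkage_tree(d, labels)
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        scipy_clades = set()
        members = {i: frozenset([labels[i]]) for i in range(n)}
        for row_idx, (i, j, _, _) in enumerate(Z):
            merged = members[int(i)] | members[int(j)]
            members[n + row_idx] = merged
            if len(merged) < n:
                scipy_clades.add(merged)
        assert ours.clades() == scipy_clades

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tc.average_linkage_tree(d, ["a", "b"])


class TestCladeEnumeration:
    def test_balanced_four_leaf(self):
        from epifootprint.io_formats import read_newick

        assert read_newick("((A,B),(C,D));").clades() == {frozenset("AB"), frozenset("CD")}

    def test_caterpillar(self):
        from epifootprint.io_formats import read_newick

        tree = read_newick("((((A,B),C),D),E);")
        assert tree.clades() == {
            frozenset("AB"),
            frozenset("ABC"),
            frozenset("ABCD"),
        }

    def test_two_leaf_tree_has_no_nontrivial_clades(self):
        from epifootprint.io_formats import read_newick

        assert read_newick("(A,B);").clades() == set()


class TestCladeFrequencies:
    def test_manual_count_two_of_three(self):
        from epifootprint.io_formats import read_newick

        trees = [
            read_newick("((A,B),(C,D));"),
            read_newick("((A,B),(C,D));"),
            read_newick("((A,C),(B,D));"),
        ]
        table = tc.clade_frequencies(trees)
        assert table.frequency(frozenset("AB")) == pytest.approx(2 / 3)

    def test_omnipresent_clade_frequency_one(self):
        from epifootprint.io_formats import read_newick

        trees = [read_newick("((A,B),(C,D));")] * 5
        assert tc.clade_frequencies(trees).frequency(frozenset("CD")) == 1.0

    def test_mismatched_leafsets_rejected(self):
        from epifootprint.io_formats import read_newick

        with pytest.raises(ValueError, match="leaf"):
            tc.clade_frequencies([read_newick("((A,B),C);"), read_newick("((A,B),D);")])


class TestConfirmationScores:
    def test_single_tree_scores_one_against_itself(self):
        from epifootprint.io_formats import read_newick

        tree = read_newick("((((A,B),C),D),E);")
        table = tc.clade_frequencies([tree])
        assert tc.tree_confirmation_score(tree, table) == pytest.approx(1.0)

    def test_mean_of_clade_frequencies(self):
        from epifootprint.io_formats import read_newick

        tree = read_newick("((A,B),(C,D));")
        table = tc.CladeFrequencyTable(
            {frozenset("AB"): 0.9, frozenset("CD"): 0.5}, n_trees=10
        )
        assert tc.tree_confirmation_score(tree, table) == pytest.approx(0.7)

    def test_identical_forest_all_trees_score_one(self):
        from epifootprint.io_formats import read_newick

        trees = [read_newick("((A,B),(C,(D,E)));")] * 4
        table = tc.clade_frequencies(trees)
        assert tc.markroi_confirmation_score(trees, table) == pytest.approx(1.0)

    def test_tree_score_equals_mean_of_cluster_scores(self, confirm_result):
        scores, table, trees_by_combo = confirm_result
        tree = trees_by_combo[("H3K4me1", "lincRNA_TSS")][0]
        per_clade = [tc.cluster_confirmation_score(c, table) for c in tree.clades()]
        assert tc.tree_confirmation_score(tree, table) == pytest.approx(np.mean(per_clade))

    def test_scores_within_unit_interval(self, confirm_result):
        scores, _, _ = confirm_result
        assert all(0.0 <= s <= 1.0 for s in scores.values())


class TestSubsampleReplicates:
    def test_single_replicate_selections_identical(self):
        sels = tc.subsample_replicates({"a": ["r1"], "b": ["r1"]}, n_rounds=5, seed=0)
        assert all(s == {"a": "r1", "b": "r1"} for s in sels)

    def test_uniform_choice_over_two_replicates(self):
        sels = tc.subsample_replicates({"a": ["r1", "r2"]}, n_rounds=1000, seed=3)
        n_r1 = sum(1 for s in sels if s["a"] == "r1")
        # binomial(1000, 0.5): 4 sigma ~ 63
        assert abs(n_r1 - 500) < 70

    def test_default_round_count_is_fifty(self):
        assert len(tc.subsample_replicates({"a": ["r1"]}, seed=1)) == 50

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            tc.subsample_replicates({}, 10, 0)


class TestBootstrap:
    def test_separated_blocks_get_full_support(self, rng):
        # two tight sample blocks, strong block effect over many regions:
        # every non-trivial clade of the full-data tree is a block clade
        n_regions = 60
        block = np.r_[np.ones(30), np.zeros(30)]
        x = np.column_stack(
            [block * 10 + rng.normal(0, 0.1, n_regions) for _ in range(2)]
            + [(1 - block) * 10 + rng.normal(0, 0.1, n_regions) for _ in range(2)]
        )
        slice_ = make_slice(x, samples=list("ABCD"))
        support = tc.bootstrap_support(slice_, n_boot=200, seed=5)
        assert support.keys() == {frozenset("AB"), frozenset("CD")}
        assert all(s >= 0.95 for s in support.values())

    def test_single_bootstrap_gives_zero_or_one(self, rng):
        x = rng.normal(size=(10, 4))
        support = tc.bootstrap_support(make_slice(x), n_boot=1, seed=0)
        assert set(support.values()) <= {0.0, 1.0}

    def test_nboot_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            tc.bootstrap_support(make_slice(rng.normal(size=(5, 3))), n_boot=0)


def test_label_permutation_leaves_scores_unchanged(rng):
    x = rng.normal(size=(30, 6))
    labels = list("ABCDEF")
    permuted = ["F", "A", "B", "C", "D", "E"]
    t1 = tc.average_linkage_tree(tc.correlation_distance(make_slice(x, labels)), labels)
    # same data, columns renamed consistently
    t2 = tc.average_linkage_tree(tc.correlation_distance(make_slice(x, permuted)), permuted)
    mapping = dict(zip(labels, permuted))
    relabelled = {frozenset(mapping[l] for l in c) for c in t1.clades()}
    assert relabelled == t2.clades()
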