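"""Hierarchical clustering of epigenomes and clade-concordance scoring.

The central idea: if a group of samples shares epigenetically encoded cellular
identity, the same sample clade keeps re-appearing in dendrograms built from
*independent* histone-mark / region-class combinations.  Each mark-ROI
combination yields one tree per replicate-subsampling round; pooling all trees
gives a clade-frequency table, and a tree (or combination) is scored by the
mean pooled frequency of its clades.

Distances are 1 - Pearson correlation between sample columns of a data slice;
trees are built with unweighted average linkage (UPGMA).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .slicing import DataSlice


class TreeNode:
    """Node of a dendrogram; leaves carry a label, internal nodes a height."""

    __slots__ = ("label", "height", "children")

    def __init__(self, label=None, height=0.0, children=()):
        self.label = label
        self.height = float(height)
        self.children = list(children)

    def is_leaf(self) -> bool:
        return not self.children

    def leafset(self) -> frozenset:
        if self.is_leaf():
            return frozenset([self.label])
        return frozenset().union(*(c.leafset() for c in self.children))


class Dendrogram:
    """Rooted binary tree over sample labels with merge heights."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaves(self) -> frozenset:
        return self.root.leafset()

    def n_leaves(self) -> int:
        return len(self.leaves())

    def clades(self) -> set[frozenset]:
        """Non-trivial clades: one per internal node, excluding singletons and
        the full leaf set."""
        out: set[frozenset] = set()
        full = self.leaves()

        def walk(node):
            if node.is_leaf():
                return
            ls = node.leafset()
            if 1 < len(ls) < len(full):
                out.add(ls)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        from .io_formats import write_newick

        return write_newick(self)


def correlation_distance(slice_: DataSlice) -> np.ndarray:
    """Pairwise distance d(i,j) = 1 - Pearson r between sample columns.

    A zero-variance column (sample constant over regions) is an error naming
    the sample.
    """
    X = np.asarray(slice_.values, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("correlation distance needs >= 2 samples")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [s for s, z in zip(slice_.sample_ids, sd == 0) if z]
        raise ValueError(f"zero-variance sample column(s): {bad}")
    r = np.corrcoef(X.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # exact symmetry (corrcoef is symmetric up to rounding)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def average_linkage_tree(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """UPGMA (unweighted average linkage) dendrogram.

    Merge heights equal the average inter-cluster distance at merge time; ties
    are broken by the smallest (i, j) index pair over the current cluster
    list, so the result is fully deterministic.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if len(labels) != n:
        raise ValueError("labels must match distance matrix size")
    D = D.copy()
    nodes = [TreeNode(label=lab) for lab in labels]
    sizes = [1] * n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for a_pos, b_pos in itertools.combinations(range(len(active)), 2):
            d = D[active[a_pos], active[b_pos]]
            if best is None or d < best[0]:
                best = (d, a_pos, b_pos)
        d, a_pos, b_pos = best
        i, j = active[a_pos], active[b_pos]
        merged = TreeNode(children=[nodes[i], nodes[j]], height=d)
        # average-linkage update against every other active cluster
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (sizes[i] * D[i, k] + sizes[j] * D[j, k]) / (
                sizes[i] + sizes[j]
            )
        nodes[i] = merged
        sizes[i] += sizes[j]
        active.pop(b_pos)
    return Dendrogram(nodes[active[0]])


def subsample_replicates(
    manifest: dict[str, list[str]], n_rounds: int = 50, seed: int | None = None
) -> list[dict[str, str]]:
    """Randomly pick one replicate per sample, ``n_rounds`` times.

    Replicate subsampling (rather than averaging) puts samples with unequal
    replicate counts on an equal footing; 50 rounds is the default protocol.
    """
    if not manifest:
        raise ValueError("empty replicate manifest")
    for sample, reps in manifest.items():
        if not reps:
            raise ValueError(f"sample {sample} has no replicates")
    rng = np.random.default_rng(seed)
    selections = []
    for _ in range(n_rounds):
        sel = {s: reps[rng.integers(len(reps))] for s, reps in manifest.items()}
        selections.append(sel)
    return selections


def enumerate_clades(tree: Dendrogram) -> set[frozenset]:
    return tree.clades()


@dataclass
class CladeFrequencyTable:
    """Fraction of trees containing each non-trivial clade."""

    frequencies: dict[frozenset, float]
    n_trees: int

    def frequency(self, clade: frozenset) -> float:
        return self.frequencies.get(frozenset(clade), 0.0)


def clade_frequencies(trees: list[Dendrogram]) -> CladeFrequencyTable:
    """Pooled clade-frequency table over a forest sharing one leaf set."""
    if not trees:
        raise ValueError("need >= 1 tree")
    leafsets = {t.leaves() for t in trees}
    if len(leafsets) != 1:
        raise ValueError("all trees must share the same leaf label set")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for clade in t.clades():
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return CladeFrequencyTable({c: k / n for c, k in counts.items()}, n)


def cluster_confirmation_score(clade, table: CladeFrequencyTable) -> float:
    """Fraction of pooled trees containing the clade (0 if never observed)."""
    return table.frequency(frozenset(clade))


def tree_confirmation_score(tree: Dendrogram, table: CladeFrequencyTable) -> float:
    """Unweighted mean of the pooled frequencies of the tree's clades."""
    clades = tree.clades()
    if not clades:
        raise ValueError("tree has no non-trivial clades")
    return float(np.mean([table.frequency(c) for c in clades]))


def markroi_confirmation_score(
    trees: list[Dendrogram], table: CladeFrequencyTable
) -> float:
    """Mean tree confirmation score over one combination's subsampling rounds."""
    if not trees:
        raise ValueError("need >= 1 tree for the combination")
    return float(np.mean([tree_confirmation_score(t, table) for t in trees]))


def bootstrap_support(
    slice_: DataSlice, n_boot: int = 200, seed: int | None = None
) -> dict[frozenset, float]:
    """Row (region) bootstrap support for each clade of the full-data tree."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if slice_.values.shape[0] < 2:
        raise ValueError("bootstrap needs >= 2 rows")
    full_tree = average_linkage_tree(correlation_distance(slice_), slice_.sample_ids)
    target = full_tree.clades()
    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in target}
    n_rows = slice_.values.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_rows, size=n_rows)
        boot = DataSlice(
            mark=slice_.mark,
            roi_class=slice_.roi_class,
            region_names=[slice_.region_names[i] for i in idx],
            sample_ids=slice_.sample_ids,
            values=slice_.values[idx],
            _allow_duplicate_rows=True,
        )
        tree = average_linkage_tree(correlation_distance(boot), boot.sample_ids)
        for c in tree.clades():
            if c in hits:
                hits[c] += 1
    return {c: k / n_boot for c, k in hits.items()}


def chance_assignment_concordance(
    n_clusters: int, n_draws: int | None = None, seed: int | None = None
) -> float:
    """Probability that a uniformly random cluster assignment matches a fixed
    reference assignment.

    Analytically 1/n_clusters; with ``n_draws`` the rate is estimated by Monte
    Carlo instead (used as the null baseline for literature-concordance style
    comparisons).
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_draws is None:
        return 1.0 / n_clusters
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_clusters, size=n_draws)
    reference = rng.integers(0, n_clusters, size=n_draws)
    return float(np.mean(draws == reference))
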