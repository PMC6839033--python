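"""Clustering preprocessing, Spearman distances, UPGMA, RF, PCA/varimax."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from aarcode.profile_phylo import (
    adjust_table,
    average_linkage_cluster,
    dendrogram_to_unrooted,
    pca_varimax,
    rf_distance,
    spearman_distance,
    varimax,
    varimax_criterion,
)
from aarcode.seqio import TreeTopology


@pytest.fixture
def random_table(rng):
    return pd.DataFrame(
        rng.normal(size=(30, 8)),
        index=[f"f{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(8)],
    )


class TestAdjustTable:
    def test_rows_have_unit_sum_of_squares(self, random_table):
        out = adjust_table(random_table)
        # rows are re-normalized then columns scaled; after convergence the
        # fixed point satisfies all three constraints simultaneously
        assert np.allclose((out**2).sum(axis=1), (out**2).sum(axis=1).iloc[0])
        assert np.allclose(out.mean(axis=1), 0, atol=1e-8)

    def test_constant_row_dropped(self, random_table):
        random_table.loc["const"] = 1.0
        out = adjust_table(random_table)
        assert "const" not in out.index

    def test_idempotent(self, random_table):
        once = adjust_table(random_table)
        twice = adjust_table(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-6)

    def test_missing_values_rejected(self, random_table):
        random_table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            adjust_table(random_table)

    def test_collapse_to_too_few_rows_errors(self):
        ft = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [1.0, 2.0]],
                          index=list("abc"), columns=list("xy"))
        with pytest.raises(ValueError):
            adjust_table(ft)


class TestSpearmanDistance:
    def test_monotone_transform_distance_zero(self):
        ft = pd.DataFrame({"a": [1.0, 2, 3, 5], "b": [2.0, 4, 9, 100]})
        d = spearman_distance(ft)
        assert d.at["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_rank_reversal_distance_two(self):
        ft = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [9.0, 7, 5, 3]})
        assert spearman_distance(ft).at["a", "b"] == pytest.approx(2.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        ft = pd.DataFrame(rng.normal(size=(50, 6)),
                          columns=[f"s{j}" for j in range(6)])
        d = spearman_distance(ft)
        ranks = np.apply_along_axis(rankdata, 0, ft.to_numpy())
        oracle = 1 - np.corrcoef(ranks, rowvar=False)
        np.testing.assert_allclose(d.to_numpy(), oracle - np.diag(np.diag(oracle)),
                                   atol=1e-12)

    def test_constant_vector_named_in_error(self):
        ft = pd.DataFrame({"good": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            spearman_distance(ft)


def brute_force_upgma(d: pd.DataFrame):
    """Naive O(n^3) average-linkage agglomeration oracle.

    Returns merge heights in order, with cluster-pair distances computed as
    the mean of all cross-pair original distances.
    """
    clusters = {i: [lab] for i, lab in enumerate(sorted(d.index))}
    heights = []
    next_id = len(clusters)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                dist = np.mean(
                    [d.at[a, b] for a in clusters[i] for b in clusters[j]]
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return heights


class TestAverageLinkage:
    def test_closest_pair_merges_first(self):
        labels = list("abc")
        d = pd.DataFrame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], index=labels, columns=labels,
            dtype=float,
        )
        dend = average_linkage_cluster(d)
        first = {dend.labels[int(dend.merge[0, 0])], dend.labels[int(dend.merge[0, 1])]}
        assert first == {"a", "b"}

    def test_block_structure_topology(self):
        labels = list("abcd")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        d.loc["a", "b"] = d.loc["b", "a"] = 0.1
        d.loc["c", "d"] = d.loc["d", "c"] = 0.1
        tree = dendrogram_to_unrooted(average_linkage_cluster(d))
        assert tree.splits == TreeTopology.from_newick("((a,b),(c,d));").splits

    def test_heights_match_bruteforce_oracle(self, rng):
        for n in (4, 5, 6, 7):
            for _ in range(5):
                m = rng.random((n, n))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0.0)
                labels = [f"s{i}" for i in range(n)]
                d = pd.DataFrame(m, index=labels, columns=labels)
                dend = average_linkage_cluster(d)
                np.testing.assert_allclose(
                    dend.merge[:, 2], brute_force_upgma(d), atol=1e-10
                )

    def test_nan_rejected(self):
        d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("ab"),
                         columns=list("ab"))
        with pytest.raises(ValueError):
            average_linkage_cluster(d)


class TestDendrogramToUnrooted:
    def _dend_from_newick_shape(self, d):
        return dendrogram_to_unrooted(d)

    def test_quartet(self):
        labels = list("abcd")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(d.values, 0.0)
        d.loc["a", "b"] = d.loc["b", "a"] = 0.1
        d.loc["c", "d"] = d.loc["d", "c"] = 0.2
        tree = dendrogram_to_unrooted(average_linkage_cluster(d))
        assert tree.splits == frozenset({frozenset({"c", "d"})})

    def test_caterpillar_same_quartet(self):
        # (((a,b),c),d) unroots to the single split ab|cd
        t = TreeTopology.from_newick("(((a,b),c),d);")
        assert t.splits == TreeTopology.from_newick("((a,b),(c,d));").splits

    def test_leafset_preserved(self, rng):
        n = 6
        m = rng.random((n, n)); m = (m + m.T) / 2; np.fill_diagonal(m, 0)
        labels = [f"s{i}" for i in range(n)]
        tree = dendrogram_to_unrooted(
            average_linkage_cluster(pd.DataFrame(m, index=labels, columns=labels))
        )
        assert tree.leaves == frozenset(labels)

    def test_too_few_leaves(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"),
                         dtype=float)
        with pytest.raises(ValueError):
            dendrogram_to_unrooted(average_linkage_cluster(d))


class TestRFDistance:
    def test_identical_zero(self):
        t = TreeTopology.from_newick("((a,b),(c,d));")
        assert rf_distance(t, t) == 0

    def test_alternative_quartets_two(self):
        t1 = TreeTopology.from_newick("((a,b),(c,d));")
        t2 = TreeTopology.from_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_mismatched_leafsets_error(self):
        t1 = TreeTopology.from_newick("((a,b),(c,d));")
        t2 = TreeTopology.from_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="differ"):
            rf_distance(t1, t2)

    def test_matches_dendropy_oracle(self, rng):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import treecompare

        taxa = [f"t{i}" for i in range(8)]
        ns = dendropy.TaxonNamespace(taxa)

        def random_newick():
            """Random binary topology by sequential leaf attachment."""
            import io

            from skbio import TreeNode

            nodes = taxa[:]
            rng_local = rng
            newick = f"({nodes[0]},{nodes[1]},{nodes[2]});"
            tree = TreeNode.read(io.StringIO(newick))
            for leaf in nodes[3:]:
                edges = [n for n in tree.traverse(include_self=False)]
                target = edges[int(rng_local.integers(len(edges)))]
                parent = target.parent
                new_internal = TreeNode()
                parent.remove(target)
                parent.append(new_internal)
                new_internal.append(target)
                new_leaf = TreeNode(name=leaf)
                new_internal.append(new_leaf)
            buf = io.StringIO()
            tree.write(buf)
            return buf.getvalue().strip()

        for _ in range(15):
            n1, n2 = random_newick(), random_newick()
            mine = rf_distance(
                TreeTopology.from_newick(n1), TreeTopology.from_newick(n2)
            )
            d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=ns)
            d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=ns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert mine == treecompare.symmetric_difference(d1, d2)


class TestPCAVarimax:
    def test_rank_one_single_component(self, rng):
        u = rng.normal(size=(10, 1))
        v = rng.normal(size=(1, 6))
        table = pd.DataFrame(u @ v + 0.0)
        res = pca_varimax(table + rng.normal(scale=1e-9, size=table.shape),
                          n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-6)

    def test_rotated_loadings_orthogonal(self, rng):
        table = pd.DataFrame(rng.normal(size=(20, 8)))
        res = pca_varimax(table, n_components=3)
        # varimax is an orthogonal rotation: R'R = I is preserved in the
        # cross-product structure of the loading matrix
        gram_raw = res.loadings.T @ res.loadings
        gram_rot = res.rotated_loadings.T @ res.rotated_loadings
        assert np.trace(gram_raw) == pytest.approx(np.trace(gram_rot), abs=1e-8)

    def test_varimax_never_decreases_criterion(self, rng):
        for _ in range(10):
            load = rng.normal(size=(12, 3))
            rotated = varimax(load, max_iter=25)
            assert varimax_criterion(rotated) >= varimax_criterion(load) - 1e-10

    def test_n_components_exceeding_rank_errors(self, rng):
        table = pd.DataFrame(rng.normal(size=(4, 10)))
        with pytest.raises(ValueError, match="rank"):
            pca_varimax(table, n_components=8)

    def test_variance_ratios_sum_below_one(self, rng):
        table = pd.DataFrame(rng.normal(size=(15, 6)))
        res = pca_varimax(table, n_components=2)
        assert 0 < res.total_variance_pct < 100
        assert res.cumulative_variance[-1] == pytest.approx(
            res.explained_variance_ratio.sum()
        )
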