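import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from netsmooth import (ClusterConfig, ExpressionMatrix, UNASSIGNED,
                       adjusted_mutual_information, cocluster_matrix,
                       consensus_clusters, kmedoids, make_views,
                       merge_similar_clusters, pam_sweep,
                       proportion_robustly_clustered, robust_cluster,
                       select_variable_genes)
from netsmooth.clustering import ViewSpec
from netsmooth.synthetic import generate_counts, generate_network


def make_expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(values,
                            [f"{prefix}{i}" for i in range(values.shape[0])],
                            [f"c{j}" for j in range(values.shape[1])])


class TestSelectVariableGenes:
    def test_all_genes_is_identity(self, random_expression):
        out = select_variable_genes(random_expression, random_expression.n_genes)
        assert out.gene_ids == random_expression.gene_ids
        assert np.array_equal(out.values, random_expression.values)

    def test_constant_gene_ranked_last(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 10, size=(5, 20))
        vals[2, :] = 3.0  # zero variance
        expr = make_expr(vals)
        out = select_variable_genes(expr, 4)
        assert "g2" not in out.gene_ids

    def test_matches_brute_force_variance_sort(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.poisson(4.0, size=(50, 25)))
        out = select_variable_genes(expr, 10)
        variances = np.var(np.log1p(expr.values), axis=1)
        expected = {expr.gene_ids[i]
                    for i in np.argsort(variances)[::-1][:10]}
        assert set(out.gene_ids) == expected
        # original order preserved among selected genes
        assert out.gene_ids == [g for g in expr.gene_ids if g in expected]


class TestMakeViews:
    @pytest.fixture
    def big_expr(self):
        rng = np.random.default_rng(2)
        return make_expr(rng.poisson(5.0, size=(1100, 60)))

    def test_pca_menu(self, big_expr):
        views = make_views(big_expr, "pca", seed=0)
        kinds = [(s.kind, s.dimensionality) for s, _ in views]
        assert kinds == [("pca", 5), ("pca", 15), ("pca", 50),
                         ("top_genes", 100), ("top_genes", 500),
                         ("top_genes", 1000)]

    def test_tsne_menu(self, big_expr):
        views = make_views(big_expr, "tsne", seed=0)
        kinds = [(s.kind, s.dimensionality) for s, _ in views]
        assert kinds == [("tsne", 2), ("tsne", 3), ("top_genes", 100),
                         ("top_genes", 500), ("top_genes", 1000)]

    def test_pca_views_have_orthogonal_columns(self, big_expr):
        views = make_views(big_expr, "pca", seed=0)
        for spec, mat in views:
            if spec.kind == "pca":
                gram = mat.T @ mat
                off = gram - np.diag(np.diag(gram))
                assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))

    def test_infeasible_views_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        small = make_expr(rng.poisson(5.0, size=(40, 30)))
        with pytest.warns(UserWarning):
            views = make_views(small, "pca", seed=0)
        dims = [s.dimensionality for s, _ in views if s.kind == "pca"]
        assert 50 not in dims


class TestPamSweep:
    def test_labeling_count(self):
        rng = np.random.default_rng(4)
        views = [(ViewSpec("pca", d), rng.normal(size=(40, d)))
                 for d in (2, 3, 4, 5, 6, 7)]
        labelings = pam_sweep(views, 5, 10, seed=0)
        assert len(labelings) == 36
        assert all(len(l) == 40 for l in labelings)

    def test_matches_exhaustive_medoid_search_on_blobs(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.3, size=(10, 2)),
                         rng.normal(5, 0.3, size=(10, 2))])
        dist = ssd.squareform(ssd.pdist(pts))
        labels = kmedoids(dist, 2, seed=1)
        # exhaustive oracle: best total point-to-nearest-medoid cost
        best = min(
            dist[:, list(pair)].min(axis=1).sum()
            for pair in itertools.combinations(range(20), 2)
        )
        medoids = []
        for c in sorted(set(labels.tolist())):
            members = np.flatnonzero(labels == c)
            within = dist[np.ix_(members, members)].sum(axis=1)
            medoids.append(members[int(np.argmin(within))])
        medoid_cost = dist[:, medoids].min(axis=1).sum()
        assert medoid_cost == pytest.approx(best)
        # blobs never mixed
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_identical_points_collapse_to_one_cluster(self):
        dist = np.zeros((12, 12))
        labels = kmedoids(dist, 3, seed=0)
        assert len(set(labels.tolist())) == 1

    def test_too_few_cells_rejected(self):
        views = [(ViewSpec("pca", 2), np.zeros((8, 2)))]
        with pytest.raises(ValueError):
            pam_sweep(views, 5, 10, seed=0)


class TestCoclusterMatrix:
    def test_single_labeling_is_binary(self):
        cc = cocluster_matrix([np.array([0, 0, 1, 1])])
        assert set(np.unique(cc)) <= {0.0, 1.0}
        assert np.allclose(np.diag(cc), 1.0)

    def test_half_agreement(self):
        cc = cocluster_matrix([np.array([0, 0]), np.array([0, 1])])
        assert cc[0, 1] == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(6)
        labelings = [rng.integers(0, 3, 15) for _ in range(7)]
        cc = cocluster_matrix(labelings)
        for i in range(15):
            for j in range(15):
                expected = np.mean([l[i] == l[j] for l in labelings])
                assert cc[i, j] == pytest.approx(expected)
        assert np.allclose(cc, cc.T)


def _consensus_oracle(cc, self_similarity, min_size):
    """Independent traversal: parse the linkage matrix directly and emit the
    qualifying nodes none of whose ancestors qualify."""
    n = cc.shape[0]
    diss = 1.0 - cc
    np.fill_diagonal(diss, 0.0)
    link = sch.linkage(ssd.squareform(diss, checks=False), method="average")
    members = {i: [i] for i in range(n)}
    parent = {}
    for row, (a, b, _, _) in enumerate(link):
        node = n + row
        members[node] = members[int(a)] + members[int(b)]
        parent[int(a)] = node
        parent[int(b)] = node

    def qualifies(node):
        m = members[node]
        if len(m) < min_size:
            return False
        block = cc[np.ix_(m, m)]
        mean_cc = (block.sum() - len(m)) / (len(m) * (len(m) - 1))
        return mean_cc >= self_similarity

    labels = np.full(n, UNASSIGNED)
    nxt = 0
    for node in sorted(members, key=lambda x: -len(members[x])):
        if qualifies(node):
            anc = node
            blocked = False
            while anc in parent:
                anc = parent[anc]
                if qualifies(anc):
                    blocked = True
                    break
            if not blocked and all(labels[m] == UNASSIGNED
                                   for m in members[node]):
                labels[members[node]] = nxt
                nxt += 1
    return labels


class TestConsensusClusters:
    def block_cc(self, sizes, within=1.0, between=0.0):
        n = sum(sizes)
        cc = np.full((n, n), between)
        start = 0
        for s in sizes:
            cc[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(cc, 1.0)
        return cc

    def test_two_perfect_blocks_fully_assigned(self):
        cc = self.block_cc([25, 20])
        labels = consensus_clusters(cc, 0.6, 20)
        assert len(set(labels.tolist())) == 2
        assert UNASSIGNED not in labels
        assert len(set(labels[:25])) == 1 and len(set(labels[25:])) == 1

    def test_undersized_block_unassigned(self):
        cc = self.block_cc([25, 19])
        labels = consensus_clusters(cc, 0.6, 20)
        assert set(labels[25:].tolist()) == {UNASSIGNED}
        assert len(set(labels[:25])) == 1 and labels[0] != UNASSIGNED

    def test_matches_exhaustive_subtree_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            base = self.block_cc([6, 6], within=0.9, between=0.1)
            noise = rng.uniform(-0.15, 0.15, size=base.shape)
            cc = np.clip(base + (noise + noise.T) / 2, 0, 1)
            np.fill_diagonal(cc, 1.0)
            ours = consensus_clusters(cc, 0.6, 3)
            oracle = _consensus_oracle(cc, 0.6, 3)
            assert adjusted_mutual_information(ours + 2, oracle + 2) == \
                pytest.approx(1.0) or np.array_equal(ours, oracle)
            assert np.array_equal(ours == UNASSIGNED, oracle == UNASSIGNED)


class TestMergeSimilarClusters:
    def test_identical_distributions_merged(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(1.0, 0.5, size=(200, 60))
        expr = make_expr(vals)
        labels = np.array([0] * 30 + [1] * 30)
        merged = merge_similar_clusters(expr, labels)
        assert len(set(merged.tolist())) == 1

    def test_shifted_clusters_not_merged(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(10.0, 1.0, size=(200, 60))
        vals[:80, 30:] += 3.0  # 40% of genes shifted by 3 SD in cluster 1
        expr = make_expr(np.abs(vals))
        labels = np.array([0] * 30 + [1] * 30)
        merged = merge_similar_clusters(expr, labels)
        assert len(set(merged.tolist())) == 2

    def test_single_cluster_unchanged(self, random_expression):
        labels = np.zeros(random_expression.n_cells, dtype=int)
        merged = merge_similar_clusters(random_expression, labels)
        assert np.array_equal(merged, labels)

    def test_unassigned_stay_unassigned(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(10, 1, size=(100, 45))
        vals[:40, 15:30] += 4.0
        vals[40:80, 30:] += 4.0
        expr = make_expr(np.abs(vals))
        labels = np.array([0] * 15 + [1] * 15 + [2] * 10 + [UNASSIGNED] * 5)
        merged = merge_similar_clusters(expr, labels)
        assert set(np.flatnonzero(merged == UNASSIGNED)) >= set(range(40, 45))


class TestRobustCluster:
    def test_recovers_types_on_clean_synthetic_data(self, easy_dataset):
        rc = robust_cluster(easy_dataset.counts,
                            ClusterConfig(seed=easy_dataset.seed))
        assert rc.n_clusters == 3
        assert proportion_robustly_clustered(rc.labels) >= 0.9
        assert adjusted_mutual_information(
            rc.labels, easy_dataset.true_labels) >= 0.9

    def test_no_structure_negative_control(self):
        net, mods = generate_network(300, 6, 0.2, 0.01, seed=77)
        ds = generate_counts(mods, 150, 3, fold_change=1.0, seed=77,
                             network=net)
        rc = robust_cluster(ds.counts, ClusterConfig(seed=5))
        assert rc.n_clusters <= 1 or \
            proportion_robustly_clustered(rc.labels) < 0.5

    def test_deterministic_under_seed(self, easy_dataset):
        cfg = ClusterConfig(seed=9)
        a = robust_cluster(easy_dataset.counts, cfg)
        b = robust_cluster(easy_dataset.counts, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.cocluster, b.cocluster)

    def test_cocluster_matrix_well_formed(self, easy_dataset):
        rc = robust_cluster(easy_dataset.counts, ClusterConfig(seed=5))
        cc = rc.cocluster
        assert np.allclose(cc, cc.T)
        assert np.allclose(np.diag(cc), 1.0)
        assert cc.min() >= 0.0 and cc.max() <= 1.0

    def test_every_cluster_meets_min_size(self, default_dataset):
        cfg = ClusterConfig(seed=4)
        rc = robust_cluster(default_dataset.counts, cfg)
        for c in set(rc.labels.tolist()) - {UNASSIGNED}:
            assert (rc.labels == c).sum() >= cfg.min_size

    def test_too_few_cells_rejected(self, random_expression):
        sub = ExpressionMatrix(random_expression.values[:, :10],
                               random_expression.gene_ids,
                               random_expression.cell_ids[:10])
        with pytest.raises(ValueError):
            robust_cluster(sub, ClusterConfig(seed=1))
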