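"""Graph auto-encoder: encoder, decoder, loss, splits, metrics, regression."""

import numpy as np
import pytest

from graphfae.core_data import Graph, normalize_adjacency
from graphfae.gae import (GaeConfig, GaeWeights, GraphAutoEncoder,
                          correlation_edge_scores, decode_adjacency,
                          evaluate_link_prediction, gcn_encode,
                          identity_features, indirect_predict,
                          reconstruction_loss, split_edges, train_gae,
                          variance_explained)
from graphfae.synthetic import erdos_renyi_graph, two_block_graph


def _random_graph(seed, n=6, p=0.5):
    g = erdos_renyi_graph(n, p, seed)
    if g.n_edges == 0:
        g = Graph.from_edge_pairs(g.node_ids, [(0, 1)])
    return g


class TestEncoder:
    def test_zero_input_gives_zero_embedding(self):
        g = _random_graph(0)
        w = GaeWeights(w0=np.ones((4, 3)), w1=np.ones((3, 2)))
        z = gcn_encode(np.zeros((6, 4)), normalize_adjacency(g), w)
        np.testing.assert_array_equal(z, np.zeros((6, 2)))

    def test_single_node_self_loop_only(self):
        g = Graph.from_edge_pairs(("a",), [])
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 3))
        w = GaeWeights(w0=rng.standard_normal((3, 4)),
                       w1=rng.standard_normal((4, 2)))
        z = gcn_encode(x, normalize_adjacency(g), w)
        expected = np.maximum(x @ w.w0, 0) @ w.w1
        np.testing.assert_allclose(z, expected, atol=1e-12)

    def test_matches_dense_two_step_oracle(self):
        rng = np.random.default_rng(2)
        g = _random_graph(2)
        x = rng.standard_normal((6, 5))
        w = GaeWeights(w0=rng.standard_normal((5, 4)),
                       w1=rng.standard_normal((4, 3)))
        a = normalize_adjacency(g).toarray()
        expected = a @ np.maximum(a @ x @ w.w0, 0) @ w.w1
        np.testing.assert_allclose(
            gcn_encode(x, normalize_adjacency(g), w), expected, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        g = _random_graph(0)
        w = GaeWeights(w0=np.ones((3, 2)), w1=np.ones((2, 2)))
        with pytest.raises(ValueError):
            gcn_encode(np.zeros((6, 4)), normalize_adjacency(g), w)


class TestDecoder:
    def test_zero_embedding_gives_half(self):
        probs = decode_adjacency(np.zeros((4, 3)), [(0, 1), (2, 3)])
        np.testing.assert_allclose(probs, 0.5)

    def test_unit_inner_product_closed_form(self):
        z = np.zeros((2, 4))
        z[0] = z[1] = [1.0, 0, 0, 0]
        assert decode_adjacency(z, [(0, 1)])[0] == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12)

    def test_symmetry_and_brute_force(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((5, 3))
        pairs = [(i, j) for i in range(5) for j in range(5) if i != j]
        probs = decode_adjacency(z, pairs)
        for k, (i, j) in enumerate(pairs):
            expected = 1 / (1 + np.exp(-float(z[i] @ z[j])))
            assert probs[k] == pytest.approx(expected, abs=1e-12)
        probs_rev = decode_adjacency(z, [(j, i) for i, j in pairs])
        np.testing.assert_allclose(probs, probs_rev)


class TestReconstructionLoss:
    def test_separated_embedding_loss_vanishes(self):
        # orthogonal cluster embeddings: within-pair logits >> 0,
        # cross-pair logits = 0 - eps -> weighted BCE approaches 0
        g = Graph.from_edge_pairs(("a", "b", "c", "d"), [(0, 1), (2, 3)])
        losses = []
        for scale in (1.0, 5.0, 30.0):
            z = np.zeros((4, 4))
            z[0] = z[1] = [scale, 0, 0, 0]
            z[2] = z[3] = [0, scale, 0, 0]
            # separate the two clusters with a shared negative component
            z[0, 2] = z[1, 2] = scale
            z[2, 3] = z[3, 3] = scale
            z[0, 3] = z[1, 3] = -scale
            z[2, 2] = z[3, 2] = -scale
            losses.append(reconstruction_loss(z, g))
        assert losses[2] < losses[1] < losses[0]
        assert losses[2] < 1e-6

    def test_zero_embedding_closed_form(self):
        # at Z=0 every entry contributes ln 2; weighted mean reduces to
        # 2*n_neg*ln2/N^2 (equals ln 2 exactly at class balance)
        g = Graph.from_edge_pairs(("a", "b", "c"), [(0, 1)])
        n_pos = 2 * 1 + 3
        n_neg = 9 - n_pos
        expected = 2 * n_neg * np.log(2) / 9
        assert reconstruction_loss(np.zeros((3, 2)), g) == pytest.approx(
            expected, abs=1e-12)

    def test_matches_entrywise_oracle(self):
        rng = np.random.default_rng(4)
        g = _random_graph(4, n=5)
        z = rng.standard_normal((5, 3))
        a = g.adjacency().toarray() + np.eye(5)
        n_pos = 2 * g.n_edges + 5
        pw = (25 - n_pos) / n_pos
        s = z @ z.T
        total = 0.0
        for i in range(5):
            for j in range(5):
                p = 1 / (1 + np.exp(-s[i, j]))
                if a[i, j]:
                    total += -pw * np.log(p)
                else:
                    total += -np.log(1 - p)
        assert reconstruction_loss(z, g) == pytest.approx(total / 25,
                                                          rel=1e-10)

    def test_edgeless_graph_rejected(self):
        g = Graph.from_edge_pairs(("a", "b"), [])
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), g)


class TestSplitEdges:
    def test_zero_fractions(self):
        g = _random_graph(5, n=10, p=0.4)
        s = split_edges(g, 0.0, 0.0, 0)
        assert len(s.train_pos) == g.n_edges
        assert len(s.val_neg) == 0 and len(s.test_neg) == 0

    def test_partition_contract(self):
        g = erdos_renyi_graph(30, 0.2, 6)
        s = split_edges(g, 0.1, 0.2, 1)
        all_edges = {tuple(e) for e in g.edge_array()}
        parts = [set(map(tuple, s.train_pos)), set(map(tuple, s.val_pos)),
                 set(map(tuple, s.test_pos))]
        assert parts[0] | parts[1] | parts[2] == all_edges
        assert not (parts[0] & parts[1] or parts[0] & parts[2]
                    or parts[1] & parts[2])
        assert len(s.val_neg) == len(s.val_pos)
        assert len(s.test_neg) == len(s.test_pos)

    def test_negatives_avoid_edges_many_graphs(self):
        for seed in range(100):
            g = erdos_renyi_graph(12, 0.3, seed)
            if g.n_edges < 5:
                continue
            s = split_edges(g, 0.1, 0.2, seed)
            negs = np.vstack([s.val_neg.reshape(-1, 2),
                              s.test_neg.reshape(-1, 2)])
            for i, j in negs:
                assert not g.has_edge(int(i), int(j))
            neg_set = set(map(tuple, negs))
            assert len(neg_set) == len(negs)  # negatives mutually disjoint

    def test_determinism_and_validation(self):
        g = erdos_renyi_graph(20, 0.3, 7)
        s1, s2 = split_edges(g, 0.1, 0.1, 3), split_edges(g, 0.1, 0.1, 3)
        np.testing.assert_array_equal(s1.train_pos, s2.train_pos)
        np.testing.assert_array_equal(s1.test_neg, s2.test_neg)
        with pytest.raises(ValueError):
            split_edges(g, 0.6, 0.5, 0)


class TestTrainGae:
    def test_seeded_runs_identical(self):
        g = erdos_renyi_graph(25, 0.2, 8)
        split = split_edges(g, 0.1, 0.1, 8)
        cfg = GaeConfig(epochs=30, seed=5)
        z1, _, c1 = train_gae(identity_features(25), g, split, cfg)
        z2, _, c2 = train_gae(identity_features(25), g, split, cfg)
        np.testing.assert_array_equal(z1, z2)
        np.testing.assert_array_equal(c1, c2)

    def test_loss_decreases_early(self):
        g = two_block_graph(60, 0.4, 0.02, 0)
        split = split_edges(g, 0.05, 0.1, 0)
        _, _, curve = train_gae(identity_features(60), g, split,
                                GaeConfig(epochs=12, seed=0))
        assert curve[10] < curve[0]

    def test_dense_two_block_auc_high(self):
        # learnable planted structure: dense blocks, sparse between
        g = two_block_graph(200, 0.9, 0.01, 0)
        split = split_edges(g, 0.05, 0.1, 0)
        z, _, _ = train_gae(identity_features(200), g, split,
                            GaeConfig(epochs=500, seed=0))
        auc, _ = evaluate_link_prediction(
            decode_adjacency(z, split.test_pos),
            decode_adjacency(z, split.test_neg))
        assert auc > 0.85


class TestLinkMetrics:
    def test_perfect_separation(self):
        auc, ap = evaluate_link_prediction([0.9, 0.8], [0.1, 0.2])
        assert auc == 1.0 and ap == 1.0

    def test_all_ties_half_auc(self):
        auc, _ = evaluate_link_prediction([0.5] * 4, [0.5] * 4)
        assert auc == 0.5

    def test_auc_matches_pairwise_count_oracle(self):
        rng = np.random.default_rng(9)
        pos, neg = rng.random(20), rng.random(20)
        auc, _ = evaluate_link_prediction(pos, neg)
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / 400, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_link_prediction([], [0.5])


class TestVarianceExplained:
    def test_exact_linear_map_is_one(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal((40, 5))
        x = z @ rng.standard_normal((5, 7))
        assert variance_explained(z, x) == pytest.approx(1.0, abs=1e-10)

    def test_constant_embedding_is_zero(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((30, 4))
        assert variance_explained(np.ones((30, 1)), x) == pytest.approx(
            0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal((25, 3))
        x = rng.standard_normal((25, 6))
        design = np.column_stack([z, np.ones(25)])
        beta = np.linalg.pinv(design.T @ design) @ design.T @ x
        ss_res = ((x - design @ beta) ** 2).sum()
        ss_tot = ((x - x.mean(axis=0)) ** 2).sum()
        assert variance_explained(z, x) == pytest.approx(
            1 - ss_res / ss_tot, abs=1e-8)


class TestCorrelationScores:
    def test_identical_and_orthogonal_rows(self):
        x = np.array([[1.0, 2, 3, 4],
                      [1.0, 2, 3, 4],
                      [1.0, -1, -1, 1]])
        s = correlation_edge_scores(x, [(0, 1), (0, 2)])
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((6, 10))
        pairs = [(0, 1), (2, 5), (3, 4)]
        s = correlation_edge_scores(x, pairs)
        for k, (i, j) in enumerate(pairs):
            r = np.corrcoef(x[i], x[j])[0, 1]
            assert s[k] == pytest.approx(abs(r), abs=1e-10)

    def test_too_few_experiments_rejected(self):
        with pytest.raises(ValueError):
            correlation_edge_scores(np.ones((3, 1)), [(0, 1)])


class TestIndirectPredict:
    def test_linear_target_recovered_by_lr(self):
        rng = np.random.default_rng(14)
        z = rng.standard_normal((30, 4))
        beta = rng.standard_normal(4)
        y = z @ beta
        pred = indirect_predict(z, y[:20], np.arange(20), np.arange(20, 30),
                                "LR")
        np.testing.assert_allclose(pred, y[20:], atol=1e-8)

    def test_constant_target_rf(self):
        rng = np.random.default_rng(15)
        z = rng.standard_normal((20, 3))
        pred = indirect_predict(z, np.full(15, 2.0), np.arange(15),
                                np.arange(15, 20), "RF", seed=0)
        np.testing.assert_allclose(pred, 2.0)

    def test_overlapping_sets_and_bad_enum_rejected(self):
        z = np.zeros((10, 2))
        with pytest.raises(ValueError):
            indirect_predict(z, np.zeros(5), np.arange(5), np.arange(4, 8),
                             "LR")
        with pytest.raises(ValueError, match="unknown regressor"):
            indirect_predict(z, np.zeros(5), np.arange(5), np.arange(5, 8),
                             "SVM")


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = GraphAutoEncoder(epochs=10, seed=3)
        params = est.get_params()
        assert params["epochs"] == 10
        est.set_params(hidden2=16)
        assert est.hidden2 == 16

    def test_fit_transform_and_scores(self):
        g = two_block_graph(40, 0.5, 0.05, 1)
        est = GraphAutoEncoder(epochs=30, seed=1)
        est.fit(None, graph=g)
        z = est.transform()
        assert z.shape == (40, 32)
        auc, ap = est.score_link_prediction()
        assert 0.0 <= auc <= 1.0 and 0.0 <= ap <= 1.0
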