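"""Episode construction and the dynamic-prototype episodic core."""

import math

import numpy as np
import pytest

from crossdti.autodiff import Tensor
from crossdti.encoder import DTIEncoder
from crossdti.inductive import PairFeaturizer
from crossdti.io_featurize import ClusterAssignment, InteractionRecord
from crossdti.meta import (AffineAttentionParams, Episode, FocalParams,
                           MetaModel, MetaTrainConfig, affine_attention,
                           build_episodes, classify_and_loss,
                           dynamic_prototypes, evaluate_fewshot,
                           expand_concat, predict_episode, train_meta)


def _interactions(n_prot=6, n_drug=8, cluster=0):
    """A dense balanced block of labelled pairs within one cluster."""
    out, mapping = [], {}
    for i in range(n_prot):
        pid = f"c{cluster}_p{i}"
        mapping[pid] = cluster
        for j in range(n_drug):
            out.append(InteractionRecord(f"d{j}", pid, (i + j) % 2))
    return out, mapping


class TestBuildEpisodes:
    def test_size_contract(self):
        inter, mapping = _interactions()
        asg = ClusterAssignment(mapping, 1)
        eps = build_episodes(inter, asg, k=3, k_q=5, n_tasks=7, seed=0)
        assert len(eps) == 7
        for ep in eps:
            assert len(ep.support) == 6
            assert ep.support_labels.sum() == 3
            assert len(ep.query) == 5

    def test_unseen_protein_guard(self):
        inter, mapping = _interactions()
        asg = ClusterAssignment(mapping, 1)
        for ep in build_episodes(inter, asg, k=2, k_q=4, n_tasks=10, seed=1):
            sup = {r.protein_id for r in ep.support}
            qry = {r.protein_id for r in ep.query}
            assert not sup & qry

    def test_single_protein_cluster_skipped_with_warning(self):
        inter = [InteractionRecord("d0", "lone", 1),
                 InteractionRecord("d1", "lone", 0)]
        good, mapping = _interactions(cluster=1)
        mapping["lone"] = 0
        asg = ClusterAssignment(mapping, 2)
        with pytest.warns(UserWarning, match="cluster 0"):
            eps = build_episodes(inter + good, asg, k=1, k_q=2, n_tasks=30,
                                 seed=0)
        assert all(ep.cluster_id == 1 for ep in eps)

    def test_no_feasible_cluster_raises(self):
        inter = [InteractionRecord("d0", "lone", 1)]
        asg = ClusterAssignment({"lone": 0}, 1)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            build_episodes(inter, asg, k=1, k_q=1, n_tasks=2, seed=0)

    def test_deterministic_per_seed(self):
        inter, mapping = _interactions()
        asg = ClusterAssignment(mapping, 1)
        def key(eps):
            return [([(r.drug_id, r.protein_id) for r in ep.support],
                     [(r.drug_id, r.protein_id) for r in ep.query])
                    for ep in eps]
        a = build_episodes(inter, asg, k=2, k_q=4, n_tasks=20, seed=5)
        b = build_episodes(inter, asg, k=2, k_q=4, n_tasks=20, seed=5)
        assert key(a) == key(b)

    def test_same_protein_mode_excludes_support_pairs_from_queries(self):
        inter, mapping = _interactions(n_prot=2)
        asg = ClusterAssignment(mapping, 1)
        for ep in build_episodes(inter, asg, k=2, k_q=4, n_tasks=5,
                                 mode="same_protein", seed=0):
            sup = {(r.drug_id, r.protein_id) for r in ep.support}
            qry = {(r.drug_id, r.protein_id) for r in ep.query}
            assert not sup & qry

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_episodes([], ClusterAssignment({}, 0), 1, 1, 1,
                           mode="bogus", seed=0)


class TestExpandConcat:
    def test_explicit_small_layout(self):
        O_s = Tensor(np.array([[[1.0, 0.0], [0.0, 1.0]]]))
        O_q = Tensor(np.array([[[5.0, 5.0]]]))
        O_c = expand_concat(O_s, O_q)
        expected = np.array([[[[5.0, 5.0], [1.0, 0.0], [0.0, 1.0]]]])
        np.testing.assert_array_equal(O_c.data, expected)

    def test_matches_three_nested_loops(self, rng):
        N, k, k_q, d = 3, 2, 4, 5
        O_s = Tensor(rng.normal(size=(N, 2 * k, d)))
        O_q = Tensor(rng.normal(size=(N, k_q, d)))
        O_c = expand_concat(O_s, O_q)
        assert O_c.shape == (N, k_q, 2 * k + 1, d)
        for n in range(N):
            for q in range(k_q):
                np.testing.assert_array_equal(O_c.data[n, q, 0], O_q.data[n, q])
                for i in range(2 * k):
                    np.testing.assert_array_equal(O_c.data[n, q, 1 + i],
                                                  O_s.data[n, i])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            expand_concat(Tensor(rng.normal(size=(2, 4, 3))),
                          Tensor(rng.normal(size=(2, 5, 4))))


class TestAffineAttention:
    def test_zero_modulation_gives_zero_scores(self, rng):
        d = 4
        params = AffineAttentionParams.init(d, seed=0)
        params.gamma1 = Tensor(np.zeros(d), True)
        params.beta1 = Tensor(np.zeros(d), True)
        O_c = Tensor(rng.normal(size=(2, 3, 5, d)))
        A = affine_attention(O_c, params)
        np.testing.assert_array_equal(A.data, np.zeros((2, 3, 4)))

    def test_nonnegative_everywhere(self, rng):
        params = AffineAttentionParams.init(6, seed=1)
        A = affine_attention(Tensor(rng.normal(size=(2, 3, 7, 6))), params)
        assert (A.data >= 0).all()

    def test_matches_hand_unrolled_evaluation(self, rng):
        """SiLU projection, two affine branches, squared-ReLU scores."""
        d = 2
        params = AffineAttentionParams.init(d, seed=3)
        O_c = Tensor(rng.normal(size=(1, 1, 3, d)))
        A = affine_attention(O_c, params)
        x = O_c.data[0, 0]
        h = x @ params.W_I.data
        h = h / (1 + np.exp(-h))
        Q = h * params.gamma1.data + params.beta1.data
        K = h * params.gamma2.data + params.beta2.data
        raw = np.maximum(Q @ K.T, 0) ** 2
        np.testing.assert_allclose(A.data[0, 0], raw[0, 1:], rtol=1e-10)


class TestDynamicPrototypes:
    def test_zero_scores_give_class_means(self, rng):
        N, k_q, k, d = 2, 3, 2, 4
        O_s = rng.normal(size=(N, 2 * k, d))
        labels = np.array([0, 0, 1, 1])
        O_c = expand_concat(Tensor(O_s), Tensor(rng.normal(size=(N, k_q, d))))
        A = Tensor(np.zeros((N, k_q, 2 * k)))
        P = dynamic_prototypes(O_c[:, :, 1:, :], labels, A)
        for c in (0, 1):
            mean = O_s[:, labels == c].mean(axis=1)
            for q in range(k_q):
                np.testing.assert_allclose(P.data[:, q, c], mean, atol=1e-12)

    def test_one_shot_prototype_is_the_single_support(self, rng):
        O_s = rng.normal(size=(1, 2, 3))
        labels = np.array([0, 1])
        O_c = expand_concat(Tensor(O_s), Tensor(rng.normal(size=(1, 2, 3))))
        A = Tensor(rng.random((1, 2, 2)))
        P = dynamic_prototypes(O_c[:, :, 1:, :], labels, A)
        for q in range(2):
            np.testing.assert_allclose(P.data[0, q, 0], O_s[0, 0], atol=1e-12)
            np.testing.assert_allclose(P.data[0, q, 1], O_s[0, 1], atol=1e-12)

    def test_matches_loop_and_softmax_oracle(self, rng):
        N, k_q, k, d = 2, 3, 3, 4
        O_s = rng.normal(size=(N, 2 * k, d))
        labels = rng.permutation([0] * k + [1] * k)
        O_q = rng.normal(size=(N, k_q, d))
        O_c = expand_concat(Tensor(O_s), Tensor(O_q))
        A = Tensor(rng.random((N, k_q, 2 * k)) * 3)
        P = dynamic_prototypes(O_c[:, :, 1:, :], labels, A)
        for n in range(N):
            for q in range(k_q):
                for c in (0, 1):
                    idx = np.where(labels == c)[0]
                    w = np.exp(A.data[n, q, idx])
                    w = w / w.sum()
                    ref = (w[:, None] * O_s[n, idx]).sum(axis=0)
                    np.testing.assert_allclose(P.data[n, q, c], ref, atol=1e-6)

    def test_within_class_support_permutation_invariance(self, rng):
        N, k_q, k, d = 1, 2, 3, 4
        O_s = rng.normal(size=(N, 2 * k, d))
        labels = np.array([0] * k + [1] * k)
        O_q = rng.normal(size=(N, k_q, d))
        A_raw = rng.random((N, k_q, 2 * k))
        perm = np.concatenate([rng.permutation(k), k + rng.permutation(k)])
        O_c1 = expand_concat(Tensor(O_s), Tensor(O_q))
        O_c2 = expand_concat(Tensor(O_s[:, perm]), Tensor(O_q))
        P1 = dynamic_prototypes(O_c1[:, :, 1:, :], labels, Tensor(A_raw))
        P2 = dynamic_prototypes(O_c2[:, :, 1:, :], labels[perm],
                                Tensor(A_raw[:, :, perm]))
        np.testing.assert_allclose(P1.data, P2.data, atol=1e-12)

    def test_cardinality_prefactor_rescales_without_changing_predictions(
            self, rng):
        N, k_q, k, d = 1, 2, 2, 3
        O_s = rng.normal(size=(N, 2 * k, d))
        labels = np.array([0] * k + [1] * k)
        O_q = rng.normal(size=(N, k_q, d))
        O_c = expand_concat(Tensor(O_s), Tensor(O_q))
        A = Tensor(rng.random((N, k_q, 2 * k)))
        P = dynamic_prototypes(O_c[:, :, 1:, :], labels, A)
        Pf = dynamic_prototypes(O_c[:, :, 1:, :], labels, A,
                                cardinality_prefactor=True)
        np.testing.assert_allclose(Pf.data, P.data / (2 * k + 1), atol=1e-12)
        s1, _, _ = classify_and_loss(P, Tensor(O_q),
                                     np.zeros((N, k_q), int), FocalParams())
        s2, _, _ = classify_and_loss(Pf, Tensor(O_q),
                                     np.zeros((N, k_q), int), FocalParams())
        np.testing.assert_allclose(s1.data, s2.data, atol=1e-6)

    def test_missing_class_rejected(self, rng):
        O_c = expand_concat(Tensor(rng.normal(size=(1, 2, 3))),
                            Tensor(rng.normal(size=(1, 1, 3))))
        with pytest.raises(ValueError):
            dynamic_prototypes(O_c[:, :, 1:, :], np.array([1, 1]),
                               Tensor(np.zeros((1, 1, 2))))


class TestClassifyAndLoss:
    def test_orthogonal_prototypes_softmax_value(self):
        """Query aligned with one prototype and orthogonal to the other:
        scores (1, 0), true-class probability e/(e+1)."""
        P = Tensor(np.array([[[[0.0, 1.0], [1.0, 0.0]]]]))
        O_q = Tensor(np.array([[[1.0, 0.0]]]))
        scores, p, _ = classify_and_loss(P, O_q, np.array([[1]]),
                                         FocalParams(1.0, 2.0))
        np.testing.assert_allclose(scores.data[0, 0], [0.0, 1.0], atol=1e-7)
        assert p.data[0, 0] == pytest.approx(math.e / (math.e + 1), abs=1e-7)

    def test_focal_reduces_to_cross_entropy(self, rng):
        """gamma=0, alpha=1 recovers the mean cross-entropy exactly."""
        N, k_q, d = 3, 4, 5
        P = Tensor(rng.normal(size=(N, k_q, 2, d)))
        O_q = Tensor(rng.normal(size=(N, k_q, d)))
        y = rng.integers(0, 2, size=(N, k_q))
        _, p, loss = classify_and_loss(P, O_q, y, FocalParams(1.0, 0.0))
        ce = -np.log(p.data).mean()
        assert float(loss.data) == pytest.approx(ce, abs=1e-7)

    def test_half_probability_closed_form(self):
        """p = 0.5, gamma = 2, alpha = 1 on one query gives 0.25*ln 2."""
        P = Tensor(np.array([[[[1.0, 0.0], [0.0, 1.0]]]]))
        O_q = Tensor(np.array([[[1.0, 1.0]]]))
        _, p, loss = classify_and_loss(P, O_q, np.array([[1]]),
                                       FocalParams(1.0, 2.0))
        assert p.data[0, 0] == pytest.approx(0.5, abs=1e-9)
        assert float(loss.data) == pytest.approx(0.25 * math.log(2), abs=1e-9)

    def test_prototype_scale_invariance(self, rng):
        """Rescaling prototypes by any c > 0 leaves scores and loss alone."""
        N, k_q, d = 2, 3, 4
        P = rng.normal(size=(N, k_q, 2, d))
        O_q = Tensor(rng.normal(size=(N, k_q, d)))
        y = rng.integers(0, 2, size=(N, k_q))
        fp = FocalParams(1.5, 2.0)
        s1, _, l1 = classify_and_loss(Tensor(P), O_q, y, fp)
        s2, _, l2 = classify_and_loss(Tensor(P * 37.0), O_q, y, fp)
        np.testing.assert_allclose(s1.data, s2.data, atol=1e-6)
        assert float(l1.data) == pytest.approx(float(l2.data), abs=1e-6)

    def test_zero_norm_query_is_guarded(self):
        P = Tensor(np.ones((1, 1, 2, 3)))
        O_q = Tensor(np.zeros((1, 1, 3)))
        scores, p, loss = classify_and_loss(P, O_q, np.array([[0]]),
                                            FocalParams())
        assert np.isfinite(scores.data).all() and np.isfinite(loss.data)
        assert p.data[0, 0] == pytest.approx(0.5)

    def test_alpha_weights_only_positive_queries(self, rng):
        P = Tensor(rng.normal(size=(1, 2, 2, 3)))
        O_q = Tensor(rng.normal(size=(1, 2, 3)))
        y = np.array([[1, 0]])
        _, p, l1 = classify_and_loss(P, O_q, y, FocalParams(alpha=1.0, gamma=0.0))
        _, _, l2 = classify_and_loss(P, O_q, y, FocalParams(alpha=3.0, gamma=0.0))
        ce = -np.log(p.data)[0]
        expect = ((3.0 * ce[0] + ce[1]) / 2)
        assert float(l2.data) == pytest.approx(expect, rel=1e-6)


def _mini_meta_setup(small_encoder_config):
    inter, mapping = _interactions(n_prot=4, n_drug=6)
    from crossdti.io_featurize import DrugRecord, ProteinRecord
    rng = np.random.default_rng(0)
    proteins = [ProteinRecord(pid, "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20)))
                for pid in mapping]
    drugs = [DrugRecord(f"d{j}", s) for j, s in enumerate(
        ["CCO", "CCN", "c1ccccc1", "CC(=O)O", "CCCl", "COC"])]
    feat = PairFeaturizer(proteins, drugs, small_encoder_config.l_max)
    asg = ClusterAssignment(mapping, 1)
    episodes = build_episodes(inter, asg, k=2, k_q=4, n_tasks=6, seed=2)
    return episodes, feat


class TestTrainMeta:
    def test_zero_epochs_returns_stage_one_encoder(self, small_encoder_config):
        episodes, feat = _mini_meta_setup(small_encoder_config)
        init = DTIEncoder(small_encoder_config, seed=8)
        model, log = train_meta(episodes, init, feat,
                                MetaTrainConfig(epochs=0, dtype="float64"),
                                seed=1)
        assert log == []
        for k in init.params:
            np.testing.assert_array_equal(model.encoder.params[k].data,
                                          init.params[k].data)

    def test_training_is_deterministic(self, small_encoder_config):
        episodes, feat = _mini_meta_setup(small_encoder_config)
        init = DTIEncoder(small_encoder_config, seed=8)
        m1, _ = train_meta(episodes, init, feat, MetaTrainConfig(epochs=2),
                           seed=3)
        m2, _ = train_meta(episodes, init, feat, MetaTrainConfig(epochs=2),
                           seed=3)
        for k in m1.encoder.params:
            np.testing.assert_array_equal(m1.encoder.params[k].data,
                                          m2.encoder.params[k].data)
        np.testing.assert_array_equal(m1.attention.W_I.data,
                                      m2.attention.W_I.data)

    def test_model_round_trip(self, small_encoder_config, tmp_path):
        episodes, feat = _mini_meta_setup(small_encoder_config)
        init = DTIEncoder(small_encoder_config, seed=8)
        model, _ = train_meta(episodes, init, feat, MetaTrainConfig(epochs=1),
                              seed=3)
        model.save(tmp_path / "meta.npz")
        loaded = MetaModel.load(tmp_path / "meta.npz")
        p1 = predict_episode(model, episodes[0], feat)
        p2 = predict_episode(loaded, episodes[0], feat)
        np.testing.assert_allclose(p1, p2, atol=1e-7)


def test_episode_jsonl_round_trip(tmp_path):
    from crossdti.meta import episodes_from_jsonl, episodes_to_jsonl
    inter, mapping = _interactions()
    asg = ClusterAssignment(mapping, 1)
    eps = build_episodes(inter, asg, k=2, k_q=3, n_tasks=4, seed=9)
    episodes_to_jsonl(eps, tmp_path / "eps.jsonl")
    loaded = episodes_from_jsonl(tmp_path / "eps.jsonl")
    assert len(loaded) == len(eps)
    for a, b in zip(eps, loaded):
        assert [(r.drug_id, r.protein_id, r.label) for r in a.support] == \
            [(r.drug_id, r.protein_id, r.label) for r in b.support]
        assert [(r.drug_id, r.protein_id, r.label) for r in a.query] == \
            [(r.drug_id, r.protein_id, r.label) for r in b.query]
        assert (a.cluster_id, a.mode) == (b.cluster_id, b.mode)


class TestEvaluateFewshot:
    def test_zeroed_model_scores_half_everywhere(self, small_encoder_config):
        episodes, feat = _mini_meta_setup(small_encoder_config)
        model = MetaModel(DTIEncoder(small_encoder_config, seed=0))
        model.zero_parameters()
        probs = predict_episode(model, episodes[0], feat)
        np.testing.assert_allclose(probs, 0.5, atol=1e-9)
        reports, agg = evaluate_fewshot(model, episodes, feat)
        assert agg["auroc_mean"] == pytest.approx(0.5)

    def test_single_class_queries_excluded_with_warning(self,
                                                        small_encoder_config):
        episodes, feat = _mini_meta_setup(small_encoder_config)
        ep = episodes[0]
        bad = Episode(support=ep.support, support_labels=ep.support_labels,
                      query=ep.query, query_labels=np.ones(len(ep.query), int),
                      cluster_id=ep.cluster_id, mode=ep.mode)
        model = MetaModel(DTIEncoder(small_encoder_config, seed=0))
        with pytest.warns(UserWarning, match="single-class"):
            reports, agg = evaluate_fewshot(model, [bad], feat)
        assert reports[0].auroc is None
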