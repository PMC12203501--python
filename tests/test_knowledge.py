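"""Graph filtering, the four scoring functions, negative sampling, texts."""

import numpy as np
import pytest
from scipy import stats

from subloc3d import (
    HashingTextEmbedder,
    KGEModel,
    KnowledgeGraph,
    embed_go_terms,
    filter_sproteinkg,
    invert_head,
    knowledge_feature,
    sample_negatives,
    score_triple,
)
from subloc3d.knowledge import invert_head_batch, score_batch
from subloc3d.autodiff import Tensor


# -- independent scoring oracle (complex arithmetic, no package code) --------


def oracle_score(method, h, r, t):
    h, r, t = (np.asarray(v, float) for v in (h, r, t))
    d = len(h)
    if method == "transe":
        return np.sqrt(((h + r - t) ** 2).sum())
    if method == "rotate":
        hc = h[: d // 2] + 1j * h[d // 2:]
        tc = t[: d // 2] + 1j * t[d // 2:]
        rc = np.exp(1j * r)
        return np.sqrt((np.abs(hc * rc - tc) ** 2).sum())
    if method == "pairre":
        rh, rt = r[:d], r[d:]
        hn = h / np.linalg.norm(h)
        tn = t / np.linalg.norm(t)
        return np.sqrt(((hn * rh - tn * rt) ** 2).sum())
    if method == "complex":
        hc = h[: d // 2] + 1j * h[d // 2:]
        rc = r[: d // 2] + 1j * r[d // 2:]
        tc = t[: d // 2] + 1j * t[d // 2:]
        return -np.real((hc * rc * np.conj(tc)).sum())
    raise AssertionError(method)


def _rel_dim(method, d):
    return {"transe": d, "rotate": d // 2, "pairre": 2 * d, "complex": d}[
        method
    ]


@pytest.mark.parametrize("method", ["transe", "rotate", "pairre", "complex"])
def test_scoring_matches_independent_oracle(method):
    rng = np.random.default_rng(2024)
    d = 4
    for _ in range(100):
        h = rng.normal(size=d)
        t = rng.normal(size=d)
        r = (rng.uniform(-np.pi, np.pi, size=2) if method == "rotate"
             else rng.normal(size=_rel_dim(method, d)))
        got = float(score_batch(method, Tensor(h[None]), Tensor(r[None]),
                                Tensor(t[None])).data[0])
        assert abs(got - oracle_score(method, h, r, t)) < 1e-8


class TestScoringSpecialCases:
    def test_transe_exact_translation_scores_zero(self):
        h, r = np.array([1.0, 2.0]), np.array([0.5, -1.0])
        d = score_batch("transe", Tensor(h[None]), Tensor(r[None]),
                        Tensor((h + r)[None]))
        assert abs(float(d.data[0])) < 1e-9

    def test_rotate_identity_rotation_is_plain_distance(self):
        rng = np.random.default_rng(0)
        h, t = rng.normal(size=4), rng.normal(size=4)
        d = score_batch("rotate", Tensor(h[None]),
                        Tensor(np.zeros(2)[None]), Tensor(t[None]))
        assert abs(float(d.data[0]) - np.linalg.norm(h - t)) < 1e-9

    def test_pairre_unit_relations_on_prenormalized_equal_entities(self):
        h = np.array([0.6, 0.8])
        r = np.ones(4)
        d = score_batch("pairre", Tensor(h[None]), Tensor(r[None]),
                        Tensor(h[None]), h_normalized=True,
                        t_normalized=True)
        assert abs(float(d.data[0])) < 1e-9

    def test_complex_all_ones_real_triple_scores_minus_one(self):
        v = np.array([1.0, 0.0])  # 1 + 0i in one complex coordinate
        d = score_batch("complex", Tensor(v[None]), Tensor(v[None]),
                        Tensor(v[None]))
        assert abs(float(d.data[0]) + 1.0) < 1e-12

    @pytest.mark.parametrize("method", ["transe", "rotate", "pairre",
                                        "complex"])
    def test_score_invariant_under_joint_coordinate_permutation(self, method):
        rng = np.random.default_rng(7)
        d = 6
        h, t = rng.normal(size=d), rng.normal(size=d)
        r = (rng.uniform(-np.pi, np.pi, size=3) if method == "rotate"
             else rng.normal(size=_rel_dim(method, d)))
        base = float(score_batch(method, Tensor(h[None]), Tensor(r[None]),
                                 Tensor(t[None])).data[0])
        # permute complex coordinates jointly (keep re/im pairing)
        perm = np.array([2, 0, 1])
        full = np.concatenate([perm, perm + 3])
        if method == "transe":
            hp, tp = h[full], t[full]
            rp = r[full]
        elif method == "rotate":
            hp, tp, rp = h[full], t[full], r[perm]
        elif method == "pairre":
            hp, tp = h[full], t[full]
            rp = np.concatenate([r[:6][full], r[6:][full]])
        else:
            hp, tp, rp = h[full], t[full], r[full]
        permuted = float(score_batch(method, Tensor(hp[None]),
                                     Tensor(rp[None]),
                                     Tensor(tp[None])).data[0])
        assert abs(base - permuted) < 1e-10

    def test_rotate_rotation_preserves_norm(self):
        rng = np.random.default_rng(8)
        h = rng.normal(size=6)
        r = rng.uniform(-np.pi, np.pi, size=3)
        # score vs zero tail equals the norm of the rotated head = |h|
        d = score_batch("rotate", Tensor(h[None]), Tensor(r[None]),
                        Tensor(np.zeros(6)[None]))
        assert abs(float(d.data[0]) - np.linalg.norm(h)) < 1e-9


class TestHeadInversion:
    def test_transe_example(self):
        hat = invert_head_batch("transe", np.array([[0.0, 1.0]]),
                                np.array([[1.0, 1.0]]))[0]
        assert np.allclose(hat, [1.0, 0.0])

    def test_rotate_zero_phase_returns_tail(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        hat = invert_head_batch("rotate", np.zeros((1, 2)), t[None])[0]
        assert np.allclose(hat, t)

    @pytest.mark.parametrize("method", ["transe", "rotate", "pairre"])
    def test_inversion_self_consistency(self, method):
        rng = np.random.default_rng(99)
        d = 4
        for _ in range(100):
            t = rng.normal(size=d)
            if method == "rotate":
                r = rng.uniform(-np.pi, np.pi, size=2)
            elif method == "pairre":
                r = rng.normal(size=8)
                r[:4] += np.sign(r[:4]) * 0.2  # keep r_H away from zero
            else:
                r = rng.normal(size=d)
            hat = invert_head_batch(method, r[None], t[None])[0]
            d_val = float(score_batch(
                method, Tensor(hat[None]), Tensor(r[None]), Tensor(t[None]),
                h_normalized=(method == "pairre"),
            ).data[0])
            assert d_val < 1e-6

    def test_pairre_near_zero_relation_entry_names_coordinate(self):
        r = np.ones(8)
        r[2] = 1e-12
        with pytest.raises(ValueError, match="coordinate"):
            invert_head_batch("pairre", r[None], np.ones(4)[None])

    def test_complex_inversion_unsupported(self):
        with pytest.raises(ValueError, match="surrogate"):
            invert_head_batch("complex", np.ones(4)[None],
                              np.ones(4)[None])


# -- graph fixtures ----------------------------------------------------------


def toy_graph():
    """Hand-enumerated filter fixture.

    Tagged proteins p1-p3; p4 untagged.  g1 and g2 are each cited by all
    three tagged proteins; g3 only via the untagged p4.  After filtering:
    6 protein-GO triples survive (p4's is dropped), and of the GO-GO
    triples only (g1, is_a, g2) survives — g3's tagged degree is 0.
    """
    entities = {f"p{i}": "protein" for i in range(1, 5)}
    entities.update({"g1": "CC", "g2": "CC", "g3": "BP", "g4": "MF"})
    triples = [
        ("p1", "located_in", "g1"), ("p2", "located_in", "g1"),
        ("p3", "located_in", "g1"), ("p1", "located_in", "g2"),
        ("p2", "located_in", "g2"), ("p3", "located_in", "g2"),
        ("p4", "involved_in", "g3"),
        ("g1", "is_a", "g2"), ("g2", "is_a", "g3"), ("g3", "is_a", "g1"),
    ]
    texts = {g: f"annotation text describing term {g} in detail"
             for g in ("g1", "g2", "g3", "g4")}
    return KnowledgeGraph(
        entities=entities,
        relations=["located_in", "involved_in", "is_a"],
        triples=triples, go_texts=texts,
    )


class TestFilter:
    def test_designed_fixture_surviving_counts(self):
        out = filter_sproteinkg(toy_graph(), {"p1", "p2", "p3"})
        assert len(out.protein_go_triples()) == 6
        assert out.go_go_triples() == [("g1", "is_a", "g2")]
        assert "p4" not in out.entities and "g3" not in out.entities

    def test_degree_threshold_is_strictly_greater_than_two(self):
        g = toy_graph()
        # drop p3's citation of g2 -> g2 degree 2 -> its GO-GO edge dies
        g.triples.remove(("p3", "located_in", "g2"))
        out = filter_sproteinkg(g, {"p1", "p2", "p3"})
        assert out.go_go_triples() == []

    def test_no_tagged_heads_leaves_nothing(self):
        with pytest.warns(UserWarning):
            out = filter_sproteinkg(toy_graph(), set())
        assert out.triples == []

    def test_filter_is_idempotent(self):
        tagged = {"p1", "p2", "p3"}
        once = filter_sproteinkg(toy_graph(), tagged)
        twice = filter_sproteinkg(once, tagged)
        assert once.triples == twice.triples
        assert once.entities == twice.entities


class TestGraphInvariants:
    def test_duplicate_triples_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            KnowledgeGraph(
                entities={"p1": "protein", "g1": "CC"},
                relations=["located_in"],
                triples=[("p1", "located_in", "g1")] * 2,
            )

    def test_protein_tail_rejected(self):
        with pytest.raises(ValueError, match="tail"):
            KnowledgeGraph(
                entities={"p1": "protein", "p2": "protein", "g1": "CC"},
                relations=["r"], triples=[("g1", "r", "p2")],
            )


class TestNegativeSampling:
    def test_negatives_share_tail_category(self):
        g = toy_graph()
        rng = np.random.default_rng(0)
        negs = sample_negatives(g, ("p1", "located_in", "g1"), 20, rng)
        for h, r, t in negs:
            assert (h, r) == ("p1", "located_in")
            assert g.entities[t] == "CC" and t != "g1"

    def test_two_member_category_always_picks_the_alternative(self):
        g = toy_graph()
        negs = sample_negatives(g, ("p1", "located_in", "g1"), 10,
                                np.random.default_rng(1))
        assert {t for _, _, t in negs} == {"g2"}

    def test_singleton_category_rejected(self):
        g = toy_graph()
        with pytest.raises(ValueError, match="category"):
            sample_negatives(g, ("p4", "involved_in", "g3"), 2,
                             np.random.default_rng(0))

    def test_uniformity_passes_chi_square_at_99_percent(self):
        entities = {"p1": "protein"}
        entities.update({f"c{i}": "CC" for i in range(5)})
        g = KnowledgeGraph(entities=entities, relations=["located_in"],
                           triples=[("p1", "located_in", "c0")])
        rng = np.random.default_rng(3)
        negs = sample_negatives(g, ("p1", "located_in", "c0"), 10_000, rng)
        counts = np.array([sum(1 for _, _, t in negs if t == f"c{i}")
                           for i in range(1, 5)])
        chi2 = ((counts - 2500.0) ** 2 / 2500.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=3)


class TestTextEmbedding:
    def test_same_text_same_vector_and_dimension(self):
        emb = HashingTextEmbedder(dim=32, seed=0)
        v = emb.embed(["endoplasmic reticulum network", "golgi stack",
                       "endoplasmic reticulum network"])
        assert v.shape == (3, 32)
        assert np.array_equal(v[0], v[2])
        assert not np.array_equal(v[0], v[1])

    def test_embedder_reproducible_across_instances(self):
        a = HashingTextEmbedder(dim=16, seed=5).embed(["membrane bilayer"])
        b = HashingTextEmbedder(dim=16, seed=5).embed(["membrane bilayer"])
        c = HashingTextEmbedder(dim=16, seed=6).embed(["membrane bilayer"])
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_embed_go_terms_requires_text(self):
        g = toy_graph()
        del g.go_texts["g2"]
        with pytest.raises(ValueError, match="g2"):
            embed_go_terms(g, HashingTextEmbedder(dim=8))

    def test_model_initialization_is_deterministic(self):
        g = toy_graph()
        a = KGEModel("transe", g, entity_dim=8, seed=3)
        b = KGEModel("transe", g, entity_dim=8, seed=3)
        assert np.array_equal(a.go_embeddings.data, b.go_embeddings.data)
        assert np.array_equal(a.relation_parameters.data,
                              b.relation_parameters.data)


class TestKnowledgeFeature:
    def _model(self, method="transe"):
        return KGEModel(method, toy_graph(), entity_dim=8, seed=0)

    def test_single_triple_feature_equals_implied_head(self):
        g = toy_graph()
        g.triples = [tr for tr in g.triples if tr[0] != "p1"
                     or tr == ("p1", "located_in", "g1")]
        model = KGEModel("transe", g, entity_dim=8, seed=0)
        feat, present = knowledge_feature(model, "p1", g)
        assert present
        expected = invert_head(model, "located_in",
                               model.go_embedding("g1"))
        assert np.allclose(feat, expected)

    def test_identical_implied_heads_average_to_themselves(self):
        model = self._model()
        g = toy_graph()
        # make both GO embeddings equal -> identical implied heads
        model.go_embeddings.data[model.go_index["g2"]] = \
            model.go_embeddings.data[model.go_index["g1"]]
        feat, _ = knowledge_feature(model, "p1", g)
        head = invert_head(model, "located_in", model.go_embedding("g1"))
        assert np.allclose(feat, head)

    def test_protein_without_triples_gets_zero_vector_and_flag(self):
        model = self._model()
        g = toy_graph()
        g.triples = [tr for tr in g.triples if tr[0] != "p2"]
        feat, present = knowledge_feature(model, "p2", g)
        assert not present and np.all(feat == 0)

    def test_tail_embedding_pooling_mode(self):
        model = self._model()
        g = toy_graph()
        feat, _ = knowledge_feature(model, "p1", g,
                                    pooling="tail_embedding")
        expected = np.mean([model.go_embedding("g1"),
                            model.go_embedding("g2")], axis=0)
        assert np.allclose(feat, expected)

    def test_complex_uses_conjugate_product_surrogate(self):
        model = self._model("complex")
        feat, present = knowledge_feature(model, "p1", toy_graph())
        assert present and feat.shape == (8,) and np.isfinite(feat).all()


def test_score_triple_validates_dimensions():
    model = KGEModel("transe", toy_graph(), entity_dim=8, seed=0)
    with pytest.raises(ValueError, match="dim"):
        score_triple(model, np.ones(4), "located_in", np.ones(8))


def test_kge_model_rejects_odd_dims_for_complex_pairing():
    for method in ("rotate", "complex"):
        with pytest.raises(ValueError, match="even"):
            KGEModel(method, toy_graph(), entity_dim=7, seed=0)
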