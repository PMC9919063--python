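"""Language metrics, diversity metrics and the latent separation score."""

import numpy as np
import pytest

from divqg.evaluation import (
    HashingEmbedder,
    compute_language_metrics,
    corpus_similarity,
    evaluate_generated,
    get_embedder,
    inventiveness,
    latent_separation_score,
    similarity_heatmap,
    similarity_score,
)


# -- embedder ---------------------------------------------------------------


def test_hash_embedder_is_unit_norm_and_deterministic():
    emb = HashingEmbedder()
    v1 = emb("does the picture contain the liver ?")
    v2 = emb("does the picture contain the liver ?")
    assert np.linalg.norm(v1) == pytest.approx(1.0, abs=1e-6)
    assert np.array_equal(v1, v2)
    assert not np.array_equal(v1, emb("in what plane is this image scanned ?"))


def test_embedder_registry():
    assert isinstance(get_embedder("hash"), HashingEmbedder)
    with pytest.raises(ValueError):
        get_embedder("universal-sentence-encoder")


# -- language metrics -------------------------------------------------------


def test_perfect_match_gives_unit_bleu_and_rouge():
    g = {"im0": ["is the lung shown in this image ?"]}
    r = {"im0": ["is the lung shown in this image ?"]}
    m = compute_language_metrics(g, r)
    for key in ("bleu_1", "bleu_2", "bleu_3", "bleu_4", "rouge_l"):
        assert m[key] == pytest.approx(1.0), key
    assert m["meteor"] > 0.9
    assert m["cider"] > 0


def test_disjoint_unigrams_give_zero_bleu1():
    g = {"im0": ["what modality ?"]}
    r = {"im0": ["is the lung shown"]}
    m = compute_language_metrics(g, r)
    assert m["bleu_1"] == 0.0
    assert m["rouge_l"] == 0.0
    assert m["meteor"] == 0.0


def test_clipped_precision_hand_case():
    """Candidate 'the the the' vs reference 'the cat sat': BLEU-1 = 1/3."""
    m = compute_language_metrics({"a": ["the the the"]}, {"a": ["the cat sat"]})
    assert m["bleu_1"] == pytest.approx(1.0 / 3.0)


def test_key_misalignment_reported():
    with pytest.raises(ValueError, match="im1"):
        compute_language_metrics({"im0": ["q ?"]}, {"im0": ["q ?"], "im1": ["p ?"]})


def test_metrics_invariant_to_image_ordering():
    g = {"a": ["is the lung shown in this image ?"],
         "b": ["where is the liver located ?"]}
    r = {"a": ["is the lung shown in this image ?"],
         "b": ["is the liver on the left side ?"]}
    m1 = compute_language_metrics(g, r)
    g2 = dict(reversed(list(g.items())))
    r2 = dict(reversed(list(r.items())))
    m2 = compute_language_metrics(g2, r2)
    assert m1 == m2


# -- inventiveness ----------------------------------------------------------


@pytest.mark.parametrize(
    "generated,training,expected",
    [
        (["a b ?", "c d ?"], ["a b ?", "c d ?"], 0.0),
        (["x y ?", "z w ?"], ["a b ?"], 100.0),
        (["a b ?", "a b ?", "a b ?", "new one ?"], ["a b ?"], 25.0),
    ],
)
def test_inventiveness_counts_exact_novelty(generated, training, expected):
    assert inventiveness(generated, training) == pytest.approx(expected)


def test_inventiveness_normalizes_tokenization():
    assert inventiveness(["Is the Lung shown?"], ["is the lung shown ?"]) == 0.0


def test_inventiveness_empty_generated_is_undefined():
    assert np.isnan(inventiveness([], ["a ?"]))


# -- similarity -------------------------------------------------------------


def test_identical_questions_have_unit_similarity():
    q = ["is the lung shown in this image ?"] * 3
    assert similarity_score(q, HashingEmbedder()) == pytest.approx(1.0)


def test_orthogonal_embeddings_have_zero_similarity():
    basis = {"q1": np.array([1.0, 0.0]), "q2": np.array([0.0, 1.0])}
    assert similarity_score(["q1", "q2"], basis.get) == pytest.approx(0.0)


def test_similarity_invariant_under_permutation(rng):
    questions = [
        "is the lung shown in this image ?",
        "where is the liver located ?",
        "what modality was used to take this image ?",
    ]
    emb = HashingEmbedder()
    base = similarity_score(questions, emb)
    perm = [questions[i] for i in rng.permutation(3)]
    assert similarity_score(perm, emb) == pytest.approx(base)


def test_similarity_range_bounds(rng):
    questions = ["a b ?", "c d ?", "a d ?", "b c ?"]
    score = similarity_score(questions, HashingEmbedder())
    assert -1.0 <= score <= 1.0


def test_similarity_requires_two_questions():
    with pytest.raises(ValueError):
        similarity_score(["only one ?"], HashingEmbedder())


def test_corpus_similarity_skips_single_question_images():
    emb = HashingEmbedder()
    gen = {"a": ["x y ?", "x y ?"], "b": ["solo ?"]}
    assert corpus_similarity(gen, emb) == pytest.approx(1.0)
    assert np.isnan(corpus_similarity({"b": ["solo ?"]}, emb))


# -- heatmap ----------------------------------------------------------------


def test_heatmap_shape_and_diagonal():
    questions = ["is the lung shown ?", "where is the liver located ?"]
    m = similarity_heatmap(questions, questions, HashingEmbedder())
    assert m.shape == (2, 2)
    assert np.allclose(np.diag(m), 1.0)
    assert np.all((m >= -1 - 1e-9) & (m <= 1 + 1e-9))


def test_heatmap_orthogonal_embeddings_zero_off_diagonal():
    basis = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
    m = similarity_heatmap(["a", "b"], ["a", "b"], basis.get)
    assert m[0, 1] == 0.0 and m[1, 0] == 0.0


def test_heatmap_rejects_empty_lists():
    with pytest.raises(ValueError):
        similarity_heatmap([], ["a ?"], HashingEmbedder())


# -- latent separation ------------------------------------------------------


def test_far_apart_point_clouds_approach_unit_silhouette(rng):
    a = rng.normal(size=(50, 4)) * 0.01
    b = rng.normal(size=(50, 4)) * 0.01 + 100.0
    assert latent_separation_score([a, b]) > 0.99


def test_same_distribution_scores_near_zero(rng):
    a = rng.normal(size=(100, 4))
    b = rng.normal(size=(100, 4))
    assert abs(latent_separation_score([a, b])) < 0.1


def test_separation_requires_two_spaces_with_samples(rng):
    with pytest.raises(ValueError):
        latent_separation_score([rng.normal(size=(5, 2))])
    with pytest.raises(ValueError):
        latent_separation_score([rng.normal(size=(5, 2)), rng.normal(size=(1, 2))])


# -- report -----------------------------------------------------------------


def test_full_report_table_scaling():
    gen = {"a": ["is the lung shown in this image ?",
                 "where is the liver located ?"]}
    refs = {"a": ["is the lung shown in this image ?"]}
    report = evaluate_generated(gen, refs, ["is the lung shown in this image ?"])
    table = report.as_table()
    assert table["BLEU-1"] == pytest.approx(100 * report.bleu_1)
    assert table["Inventiveness"] == pytest.approx(50.0)
    assert -1.0 <= table["Similarity"] <= 1.0
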