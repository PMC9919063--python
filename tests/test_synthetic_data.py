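"""Synthetic dataset generation, IO, ground-truth selection and splitting."""

import json
import logging

import numpy as np
import pytest

from divqg.categories import CATEGORIES
from divqg.evaluation import HashingEmbedder
from divqg.synthetic_data import (
    TABLE1_WEIGHTS,
    SyntheticSpec,
    VqgDataset,
    VqgExample,
    classify_question,
    generate_dataset,
    load_dataset,
    save_dataset,
    select_ground_truth,
    split_dataset,
    verify_question,
)

from conftest import exhaustive_min_similarity_subset


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def test_category_proportions_follow_weights():
    """Question categories follow the emulated corpus tallies within 3 sigma."""
    ds = generate_dataset(
        SyntheticSpec(n_images=100, seed=1, category_weights=TABLE1_WEIGHTS)
    )
    total = ds.n_questions
    probs = np.asarray(TABLE1_WEIGHTS) / sum(TABLE1_WEIGHTS)
    for cat, p in zip(CATEGORIES, probs):
        observed = ds.category_counts[cat] / total
        sigma = np.sqrt(p * (1 - p) / total)
        assert abs(observed - p) <= 3 * sigma, cat


def test_degenerate_weights_yield_single_category():
    weights = tuple(1.0 if c == "Organ" else 0.0 for c in CATEGORIES)
    ds = generate_dataset(SyntheticSpec(n_images=20, seed=3, category_weights=weights))
    assert all(
        c == "Organ" for ex in ds.examples for c in ex.question_categories
    )


def test_same_seed_gives_identical_datasets():
    spec = SyntheticSpec(n_images=15, seed=11, image_size=32)
    a, b = generate_dataset(spec), generate_dataset(spec)
    for ea, eb in zip(a.examples, b.examples):
        assert np.array_equal(ea.image, eb.image)
        assert ea.ground_truth_questions == eb.ground_truth_questions
        assert ea.question_categories == eb.question_categories
        assert ea.category == eb.category and ea.scene == eb.scene


def test_every_question_is_answerable_from_its_scene(tiny_dataset):
    """Template slots must match the drawn attributes of the image's scene."""
    for ex in tiny_dataset.examples:
        for q in ex.ground_truth_questions:
            assert verify_question(q, ex.scene), (ex.image_id, q)


def test_generated_questions_parse_back_to_their_category(tiny_dataset):
    for ex in tiny_dataset.examples:
        for q, c in zip(ex.ground_truth_questions, ex.question_categories):
            assert classify_question(q) == c


def test_category_counts_sum_to_question_total(tiny_dataset):
    assert sum(tiny_dataset.category_counts.values()) == tiny_dataset.n_questions


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(n_images=0)
    with pytest.raises(ValueError):
        SyntheticSpec(n_images=5, category_weights=(0, 0, 0, 0, 0, 0))
    with pytest.raises(ValueError):
        SyntheticSpec(n_images=5, category_weights=(1, 1, 1, 1, 1, -1))
    with pytest.raises(ValueError):
        SyntheticSpec(n_images=5, noise_sd=-2.0)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def test_save_load_round_trip(tiny_dataset, tmp_path):
    save_dataset(tiny_dataset, tmp_path)
    loaded = load_dataset(tmp_path / "questions.json")
    assert len(loaded) == len(tiny_dataset)
    orig = {ex.image_id: ex for ex in tiny_dataset.examples}
    for ex in loaded.examples:
        src = orig[ex.image_id.removesuffix(".png")]
        assert ex.ground_truth_questions == src.ground_truth_questions
        assert ex.question_categories == src.question_categories
        assert ex.scene == src.scene
        assert np.array_equal(ex.image, src.image)


def test_load_groups_records_by_image(tmp_path):
    from PIL import Image

    Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(tmp_path / "a.png")
    records = [
        {"img_name": "a.png", "question": "is the lung shown in this image ?",
         "content_type": "Organ"},
        {"img_name": "a.png", "question": "in what plane is this image scanned ?",
         "content_type": "Plane"},
    ]
    (tmp_path / "d.json").write_text(json.dumps(records))
    ds = load_dataset(tmp_path / "d.json")
    assert len(ds) == 1
    assert len(ds.examples[0].ground_truth_questions) == 2


def test_load_empty_array_gives_empty_dataset(tmp_path):
    (tmp_path / "d.json").write_text("[]")
    assert len(load_dataset(tmp_path / "d.json")) == 0


def test_unknown_category_maps_to_others_with_warning(tmp_path, caplog):
    from PIL import Image

    Image.fromarray(np.zeros((8, 8), dtype=np.uint8)).save(tmp_path / "a.png")
    records = [{"img_name": "a.png", "question": "what shape is this ?",
                "content_type": "Shape"}]
    (tmp_path / "d.json").write_text(json.dumps(records))
    with caplog.at_level(logging.WARNING):
        ds = load_dataset(tmp_path / "d.json")
    assert ds.examples[0].question_categories == ["Others"]
    assert any("Shape" in rec.message for rec in caplog.records)


def test_missing_image_raises_naming_the_file(tmp_path):
    records = [{"img_name": "ghost.png", "question": "is the lung shown ?",
                "content_type": "Organ"}]
    (tmp_path / "d.json").write_text(json.dumps(records))
    with pytest.raises(FileNotFoundError, match="ghost.png"):
        load_dataset(tmp_path / "d.json")


def test_malformed_record_raises_with_index(tmp_path):
    records = [{"img_name": "a.png", "question": "q ?", "content_type": "Organ"},
               {"question": "no image field ?"}]
    (tmp_path / "d.json").write_text(json.dumps(records))
    with pytest.raises(ValueError, match="index 1"):
        load_dataset(tmp_path / "d.json")


# ---------------------------------------------------------------------------
# ground-truth selection
# ---------------------------------------------------------------------------


class _TableEmbedder:
    """Fixed unit-norm embeddings with prescribed pairwise inner products."""

    def __init__(self, table):
        self.table = table

    def __call__(self, text):
        return self.table[text]


def test_identical_questions_tie_break_by_input_order():
    q = [("is the lung shown in this image ?", "Organ")] * 3
    out = select_ground_truth(q, "Organ", HashingEmbedder(), k=2)
    assert out == [q[0][0], q[1][0]]


def test_least_similar_pair_selected():
    """Pairwise sims {(a,b):0.9,(a,c):0.1,(b,c):0.1} with k=2 -> {a,c}."""
    # unit vectors realizing the prescribed inner products
    a = np.array([1.0, 0.0, 0.0])
    b = np.array([0.9, np.sqrt(1 - 0.81), 0.0])
    x = 0.1
    y = (0.1 - 0.9 * x) / np.sqrt(1 - 0.81)
    c = np.array([x, y, np.sqrt(1 - x * x - y * y)])
    emb = _TableEmbedder({"a": a, "b": b, "c": c})
    assert np.isclose(a @ b, 0.9) and np.isclose(a @ c, 0.1) and np.isclose(b @ c, 0.1)
    out = select_ground_truth(
        [("a", "Organ"), ("b", "Organ"), ("c", "Organ")], "Organ", emb, k=2
    )
    assert out == ["a", "c"]


def test_single_match_returned_for_large_k():
    q = [("is the lung shown in this image ?", "Organ"), ("where is it ?", "Position")]
    assert select_ground_truth(q, "Organ", HashingEmbedder(), k=3) == [q[0][0]]


def test_no_match_returns_empty():
    q = [("where is the liver located ?", "Position")]
    assert select_ground_truth(q, "Organ", HashingEmbedder(), k=2) == []


@pytest.mark.parametrize("seed", range(5))
def test_greedy_selection_near_exhaustive_optimum(seed, tiny_dataset):
    """For <= 6 candidates the greedy mean similarity is within 10% of optimal."""
    rng = np.random.default_rng(seed)
    pool = [
        q for ex in tiny_dataset.examples for q in ex.ground_truth_questions
    ]
    texts = list(dict.fromkeys(pool))
    rng.shuffle(texts)
    cands = texts[:6]
    k = 3
    embedder = HashingEmbedder()
    chosen = select_ground_truth([(t, "Organ") for t in cands], "Organ", embedder, k)
    emb = np.stack([embedder(t) for t in chosen])
    sims = emb @ emb.T
    iu = np.triu_indices(k, 1)
    greedy_val = sims[iu].mean()
    opt = exhaustive_min_similarity_subset(
        np.stack([embedder(t) for t in cands]), k
    )
    assert greedy_val <= opt * 1.1 + 1e-12


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _stub_dataset(n):
    img = np.zeros((4, 4), dtype=np.uint8)
    return VqgDataset(
        [
            VqgExample(
                image=img,
                category="Others",
                ground_truth_questions=["how many organs can be seen in this image ?"],
                image_id=f"im-{i}",
            )
            for i in range(n)
        ]
    )


def test_split_sizes_for_the_published_corpus_size():
    """956 images with a 100-image test holdout and a 5:1 split -> 713/143."""
    train, val, test = split_dataset(_stub_dataset(956), 100, (5, 1), seed=0)
    assert (len(train), len(val), len(test)) == (713, 143, 100)


def test_split_floor_arithmetic_tiny_case():
    train, val, test = split_dataset(_stub_dataset(2), 1, (5, 1), seed=0)
    assert (len(train), len(val), len(test)) == (0, 1, 1)


def test_split_partition_is_disjoint_and_exhaustive():
    ds = _stub_dataset(57)
    train, val, test = split_dataset(ds, 10, (5, 1), seed=5)
    ids = lambda d: {ex.image_id for ex in d.examples}
    assert ids(train) | ids(val) | ids(test) == ids(ds)
    assert not (ids(train) & ids(val)) and not (ids(train) & ids(test))
    assert not (ids(val) & ids(test))


def test_split_deterministic_given_seed():
    ds = _stub_dataset(40)
    a = split_dataset(ds, 8, (5, 1), seed=9)
    b = split_dataset(ds, 8, (5, 1), seed=9)
    for da, db in zip(a, b):
        assert [e.image_id for e in da.examples] == [e.image_id for e in db.examples]


def test_split_rejects_oversized_test_set():
    with pytest.raises(ValueError):
        split_dataset(_stub_dataset(5), 5, (5, 1), seed=0)
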