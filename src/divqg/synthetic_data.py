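"""Desk-scale synthetic image/question datasets for visual question generation.

Each synthetic example is a pseudo-radiograph rendered from a small
scene description — a modality-dependent background, a plane marker, a
handful of organ blobs at anatomically loose canonical positions, and
an optional bright abnormality — paired with templated questions whose
slots are filled from the very attributes that were drawn.  Every
question is therefore answerable from its image by construction, and a
template grammar (:func:`classify_question`) can recover the category
of any generated question, which is what the category-control property
of the trained model is scored against.

The module also reads real-format datasets (a JSON array of
``img_name`` / ``question`` / ``content_type`` records, the public
Slake schema), performs lowest-similarity ground-truth selection, and
splits datasets into train/validation/test partitions.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .categories import CATEGORIES, normalize_category
from .question_decoder import tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "VqgExample",
    "VqgDataset",
    "SyntheticSpec",
    "generate_dataset",
    "load_dataset",
    "save_dataset",
    "select_ground_truth",
    "split_dataset",
    "classify_question",
    "verify_question",
    "TABLE1_WEIGHTS",
]

# Per-category question tallies of the combined radiology QA corpus the
# generator emulates (Abnormality, Modality, Organ, Plane, Position, Others).
TABLE1_WEIGHTS: tuple[float, ...] = (312, 290, 290, 484, 742, 1772)

MODALITIES = ("xray", "ct", "mri")
PLANES = ("axial", "coronal", "sagittal")
_MODALITY_LEVEL = {"xray": 30, "ct": 70, "mri": 120}
_PLANE_CORNER = {"axial": (0, 0), "coronal": (0, 1), "sagittal": (1, 0)}

# organ name -> (cy, cx, ry, rx) as canvas fractions, intensity
_ORGAN_TABLE = {
    "lung": (0.35, 0.30, 0.18, 0.12, 80),
    "heart": (0.45, 0.62, 0.13, 0.12, 115),
    "liver": (0.65, 0.35, 0.12, 0.16, 95),
    "kidney": (0.72, 0.65, 0.08, 0.07, 140),
    "spleen": (0.55, 0.82, 0.07, 0.06, 160),
}
DEFAULT_ORGAN_PALETTE = tuple(_ORGAN_TABLE)


@dataclass
class VqgExample:
    """One image with its conditioning category and ground-truth questions."""

    image: np.ndarray
    category: str
    ground_truth_questions: list[str]
    image_id: str
    question_categories: list[str] | None = None
    scene: dict | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.ground_truth_questions:
            raise ValueError("ground_truth_questions must be non-empty")
        for q in self.ground_truth_questions:
            if not tokenize(q):
                raise ValueError(f"question {q!r} is empty after tokenization")

    def questions_of_category(self, category: str | None = None) -> list[str]:
        """Questions whose category matches (defaults to the example's own)."""
        category = category or self.category
        if self.question_categories is None:
            return list(self.ground_truth_questions)
        return [
            q
            for q, c in zip(self.ground_truth_questions, self.question_categories)
            if c == category
        ]


@dataclass
class VqgDataset:
    examples: list[VqgExample]
    category_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.category_counts:
            self.category_counts = _tally(self.examples)
        ids = [ex.image_id for ex in self.examples]
        if len(set(ids)) != len(ids):
            raise ValueError("image_id values must be unique")

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def n_questions(self) -> int:
        return sum(len(ex.ground_truth_questions) for ex in self.examples)


def _tally(examples) -> dict[str, int]:
    counts: Counter = Counter()
    for ex in examples:
        cats = ex.question_categories or [ex.category] * len(ex.ground_truth_questions)
        counts.update(cats)
    return {c: counts.get(c, 0) for c in CATEGORIES}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dataset generator."""

    n_images: int
    category_weights: tuple = TABLE1_WEIGHTS
    organ_palette: tuple = DEFAULT_ORGAN_PALETTE
    noise_sd: float = 8.0
    seed: int = 0
    image_size: int = 64
    questions_per_image: tuple = (3, 5)

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        w = np.asarray(self.category_weights, dtype=np.float64)
        if w.shape != (len(CATEGORIES),) or np.any(w < 0) or w.sum() == 0:
            raise ValueError(
                "category_weights must be six non-negative reals, not all zero"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        unknown = [o for o in self.organ_palette if o not in _ORGAN_TABLE]
        if unknown:
            raise ValueError(f"unknown organs in palette: {unknown}")


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _draw_scene(spec: SyntheticSpec, rng: np.random.Generator) -> dict:
    organs_n = int(rng.integers(2, min(4, len(spec.organ_palette)) + 1))
    names = list(rng.choice(spec.organ_palette, size=organs_n, replace=False))
    organs = []
    for name in names:
        cy, cx, ry, rx, level = _ORGAN_TABLE[name]
        cy = float(np.clip(cy + rng.uniform(-0.05, 0.05), 0.15, 0.85))
        cx = float(np.clip(cx + rng.uniform(-0.05, 0.05), 0.15, 0.85))
        organs.append(
            {
                "name": str(name),
                "cy": cy,
                "cx": cx,
                "ry": ry,
                "rx": rx,
                "level": level,
                "side_h": "left" if cx < 0.5 else "right",
                "side_v": "upper" if cy < 0.5 else "lower",
            }
        )
    abnormal = bool(rng.random() < 0.35)
    abnormal_organ = str(rng.choice(names)) if abnormal else None
    return {
        "modality": str(rng.choice(MODALITIES)),
        "plane": str(rng.choice(PLANES)),
        "organs": organs,
        "abnormal": abnormal,
        "abnormal_organ": abnormal_organ,
    }


def _render_scene(scene: dict, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    canvas = np.full((size, size), _MODALITY_LEVEL[scene["modality"]], dtype=np.float64)
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=(size, size))
    yy, xx = np.mgrid[0:size, 0:size] / size
    for organ in scene["organs"]:
        mask = ((yy - organ["cy"]) / organ["ry"]) ** 2 + (
            (xx - organ["cx"]) / organ["rx"]
        ) ** 2 <= 1.0
        canvas[mask] = organ["level"]
    if scene["abnormal"]:
        target = next(o for o in scene["organs"] if o["name"] == scene["abnormal_organ"])
        mask = ((yy - target["cy"]) / 0.04) ** 2 + ((xx - target["cx"]) / 0.04) ** 2 <= 1.0
        canvas[mask] = 235
    cy, cx = _PLANE_CORNER[scene["plane"]]
    marker = 5
    ys = slice(0, marker) if cy == 0 else slice(size - marker, size)
    xs = slice(0, marker) if cx == 0 else slice(size - marker, size)
    canvas[ys, xs] = 250
    return np.clip(canvas, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# question templates and the category grammar
# ---------------------------------------------------------------------------

def _make_question(category: str, scene: dict, rng: np.random.Generator) -> str:
    organ = scene["organs"][int(rng.integers(len(scene["organs"])))]
    variant = int(rng.integers(2))
    if category == "Organ":
        return (
            f"does the picture contain the {organ['name']} ?"
            if variant == 0
            else f"is the {organ['name']} shown in this image ?"
        )
    if category == "Modality":
        return (
            "what modality was used to take this image ?"
            if variant == 0
            else f"is this image taken by {scene['modality']} ?"
        )
    if category == "Plane":
        return (
            "in what plane is this image scanned ?"
            if variant == 0
            else f"is this image scanned in the {scene['plane']} plane ?"
        )
    if category == "Abnormality":
        if scene["abnormal"] and variant == 0:
            return f"does the {scene['abnormal_organ']} look abnormal ?"
        return "is there something abnormal in this image ?"
    if category == "Position":
        if variant == 0:
            return f"where is the {organ['name']} located ?"
        side = organ["side_h"] if rng.integers(2) == 0 else organ["side_v"]
        return f"is the {organ['name']} on the {side} side ?"
    if category == "Others":
        return (
            "how many organs can be seen in this image ?"
            if variant == 0
            else "what is the biggest organ in this image ?"
        )
    raise ValueError(f"unknown category {category!r}")


def classify_question(text: str) -> str | None:
    """Recover the category of a templated question; None if unparseable."""
    toks = set(tokenize(text))
    lower = text.lower()
    if "abnormal" in toks:
        return "Abnormality"
    if "modality" in toks or "taken by" in lower:
        return "Modality"
    if "plane" in toks:
        return "Plane"
    if "where" in toks or "located" in toks or "side" in toks:
        return "Position"
    if "many" in toks or "biggest" in toks:
        return "Others"
    if "contain" in toks or "shown" in toks:
        return "Organ"
    return None


def verify_question(text: str, scene: dict) -> bool:
    """Check that every slot of a templated question matches the scene."""
    toks = tokenize(text)
    tokset = set(toks)
    organ_names = {o["name"] for o in scene["organs"]}
    named = [t for t in toks if t in _ORGAN_TABLE]
    if any(t not in organ_names for t in named):
        return False
    for m in MODALITIES:
        if m in tokset and m != scene["modality"]:
            return False
    for p in PLANES:
        if p in tokset and p != scene["plane"]:
            return False
    category = classify_question(text)
    if category == "Abnormality" and named:
        if not scene["abnormal"] or named[0] != scene["abnormal_organ"]:
            return False
    sides = [t for t in toks if t in ("left", "right", "upper", "lower")]
    if sides:
        if not named:
            return False
        organ = next(o for o in scene["organs"] if o["name"] == named[0])
        if sides[0] not in (organ["side_h"], organ["side_v"]):
            return False
    return True


# ---------------------------------------------------------------------------
# generation, IO, selection, splitting
# ---------------------------------------------------------------------------

def generate_dataset(spec: SyntheticSpec) -> VqgDataset:
    """Deterministically generate a synthetic dataset from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.category_weights, dtype=np.float64)
    probs = weights / weights.sum()
    lo, hi = spec.questions_per_image
    examples = []
    for i in range(spec.n_images):
        scene = _draw_scene(spec, rng)
        image = _render_scene(scene, spec, rng)
        m = int(rng.integers(lo, hi + 1))
        cats = [CATEGORIES[j] for j in rng.choice(len(CATEGORIES), size=m, p=probs)]
        questions = [_make_question(c, scene, rng) for c in cats]
        # conditioning category = modal category; ties -> earliest drawn
        counts = Counter(cats)
        top = max(counts.values())
        category = next(c for c in cats if counts[c] == top)
        examples.append(
            VqgExample(
                image=image,
                category=category,
                ground_truth_questions=questions,
                image_id=f"synth-{i:05d}",
                question_categories=cats,
                scene=scene,
            )
        )
    return VqgDataset(examples)


def save_dataset(dataset: VqgDataset, out_dir) -> Path:
    """Write images as PNG plus the JSON record file (and scene sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    scenes = {}
    for ex in dataset.examples:
        fname = f"{ex.image_id}.png"
        Image.fromarray(ex.image).save(out_dir / fname)
        cats = ex.question_categories or [ex.category] * len(ex.ground_truth_questions)
        for q, c in zip(ex.ground_truth_questions, cats):
            records.append({"img_name": fname, "question": q, "content_type": c})
        if ex.scene is not None:
            scenes[fname] = ex.scene
    path = out_dir / "questions.json"
    path.write_text(json.dumps(records, indent=1))
    if scenes:
        (out_dir / "scenes.json").write_text(json.dumps(scenes, indent=1))
    return path


def load_dataset(path) -> VqgDataset:
    """Load a JSON-array dataset (img_name / question / content_type records)."""
    path = Path(path)
    records = json.loads(path.read_text())
    if not isinstance(records, list):
        raise ValueError("dataset file must hold a JSON array of records")
    grouped: dict[str, list[tuple[str, str]]] = {}
    for i, rec in enumerate(records):
        if not isinstance(rec, dict) or not {"img_name", "question", "content_type"} <= set(rec):
            raise ValueError(
                f"malformed record at index {i}: expected img_name, question, content_type"
            )
        category = normalize_category(str(rec["content_type"]))
        if category is None:
            logger.warning(
                "record %d: unknown category %r mapped to Others", i, rec["content_type"]
            )
            category = "Others"
        grouped.setdefault(str(rec["img_name"]), []).append(
            (str(rec["question"]), category)
        )
    scenes = {}
    scene_path = path.parent / "scenes.json"
    if scene_path.exists():
        scenes = json.loads(scene_path.read_text())
    examples = []
    for img_name, pairs in grouped.items():
        img_path = path.parent / img_name
        if not img_path.exists():
            raise FileNotFoundError(f"image file not found: {img_path}")
        image = np.asarray(Image.open(img_path))
        cats = [c for _, c in pairs]
        counts = Counter(cats)
        top = max(counts.values())
        category = next(c for c in cats if counts[c] == top)
        examples.append(
            VqgExample(
                image=image,
                category=category,
                ground_truth_questions=[q for q, _ in pairs],
                image_id=img_name,
                question_categories=cats,
                scene=scenes.get(img_name),
            )
        )
    return VqgDataset(examples)


def select_ground_truth(questions, target_category: str, embedder, k: int) -> list[str]:
    """Up to ``k`` same-category questions greedily minimizing mean similarity.

    ``questions`` is a list of (text, category) pairs; similarity is the
    inner product of unit-norm sentence embeddings.  Returns [] when no
    question has the target category.  Ties break by input order, and
    the result preserves input order.
    """
    if k < 1:
        raise ValueError("k must be positive")
    cands = [(i, text) for i, (text, cat) in enumerate(questions) if cat == target_category]
    if not cands:
        return []
    if len(cands) <= k or k == 1:
        return [text for _, text in cands[: k if k < len(cands) else len(cands)]]
    emb = np.stack([np.asarray(embedder(text), dtype=np.float64) for _, text in cands])
    sims = emb @ emb.T
    m = len(cands)
    # seed with the least-similar pair (lexicographic index tie-break)
    best_pair, best_val = (0, 1), np.inf
    for i in range(m):
        for j in range(i + 1, m):
            if sims[i, j] < best_val - 1e-12:
                best_val = sims[i, j]
                best_pair = (i, j)
    chosen = list(best_pair)
    while len(chosen) < k:
        remaining = [i for i in range(m) if i not in chosen]
        best_idx, best_score = remaining[0], np.inf
        for i in remaining:
            score = sum(sims[i, j] for j in chosen)
            if score < best_score - 1e-12:
                best_score = score
                best_idx = i
        chosen.append(best_idx)
    chosen.sort()
    return [cands[i][1] for i in chosen]


def split_dataset(dataset: VqgDataset, n_test: int, train_val_ratio=(5, 1),
                  seed: int = 0):
    """Uniform test holdout, then an a:b train/validation split of the rest.

    The train partition gets ``floor(remainder * a / (a + b))`` images.
    Partitions are disjoint and exhaustive, deterministic given the seed.
    """
    N = len(dataset)
    if not 0 <= n_test < N:
        raise ValueError(f"n_test must lie in [0, {N})")
    a, b = train_val_ratio
    if a <= 0 or b <= 0:
        raise ValueError("ratio parts must be positive")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    test_idx = sorted(perm[:n_test])
    rest = perm[n_test:]
    n_train = int(np.floor(len(rest) * a / (a + b)))
    train_idx = sorted(rest[:n_train])
    val_idx = sorted(rest[n_train:])
    make = lambda idx: VqgDataset([dataset.examples[i] for i in idx])
    return make(train_idx), make(val_idx), make(test_idx)
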