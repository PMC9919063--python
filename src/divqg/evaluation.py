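"""Evaluation metrics for generated question sets.

Language-modeling metrics (BLEU-1..4, METEOR, ROUGE-L, CIDEr) measure
word-level agreement with the ground truth; the diversity metrics are
Inventiveness — the percentage of generated questions that appear
nowhere in the training ground truth — and Similarity, the mean inner
product of unit-norm sentence embeddings over all question pairs of an
image, averaged over images (lower = more diverse / informative).

The default sentence embedder is an offline character-3-gram hashing
bag vector, deterministic and dependency-free.  External semantic
encoders (e.g. a universal sentence encoder) can be registered behind
the same unit-norm callable contract and will change the Similarity
values but none of its invariants.

METEOR here is the exact-unigram-match variant (no stemming or synonym
resources): harmonic mean weighted toward recall with the standard
fragmentation penalty.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score

from .question_decoder import tokenize

__all__ = [
    "HashingEmbedder",
    "register_embedder",
    "get_embedder",
    "MetricReport",
    "compute_language_metrics",
    "inventiveness",
    "similarity_score",
    "corpus_similarity",
    "similarity_heatmap",
    "latent_separation_score",
    "evaluate_generated",
]


# ---------------------------------------------------------------------------
# sentence embedders
# ---------------------------------------------------------------------------


class HashingEmbedder:
    """Character-3-gram hashed bag vector, L2-normalized.

    Deterministic across processes (md5-based hashing).  Satisfies the
    embedder contract: text -> unit-norm vector of fixed dimension.
    """

    def __init__(self, dim: int = 256):
        self.dim = dim

    def __call__(self, text: str) -> np.ndarray:
        padded = f" {text.strip().lower()} "
        vec = np.zeros(self.dim)
        for i in range(max(len(padded) - 2, 0)):
            gram = padded[i : i + 3]
            digest = hashlib.md5(gram.encode("utf8")).hexdigest()
            vec[int(digest, 16) % self.dim] += 1.0
        norm = np.linalg.norm(vec)
        if norm == 0:
            vec[0] = 1.0
            return vec
        return vec / norm


_EMBEDDERS = {"hash": HashingEmbedder}


def register_embedder(name: str, factory) -> None:
    """Register an embedder factory (e.g. an external semantic encoder)."""
    _EMBEDDERS[name] = factory


def get_embedder(name: str = "hash"):
    if name not in _EMBEDDERS:
        raise ValueError(f"unknown embedder {name!r}; available: {sorted(_EMBEDDERS)}")
    return _EMBEDDERS[name]()


# ---------------------------------------------------------------------------
# language-modeling metrics
# ---------------------------------------------------------------------------


def _ngram_counts(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _check_alignment(generated: dict, references: dict) -> list[str]:
    missing = sorted(set(references) - set(generated))
    extra = sorted(set(generated) - set(references))
    if missing or extra:
        raise ValueError(
            f"generated/reference image keys differ; missing={missing} extra={extra}"
        )
    keys = sorted(generated)
    if not keys:
        raise ValueError("no images to evaluate")
    for key in keys:
        if not references[key]:
            raise ValueError(f"image {key!r} has no reference questions")
    return keys


def _corpus_bleu(pairs, max_n: int = 4) -> list[float]:
    """Corpus BLEU-1..max_n with clipped precision and brevity penalty."""
    clipped = np.zeros(max_n)
    totals = np.zeros(max_n)
    cand_len = 0
    eff_ref_len = 0
    for cand, refs in pairs:
        cand_len += len(cand)
        # closest reference length (ties -> shorter)
        eff_ref_len += min((abs(len(r) - len(cand)), len(r)) for r in refs)[1]
        for n in range(1, max_n + 1):
            counts = _ngram_counts(cand, n)
            max_ref = Counter()
            for ref in refs:
                for gram, c in _ngram_counts(ref, n).items():
                    max_ref[gram] = max(max_ref[gram], c)
            totals[n - 1] += sum(counts.values())
            clipped[n - 1] += sum(min(c, max_ref[g]) for g, c in counts.items())
    with np.errstate(divide="ignore", invalid="ignore"):
        precisions = np.where(totals > 0, clipped / np.maximum(totals, 1), 0.0)
    bp = 1.0 if cand_len > eff_ref_len else np.exp(1.0 - eff_ref_len / max(cand_len, 1))
    scores = []
    for n in range(1, max_n + 1):
        p = precisions[:n]
        if np.any(p == 0):
            scores.append(0.0)
        else:
            scores.append(float(bp * np.exp(np.mean(np.log(p)))))
    return scores


def _lcs_len(a: list[str], b: list[str]) -> int:
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int64)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            dp[i + 1, j + 1] = dp[i, j] + 1 if x == y else max(dp[i, j + 1], dp[i + 1, j])
    return int(dp[len(a), len(b)])


def _rouge_l(cand: list[str], refs: list[list[str]], beta: float = 1.2) -> float:
    best = 0.0
    for ref in refs:
        lcs = _lcs_len(cand, ref)
        if lcs == 0:
            continue
        prec = lcs / len(cand)
        rec = lcs / len(ref)
        score = (1 + beta**2) * prec * rec / (rec + beta**2 * prec)
        best = max(best, score)
    return best


def _meteor_single(cand: list[str], ref: list[str]) -> float:
    # leftmost exact-match alignment
    used = [False] * len(ref)
    pairs = []
    for ci, tok in enumerate(cand):
        for ri, rtok in enumerate(ref):
            if not used[ri] and rtok == tok:
                used[ri] = True
                pairs.append((ci, ri))
                break
    m = len(pairs)
    if m == 0:
        return 0.0
    chunks = 1
    for (pc, pr), (cc, cr) in zip(pairs[:-1], pairs[1:]):
        if cc != pc + 1 or cr != pr + 1:
            chunks += 1
    prec = m / len(cand)
    rec = m / len(ref)
    fmean = 10 * prec * rec / (rec + 9 * prec)
    penalty = 0.5 * (chunks / m) ** 3
    return fmean * (1 - penalty)


def _cider(pairs, n_max: int = 4, d_variant: bool = False, sigma: float = 6.0) -> float:
    """Consensus tf-idf n-gram cosine; the D variant clips counts and adds
    a Gaussian length penalty."""
    n_docs = len(pairs)
    df = [Counter() for _ in range(n_max)]
    for _, refs in pairs:
        for n in range(1, n_max + 1):
            grams = set()
            for ref in refs:
                grams.update(_ngram_counts(ref, n))
            for g in grams:
                df[n - 1][g] += 1

    def tfidf(tokens, n):
        counts = _ngram_counts(tokens, n)
        return {
            g: c * np.log(max(n_docs, 2) / max(df[n - 1][g], 1))
            for g, c in counts.items()
        }

    scores = []
    for cand, refs in pairs:
        per_n = []
        for n in range(1, n_max + 1):
            cvec = tfidf(cand, n)
            cnorm = np.sqrt(sum(v * v for v in cvec.values()))
            sim_total = 0.0
            for ref in refs:
                rvec = tfidf(ref, n)
                rnorm = np.sqrt(sum(v * v for v in rvec.values()))
                if cnorm == 0 or rnorm == 0:
                    continue
                if d_variant:
                    dot = sum(min(cv, rvec.get(g, 0.0)) * rvec.get(g, 0.0)
                              for g, cv in cvec.items())
                    dot *= np.exp(-((len(cand) - len(ref)) ** 2) / (2 * sigma**2))
                else:
                    dot = sum(cv * rvec.get(g, 0.0) for g, cv in cvec.items())
                sim_total += dot / (cnorm * rnorm)
            per_n.append(sim_total / len(refs))
        scores.append(10.0 * np.mean(per_n))
    return float(np.mean(scores))


def compute_language_metrics(generated: dict, references: dict,
                             cider_d: bool = False) -> dict:
    """BLEU-1..4, METEOR, ROUGE-L and CIDEr at the corpus level.

    ``generated``/``references`` map image keys to question lists; every
    generated question of an image is scored against that image's
    references.  Values are on the [0, 1] scale except CIDEr ([0, 10]).
    """
    keys = _check_alignment(generated, references)
    pairs = []
    for key in keys:
        refs = [tokenize(r) for r in references[key]]
        for g in generated[key]:
            cand = tokenize(g)
            if cand:
                pairs.append((cand, refs))
    if not pairs:
        raise ValueError("no non-empty generated questions to evaluate")
    bleu = _corpus_bleu(pairs)
    rouge = float(np.mean([_rouge_l(c, r) for c, r in pairs]))
    meteor = float(np.mean([max(_meteor_single(c, ref) for ref in r) for c, r in pairs]))
    cider = _cider(pairs, d_variant=cider_d)
    return {
        "bleu_1": bleu[0],
        "bleu_2": bleu[1],
        "bleu_3": bleu[2],
        "bleu_4": bleu[3],
        "meteor": meteor,
        "rouge_l": rouge,
        "cider": cider,
    }


# ---------------------------------------------------------------------------
# diversity metrics
# ---------------------------------------------------------------------------


def inventiveness(generated, training_ground_truth) -> float:
    """Percentage of generated questions appearing nowhere in the training
    ground truth (exact match on normalized token sequences)."""
    generated = list(generated)
    if not generated:
        return float("nan")
    seen = {tuple(tokenize(q)) for q in training_ground_truth}
    novel = sum(tuple(tokenize(q)) not in seen for q in generated)
    return 100.0 * novel / len(generated)


def similarity_score(question_set, embedder) -> float:
    """Mean pairwise embedding inner product within one question set."""
    questions = list(question_set)
    if len(questions) < 2:
        raise ValueError("a per-image similarity needs at least 2 questions")
    emb = np.stack([np.asarray(embedder(q), dtype=np.float64) for q in questions])
    sims = emb @ emb.T
    iu = np.triu_indices(len(questions), k=1)
    return float(sims[iu].mean())


def corpus_similarity(generated: dict, embedder) -> float:
    """Mean per-image similarity over images with >= 2 generated questions.

    NaN (undefined) when no image has at least two questions.
    """
    scores = [
        similarity_score(qs, embedder) for qs in generated.values() if len(qs) >= 2
    ]
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def similarity_heatmap(generated, ground_truth, embedder) -> np.ndarray:
    """|generated| x |ground truth| matrix of embedding inner products."""
    generated, ground_truth = list(generated), list(ground_truth)
    if not generated or not ground_truth:
        raise ValueError("both question lists must be non-empty")
    ge = np.stack([np.asarray(embedder(q), dtype=np.float64) for q in generated])
    re_ = np.stack([np.asarray(embedder(q), dtype=np.float64) for q in ground_truth])
    return ge @ re_.T


def latent_separation_score(samples_by_space) -> float:
    """Mean silhouette coefficient of latent samples labeled by space index.

    ``samples_by_space``: list over K spaces of (n_k, d_z) arrays.  A
    score near 1 means the spaces occupy well-separated regions; near 0
    means they overlap.
    """
    arrays = [np.asarray(s, dtype=np.float64) for s in samples_by_space]
    if len(arrays) < 2:
        raise ValueError("need at least 2 latent spaces")
    if any(a.ndim != 2 or len(a) < 2 for a in arrays):
        raise ValueError("each space needs at least 2 samples of shape (n, d_z)")
    X = np.concatenate(arrays, axis=0)
    labels = np.concatenate([np.full(len(a), k) for k, a in enumerate(arrays)])
    return float(silhouette_score(X, labels, metric="euclidean"))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    bleu_1: float
    bleu_2: float
    bleu_3: float
    bleu_4: float
    meteor: float
    rouge_l: float
    cider: float
    inventiveness: float
    similarity: float

    def as_table(self) -> dict:
        """Table-style scaling: language metrics x100, similarity raw."""
        return {
            "BLEU-1": 100 * self.bleu_1,
            "BLEU-2": 100 * self.bleu_2,
            "BLEU-3": 100 * self.bleu_3,
            "BLEU-4": 100 * self.bleu_4,
            "METEOR": 100 * self.meteor,
            "ROUGE-L": 100 * self.rouge_l,
            "CIDEr": 100 * self.cider / 10.0,
            "Inventiveness": self.inventiveness,
            "Similarity": self.similarity,
        }


def evaluate_generated(generated: dict, references: dict, training_questions,
                       embedder=None, cider_d: bool = False) -> MetricReport:
    """Full metric report for generated question sets."""
    embedder = embedder or HashingEmbedder()
    lang = compute_language_metrics(generated, references, cider_d=cider_d)
    all_generated = [q for qs in generated.values() for q in qs]
    return MetricReport(
        **lang,
        inventiveness=inventiveness(all_generated, training_questions),
        similarity=corpus_similarity(generated, embedder),
    )
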