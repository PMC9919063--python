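"""Question-set decoding from latent samples with a shared LSTM.

One LSTM decodes every latent space's sample independently: a learned
linear map projects the sample onto the initial hidden and cell states
of all layers, decoding starts from BOS, and the K decoded sequences
form the question set.  Diversity between the K questions must come
from the latents, not from per-space decoders.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .nn import LSTM, Embedding, Linear, Module, Tensor, stack

__all__ = [
    "tokenize",
    "detokenize",
    "Vocabulary",
    "DecoderConfig",
    "QuestionDecoder",
    "decode_question_set",
    "generation_loss",
    "masked_sequence_nll",
]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Lowercased word/punctuation tokens; empty text gives an empty list."""
    return _TOKEN_RE.findall(text.lower())


def detokenize(tokens) -> str:
    return " ".join(tokens)


class Vocabulary:
    """Token-index map with PAD/BOS/EOS/UNK specials at fixed positions."""

    PAD, BOS, EOS, UNK = 0, 1, 2, 3
    SPECIALS = ("<pad>", "<bos>", "<eos>", "<unk>")

    def __init__(self, tokens: list[str]):
        self.index = {tok: i for i, tok in enumerate(self.SPECIALS)}
        for tok in tokens:
            if tok not in self.index:
                self.index[tok] = len(self.index)
        self.tokens = [t for t, _ in sorted(self.index.items(), key=lambda kv: kv[1])]

    @classmethod
    def build(cls, texts) -> "Vocabulary":
        """Build from training texts: tokens ordered by frequency then alphabet."""
        counts = Counter(tok for text in texts for tok in tokenize(text))
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
        return cls(ordered)

    @property
    def size(self) -> int:
        return len(self.index)

    def encode(self, text: str, add_specials: bool = True) -> list[int]:
        ids = [self.index.get(tok, self.UNK) for tok in tokenize(text)]
        if add_specials:
            ids = [self.BOS] + ids + [self.EOS]
        return ids

    def decode(self, ids) -> str:
        words = []
        for i in ids:
            if i == self.EOS:
                break
            if i in (self.PAD, self.BOS):
                continue
            words.append(self.tokens[int(i)])
        return detokenize(words)

    def to_json(self) -> str:
        return json.dumps(self.tokens[len(self.SPECIALS):])

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        return cls(json.loads(payload))


@dataclass
class DecoderConfig:
    layers: int = 3
    hidden: int = 256
    max_len: int = 20
    decoding: str = "greedy"  # or "sampled"
    token_embedding_dim: int | None = None

    def __post_init__(self):
        if self.layers <= 0 or self.hidden <= 0:
            raise ValueError("layers and hidden must be positive")
        if self.decoding not in ("greedy", "sampled"):
            raise ValueError(f"unknown decoding mode {self.decoding!r}")
        if self.token_embedding_dim is None:
            self.token_embedding_dim = self.hidden


class QuestionDecoder(Module):
    """Shared conditional LSTM language model over the question vocabulary."""

    def __init__(self, vocab_size: int, d_z: int, config: DecoderConfig,
                 rng: np.random.Generator):
        self.config = config
        self.embedding = Embedding(vocab_size, config.token_embedding_dim, rng)
        self.state_proj = Linear(d_z, config.layers * 2 * config.hidden, rng)
        self.lstm = LSTM(config.token_embedding_dim, config.hidden, config.layers, rng)
        self.out = Linear(config.hidden, vocab_size, rng)
        self.vocab_size = vocab_size

    def initial_states(self, s: Tensor) -> list:
        """Project a latent sample batch (B, d_z) to per-layer (h, c) states."""
        cfg = self.config
        flat = self.state_proj(s).tanh()
        states = []
        for layer in range(cfg.layers):
            off = layer * 2 * cfg.hidden
            h = flat[:, off : off + cfg.hidden]
            c = flat[:, off + cfg.hidden : off + 2 * cfg.hidden]
            states.append((h, c))
        return states

    def teacher_forcing_logits(self, s: Tensor, tokens: np.ndarray) -> Tensor:
        """Logits for predicting tokens[:, 1:] from ground-truth prefixes.

        ``tokens``: (B, L) int ids starting with BOS.  Returns (B, L-1, V).
        """
        states = self.initial_states(s)
        steps = []
        for t in range(tokens.shape[1] - 1):
            emb = self.embedding(tokens[:, t])
            h, states = self.lstm.step(emb, states)
            steps.append(self.out(h))
        return stack(steps, axis=1)

    def greedy_decode(self, s: Tensor, max_len: int | None = None,
                      rng: np.random.Generator | None = None,
                      sampled: bool = False) -> list[list[int]]:
        """Decode one sequence per row of ``s``; deterministic unless sampled."""
        if sampled and rng is None:
            raise ValueError("sampled decoding requires a random generator")
        max_len = max_len or self.config.max_len
        B = s.data.shape[0]
        states = self.initial_states(s)
        current = np.full(B, Vocabulary.BOS, dtype=np.int64)
        seqs: list[list[int]] = [[Vocabulary.BOS] for _ in range(B)]
        done = np.zeros(B, dtype=bool)
        for _ in range(max_len):
            emb = self.embedding(current)
            h, states = self.lstm.step(emb, states)
            logits = self.out(h).data
            if sampled:
                z = logits - logits.max(axis=1, keepdims=True)
                p = np.exp(z)
                p /= p.sum(axis=1, keepdims=True)
                nxt = np.array([rng.choice(len(row), p=row) for row in p])
            else:
                nxt = logits.argmax(axis=1)
            for b in range(B):
                if not done[b]:
                    seqs[b].append(int(nxt[b]))
                    if nxt[b] == Vocabulary.EOS:
                        done[b] = True
            current = np.where(done, Vocabulary.EOS, nxt)
            if done.all():
                break
        return seqs


def decode_question_set(samples, decoder: QuestionDecoder,
                        config: DecoderConfig | None = None,
                        rng: np.random.Generator | None = None) -> list[list[int]]:
    """Decode the K latent samples of one example into K token sequences."""
    config = config or decoder.config
    arr = samples.data if isinstance(samples, Tensor) else np.asarray(samples, float)
    if arr.ndim != 2:
        raise ValueError("expected (K, d_z) latent samples")
    return decoder.greedy_decode(
        Tensor(arr), max_len=config.max_len, rng=rng,
        sampled=(config.decoding == "sampled"),
    )


def masked_sequence_nll(logits: Tensor, targets: np.ndarray,
                        mask: np.ndarray) -> Tensor:
    """Per-sequence token-mean negative log-likelihood, shape (B,).

    ``logits``: (B, L, V); ``targets``: (B, L) ids; ``mask``: (B, L) with 0
    at PAD positions.
    """
    B, L, V = logits.data.shape
    onehot = np.zeros((B, L, V))
    onehot[np.arange(B)[:, None], np.arange(L)[None, :], targets] = 1.0
    logp = logits.log_softmax(axis=-1)
    nll = -(logp * Tensor(onehot)).sum(axis=-1)  # (B, L)
    masked = nll * Tensor(mask)
    return masked.sum(axis=1) * Tensor(1.0 / np.maximum(mask.sum(axis=1), 1.0))


def generation_loss(step_distributions, ground_truth, pad_index: int | None = None) -> float:
    """Cross-entropy generation loss summed over the K spaces.

    ``step_distributions``: iterable over K of (L, V) row-stochastic arrays
    of predicted next-token distributions under teacher forcing.
    ``ground_truth``: iterable over K of token-id sequences of length L.
    PAD positions (``pad_index``) are masked out of the token mean.
    """
    total = 0.0
    dists = list(step_distributions)
    truths = list(ground_truth)
    if len(dists) != len(truths):
        raise ValueError("need one distribution sequence per ground-truth sequence")
    for probs, targets in zip(dists, truths):
        probs = np.asarray(probs, dtype=np.float64)
        targets = np.asarray(targets, dtype=np.int64)
        if probs.ndim != 2 or probs.shape[0] != len(targets):
            raise ValueError("distribution/target length mismatch")
        keep = np.ones(len(targets), dtype=bool)
        if pad_index is not None:
            keep = targets != pad_index
        if not keep.any():
            continue
        p = probs[np.arange(len(targets)), targets][keep]
        if np.any(p <= 0):
            raise ValueError("ground-truth token has zero predicted probability")
        total += float(-np.mean(np.log(p)))
    return total
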