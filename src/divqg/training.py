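"""Weighted total loss, the optimization schedule, and train/generate.

Training minimizes ``L = alpha * L_I + beta * L_MIC + gamma * L_KL +
delta * L_G`` with Adam, a learning rate that starts at 1e-3 and decays
by one tenth every five epochs down to a floor of 1e-7, batch size 32,
and keeps the checkpoint with the best validation total loss.  Every
source of randomness (initialization, data order, reparameterization
noise, flip augmentation) descends from one seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .feature_encoders import EncoderConfig, prepare_image, random_flip
from .mic import MicConfig
from .model import VqgModel, resize_image
from .multi_latent import LatentConfig
from .nn import Adam, Tensor
from .question_decoder import DecoderConfig, Vocabulary
from .synthetic_data import VqgDataset

__all__ = [
    "LossWeights",
    "TrainConfig",
    "Checkpoint",
    "TrainResult",
    "total_loss",
    "lr_at_epoch",
    "train",
    "generate",
]


@dataclass
class LossWeights:
    """Weights (alpha, beta, gamma, delta) of the four loss terms:
    reconstruction, MIC diversity, KL, and generation."""

    alpha: float = 0.001
    beta: float = 1.0
    gamma: float = 0.001
    delta: float = 1.0

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.gamma, self.delta)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class TrainConfig:
    base_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 5
    lr_floor: float = 1e-7
    batch_size: int = 32
    epochs: int = 40
    random_flip: bool = True
    seed: int = 0
    mic_mode: str = "surrogate"

    def __post_init__(self):
        if self.base_lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("base_lr, batch_size and epochs must be positive")
        if not 0 < self.lr_floor < self.base_lr:
            raise ValueError("lr_floor must lie in (0, base_lr)")


def total_loss(loss_recon, loss_mic, loss_kl, loss_gen, weights: LossWeights):
    """Weighted sum ``alpha*L_I + beta*L_MIC + gamma*L_KL + delta*L_G``.

    Works on plain floats or on autodiff Tensors (for backprop).
    """
    components = {
        "L_I": loss_recon,
        "L_MIC": loss_mic,
        "L_KL": loss_kl,
        "L_G": loss_gen,
    }
    for name, value in components.items():
        scalar = value.item() if isinstance(value, Tensor) else float(value)
        if not np.isfinite(scalar):
            raise ValueError(f"loss component {name} is not finite ({scalar})")
    return (
        weights.alpha * loss_recon
        + weights.beta * loss_mic
        + weights.gamma * loss_kl
        + weights.delta * loss_gen
    )


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """base_lr scaled by decay_factor every decay interval, floored."""
    steps = epoch // config.lr_decay_every
    return max(config.base_lr * config.lr_decay_factor**steps, config.lr_floor)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    state: dict
    vocab_payload: str
    encoder_config: dict
    latent_config: dict
    decoder_config: dict
    epoch: int
    val_metrics: dict = field(default_factory=dict)

    def save(self, path) -> Path:
        path = Path(path)
        meta = json.dumps(
            {
                "vocab": self.vocab_payload,
                "encoder_config": self.encoder_config,
                "latent_config": self.latent_config,
                "decoder_config": self.decoder_config,
                "epoch": self.epoch,
                "val_metrics": self.val_metrics,
            }
        )
        if path.suffix != ".npz":
            path = path.with_name(path.name + ".npz")
        np.savez(path, __meta__=np.array(meta), **self.state)
        return path

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            state=state,
            vocab_payload=meta["vocab"],
            encoder_config=meta["encoder_config"],
            latent_config=meta["latent_config"],
            decoder_config=meta["decoder_config"],
            epoch=meta["epoch"],
            val_metrics=meta["val_metrics"],
        )

    def build_model(self) -> VqgModel:
        vocab = Vocabulary.from_json(self.vocab_payload)
        model = VqgModel(
            EncoderConfig(**self.encoder_config),
            LatentConfig(**self.latent_config),
            DecoderConfig(**self.decoder_config),
            vocab,
            np.random.default_rng(0),
        )
        model.load_state_dict(self.state)
        return model


@dataclass
class TrainResult:
    checkpoint: Checkpoint
    history: list
    model: VqgModel


# ---------------------------------------------------------------------------
# batch preparation
# ---------------------------------------------------------------------------


def _prepare_examples(dataset: VqgDataset, vocab: Vocabulary, K: int,
                      image_size: int, max_len: int):
    """Images, categories, and (N, K, L) padded token arrays.

    Each image contributes one training sample per distinct category
    among its questions: (image, category word, the questions of that
    category) — mirroring how ground truth is selected per category.
    Within a sample the questions are cycled (truncated or reused) to K
    sequences so that question j pairs with latent space j.
    """
    prepared = {}
    images_list, categories, encoded = [], [], []
    for ex in dataset.examples:
        if ex.image_id not in prepared:
            prepared[ex.image_id] = prepare_image(
                resize_image(ex.image, image_size), image_size
            )
        cats = ex.question_categories or [ex.category] * len(ex.ground_truth_questions)
        distinct = list(dict.fromkeys(cats))  # first-appearance order
        for cat in distinct:
            questions = [
                q for q, c in zip(ex.ground_truth_questions, cats) if c == cat
            ]
            seqs = [
                vocab.encode(questions[j % len(questions)])[: max_len + 2]
                for j in range(K)
            ]
            images_list.append(prepared[ex.image_id])
            categories.append(cat)
            encoded.append(seqs)
    images = np.stack(images_list)
    L = max(len(seq) for seqs in encoded for seq in seqs)
    tokens = np.full((len(encoded), K, L), Vocabulary.PAD, dtype=np.int64)
    for i, seqs in enumerate(encoded):
        for k, seq in enumerate(seqs):
            tokens[i, k, : len(seq)] = seq
    return images, categories, tokens


def _epoch_pass(model, images, categories, tokens, weights, train_cfg,
                mic_config, optimizer=None, noise_rng=None, flip_rng=None,
                order=None):
    """One pass over the data; optimizes when an optimizer is given."""
    N = len(images)
    idx = order if order is not None else np.arange(N)
    sums = {"recon": 0.0, "mic": 0.0, "kl": 0.0, "gen": 0.0, "total": 0.0}
    compute_mic = weights.beta > 0  # beta=0 never invokes MIC estimation
    for start in range(0, N, train_cfg.batch_size):
        sel = idx[start : start + train_cfg.batch_size]
        batch_images = images[sel]
        if flip_rng is not None and train_cfg.random_flip:
            batch_images = random_flip(batch_images, flip_rng)
        batch_cats = [categories[i] for i in sel]
        if noise_rng is None:
            losses = model.forward_losses(
                batch_images, batch_cats, tokens[sel],
                noise_rng=None, mic_config=mic_config,
                mic_mode=train_cfg.mic_mode, compute_mic=compute_mic,
            )
        else:
            losses = model.forward_losses(
                batch_images, batch_cats, tokens[sel],
                noise_rng=noise_rng, mic_config=mic_config,
                mic_mode=train_cfg.mic_mode, compute_mic=compute_mic,
            )
        loss = total_loss(losses["recon"], losses["mic"], losses["kl"],
                          losses["gen"], weights)
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        w = len(sel) / N
        for key in ("recon", "mic", "kl", "gen"):
            sums[key] += losses[key].item() * w
        sums["total"] += loss.item() * w
    return sums


def train(
    train_set: VqgDataset,
    val_set: VqgDataset,
    encoder_config: EncoderConfig | None = None,
    latent_config: LatentConfig | None = None,
    decoder_config: DecoderConfig | None = None,
    train_config: TrainConfig | None = None,
    weights: LossWeights | None = None,
    mic_config: MicConfig | None = None,
) -> TrainResult:
    """Train the full model; returns the best-validation checkpoint and log."""
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    encoder_config = encoder_config or EncoderConfig()
    latent_config = latent_config or LatentConfig()
    decoder_config = decoder_config or DecoderConfig()
    train_config = train_config or TrainConfig()
    weights = weights or LossWeights()
    mic_config = mic_config or MicConfig()

    seeds = np.random.SeedSequence(train_config.seed).spawn(4)
    init_rng, order_rng, noise_rng, flip_rng = (
        np.random.default_rng(s) for s in seeds
    )

    vocab = Vocabulary.build(
        q for ex in train_set.examples for q in ex.ground_truth_questions
    )
    model = VqgModel(encoder_config, latent_config, decoder_config, vocab, init_rng)
    optimizer = Adam(model.parameters(), lr=train_config.base_lr)

    K = latent_config.n_spaces
    size = encoder_config.image_size
    max_len = decoder_config.max_len
    tr_images, tr_cats, tr_tokens = _prepare_examples(train_set, vocab, K, size, max_len)
    if len(val_set):
        va_images, va_cats, va_tokens = _prepare_examples(val_set, vocab, K, size, max_len)

    history = []
    best = {"loss": np.inf, "state": model.state_dict(), "epoch": -1, "metrics": {}}
    for epoch in range(train_config.epochs):
        optimizer.lr = lr_at_epoch(epoch, train_config)
        order = order_rng.permutation(len(tr_images))
        tr = _epoch_pass(
            model, tr_images, tr_cats, tr_tokens, weights, train_config,
            mic_config, optimizer=optimizer, noise_rng=noise_rng,
            flip_rng=flip_rng, order=order,
        )
        row = {"epoch": epoch, "lr": optimizer.lr}
        row.update({f"train_{k}": v for k, v in tr.items()})
        if len(val_set):
            # validation at the latent means (eta = 0), no augmentation
            va = _epoch_pass(
                model, va_images, va_cats, va_tokens, weights, train_config,
                mic_config, optimizer=None, noise_rng=None, flip_rng=None,
            )
            row.update({f"val_{k}": v for k, v in va.items()})
            if va["total"] < best["loss"]:
                best = {
                    "loss": va["total"],
                    "state": model.state_dict(),
                    "epoch": epoch,
                    "metrics": {k: va[k] for k in va},
                }
        history.append(row)
    if best["epoch"] < 0:  # no validation set: keep the final weights
        best = {"loss": np.nan, "state": model.state_dict(),
                "epoch": train_config.epochs - 1, "metrics": {}}
    model.load_state_dict(best["state"])
    checkpoint = Checkpoint(
        state=best["state"],
        vocab_payload=vocab.to_json(),
        encoder_config=asdict(encoder_config),
        latent_config=asdict(latent_config),
        decoder_config=asdict(decoder_config),
        epoch=best["epoch"],
        val_metrics=best["metrics"],
    )
    return TrainResult(checkpoint=checkpoint, history=history, model=model)


def generate(source, image: np.ndarray, category: str,
             rng: np.random.Generator | None = None,
             sampled_latents: bool = False,
             sampled_tokens: bool = False) -> list[str]:
    """K questions from a trained model or checkpoint for one image."""
    model = source.build_model() if isinstance(source, Checkpoint) else source
    return model.generate(
        image, category, rng=rng,
        sampled_latents=sampled_latents, sampled_tokens=sampled_tokens,
    )
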