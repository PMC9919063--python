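"""Image and category encoders producing the joint conditioning vector.

An image encoder (a small 4-block CNN by default; other backbones can
be registered) maps the input radiograph to a feature vector ``f_I``,
a category encoder embeds the question-category word and passes it
through a 3-layer MLP to give ``f_C``, and the two are concatenated —
image first — into the joint feature that conditions the latent spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categories import CATEGORIES, CATEGORY_TO_INDEX
from .nn import MLP, Conv2d, Embedding, Linear, Module, Tensor, concat, max_pool2x2

__all__ = [
    "EncoderConfig",
    "ImageEncoder",
    "CategoryEncoder",
    "TinyCNN",
    "joint_feature",
    "register_backbone",
    "prepare_image",
    "random_flip",
]


@dataclass
class EncoderConfig:
    backbone: str = "tiny-cnn"
    image_size: int = 224
    d_I: int = 128
    d_C: int = 64
    category_embedding_dim: int = 64
    mlp_hidden: int = 512
    conv_channels: tuple = (8, 16, 32, 64)

    def __post_init__(self):
        for name in ("image_size", "d_I", "d_C", "category_embedding_dim", "mlp_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.image_size % 2 ** len(self.conv_channels) != 0:
            raise ValueError(
                "image_size must be divisible by 2**len(conv_channels) for pooling"
            )


class TinyCNN(Module):
    """Four conv(3x3)+ReLU+maxpool blocks, global average pool, linear head."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        channels = (1,) + tuple(config.conv_channels)
        self.blocks = [
            Conv2d(c_in, c_out, rng) for c_in, c_out in zip(channels[:-1], channels[1:])
        ]
        self.head = Linear(channels[-1], config.d_I, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = max_pool2x2(block(x).relu())
        pooled = x.mean(axis=(2, 3))
        return self.head(pooled)


_BACKBONES = {"tiny-cnn": TinyCNN}


def register_backbone(name: str, factory) -> None:
    """Register an image-backbone factory ``(config, rng) -> Module``.

    The module must map a (B, 1, H, W) Tensor to (B, d_I).  This is the
    hook for heavyweight pretrained backbones (e.g. a ResNet-50 from an
    external deep-learning runtime) which are not bundled here.
    """
    _BACKBONES[name] = factory


def prepare_image(image: np.ndarray, image_size: int) -> np.ndarray:
    """Validate/normalize one image to a (1, H, W) float array in [0, 1].

    RGB input is collapsed to luminance.  The spatial size must already
    match the configured input size (use PIL resizing upstream).
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D image, got ndim={arr.ndim}")
    if arr.shape != (image_size, image_size):
        raise ValueError(
            f"expected a {image_size}x{image_size} image, got {arr.shape}"
        )
    return (arr / 255.0)[None, :, :]


def random_flip(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Horizontal flip with probability 1/2 per image (training-time only)."""
    out = batch.copy()
    flips = rng.random(len(batch)) < 0.5
    out[flips] = out[flips][..., ::-1]
    return out


class ImageEncoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        if config.backbone not in _BACKBONES:
            raise ValueError(
                f"backbone {config.backbone!r} is not registered; "
                f"available: {sorted(_BACKBONES)} (use register_backbone for plugins)"
            )
        self.backbone = _BACKBONES[config.backbone](config, rng)

    def encode(self, images: np.ndarray) -> Tensor:
        """Encode a (B, 1, H, W) or (B, H, W) float batch to (B, d_I)."""
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[:, None, :, :]
        size = self.config.image_size
        if arr.shape[2:] != (size, size):
            raise ValueError(f"expected {size}x{size} images, got {arr.shape[2:]}")
        return self.backbone(Tensor(arr))

    def encode_one(self, image: np.ndarray) -> np.ndarray:
        """Feature vector of a single raw image (handles normalization)."""
        prepared = prepare_image(image, self.config.image_size)
        return self.encode(prepared[None]).data[0]


class CategoryEncoder(Module):
    """Embedding of the category word followed by a 3-layer MLP."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.embedding = Embedding(len(CATEGORIES), config.category_embedding_dim, rng)
        self.mlp = MLP(config.category_embedding_dim, config.mlp_hidden, config.d_C, rng)

    def encode(self, labels) -> Tensor:
        if isinstance(labels, str):
            labels = [labels]
        try:
            idx = np.array([CATEGORY_TO_INDEX[c] for c in labels], dtype=np.int64)
        except KeyError as err:
            raise ValueError(f"unknown category {err.args[0]!r}") from None
        return self.mlp(self.embedding(idx))

    def encode_one(self, label: str) -> np.ndarray:
        return self.encode(label).data[0]


def joint_feature(f_image, f_category) -> Tensor:
    """Concatenate image and category features (image first)."""
    fi = f_image if isinstance(f_image, Tensor) else Tensor(np.asarray(f_image, float))
    fc = (
        f_category
        if isinstance(f_category, Tensor)
        else Tensor(np.asarray(f_category, float))
    )
    if fi.ndim != fc.ndim:
        raise ValueError("image and category features must have matching rank")
    return concat([fi, fc], axis=-1)
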