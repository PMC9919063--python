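"""The assembled question-generation network.

Wires the image/category encoders, the K latent heads, the feature
reconstructor and the shared LSTM decoder into one module and exposes
the forward pass that produces the four training losses.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .feature_encoders import (
    CategoryEncoder,
    EncoderConfig,
    ImageEncoder,
    joint_feature,
    prepare_image,
)
from .mic import MicConfig
from .multi_latent import (
    FeatureReconstructor,
    LatentConfig,
    LatentHeads,
    kl_loss,
    mic_loss,
    reconstruction_loss,
    sample_latents,
)
from .nn import Module, Tensor
from .question_decoder import (
    DecoderConfig,
    QuestionDecoder,
    Vocabulary,
    masked_sequence_nll,
)

__all__ = ["VqgModel", "resize_image"]


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a raw intensity image to (size, size)."""
    arr = np.asarray(image)
    if arr.shape[:2] == (size, size):
        return arr
    return np.asarray(Image.fromarray(arr).resize((size, size), Image.BILINEAR))


class VqgModel(Module):
    def __init__(
        self,
        encoder_config: EncoderConfig,
        latent_config: LatentConfig,
        decoder_config: DecoderConfig,
        vocab: Vocabulary,
        rng: np.random.Generator,
    ):
        self.encoder_config = encoder_config
        self.latent_config = latent_config
        self.decoder_config = decoder_config
        self.vocab = vocab
        self.image_encoder = ImageEncoder(encoder_config, rng)
        self.category_encoder = CategoryEncoder(encoder_config, rng)
        self.latent_heads = LatentHeads(
            encoder_config.d_I + encoder_config.d_C, latent_config, rng
        )
        self.reconstructor = FeatureReconstructor(encoder_config.d_I, latent_config, rng)
        self.decoder = QuestionDecoder(
            vocab.size, latent_config.d_z, decoder_config, rng
        )

    # -- encoding -----------------------------------------------------------
    def joint_features(self, images: np.ndarray, categories) -> tuple[Tensor, Tensor]:
        f_i = self.image_encoder.encode(images)
        f_c = self.category_encoder.encode(categories)
        return f_i, joint_feature(f_i, f_c)

    def latent_samples(self, f_joint: Tensor, noise=None,
                       rng: np.random.Generator | None = None):
        params = self.latent_heads(f_joint)
        if noise is None and rng is None:
            K = self.latent_config.n_spaces
            noise = [np.zeros_like(mu.data) for mu, _ in params]
        return params, sample_latents(params, noise=noise, rng=rng)

    # -- training forward ---------------------------------------------------
    def forward_losses(
        self,
        images: np.ndarray,
        categories,
        tokens: np.ndarray,
        noise_rng: np.random.Generator,
        mic_config: MicConfig | None = None,
        mic_mode: str = "surrogate",
        compute_mic: bool = True,
    ) -> dict:
        """Four component losses for a prepared batch.

        ``images``: (B, 1, H, W) floats in [0, 1]; ``tokens``: (B, K, L)
        padded id sequences starting with BOS.  Teacher forcing pairs
        question j with latent space j.
        """
        B, K, L = tokens.shape
        if K != self.latent_config.n_spaces:
            raise ValueError(f"expected {self.latent_config.n_spaces} sequences, got {K}")
        f_i, f_j = self.joint_features(images, categories)
        params, samples = self.latent_samples(f_j, rng=noise_rng)
        recons = [self.reconstructor(s, k) for k, s in enumerate(samples)]
        loss_recon = reconstruction_loss(f_i, recons)
        loss_kl = kl_loss(params)
        if compute_mic and K >= 2 and B >= 4:
            loss_mic = mic_loss(samples, config=mic_config, mode=mic_mode)
        else:
            loss_mic = Tensor(0.0)
        gen_total = None
        for k in range(K):
            logits = self.decoder.teacher_forcing_logits(samples[k], tokens[:, k, :])
            targets = tokens[:, k, 1:]
            mask = (targets != Vocabulary.PAD).astype(np.float64)
            nll = masked_sequence_nll(logits, targets, mask)
            gen_total = nll if gen_total is None else gen_total + nll
        loss_gen = gen_total.mean()
        return {
            "recon": loss_recon,
            "kl": loss_kl,
            "mic": loss_mic,
            "gen": loss_gen,
            "samples": samples,
            "params": params,
        }

    # -- inference ----------------------------------------------------------
    def generate(self, image: np.ndarray, category: str,
                 rng: np.random.Generator | None = None,
                 sampled_latents: bool = False,
                 sampled_tokens: bool = False) -> list[str]:
        """K questions for one image under one category.

        Deterministic by default: latents are the space means (eta = 0)
        and decoding is greedy.
        """
        prepared = prepare_image(
            resize_image(image, self.encoder_config.image_size),
            self.encoder_config.image_size,
        )[None]
        _, f_j = self.joint_features(prepared, [category])
        noise_rng = rng if sampled_latents else None
        _, samples = self.latent_samples(f_j, rng=noise_rng)
        stacked = Tensor(np.concatenate([s.data for s in samples], axis=0))
        seqs = self.decoder.greedy_decode(
            stacked, max_len=self.decoder_config.max_len,
            rng=rng, sampled=sampled_tokens,
        )
        return [self.vocab.decode(seq) for seq in seqs]
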