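"""The multi-latent space processor and its training losses.

The joint image–category feature is mapped into K independent diagonal
Gaussian latent spaces (one un-shared MLP per space predicts a mean and
a log standard deviation).  Reparameterized samples ``s_k = mu_k +
eta * sigma_k`` feed (a) a reconstruction MLP that must recover the
image feature (squared-error loss), (b) a KL regularizer against the
standard normal, and (c) the diversity loss: the sum over space pairs
of the maximal information coefficient between their samples, which is
minimized so that different spaces encode different information.

MIC itself is a non-differentiable grid search, so training defaults to
a differentiable surrogate — the Gaussian mutual information of the
batch Pearson correlation per latent coordinate, squashed to [0, 1] as
``1 - sqrt(1 - rho^2)`` — while the exact DP estimator is used for
evaluation and logging (``mode="exact"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mic import MicConfig, mic_exact
from .nn import MLP, Module, Tensor, as_tensor

__all__ = [
    "LatentConfig",
    "LatentHeads",
    "FeatureReconstructor",
    "sample_latents",
    "reconstruction_loss",
    "kl_loss",
    "mic_loss",
    "pairwise_mic_matrix",
]

# LatentParams: list over K spaces of (mu, sigma) batch Tensors (B, d_z).
# LatentSampleSet: list over K spaces of sample batch Tensors (B, d_z).


@dataclass
class LatentConfig:
    n_spaces: int = 3
    d_z: int = 64
    mlp_hidden: int = 512
    share_reconstruction: bool = True

    def __post_init__(self):
        if self.n_spaces < 1:
            raise ValueError("need at least one latent space")
        if self.d_z <= 0 or self.mlp_hidden <= 0:
            raise ValueError("d_z and mlp_hidden must be positive")


class LatentHeads(Module):
    """One MLP per latent space predicting (mu, log sigma); no weight sharing."""

    def __init__(self, d_in: int, config: LatentConfig, rng: np.random.Generator):
        self.config = config
        self.heads = [
            MLP(d_in, config.mlp_hidden, 2 * config.d_z, rng)
            for _ in range(config.n_spaces)
        ]

    def space_params(self, f_joint: Tensor, k: int):
        """(mu_k, sigma_k) of space ``k`` (0-based); sigma = exp(log-sigma head)."""
        if not 0 <= k < self.config.n_spaces:
            raise IndexError(
                f"space index {k} out of range for K={self.config.n_spaces}"
            )
        d_z = self.config.d_z
        out = self.heads[k](as_tensor(f_joint))
        mu = out[..., :d_z]
        sigma = out[..., d_z:].exp()
        return mu, sigma

    def __call__(self, f_joint: Tensor):
        return [
            self.space_params(f_joint, k) for k in range(self.config.n_spaces)
        ]


class FeatureReconstructor(Module):
    """MLP from a latent sample back to the image-feature space.

    Shared across spaces by default; set ``share_reconstruction=False``
    for one reconstruction MLP per space.
    """

    def __init__(self, d_I: int, config: LatentConfig, rng: np.random.Generator):
        self.config = config
        n = 1 if config.share_reconstruction else config.n_spaces
        self.mlps = [MLP(config.d_z, config.mlp_hidden, d_I, rng) for _ in range(n)]

    def __call__(self, s_k: Tensor, k: int = 0) -> Tensor:
        mlp = self.mlps[0] if self.config.share_reconstruction else self.mlps[k]
        return mlp(as_tensor(s_k))


def sample_latents(params, noise=None, rng: np.random.Generator | None = None):
    """Reparameterized samples ``s_k = mu_k + eta * sigma_k`` per space.

    ``noise`` may be a list of arrays shaped like the means (e.g. zeros
    for deterministic mean decoding); otherwise unit-Gaussian noise is
    drawn from ``rng``.
    """
    samples = []
    for k, (mu, sigma) in enumerate(params):
        mu, sigma = as_tensor(mu), as_tensor(sigma)
        if noise is not None:
            eta = np.asarray(noise[k], dtype=np.float64)
            if eta.shape != mu.data.shape:
                raise ValueError(
                    f"noise shape {eta.shape} does not match mean shape {mu.data.shape}"
                )
        elif rng is not None:
            eta = rng.standard_normal(mu.data.shape)
        else:
            raise ValueError("supply either explicit noise or a random generator")
        samples.append(mu + Tensor(eta) * sigma)
    return samples


def reconstruction_loss(f_image, reconstructions) -> Tensor:
    """Sum over spaces of the squared Euclidean error, batch-averaged."""
    fi = as_tensor(f_image)
    if fi.ndim == 1:
        fi = fi.reshape(1, -1)
    total = None
    for recon in reconstructions:
        r = as_tensor(recon)
        if r.ndim == 1:
            r = r.reshape(1, -1)
        if r.data.shape != fi.data.shape:
            raise ValueError(
                f"reconstruction shape {r.data.shape} != feature shape {fi.data.shape}"
            )
        term = ((fi - r) ** 2).sum(axis=-1).mean()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("need at least one reconstruction")
    return total


def kl_loss(params) -> Tensor:
    """KL divergence of each diagonal Gaussian from N(0, I), summed over
    spaces and dimensions and batch-averaged:
    ``0.5 * (-log sigma^2 + mu^2 + sigma^2 - 1)`` per dimension."""
    total = None
    for mu, sigma in params:
        mu, sigma = as_tensor(mu), as_tensor(sigma)
        if np.any(sigma.data <= 0):
            raise ValueError("standard deviations must be strictly positive")
        if mu.ndim == 1:
            mu, sigma = mu.reshape(1, -1), sigma.reshape(1, -1)
        term = 0.5 * ((-2.0) * sigma.log() + mu**2 + sigma**2 - 1.0)
        total_k = term.sum(axis=-1).mean()
        total = total_k if total is None else total + total_k
    if total is None:
        raise ValueError("need at least one latent space")
    return total


def _as_sample_matrix(s) -> np.ndarray:
    arr = s.data if isinstance(s, Tensor) else np.asarray(s, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("latent samples must be (batch, d_z) matrices")
    return arr


def mic_loss(sample_set, config: MicConfig | None = None, mode: str = "surrogate") -> Tensor:
    """Pairwise dependence between latent spaces, summed over pairs k < l.

    The batch dimension provides the paired samples: for every
    unordered pair of spaces and every latent coordinate, the
    dependence between the two spaces' coordinate samples across the
    batch is computed and averaged over coordinates.  The diagonal
    (k = l) is a gradient-free constant and is excluded.

    mode="surrogate" (differentiable) uses ``1 - sqrt(1 - rho^2)`` of
    the batch Pearson correlation; mode="exact" uses the DP MIC
    estimator and carries no gradient.
    """
    config = config or MicConfig()
    K = len(sample_set)
    if K == 0:
        raise ValueError("empty sample set")
    n = _as_sample_matrix(sample_set[0]).shape[0]
    if n < 4:
        raise ValueError("need a batch of at least 4 samples to estimate MIC")
    if K == 1:
        return Tensor(0.0)
    if mode == "exact":
        total = 0.0
        for k in range(K):
            for l in range(k + 1, K):
                total += _exact_pair_mic(sample_set[k], sample_set[l], config)
        return Tensor(total)
    if mode != "surrogate":
        raise ValueError(f"unknown MIC loss mode {mode!r}")
    eps = 1e-8
    total = None
    for k in range(K):
        x = as_tensor(sample_set[k])
        for l in range(k + 1, K):
            y = as_tensor(sample_set[l])
            xc = x - x.mean(axis=0, keepdims=True)
            yc = y - y.mean(axis=0, keepdims=True)
            cov = (xc * yc).sum(axis=0)
            denom = ((xc**2).sum(axis=0) * (yc**2).sum(axis=0) + eps).sqrt()
            rho = cov / denom
            pair = (1.0 - (1.0 - rho**2 + eps).sqrt()).mean()
            total = pair if total is None else total + pair
    return total


def _exact_pair_mic(s_k, s_l, config: MicConfig) -> float:
    a = _as_sample_matrix(s_k)
    b = _as_sample_matrix(s_l)
    vals = [mic_exact(a[:, j], b[:, j], config) for j in range(a.shape[1])]
    return float(np.mean(vals))


def pairwise_mic_matrix(sample_set, config: MicConfig | None = None) -> np.ndarray:
    """Symmetric K x K matrix of coordinate-averaged exact MIC; diagonal 1."""
    config = config or MicConfig()
    K = len(sample_set)
    n = _as_sample_matrix(sample_set[0]).shape[0]
    if n < 4:
        raise ValueError("need a batch of at least 4 samples to estimate MIC")
    out = np.eye(K)
    for k in range(K):
        for l in range(k + 1, K):
            out[k, l] = out[l, k] = _exact_pair_mic(sample_set[k], sample_set[l], config)
    return out
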