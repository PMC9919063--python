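"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from divqg.synthetic_data import SyntheticSpec, generate_dataset


# ---------------------------------------------------------------------------
# independent brute-force MIC oracle: enumerates every contiguous partition
# of BOTH axes for every admissible grid shape (feasible for small n only)
# ---------------------------------------------------------------------------

def brute_force_mic(x, y, config) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0

    def all_partitions(values, max_parts):
        uniq = np.unique(values)
        rank = np.searchsorted(uniq, values)
        m = len(uniq)
        out = []
        for n_cuts in range(min(max_parts, m)):
            for cuts in itertools.combinations(range(1, m), n_cuts):
                labels = np.searchsorted(np.asarray(cuts), rank, side="right")
                out.append((labels, n_cuts + 1))
        return out

    best = 0.0
    for a, b in config.grid_shapes(n):
        for xl, na in all_partitions(x, a):
            for yl, nb in all_partitions(y, b):
                joint = np.zeros((na, nb))
                np.add.at(joint, (xl, yl), 1.0)
                p = joint / n
                px = p.sum(axis=1)
                py = p.sum(axis=0)
                mi = 0.0
                for i in range(na):
                    for j in range(nb):
                        if p[i, j] > 0:
                            mi += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
                best = max(best, mi / np.log2(min(a, b)))
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# exhaustive lowest-similarity subset oracle
# ---------------------------------------------------------------------------

def exhaustive_min_similarity_subset(embeddings: np.ndarray, k: int) -> float:
    """Minimum over all k-subsets of the mean pairwise inner product."""
    sims = embeddings @ embeddings.T
    best = np.inf
    for subset in itertools.combinations(range(len(embeddings)), k):
        pairs = [sims[i, j] for i, j in itertools.combinations(subset, 2)]
        best = min(best, float(np.mean(pairs)))
    return best


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small deterministic synthetic dataset (30 images, 32x32)."""
    return generate_dataset(SyntheticSpec(n_images=30, seed=7, image_size=32))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
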