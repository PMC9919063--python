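"""Exact maximal information coefficient (MIC) on paired scalar samples.

MIC scans two-dimensional grids laid over the scatter of (x, y): for a
grid with ``a`` columns and ``b`` rows it takes the largest empirical
mutual information achievable by any axis-aligned partition, normalizes
by ``log2(min(a, b))``, and finally maximizes over all grid shapes whose
cell count ``a * b`` stays below a bound (``n ** exponent`` by default,
or an explicit ``lambda`` override).  The score lies in [0, 1]: 1 for a
noiseless functional relationship, near 0 for independent samples.

The estimator here is exact, not heuristic: mutual information is
additive over the segments of one axis once the other axis's bin labels
are fixed, so for every grid shape we exhaustively enumerate contiguous
partitions of the axis allowed fewer bins and find the optimal partition
of the other axis by dynamic programming over segment boundaries.
Ties in the data are handled by only cutting between distinct values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["MicConfig", "mic_exact"]


@dataclass(frozen=True)
class MicConfig:
    """Grid-search bounds for MIC.

    grid_bound_exponent
        When no override is given, grids are restricted to
        ``a * b < n ** grid_bound_exponent`` (0.6 is the customary choice).
    grid_bound_override
        Explicit bound (the hyperparameter usually written as lambda);
        when set it replaces the ``n ** exponent`` rule.
    max_grid_side
        Hard cap on the number of bins per axis.
    """

    grid_bound_exponent: float = 0.6
    grid_bound_override: float | None = None
    max_grid_side: int = 5

    def effective_bound(self, n: int) -> float:
        if self.grid_bound_override is not None:
            if self.grid_bound_override <= 0:
                raise ValueError("grid_bound_override must be positive")
            return float(self.grid_bound_override)
        if not 0 < self.grid_bound_exponent <= 1:
            raise ValueError("grid_bound_exponent must lie in (0, 1]")
        return float(n) ** self.grid_bound_exponent

    def grid_shapes(self, n: int) -> list[tuple[int, int]]:
        bound = self.effective_bound(n)
        side = self.max_grid_side
        return [
            (a, b)
            for a in range(2, side + 1)
            for b in range(2, side + 1)
            if a * b < bound
        ]


def _block_ranks(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Map each sample to the index of its tie-block in sorted order."""
    uniq = np.unique(values)
    return np.searchsorted(uniq, values), len(uniq)


def _segment_mi_matrix(labels_sorted: np.ndarray, block_edges: np.ndarray,
                       n_labels: int, n: int) -> np.ndarray:
    """f[j, i] = MI contribution of the segment spanning blocks j..i-1.

    ``labels_sorted``: other-axis bin label of each sample, in the sorted
    order of this axis.  ``block_edges``: sample-index boundaries of the
    tie-blocks (length m+1, edges[0]=0, edges[m]=n).
    """
    m = len(block_edges) - 1
    onehot = np.zeros((n, n_labels))
    onehot[np.arange(n), labels_sorted] = 1.0
    pref_samples = np.concatenate([np.zeros((1, n_labels)), np.cumsum(onehot, axis=0)])
    pref = pref_samples[block_edges]  # (m+1, n_labels)
    marg = pref[-1]  # total count per label
    C = pref[None, :, :] - pref[:, None, :]  # (m+1, m+1, L); valid for j < i
    R = C.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (C * n) / (R * marg[None, None, :])
        term = np.where(C > 0, (C / n) * np.log2(np.where(C > 0, ratio, 1.0)), 0.0)
    f = term.sum(axis=-1)  # (m+1, m+1)
    j_idx, i_idx = np.indices(f.shape)
    f[j_idx >= i_idx] = -np.inf  # only forward, non-empty segments are real
    return f


def _best_partition_mi(labels_sorted: np.ndarray, block_edges: np.ndarray,
                       n_labels: int, n: int, max_parts: int) -> float:
    """Maximal MI over contiguous partitions into at most ``max_parts``."""
    m = len(block_edges) - 1
    f = _segment_mi_matrix(labels_sorted, block_edges, n_labels, n)
    neg = -np.inf
    best_prev = np.full(m + 1, neg)
    best_prev[0] = 0.0
    best = neg
    for _ in range(min(max_parts, m)):
        with np.errstate(invalid="ignore"):
            cand = best_prev[:, None] + f
        best_cur = np.max(cand, axis=0)
        best_cur[0] = neg  # a part may not be empty
        best = max(best, best_cur[m])
        best_prev = best_cur
    return best


def _max_mi_for_shape(u: np.ndarray, v: np.ndarray, parts_u: int, parts_v: int,
                      n: int) -> float:
    """Max MI with <= parts_u bins on u (exhausted) and <= parts_v on v (DP)."""
    u_rank, m_u = _block_ranks(u)
    order_v = np.argsort(v, kind="stable")
    v_sorted = v[order_v]
    u_rank_v_sorted = u_rank[order_v]
    edges_v = np.concatenate(
        [[0], np.nonzero(np.diff(v_sorted) != 0)[0] + 1, [n]]
    )
    best = 0.0
    cut_positions = range(1, m_u)  # cut before block index
    for n_cuts in range(min(parts_u, m_u)):
        for cuts in itertools.combinations(cut_positions, n_cuts):
            labels = np.searchsorted(np.asarray(cuts), u_rank, side="right")
            n_labels = n_cuts + 1
            mi = _best_partition_mi(
                labels[order_v], edges_v, n_labels, n, parts_v
            )
            if mi > best:
                best = mi
    return best


def mic_exact(x, y, config: MicConfig | None = None) -> float:
    """Exact MIC of two paired scalar sample vectors; value in [0, 1]."""
    config = config or MicConfig()
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 4:
        raise ValueError("MIC needs at least 4 paired samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0  # a constant variable carries no information

    best = 0.0
    for a, b in config.grid_shapes(n):
        # exhaust the axis allowed fewer bins; MI is symmetric
        if a <= b:
            mi = _max_mi_for_shape(x, y, a, b, n)
        else:
            mi = _max_mi_for_shape(y, x, b, a, n)
        val = mi / np.log2(min(a, b))
        if val > best:
            best = val
    return float(min(best, 1.0))
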