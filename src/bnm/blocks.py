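"""Contiguous haplotype-block decomposition of the fused similarity matrix.

A chromosome is segmented by n-ary hierarchical spectral splitting:
starting from the whole chromosome, each open branch smaller than the
SNF neighbour count kappa closes; otherwise its similarity submatrix is
split into n = 2, 3, ... clusters by normalized spectral clustering
until a split is found whose clusters are all contiguous in map order
and all of size >= s_min (the split is then accepted and its clusters
become open branches), or n reaches n_max = min(S_k // s_min, t_max)
and the branch closes.  Leaf branches are the haplotype blocks.

The SNF hyperparameters (kappa, eta) are chosen by a minimax criterion
over a grid: the pair whose decomposition has the smallest largest leaf
block wins, giving the finest localization of causative markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.linalg import eigh

from .networks import snf_fuse


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the hierarchical decomposition and the (kappa, eta) grid."""

    s_min: int = 2
    t_max: int = 50
    kappa_grid: tuple[int, ...] = (10, 11, 12, 13, 14, 15)
    eta_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7)
    snf_iterations: int = 20

    def __post_init__(self) -> None:
        if self.s_min < 1:
            raise ValueError("s_min must be >= 1")
        if not self.kappa_grid or not self.eta_grid:
            raise ValueError("parameter grids must be non-empty")


@dataclass(frozen=True)
class BlockPartition:
    """Ordered contiguous marker-index blocks of one chromosome.

    ``blocks`` holds half-open index intervals [start, end) in map
    order; they are disjoint and cover the whole marker range.
    """

    blocks: tuple[tuple[int, int], ...]
    n_markers: int
    kappa: int | None = None
    eta: float | None = None

    def __post_init__(self) -> None:
        pos = 0
        for start, end in self.blocks:
            if start != pos or end <= start:
                raise ValueError("blocks must be contiguous, ordered and non-empty")
            pos = end
        if pos != self.n_markers:
            raise ValueError("blocks must cover all markers")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(end - start for start, end in self.blocks)

    def block_of(self, marker_index: int) -> int:
        for k, (start, end) in enumerate(self.blocks):
            if start <= marker_index < end:
                return k
        raise IndexError(marker_index)


def spectral_split(m_sub: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Split a similarity submatrix into n groups by spectral clustering.

    Normalized (symmetric Laplacian) spectral clustering: the bottom n
    eigenvectors are row-normalized and clustered with seeded k-means.
    Returns integer labels; all n groups are guaranteed non-empty.
    """
    w = np.asarray(m_sub, dtype=float)
    size = w.shape[0]
    if n < 2 or n > size:
        raise ValueError("need 2 <= n <= submatrix size")
    if n == size:
        return np.arange(size)
    w = (w + w.T) / 2.0
    deg = w.sum(axis=1)
    dinv = np.zeros(size)
    pos = deg > 0
    dinv[pos] = 1.0 / np.sqrt(deg[pos])
    lsym = np.eye(size) - dinv[:, None] * w * dinv[None, :]
    _, vecs = eigh(lsym, subset_by_index=(0, n - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    embedding = vecs / norms

    for attempt in range(10):
        _, labels = kmeans2(
            embedding, n, minit="++", rng=np.random.default_rng(seed + attempt)
        )
        if len(np.unique(labels)) == n:
            return labels
    # k-means kept collapsing clusters: fall back to quantile cuts of the
    # second eigenvector, which always yields n non-empty groups
    order = np.argsort(embedding[:, min(1, embedding.shape[1] - 1)], kind="stable")
    labels = np.empty(size, dtype=int)
    for k, chunk in enumerate(np.array_split(order, n)):
        labels[chunk] = k
    return labels


def _contiguous_intervals(labels: np.ndarray, offset: int):
    """Map cluster labels to global [start, end) intervals, or None if any
    cluster is not contiguous in marker order."""
    intervals = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx[-1] - idx[0] + 1 != len(idx):
            return None
        intervals.append((offset + int(idx[0]), offset + int(idx[-1]) + 1))
    intervals.sort()
    return intervals


def hierarchical_block_decomposition(
    m: np.ndarray, cfg: ClusteringConfig, kappa: int, seed: int = 0,
    eta: float | None = None,
) -> BlockPartition:
    """Decompose one chromosome into contiguous blocks.

    Implements the open/closed branch loop: a branch of size < kappa
    closes immediately; otherwise n is escalated from 2 until a split
    with all-contiguous, all->=s_min clusters is accepted, and rejected
    branches close.  Iterations stop when every branch is closed or
    t_max rounds have run.
    """
    m = np.asarray(m, dtype=float)
    s = m.shape[0]
    if kappa < 2:
        raise ValueError("kappa must be >= 2")
    open_branches: list[tuple[int, int]] = [(0, s)]
    closed: list[tuple[int, int]] = []
    for _ in range(cfg.t_max):
        if not open_branches:
            break
        next_open: list[tuple[int, int]] = []
        for start, end in open_branches:
            size = end - start
            if size < kappa:
                closed.append((start, end))
                continue
            n_max = min(size // cfg.s_min, cfg.t_max)
            accepted = None
            for n in range(2, n_max + 1):
                labels = spectral_split(m[start:end, start:end], n, seed=seed)
                intervals = _contiguous_intervals(labels, start)
                if intervals is not None and all(
                    e - b >= cfg.s_min for b, e in intervals
                ):
                    accepted = intervals
                    break
            if accepted is None:
                closed.append((start, end))
            else:
                next_open.extend(accepted)
        open_branches = next_open
    closed.extend(open_branches)  # t_max exhausted: remaining branches end
    closed.sort()
    return BlockPartition(blocks=tuple(closed), n_markers=s, kappa=kappa, eta=eta)


def _best_pair(records):
    """Minimax selection over (kappa, eta) decompositions.

    ``records`` is a list of (kappa, eta, BlockPartition, fused) tuples
    in grid order.  The winner minimizes the maximum leaf-block size;
    ties break by fewer blocks at that maximal size, then by more total
    blocks, then by smallest (kappa, eta) lexicographically.
    """
    def key(rec):
        kappa, eta, part, _ = rec
        sizes = part.sizes
        biggest = max(sizes)
        return (biggest, sizes.count(biggest), -part.n_blocks, kappa, eta)

    return min(records, key=key)


def select_kappa_eta(
    d: np.ndarray, i: np.ndarray, cfg: ClusteringConfig, seed: int = 0
):
    """Grid-search (kappa, eta), refusing the views per pair.

    Returns ``(kappa, eta, BlockPartition, fused_matrix)`` for the
    minimax-optimal pair.
    """
    s = np.asarray(d).shape[0]
    records = []
    for kappa in cfg.kappa_grid:
        if kappa >= s:
            continue
        for eta in cfg.eta_grid:
            fused = snf_fuse(d, i, kappa, eta, iterations=cfg.snf_iterations)
            part = hierarchical_block_decomposition(
                fused, cfg, kappa, seed=seed, eta=eta
            )
            records.append((kappa, eta, part, fused))
    if not records:
        raise ValueError("every kappa in the grid is >= the number of markers")
    return _best_pair(records)
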