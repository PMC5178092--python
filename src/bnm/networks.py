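"""Per-chromosome SNP similarity networks and their fusion.

Two views of marker similarity are built per chromosome and merged with
Similarity Network Fusion (SNF):

* a genetic-distance matrix ``D[s, s'] = |cM_s - cM_s'|``, sample
  independent;
* a phenotype-weighted mutual-information matrix averaged over
  permutations of the phenotype weights, which makes it phenotype
  *independent* while respecting the empirical phenotype distribution.

The weighted mutual information between markers s and s' with states
a, b in {0, 1, 2} is

    I[s, s'] = sum_ab P[s a, s' b] log( P[s a, s' b] / (P[s a] P[s' b]) )

where the joint cell P[s a, s' b] = sum_m rho_m * 1{state(m,s)=a} *
1{state(m,s')=b} weights subject m by its normalized phenotype rho_m.
Missing states are imputed by sampling from the marker's empirical
state distribution, freshly for each permutation.
"""

from __future__ import annotations

import numpy as np

from .io import MISSING

LOG_FLOOR = 1e-300  # inside logs only; exact-zero joint cells contribute 0


def genetic_distance_matrix(gmap) -> np.ndarray:
    """Absolute cM distance between every pair of markers.

    ``gmap`` is a single-chromosome :class:`~bnm.io.GeneticMap`.
    """
    cm = np.asarray(gmap.cm, dtype=float)
    if len(cm) < 2:
        raise ValueError("need at least 2 markers")
    return np.abs(cm[:, None] - cm[None, :])


def impute_missing_states(states: np.ndarray, rng) -> np.ndarray:
    """Replace missing states by draws from each SNP's empirical distribution."""
    out = states.copy()
    for i in range(states.shape[0]):
        row = states[i]
        miss = row == MISSING
        if not miss.any():
            continue
        obs = row[~miss]
        if obs.size == 0:
            raise ValueError(f"marker row {i} is entirely missing")
        counts = np.bincount(obs, minlength=3)[:3].astype(float)
        out[i, miss] = rng.choice(3, size=miss.sum(), p=counts / counts.sum())
    return out


def weighted_mutual_information(states: np.ndarray, rho: np.ndarray, rng=None) -> np.ndarray:
    """Phenotype-weighted mutual information between all marker pairs.

    ``states`` is (S, N) with values in {0,1,2,3}; missing values are
    imputed from each marker's empirical state frequencies using ``rng``
    (a fresh default generator when omitted).  The pairwise joint
    distributions are normalized by construction (sum_ab P = sum_m rho_m
    = 1), asserted per pair.
    """
    rho = np.asarray(rho, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    if (states == MISSING).any():
        states = impute_missing_states(states, rng)
    s, n = states.shape
    if len(rho) != n:
        raise ValueError("rho length does not match subject count")

    onehot = (states[:, None, :] == np.arange(3)[None, :, None]).astype(float)
    flat = onehot.reshape(s * 3, n)
    joint = (flat * rho) @ flat.T  # (3S, 3S)
    joint4 = joint.reshape(s, 3, s, 3)

    totals = joint4.sum(axis=(1, 3))
    if not np.allclose(totals, 1.0, atol=1e-9):
        raise AssertionError("pairwise joint distributions do not sum to 1")

    marg = flat @ rho  # P[s, a], (3S,)
    marg2 = marg.reshape(s, 3)
    denom = marg2[:, :, None, None] * marg2[None, None, :, :]
    logterm = np.log(np.maximum(joint4, LOG_FLOOR)) - np.log(np.maximum(denom, LOG_FLOOR))
    mi = np.where(joint4 > 0.0, joint4 * logterm, 0.0).sum(axis=(1, 3))
    return (mi + mi.T) / 2.0


def permutation_mutual_information(
    states: np.ndarray, rho: np.ndarray, n_perm: int = 100, seed: int = 0
) -> np.ndarray:
    """Average the weighted mutual information over permuted weights.

    Each of the ``n_perm`` rounds permutes the rho weights over subjects
    and re-imputes missing states independently, giving a
    phenotype-independent linkage measure (the empirical distribution of
    phenotype values is kept, their assignment to subjects is not).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rho = np.asarray(rho, dtype=float)
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_perm):
        perm_rho = rho[rng.permutation(len(rho))]
        mi = weighted_mutual_information(states, perm_rho, rng)
        acc = mi if acc is None else acc + mi
    return acc / n_perm


def mi_to_dissimilarity(mi: np.ndarray) -> np.ndarray:
    """Affine inversion of a similarity into a dissimilarity, zero diagonal."""
    d = np.max(mi) - mi
    np.fill_diagonal(d, 0.0)
    return d


def _check_square_symmetric(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    return a


def _local_affinity(diss: np.ndarray, kappa: int, eta: float) -> np.ndarray:
    """Locally scaled exponential kernel from a dissimilarity matrix.

    Bandwidth eps_ij averages each point's mean distance to its kappa
    nearest neighbours with the pair distance itself, scaled by eta.
    """
    srt = np.sort(diss, axis=1)
    mu = srt[:, 1 : kappa + 1].mean(axis=1)  # exclude self (distance 0)
    eps = (mu[:, None] + mu[None, :] + diss) / 3.0
    eps = np.maximum(eta * eps, 1e-12)
    w = np.exp(-(diss**2) / eps)
    return (w + w.T) / 2.0


def _full_kernel(w: np.ndarray) -> np.ndarray:
    """Row-stochastic normalization placing half the mass on the diagonal."""
    p = np.array(w, dtype=float)
    np.fill_diagonal(p, 0.0)
    rows = p.sum(axis=1)
    good = rows > 0
    p[good] = p[good] / (2.0 * rows[good, None])
    np.fill_diagonal(p, 0.5)
    return p


def _sparse_kernel(w: np.ndarray, kappa: int) -> np.ndarray:
    """Keep each row's kappa strongest affinities (self included), normalized."""
    s = w.shape[0]
    p = np.zeros_like(w, dtype=float)
    top = np.argsort(-w, axis=1)[:, :kappa]
    rows = np.repeat(np.arange(s), kappa)
    p[rows, top.ravel()] = w[rows, top.ravel()]
    sums = p.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return p / sums


def snf_fuse(
    d: np.ndarray, i: np.ndarray, kappa: int, eta: float, iterations: int = 20
) -> np.ndarray:
    """Fuse the distance and mutual-information views into one network.

    The MI similarity is first inverted into a dissimilarity (max(I) - I,
    zero diagonal); both views then pass through the locally scaled
    kernel, and the SNF cross-diffusion recurrence updates each view's
    full kernel by its own sparse kernel sandwiching the other view's
    kernel.  With ``iterations=0`` the average of the two initial full
    kernels is returned.
    """
    d = _check_square_symmetric(d, "distance matrix")
    i = _check_square_symmetric(i, "mutual information matrix")
    if d.shape != i.shape:
        raise ValueError("views must cover the same markers")
    s = d.shape[0]
    if not 0 < kappa < s:
        raise ValueError("kappa must satisfy 0 < kappa < S")
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")

    views = [np.array(d, dtype=float), mi_to_dissimilarity(i)]
    kernels = [_full_kernel(_local_affinity(v, kappa, eta)) for v in views]
    sparse = [_sparse_kernel(_local_affinity(v, kappa, eta), kappa) for v in views]

    for _ in range(iterations):
        updated = []
        for v in range(2):
            other = kernels[1 - v]
            p = sparse[v] @ other @ sparse[v].T
            p = _full_kernel((p + p.T) / 2.0)
            updated.append((p + p.T) / 2.0)
        kernels = updated

    m = (kernels[0] + kernels[1]) / 2.0
    return (m + m.T) / 2.0
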