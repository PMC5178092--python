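"""Block likelihoods from train/test trials against a permutation null.

For each trial the subjects are split into halves; every block fits a
regression of the log phenotype on its markers' one-hot state
indicators, once on the observed training phenotypes and n_p more times
on permuted training phenotypes.  The block's relative predictive power
for the trial is

    R[k, t] = exp(r[k, t]) / sum_p exp(r_p[k, t])

with r the Pearson correlation between predicted and held-out log
phenotypes.  The likelihood L_k of block k is the fraction of trials in
which it attains the maximum R (tied maxima all count as winners), so
sum_k L_k = 1 when winners are unique.

The one-hot (3 indicators per marker) design lets each genotype class
carry its own mean, capturing non-additive dependence of the phenotype
on allele dosage.  The ridge penalty is selected per fit by generalized
cross-validation (GCV) on the training half, which keeps large blocks
from overfitting their many indicator columns while letting a noiseless
realizable signal be interpolated; the model is pluggable via
``fit_block_model``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .blocks import BlockPartition
from .io import GenotypeMatrix, PhenotypeVector

# descending so GCV ties resolve toward the stronger penalty
ALPHA_GRID = (100.0, 10.0, 1.0, 0.1, 1e-8)


def one_hot_states(block_states: np.ndarray) -> np.ndarray:
    """Encode (S_b, N) states as an (N, 3*S_b) indicator design matrix.

    Missing states (3) leave all three indicators at zero, so a missing
    genotype contributes the model intercept.
    """
    sb, n = block_states.shape
    x = np.zeros((n, 3 * sb))
    for a in range(3):
        x[:, a::3] = (block_states == a).T
    return x


def _gcv_alpha(evals: np.ndarray, b: np.ndarray, y_norm2: float, n: int,
               grid=ALPHA_GRID) -> float:
    """Pick the ridge penalty minimizing the GCV score.

    ``evals`` are the Gram eigenvalues, ``b`` the eigenbasis projection
    of X^T y for the centered training response with squared norm
    ``y_norm2``.
    """
    b2 = b**2
    best_alpha, best_score = grid[0], np.inf
    for alpha in grid:
        shrink = evals + alpha
        df = float(np.sum(evals / shrink))
        rss = y_norm2 - 2 * float(np.sum(b2 / shrink)) + float(
            np.sum(b2 * evals / shrink**2)
        )
        denom = max(n - df, 1e-12)
        score = n * max(rss, 0.0) / denom**2
        if score < best_score - 1e-15:
            best_alpha, best_score = alpha, score
    return best_alpha


@dataclass(frozen=True)
class BlockModel:
    """Fitted ridge regression on one-hot state indicators."""

    coef: np.ndarray
    intercept: float
    alpha: float

    def predict(self, block_states: np.ndarray) -> np.ndarray:
        return one_hot_states(block_states) @ self.coef + self.intercept


def fit_block_model(
    block_states: np.ndarray, log_phenotypes: np.ndarray, alpha: float | None = None
) -> BlockModel:
    """Fit the default block predictor on training subjects.

    ``block_states`` is (S_b, N_train); the phenotype is on the log
    scale throughout.  With ``alpha=None`` the penalty is chosen by GCV
    over :data:`ALPHA_GRID`.  A constant phenotype yields a constant
    predictor.
    """
    y = np.asarray(log_phenotypes, dtype=float)
    if block_states.shape[1] != len(y):
        raise ValueError("subject count mismatch")
    n = len(y)
    if n < 4:
        raise ValueError("need >= 4 training subjects")
    x = one_hot_states(block_states)
    ybar = float(y.mean())
    yc = y - ybar
    gram = x.T @ x
    evals, vecs = eigh(gram)
    evals = np.clip(evals, 0.0, None)
    b = vecs.T @ (x.T @ yc)
    if alpha is None:
        alpha = _gcv_alpha(evals, b, float(yc @ yc), n)
    coef = vecs @ (b / (evals + alpha))
    return BlockModel(coef=coef, intercept=ybar, alpha=float(alpha))


def trial_ratio(r_obs: float, r_null) -> float:
    """Relative predictive power exp(r_obs) / sum_p exp(r_null_p)."""
    r_null = np.asarray(r_null, dtype=float)
    if r_null.size == 0:
        raise ValueError("null correlation list must be non-empty")
    return float(np.exp(r_obs) / np.exp(r_null).sum())


@dataclass(frozen=True)
class BlockLikelihoods:
    """Winner fractions L_k over trials for one chromosome's blocks."""

    l: np.ndarray
    n_trial: int

    def __post_init__(self) -> None:
        if np.any(self.l < 0) or np.any(self.l > 1):
            raise ValueError("likelihoods must lie in [0, 1]")
        if self.l.sum() < 1.0 - 1e-9:
            raise AssertionError("winner fractions must sum to >= 1")


def _pearson_columns(preds: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each prediction column with y; 0 where undefined."""
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    pc = preds - preds.mean(axis=0)
    pnorm = np.linalg.norm(pc, axis=0)
    r = np.zeros(preds.shape[1])
    if ynorm > 0:
        ok = pnorm > 0
        r[ok] = (pc[:, ok].T @ yc) / (pnorm[ok] * ynorm)
    return np.clip(r, -1.0, 1.0)


def block_likelihoods(
    g: GenotypeMatrix,
    blocks: BlockPartition,
    phen: PhenotypeVector,
    n_trial: int = 1000,
    n_p: int = 20,
    seed: int = 0,
    alpha: float | None = None,
) -> BlockLikelihoods:
    """Score every block of a chromosome by its winner fraction L_k.

    Splits and training-phenotype permutations are shared across blocks
    within a trial so that blocks compete on identical data; within a
    (trial, block) pair the GCV penalty selected on the observed
    training phenotype is reused for the permuted null fits.  With an
    odd number of subjects the training half receives the extra one.
    """
    if n_trial < 1 or n_p < 1:
        raise ValueError("n_trial and n_p must be >= 1")
    n = g.n_subjects
    if n < 8:
        raise ValueError("need >= 8 subjects")
    if phen.n_subjects != n:
        raise ValueError("phenotype length does not match subjects")
    y = phen.raw  # log scale
    rng = np.random.default_rng(seed)
    designs = [one_hot_states(g.states[start:end]) for start, end in blocks.blocks]
    n_blocks = len(designs)

    wins = np.zeros(n_blocks)
    for _ in range(n_trial):
        perm = rng.permutation(n)
        n_test = n // 2
        test, train = perm[:n_test], perm[n_test:]
        n_train = len(train)
        y_te = y[test]
        ycols = np.empty((n_train, 1 + n_p))
        ycols[:, 0] = y[train]
        for p in range(n_p):
            ycols[:, 1 + p] = ycols[rng.permutation(n_train), 0]
        means = ycols.mean(axis=0)
        yc = ycols - means

        ratios = np.empty(n_blocks)
        for k, x in enumerate(designs):
            xtr, xte = x[train], x[test]
            evals, vecs = eigh(xtr.T @ xtr)
            evals = np.clip(evals, 0.0, None)
            b = vecs.T @ (xtr.T @ yc)  # (p, 1 + n_p)
            a = alpha
            if a is None:
                a = _gcv_alpha(evals, b[:, 0], float(yc[:, 0] @ yc[:, 0]), n_train)
            coefs = vecs @ (b / (evals + a)[:, None])
            preds = xte @ coefs + means
            r = _pearson_columns(preds, y_te)
            ratios[k] = trial_ratio(r[0], r[1:])
        wins[ratios >= ratios.max()] += 1.0

    return BlockLikelihoods(l=wins / n_trial, n_trial=n_trial)
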