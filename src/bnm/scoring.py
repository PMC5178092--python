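"""Per-SNP pseudo-probabilities and the end-to-end genome scan.

Treating each SNP s as a candidate model of the phenotype (one causative
SNP per chromosome, uniform prior), the phenotype-independent odds that
s is linked to block b are

    L0[s, b] = Q[s, b] / sum_{b' != b} Q[s, b'],
    Q[s, b]  = max_{s' in b, s' != s} M[s, s']

with M the fused similarity matrix.  The SNP's pseudo-probability r_s
is the Pearson correlation between the vector L0[s, .] and the
phenotype-dependent block likelihoods L, clamped below at zero; the
reported score is the R-value R(s) = 1 - max(0, r_s), with small values
indicating strong signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import BlockPartition, ClusteringConfig, select_kappa_eta
from .io import GenotypeMatrix, filter_missing, normalize_phenotype
from .likelihood import BlockLikelihoods, block_likelihoods
from .networks import genetic_distance_matrix, permutation_mutual_information


def interblock_odds(
    m: np.ndarray, blocks: BlockPartition, s: int, q_statistic: str = "max"
) -> np.ndarray:
    """Odds of SNP s against every block from inter-block similarities.

    ``q_statistic`` selects max (default) or mean of the similarities to
    the block's markers (excluding s itself; for a singleton block whose
    only marker is s the exclusion is waived rather than leaving Q
    undefined).
    """
    if blocks.n_blocks < 2:
        raise ValueError("need >= 2 blocks for inter-block odds")
    if not 0 <= s < blocks.n_markers:
        raise IndexError(s)
    reduce = {"max": np.max, "mean": np.mean}[q_statistic]
    q = np.empty(blocks.n_blocks)
    for k, (start, end) in enumerate(blocks.blocks):
        idx = [j for j in range(start, end) if j != s] or [s]
        q[k] = reduce(m[s, idx])
    total = q.sum()
    denom = total - q
    with np.errstate(divide="ignore"):
        return np.where(denom > 0, q / denom, np.inf)


def snp_pseudo_probability(l0: np.ndarray, l: np.ndarray) -> float:
    """Pearson correlation of the two block sequences, clamped at zero.

    Zero-variance sequences (and single-block chromosomes upstream)
    score 0 rather than propagating an undefined correlation.
    """
    l0 = np.asarray(l0, dtype=float)
    l = np.asarray(l, dtype=float)
    if l0.shape != l.shape or l0.ndim != 1 or len(l0) < 2:
        raise ValueError("need two equal-length sequences of >= 2 blocks")
    a = l0 - l0.mean()
    b = l - l.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0 or not np.all(np.isfinite(l0)):
        return 0.0
    r = float(a @ b / (na * nb))
    return max(0.0, min(1.0, r))


@dataclass
class ChromosomeScan:
    """Intermediate per-chromosome results, kept for inspection."""

    kappa: int
    eta: float
    partition: BlockPartition
    fused: np.ndarray
    likelihoods: BlockLikelihoods


def scan_chromosome(
    g: GenotypeMatrix,
    rho: np.ndarray,
    phen,
    cfg,
    seed_seq: np.random.SeedSequence,
):
    """Run the block pipeline on one chromosome; returns scores + detail."""
    s_mi, s_blocks, s_lik = (int(c.generate_state(1)[0] % 2**31) for c in seed_seq.spawn(3))
    d = genetic_distance_matrix(g.gmap)
    i = permutation_mutual_information(g.states, rho, n_perm=cfg.n_perm, seed=s_mi)
    ccfg = ClusteringConfig(
        s_min=cfg.s_min,
        t_max=cfg.t_max,
        kappa_grid=tuple(cfg.kappa_grid),
        eta_grid=tuple(cfg.eta_grid),
        snf_iterations=cfg.snf_iterations,
    )
    kappa, eta, part, fused = select_kappa_eta(d, i, ccfg, seed=s_blocks)
    lik = block_likelihoods(
        g, part, phen, n_trial=cfg.n_trial, n_p=cfg.n_p, seed=s_lik
    )
    scores = np.empty(g.n_markers)
    if part.n_blocks < 2:
        warnings.warn(
            f"chromosome {g.chromosome} collapsed to one block; scoring r_s = 0",
            stacklevel=2,
        )
        scores[:] = 0.0
    else:
        for s in range(g.n_markers):
            l0 = interblock_odds(fused, part, s, q_statistic=cfg.q_statistic)
            scores[s] = snp_pseudo_probability(l0, lik.l)
    detail = ChromosomeScan(
        kappa=kappa, eta=eta, partition=part, fused=fused, likelihoods=lik
    )
    return scores, detail


def scan(
    genotypes: dict[str, GenotypeMatrix],
    phenotype_raw: np.ndarray,
    config=None,
    seed: int = 0,
    details: dict | None = None,
) -> pd.DataFrame:
    """Genome scan: one row per SNP with r_s and R-value.

    ``phenotype_raw`` is the raw (log-scale) phenotype aligned to the
    genotype subjects.  Pass a dict as ``details`` to receive the
    per-chromosome :class:`ChromosomeScan` intermediates.
    """
    from .config import RunConfig

    cfg = config if config is not None else RunConfig()
    phen = normalize_phenotype(phenotype_raw, already_positive=cfg.already_positive)
    root = np.random.SeedSequence(seed)
    chroms = sorted(genotypes, key=lambda c: (len(c), c))
    streams = root.spawn(len(chroms))
    rows = []
    for chrom, seq in zip(chroms, streams):
        g = filter_missing(genotypes[chrom], cfg.max_missing_fraction)
        scores, detail = scan_chromosome(g, phen.rho, phen, cfg, seq)
        if details is not None:
            details[chrom] = detail
        for s in range(g.n_markers):
            rows.append(
                {
                    "chromosome": chrom,
                    "marker_id": g.gmap.marker_id[s],
                    "mb": g.gmap.mb[s],
                    "r_s": scores[s],
                    "r_value": 1.0 - max(0.0, scores[s]),
                }
            )
    df = pd.DataFrame(rows)
    df["_ck"] = df["chromosome"].map(_natural)
    df = df.sort_values(["_ck", "mb"], kind="stable").drop(columns="_ck")
    return df.reset_index(drop=True)


def _natural(label: str):
    return (0, int(label)) if str(label).isdigit() else (1, str(label))
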