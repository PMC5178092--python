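"""Synthetic genotypes with distance-decaying linkage and QTL phenotypes.

The genotype simulator emulates a dense outbred genotyping panel: each
chromosome carries equally spaced markers and every subject's genotype
is the sum of two independent haplotype chains.  A haplotype is a
two-state Markov chain along the chromosome whose stationary allele
frequency is ``allele_freq`` and whose marker-to-marker switch
probability equals the Haldane recombination fraction
``r = (1 - exp(-2 d / 100)) / 2`` for an inter-marker distance of d cM.
Genotype states follow the 0/1/2 dominant/het/recessive coding, with
state 3 injected independently at a configurable missing rate.

Phenotypes follow a sparse multi-locus model: one causative marker per
chromosome, additive dosage effects with exponentially distributed
effect sizes, the summed genetic component affinely scaled to sample
variance one, plus independent standard normal noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GeneticMap, GenotypeMatrix


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a phenotype simulation.

    ``causative`` lists one (chromosome, marker_id, effect_size) triple
    per chromosome with effect sizes on the scaled phenotype scale;
    ``qtl_component`` is the per-subject genetic effect after scaling
    (sample variance 1 unless all effects are zero); ``noise`` is the
    additive N(0,1) draw, so raw phenotype = qtl_component + noise.
    """

    causative: tuple[tuple[str, str, float], ...]
    qtl_component: np.ndarray
    noise: np.ndarray
    noise_sd: float = 1.0


def simulate_haplotypes(n_haplotypes: int, cm_positions, rng, allele_freq: float = 0.5) -> np.ndarray:
    """Draw haplotype alleles (0/1) along a chromosome.

    Transition between adjacent markers: with probability
    ``lam = r / (2 p (1-p))`` the allele is redrawn from the stationary
    Bernoulli(p), otherwise copied.  This satisfies detailed balance and
    makes the stationary switch probability exactly the Haldane r.
    """
    cm = np.asarray(cm_positions, dtype=float)
    p = float(allele_freq)
    if not 0.0 < p < 1.0:
        raise ValueError("allele_freq must be in (0, 1)")
    d = np.diff(cm)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    lam = r / (2.0 * p * (1.0 - p))
    if np.any(lam > 1.0):
        raise ValueError(
            "degenerate chain parameters: switch probability exceeds 1 "
            "(allele_freq too skewed for the requested marker spacing)"
        )
    s = len(cm)
    h = np.empty((n_haplotypes, s), dtype=np.int8)
    h[:, 0] = rng.random(n_haplotypes) < p
    for i in range(1, s):
        redraw = rng.random(n_haplotypes) < lam[i - 1]
        fresh = (rng.random(n_haplotypes) < p).astype(np.int8)
        h[:, i] = np.where(redraw, fresh, h[:, i - 1])
    return h


def simulate_genotypes(
    n_subjects: int,
    n_chromosomes: int = 19,
    markers_per_chromosome: int = 60,
    cm_length: float = 60.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    allele_freq: float = 0.5,
) -> dict[str, GenotypeMatrix]:
    """Simulate per-chromosome genotype matrices.

    Marker cM positions are equally spaced on [0, cm_length]; Mb
    positions default to cM/2, i.e. an average recombination rate of
    2 cM per Mb.  Each state is independently replaced by the missing
    code 3 with probability ``missing_rate``.
    """
    if n_subjects < 1 or n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("all counts must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cm = (
        np.linspace(0.0, cm_length, markers_per_chromosome)
        if markers_per_chromosome > 1
        else np.array([0.0])
    )
    out: dict[str, GenotypeMatrix] = {}
    for c in range(1, n_chromosomes + 1):
        chrom = str(c)
        h = simulate_haplotypes(2 * n_subjects, cm, rng, allele_freq)
        states = (h[:n_subjects] + h[n_subjects:]).T.astype(np.int8)  # (S, N)
        if missing_rate > 0:
            drop = rng.random(states.shape) < missing_rate
            states[drop] = MISSING
        gmap = GeneticMap(
            marker_id=np.array(
                [f"c{chrom}_m{i}" for i in range(markers_per_chromosome)]
            ),
            chromosome=chrom,
            cm=cm.copy(),
            mb=cm / 2.0,
        )
        out[chrom] = GenotypeMatrix(
            states=states,
            gmap=gmap,
            subject_ids=tuple(f"subj{j}" for j in range(n_subjects)),
        )
    return out


def _dosage(states: np.ndarray) -> np.ndarray:
    """Additive dosage per subject for one marker, missing imputed.

    Missing entries take the expected dosage under the marker's empirical
    state distribution among observed subjects.
    """
    d = states.astype(float)
    obs = states != MISSING
    if not obs.any():
        raise ValueError("marker has no observed states")
    d[~obs] = d[obs].mean()
    return d


def simulate_phenotypes(
    genotypes: dict[str, GenotypeMatrix],
    rate: float = 1.0,
    seed: int = 0,
    effect_sizes=None,
    causative_indices=None,
):
    """Simulate one quantitative phenotype with one QTL per chromosome.

    One causative marker is drawn uniformly per chromosome; effect sizes
    are exponential with the given ``rate`` (scale 1/rate) unless passed
    explicitly.  The summed centered-dosage effect is affinely scaled to
    sample variance 1 (ddof=1) and standard normal noise is added.

    Returns ``(raw_phenotypes, SimulationTruth)``; raw phenotypes are on
    the log scale the pipeline consumes.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    chroms = list(genotypes)
    if not chroms:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    n = genotypes[chroms[0]].n_subjects

    loci = []
    for i, chrom in enumerate(chroms):
        g = genotypes[chrom]
        if causative_indices is not None:
            idx = int(causative_indices[i])
        else:
            idx = int(rng.integers(g.n_markers))
        loci.append((chrom, idx))
    if effect_sizes is not None:
        betas = np.asarray(effect_sizes, dtype=float)
        if len(betas) != len(chroms):
            raise ValueError("need one effect size per chromosome")
        if np.any(betas < 0):
            raise ValueError("effect sizes must be >= 0")
    else:
        betas = rng.exponential(scale=1.0 / rate, size=len(chroms))

    genetic = np.zeros(n)
    for (chrom, idx), beta in zip(loci, betas):
        dos = _dosage(genotypes[chrom].states[idx])
        genetic += beta * (dos - dos.mean())

    sd = float(np.std(genetic, ddof=1)) if n > 1 else 0.0
    noise = rng.standard_normal(n)
    if sd <= 0:
        warnings.warn(
            "zero-variance genetic effect; falling back to pure-noise phenotype",
            stacklevel=2,
        )
        qtl = np.zeros(n)
        scaled = np.zeros(len(betas))
    else:
        qtl = (genetic - genetic.mean()) / sd
        scaled = betas / sd
    truth = SimulationTruth(
        causative=tuple(
            (chrom, genotypes[chrom].gmap.marker_id[idx], float(b))
            for (chrom, idx), b in zip(loci, scaled)
        ),
        qtl_component=qtl,
        noise=noise,
    )
    return qtl + noise, truth
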