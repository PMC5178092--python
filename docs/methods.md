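# Methods

## Model and pipeline

The package treats QTL mapping as a three-stage inference per
chromosome.  The central assumption throughout is that **at most one
block per chromosome carries a causative SNP**; multi-QTL chromosomes
are out of scope (their signal spreads over several blocks and the
winner-fraction likelihood dilutes).

**Stage 1 — phenotype-independent haplotype blocks.**  Two views of
marker similarity are fused: the genetic-map distance
`D[s,s'] = |cM_s − cM_s'|`, and the phenotype-weighted mutual
information `I` of the genotype state tables, averaged over
permutations of the normalized phenotype weights ρ.  The permutation
average removes the assignment of phenotype values to subjects while
retaining their empirical distribution: a skewed sampling of phenotypes
does not inject spurious marker–marker correlation, at the cost of some
power — a deliberately conservative estimator.  Missing states are
re-imputed from each marker's empirical state frequencies independently
at every permutation.  SNF cross-diffusion then merges the views; since
its kernel consumes dissimilarities, `I` enters as `max(I) − I` with a
zeroed diagonal (a monotone, parameter-free inversion; the kernel
requires zero self-dissimilarity).

**Stage 2 — block likelihoods.**  Blocks compete over repeated
half/half train–test splits.  All blocks of a chromosome share the same
split and the same training-phenotype permutations within a trial, so
the comparison is paired.  A block's trial score
`R_k = exp(r_k)/Σ_p exp(r^p_k)` normalizes its held-out prediction
correlation by its own permutation null, which compensates
block-specific overfitting (bigger blocks have more indicator columns
and a wider null).  `L_k` is the fraction of trials block *k* attains
the maximum `R`; ties count for all tied blocks, so `Σ_k L_k = 1`
exactly when winners are unique and slightly above 1 otherwise.

**Stage 3 — SNP pseudo-probabilities.**  For each SNP the inter-block
odds vector `L0[s,·]` (built from the fused similarity `M`, hence
phenotype-independent) is compared with the phenotype-dependent
likelihood vector `L` by Pearson correlation, clamped below at zero.
Negative raw correlations mean the SNP's linkage pattern is opposite to
the phenotype-implied pattern and carry no evidence; they are not a
sign of effect direction.  Chromosomes that collapse to a single block
cannot produce a correlation and score 0 with a warning.

## Block regression model

The per-block predictor regresses the log phenotype on one-hot state
indicators (three per marker), giving every genotype class its own
mean, so non-additive dosage effects (dominance, heterozygote
advantage) are representable.  The ridge penalty is selected per fit by
generalized cross-validation over the fixed grid
{1e-8, 0.1, 1, 10, 100} using the Gram-matrix eigendecomposition; GCV
ties resolve toward the stronger penalty.  Two consequences matter:

* a noiseless realizable signal drives GCV to the smallest penalty, so
  the model interpolates it (training error ~1e-8);
* on noisy data large blocks are shrunk hard, preventing their many
  collinear columns from overfitting the ~half-sized training set and
  from spuriously out-predicting small linked blocks.

The penalty chosen on the observed training phenotype is reused for
that block's permutation-null fits within the trial, keeping the
observed/null comparison on the same model.  Undefined correlations
(constant predictions, constant test phenotype) are set to 0.  Missing
genotypes leave all three indicators at zero and thus fall back to the
intercept.  The model is pluggable via `fit_block_model` / the `alpha`
argument.

## Synthetic data

The simulator emulates a dense outbred genotyping panel:

* **Haplotype chains.**  Each subject is the sum of two independent
  two-state Markov chains along the chromosome.  Between adjacent
  markers `d` cM apart the allele is redrawn from the stationary
  Bernoulli(p) with probability `λ = r / (2p(1−p))`, where
  `r = (1 − exp(−2d/100))/2` is the Haldane recombination fraction; the
  stationary switch probability then equals `r` exactly and the
  genotype marginals are Hardy–Weinberg ({0.25, 0.5, 0.25} at the
  default p = 0.5).  `λ > 1` (very skewed p with wide spacing) is
  rejected as a degenerate chain.
* **Map.**  Markers are equally spaced on [0, cm_length]; physical
  positions default to mb = cM/2 (≈2 cM/Mb, a mouse-like average).
* **Phenotype.**  One causative marker per chromosome, additive
  centered-dosage effects with exponential effect sizes (rate 1 by
  default, matching an effect-size range spanning ~1e-5 to ~10 over
  tens of thousands of draws), the *summed* multi-locus effect affinely
  scaled to sample variance 1 (ddof = 1), plus independent N(0,1)
  noise.  Scaling the joint effect (rather than per locus) is one
  reading of an ambiguous convention; it is the one consistent with
  reported effect sizes being the raw exponential draws.  Missing
  dosages are imputed with the marker's expected dosage, keeping
  `phenotype = qtl_component + noise` an exact identity.

What the simulator does **not** emulate: the 8-founder mosaic structure
of real Diversity Outbred genomes, sex effects and sex chromosomes,
epistasis, non-uniform marker spacing, genotyping error (missingness is
independent, not clustered).  Tests passing on this generator therefore
demonstrate the pipeline's statistical behaviour under idealized
linkage decay, not performance on real founder-mosaic data.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `n_perm` | 100 | permutations averaged into the phenotype-independent MI |
| `n_trial` | 1000 | train/test trials per chromosome |
| `n_p` | 20 | permutation-null fits per trial (its scale cancels in the winner comparison, so a modest value suffices) |
| `kappa_grid` | 10…15 | SNF neighbour counts searched |
| `eta_grid` | 0.3…0.7 | SNF kernel scales searched |
| `s_min` | 2 | minimum block size in the decomposition |
| `t_max` | 50 | iteration cap; also caps the split arity via `n_max = min(S_k // s_min, t_max)` |
| `snf_iterations` | 20 | cross-diffusion steps |
| `q_statistic` | max | reduction over a block's similarities in `Q_{s,b}` (`mean` available; results are insensitive) |
| `max_missing_fraction` | 0.5 | SNPs missing on more than this fraction of subjects are dropped |

## Numerical and procedural choices

* **Hierarchical splitting.**  Spectral clustering is the normalized
  (symmetric-Laplacian) variant on the similarity submatrix directly,
  with a seeded k-means++ stage; a quantile cut of the second
  eigenvector is the deterministic fallback if k-means repeatedly
  collapses a cluster.  "Contiguous" means contiguous in cM-sorted
  marker index.  A branch smaller than κ closes; otherwise the arity n
  escalates from 2 until all clusters are contiguous and ≥ `s_min`.
* **(κ, η) selection** minimizes the largest leaf block; ties break by
  fewer blocks at the maximal size, then more total blocks, then
  smallest (κ, η) lexicographically — fully deterministic.  The views
  are re-fused for every grid pair because κ enters the fusion itself.
* **Odds edge cases.**  A singleton block consisting only of SNP s
  itself would leave `Q_{s,b}` undefined; the self-exclusion is waived
  there (rare, since `s_min` = 2).  The SNP's own block is included in
  both correlated sequences.
* **Logs** are floored at 1e-300; exact-zero joint cells contribute 0
  to the mutual information, and the pairwise joint normalization
  `Σ_{αβ} P = 1` is asserted on every evaluation.
* **Randomness** flows from a single seed through named substreams
  (per-chromosome: imputation/MI, clustering, trials), so scans are
  bit-reproducible; with an odd subject count the training half takes
  the extra subject.
* **Evaluation.**  Calls are `score ≤ threshold` for R- and P-values
  alike; sliding windows drop partial tails (76 windows for both the
  4000/200 and 2000/100 configurations); windows with no calls report
  FDR as missing and are skipped when averaging for threshold matching;
  d-Mb bins are anchored at 0.

## Problem sizes used in the checks

The end-to-end recovery study runs 200 subjects, 19 chromosomes × 60
markers (60 cM ≈ 30 Mb each), one causative SNP per chromosome with
nominal effect sizes spanning 0.1–3, `n_trial` = 200 and `n_perm` = 30;
null calibration pools 20 seeds of two-chromosome scans at the same
geometry.  These sizes keep a full run in tens of seconds while leaving
the per-chromosome block structure (~10 blocks) representative.

## Known limitations

* Localization is block-resolution: within the winning block the
  ordering of `r_s` is phenotype-independent, so sub-block (≈2 Mb at
  the study geometry) localization is not informative.  With many
  jointly scaled weak loci, no per-marker method localizes much better
  — the dosage–phenotype correlation changes by less than sampling
  error across a block.
* Under a fixed pure-noise phenotype, chance sample correlation with
  some region behaves exactly like a weak QTL; low R-values under the
  null are therefore not a bug but finite-sample FDR, and they become
  rarer as the number of blocks per chromosome grows.
* One causative block per chromosome is assumed; opposite-sign linked
  effects and multi-QTL chromosomes are not handled.
* The (κ, η) grid search re-runs fusion and decomposition for each of
  the 30 pairs; for thousands of markers per chromosome this dominates
  runtime and would want coarsening.
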