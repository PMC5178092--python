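# bnm — Block Network Mapping for quantitative trait loci

`bnm` maps quantitative trait loci (QTL) by combining two sources of
marker similarity — genetic-map distance and an empirical, phenotype-independent
mutual-information network of SNP genotypes — into per-chromosome
*haplotype blocks*, scoring each block's predictive power against a
permutation null, and converting block scores into per-SNP
pseudo-probabilities through inter-block correlation odds.  It is aimed
at genome scans in dense outbred panels (for example Diversity Outbred
mice), where linkage between nearby markers both blurs single-marker
scans and carries usable structure.

## Method

Genotypes are biallelic SNP states per subject (0 = homozygous
dominant, 1 = heterozygous, 2 = homozygous recessive, 3 = missing).
Per chromosome:

1. **Similarity networks.**  A distance matrix
   `D[s,s'] = |cM_s − cM_s'|` and a phenotype-weighted mutual-information
   matrix

   `I[s,s'] = Σ_{αβ} P_{sαs'β} log( P_{sαs'β} / (P_{sα} P_{s'β}) )`,

   with joint cells weighted by normalized phenotype weights
   `ρ_m = w_m / Σ w_m'` and averaged over permutations of ρ (so *I*
   reflects linkage, not the phenotype), are fused by Similarity
   Network Fusion (SNF) into one similarity matrix *M*.
2. **Haplotype blocks.**  *M* is segmented into contiguous blocks by
   n-ary hierarchical spectral splitting; the SNF hyperparameters
   (κ neighbours, kernel scale η) are picked from a grid by minimizing
   the largest leaf block (the minimax criterion).
3. **Block likelihoods.**  Over repeated half/half train–test splits,
   every block fits a ridge regression of log phenotype on one-hot
   genotype indicators (penalty chosen per fit by generalized
   cross-validation) and is scored by
   `R_k = exp(r_k) / Σ_p exp(r^p_k)`, where `r_k` is the held-out
   Pearson correlation and `r^p_k` its value after permuting training
   phenotypes.  `L_k` is the fraction of trials block *k* wins.
4. **SNP scores.**  Phenotype-independent odds
   `L0[s,b] = Q_{s,b} / Σ_{b'≠b} Q_{s,b'}` with
   `Q_{s,b} = max_{s'∈b, s'≠s} M[s,s']` are correlated with the `L_k`
   sequence; the clamped Pearson correlation `r_s = max(0, corr(L0, L))`
   is the SNP's pseudo-probability and `R(s) = 1 − r_s` its reported
   score (small = significant).

A simulator (Markov-chain haplotypes with Haldane-map linkage decay,
exponential multi-locus QTL effects scaled to unit variance, N(0,1)
noise) and an evaluation harness (sliding effect-size windows,
power/FDR, ROC/AUROC, d-Mb block tolerance, FDR-matched threshold
pairing) make the whole pipeline testable end to end without external
data.

## Worked example

```python
import bnm

genotypes = bnm.simulate_genotypes(
    n_subjects=200, n_chromosomes=2, markers_per_chromosome=60,
    cm_length=60.0, missing_rate=0.02, seed=1)
y, truth = bnm.simulate_phenotypes(
    genotypes, seed=2, effect_sizes=[2.5, 0.3], causative_indices=[20, 40])

cfg = bnm.RunConfig(n_perm=30, n_trial=200, n_p=20)
scores = bnm.scan(genotypes, y, cfg, seed=3)
print(scores.nsmallest(5, "r_value").to_string(index=False))
```

```
chromosome marker_id        mb      r_s  r_value
         1    c1_m20 10.169492 0.980800 0.019200
         1    c1_m18  9.152542 0.975199 0.024801
         1    c1_m19  9.661017 0.973878 0.026122
         1    c1_m21 10.677966 0.945521 0.054479
         1    c1_m22 11.186441 0.925179 0.074821
```

The five lowest R-values all sit on chromosome 1 around 9–11 Mb, and
the top-ranked marker `c1_m20` is exactly the simulated causative SNP
(post-scaling effect 1.47 against unit noise); chromosome 2's much
weaker locus (0.18) does not rise above the background.  An R-value of
0.019 means the SNP's inter-block similarity pattern correlates at
`r_s = 0.98` with the observed block-likelihood profile.

The same pipeline is available from the shell:

```bash
bnm simulate --out run/ --n-subjects 200 --n-chromosomes 2
bnm scan --genotypes run/genotypes.csv --map run/map.csv \
         --pheno run/phenotypes.csv --out run/scores.tsv
bnm evaluate --scores run/scores.tsv --truth run/truth.tsv \
             --threshold 0.383 --out-prefix run/eval
bnm all --out run/          # the three stages in one command
```

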