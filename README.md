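# haplogp

Haplotype-block GWAS, yield-stability indices and genomic prediction for
multi-environment trials of inbred wheat lines.

Breeding programs evaluate advanced lines in yearly elite yield trials
(EYTs) across contrasting environments — optimum irrigation, drought,
heat — and need to know which genomic regions drive grain yield (GY) and
its stability, and whether those regions improve genomic selection.
`haplogp` implements that analysis end to end for fully inbred panels
genotyped with sparse SNP data (e.g. genotyping-by-sequencing):

- **Field adjustment**: moving-check correction of alpha-lattice plots
  (incomplete blocks with two repeated checks), adjusted entry means,
  factorial ANOVA and broad-sense heritability
  H² = σ²_G / (σ²_G + σ²_GE/e + σ²_ε/(e·r));
- **Stability**: Lin–Binns superiority index
  Pi = Σ_j (X_ij − M_j)²/(2E) and the Eberhart–Russell regression slope
  b_i on the environmental index;
- **Haplotype blocks**: pairwise D′ with likelihood-grid 95% confidence
  intervals; strong LD iff CI ≥ (0.6, 0.95); a contiguous span is a block
  when ≥ 95% of its informative comparisons are strong LD; blocks named
  `HB<chrom>.<serial>`; per-line multi-SNP allele calls with no
  imputation;
- **Association mapping**: mixed linear model y = Xb + mα + Zu + ε with
  BIC-selected principal components as fixed covariates and VanRaden
  kinship as the polygenic covariance (EMMA-style exact REML, P3D
  reuse per marker); omnibus haplotype tests; classification of hits into
  four cross-trial consistency groups;
- **Epistasis**: two- and three-locus interaction F-tests with
  sequential ΔR²;
- **Genomic prediction**: G-BLUP with four relationship matrices —
  G_M = MM′, G_H = HH′, and Gaussian kernels exp(−D/θ) on marker or
  haplotype scores — optional RKHS epistasis, GWAS-derived loci as fixed
  effects, Gibbs or closed-form REML inference, and paired whole-line
  90/10 cross-validation.

A synthetic-data module generates genotypes in founder-derived LD blocks,
alpha-lattice trials with planted QTL, epistasis and G×E, and known ground
truth, so the whole pipeline runs and is tested without any field data.

## Worked example

Simulate one trial year of 300 lines under five environments with a
multi-allelic block QTL at 20% of the genetic variance, then run the
pipeline:

```python
import pandas as pd
import haplogp as hg
from haplogp.simdata import Qtl, SimConfig

cfg = SimConfig(
    n_lines=300, n_chrom=3, snps_per_chrom=60,
    founder_haplotypes_per_block=4, missing_rate=0.05,
    qtl_spec=[Qtl(2, 1.0, 0.20, level="block")],
    h2_target=0.5, seed=11,
)
geno = hg.simulate_genotypes(cfg)
records, truth = hg.simulate_trials(geno, cfg)

adj = hg.adjust_gy_block_effects(records)
h2 = hg.broad_sense_h2(records)
print(f"broad-sense H2 (EYT1): {h2['EYT1']:.2f}")

stab = hg.stability_results(adj, "EYT1")
corr = hg.stability_vs_mean(stab)
print(f"corr(mean GY, -Pi): {corr['corr_mean_negPi']:.2f}")

filt = hg.filter_snps(geno)                      # <=40% missing, MAF>=0.15
blocks = hg.build_blocks(filt)
H = hg.call_haplotypes(filt, blocks)
print(f"{filt.n_snps} SNPs -> {len(blocks)} haplotype blocks "
      f"({H.n_columns} common alleles)")

K = hg.vanraden_kinship(filt)
y = adj.values[("EYT1", "B-5IR")]
res = hg.mlm_scan_hap(y, H, K, trial=("EYT1", "B-5IR"))
top = res.nsmallest(1, "p_value").iloc[0]
print(f"top block {top['locus']}: p={top['p_value']:.2e}, R2={top['r2']:.3f}")

y_all = adj.values.droplevel(0, axis=1)
m1 = hg.cross_validate(hg.ModelSpec.from_id(1, epistasis=False),
                       y_all, [hg.kernel_additive(filt)],
                       repeats=20, seed=1, backend="reml")
cols = [i for i, b in enumerate(H.columns["block"]) if b == top["locus"]]
fixed = pd.DataFrame(H.scores[:, cols[1:]], index=H.line_ids,
                     columns=[f"c{i}" for i in cols[1:]])
m4 = hg.cross_validate(hg.ModelSpec.from_id(4, epistasis=False),
                       y_all, [hg.kernel_gaussian(H)], fixed_loci=fixed,
                       repeats=20, seed=1, backend="reml")
comp = hg.compare_models([m1, m4])
print(f"CV accuracy: base {m1.mean:.3f}, hap+fixed {m4.mean:.3f} "
      f"({comp.loc[1,'pct_change_vs_base']:+.1f}%)")
```

Output:

```
broad-sense H2 (EYT1): 0.49
corr(mean GY, -Pi): 0.97
178 SNPs -> 43 haplotype blocks (142 common alleles)
top block HB1.5: p=1.06e-04, R2=0.060
CV accuracy: base 0.220, hap+fixed 0.282 (+28.3%)
```

Reading it: the tuned residual reproduces the target heritability; the
superiority index ranks lines almost exactly as mean yield does (low Pi =
high and stable); the filtered SNPs collapse into blocks of a few markers
each; the haplotype scan flags the block containing the planted QTL
(HB1.5 here); and supplying that block's alleles as fixed effects on top
of the Gaussian haplotype kernel raises cross-validated prediction
accuracy over the base marker G-BLUP on identical splits. Accuracies are
pooled within-environment correlations on held-out lines, so they measure
genetic signal, not environment means.

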