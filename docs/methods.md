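# Methods

`haplogp` implements an analysis pipeline for grain yield (GY) and yield
stability in multi-environment trials of fully inbred wheat lines:
check-based field adjustment, haplotype-block construction from linkage
disequilibrium, mixed-linear-model association mapping on single SNPs and
haplotype blocks, stability indices, epistasis scanning, and genomic
prediction with four kernel models that can carry GWAS-derived loci as
fixed effects. A synthetic-data generator with full ground truth stands in
for field and genotyping-by-sequencing (GBS) data, so every stage is
testable offline.

## Phenotypic adjustment and heritability

Plot-level GY from an alpha-lattice layout (incomplete blocks inside
replicates, two repeated check entries in every block) is adjusted with a
moving-check correction: within each replicate of each trial (trial = one
trial-year cohort, "EYT", crossed with one environment), every value in an
incomplete block is shifted by −(block check mean − trial check mean), and
entry means are taken over replicates. Only check values drive the
correction; a block without a check plot is an error. Covariate traits
(days to heading DH, plant height PH) are put on one scale across trials
with Y = (Y_ij − Y_i) + Y_all, where Y_i and Y_all are the trial and
global check means.

The factorial ANOVA (Rep, Geno, Env, Geno×Env, Residuals) treats all
factors as fixed, with every F against the single residual mean square.
Sums of squares are computed from marginal and cell means — exact under
balance, available-case otherwise — because designs at this scale have
thousands of Geno×Env levels and dense design matrices are impractical.
Broad-sense heritability on an entry-mean basis uses the expected mean
squares of that fit:

    H² = σ²_G / (σ²_G + σ²_GE/e + σ²_ε/(e·r)),
    σ²_ε = MS_res,  σ²_GE = (MS_GE − MS_res)/r,  σ²_G = (MS_G − MS_GE)/(e·r)

with e environments and r replicates; negative component estimates are
clipped at zero with a warning and H² is clipped to [0, 1].

## Stability indices

Lin–Binns superiority index Pi_i = Σ_j (X_ij − M_j)² / (2E), with M_j the
best entry mean in environment j and E the number of environments. The 2E
denominator follows Lin & Binns (1988); a 2(E−1) variant exists in the
literature, so this choice is stated prominently. Eberhart–Russell
stability is the regression slope b_i of a line's means on the
environmental index I_j (environment mean − grand mean), reported together
with the deviation mean square (E−2 denominator); b ≈ 1 denotes average
stability. `stability_vs_mean` correlates mean GY with −Pi and with b so
that positive values read "higher yielding lines are also superior".

## Haplotype blocks

Lines are treated as fully inbred: residual heterozygous calls are noise
and count as missing, so haplotype phase is known from homozygous calls.
SNPs are filtered at ≤ 40% missing data and MAF ≥ 0.15 (both bounds
inclusive for retention). For a SNP pair, D′ = |D|/D_max is computed from
the 2×2 haplotype counts, and its confidence interval from the multinomial
likelihood of |D′| on a grid of 101 points with allele frequencies fixed
at their observed values; the bounds cut 5% of cumulative likelihood from
each side, the convention of the Haploview/Gabriel confidence-interval
method (the grid resolution is configurable). Pairs are classified strong
LD iff CI_low ≥ 0.6 and CI_high ≥ 0.95; strong recombination iff
CI_high < 0.9 (the Gabriel convention — only the strong-LD thresholds are
inherent to the method; the 0.9 bound is configurable); otherwise
inconclusive. A contiguous span of ≥ 2 SNPs becomes a block when ≥ 95% of
its informative (non-inconclusive) pairwise comparisons are strong LD;
spans are accepted greedily, longest first and leftmost on ties, without
overlap, and capped at 50 SNPs by default for tractability. Blocks are
named `HB<chrom>.<serial>` with serials in positional order.

Haplotype calling concatenates the member-SNP bases per line; a line with
any missing member SNP is missing for that block (no imputation), and
alleles rarer than 0.05 among called lines are pooled into a rare class
with no incidence column (the floor mirrors the per-trial-year MAF ≥ 0.05
reasoning behind the 0.15 SNP filter and is configurable). The binary
incidence matrix H is the strict call used for association testing. A
soft companion (`HapMatrix.scores`) holds, for uncalled lines, the allele
probabilities conditional on whichever member SNPs were observed (allele
frequencies restricted to compatible alleles); it exists solely so
relationship matrices and fixed-effect columns do not treat an uncalled
block as "shares nothing", the haplotype analogue of frequency-centered
zeros for missing marker dosages.

## Association mapping

The per-trial model is y = Xb + mα + Zu + ε with u ~ N(0, K σ²_g): fixed
covariates (intercept, principal components, optionally line-level DH/PH
means and major-gene markers), a marker or haplotype term, and a random
polygenic term with VanRaden kinship K = ZZ′/(2Σp(1−p)) on
frequency-centered alt-allele dosages (missing dosages contribute zero;
on a fully inbred panel the diagonal averages ≈ 2 on this outbred scale).
The number of principal components (0..max) minimizes the BIC of the
phenotype-on-PCs regression. REML is exact on the null model through a
single eigendecomposition of K; the fitted variance ratio is reused for
every marker (the P3D/EMMAX approximation, the default), with exact
per-marker REML behind `p3d=False`. Marker R² is the share of the
covariate-residualized, whitened phenotype sum of squares explained.

Haplotype blocks are tested with an omnibus F-test of the (a−1) common
allele incidence columns (most frequent allele as reference; uncalled
lines enter through their soft dosages; lines carrying only rare alleles
fall to the reference level — an approximation tied to the 0.05 floor).
Per-allele effects are descriptive: allele mean minus block mean, absolute
and as % of the trial mean. Because a member SNP's dosage is an affine
combination of the block's incidence columns, the block omnibus R² is at
least any member SNP's R² on the same data.

The default significance threshold is Bonferroni at α = 0.05 over tested
loci — the analysis this mirrors does not state its cutoff, so the
threshold is configurable and prominently surfaced. Multiple testing is
not combined across trials; only the consistency classification
aggregates: a significant locus is (1) confined to one trial year, (2) in
one environment across years, (3) in several environments of each of
several years, or (4) across years in varying environments.

## Epistasis

Locus pairs (or triples) are scanned by OLS on adjusted means, each locus
a categorical factor. The pair model tests the full interaction block over
the main effects; the triple model holds all mains and two-way terms and
tests the three-way block, isolating genuine third-order signal. ΔR² is
sequential (mains first). Tuples with any genotype-combination cell under
5 observations are skipped. Kinship is deliberately absent from this scan
(it operates on adjusted means, as interaction screens in this literature
typically do); the significant-locus sets from the GWAS bound the search
space, and genome-wide scans prune to one locus per block.

## Genomic prediction

The model is y = Xb + Zu + ε with u ~ N(0, G σ²_g), y stacking adjusted
means over the environments of one trial year and X carrying one intercept
per environment plus optional GWAS-derived locus columns (marker dosages
for Model 3; haplotype incidence with the reference allele dropped for
Model 4; collinear columns pruned with a warning). Four relationship
matrices: G_M = MM′ on {1, 0, −1} codes; G_H = HH′ on haplotype incidence
(shared-allele counts); and Gaussian kernels G_ij = exp(−D_ij/θ) with
D the Euclidean distance on marker scores normalized by 1/(4m) — marker
codes differ by at most 2 — or on haplotype scores normalized by 1/m, so
D ∈ [0, 1] in both cases (the 1/(4m) normalizer is written for marker
scores; binary haplotype scores need 1/m to span the unit interval).
θ defaults to the median off-diagonal distance, a self-tuning choice since
no value is prescribed. G_M and G_H are scaled to unit mean diagonal by
default; kernels are bent (eigenvalue floor 1e-6) if numerically non-PSD.
An epistasis term enters as an additional Gaussian-kernel random effect
(RKHS regression).

Balanced multi-environment stacks are collapsed exactly: environment
intercepts are the training-line environment means, and the mixed model
runs on centered per-line means (residual variance σ²_ε/e on that scale).
This is exact for whole-line cross-validation on balanced designs and
makes each fit an n_lines-sized problem. Inference is a Gibbs sampler
(flat priors on fixed effects, scaled-inverse-χ² priors with ν = 5 and
prior modes splitting half the phenotypic variance across kernels and half
to the residual), run through each kernel's eigenbasis so every update is
diagonal; 6,000 iterations with 1,000 burn-in by default, deterministic
under a fixed seed, with a divergence guard at 10⁶ × phenotypic variance.
A closed-form REML backend (profiled single eigendecomposition) is
available for single-kernel models and matches the Gibbs posterior mean to
high accuracy; it is the natural choice inside large cross-validation
loops. Held-out lines are predicted by projecting the fitted genetic
values through the kernel (K_test,train α).

Cross-validation holds out whole lines — all their environment records —
per repeat (the stricter CV1 reading; record-level splitting would leak a
line's other environments into training), refits, and scores the Pearson
correlation between observed and predicted test records *after centering
each environment*: raw stacking across environments is dominated by the
known environment means and saturates near 1, whereas the within-
environment correlation measures genetic signal and lands on the 0.2–0.45
scale such models realistically achieve. Model comparisons require
byte-identical split sequences (asserted by split-hash equality) and
report paired differences with an LSD from the paired-repeat variance.

## Synthetic data

The generator emulates the study conditions the analysis assumes.
Genotypes: fully homozygous lines coded {1, −1}; each chromosome is a
sequence of LD blocks of 2–9 SNPs drawn from a pool of 2–4 founder
haplotypes (Dirichlet founder frequencies), so within-block D′ is high and
between-block LD ≈ 0; all MAF ≥ 0.15 by rejection sampling (a pool too
small to satisfy the floor — e.g. a single founder — is an explicit
error); optional uniform missingness (default 5%, GBS-like after
filtering) exercises the missing-data paths.

Phenotypes: plot value = environment mean + replicate effect +
incomplete-block effect + genetic value + residual, laid out as an alpha
lattice with 2 checks in every incomplete block; check lines carry fixed
genetic values not driven by any QTL. Default environment means (7000,
6700, 3900, 2500, 3500 kg/ha) follow the published per-environment means
of the five regimes (optimum bed/flat irrigation, mild and severe drought,
heat). The genetic value per line and environment is polygenic background
+ additive QTL + planted two-locus epistasis + a normal line×environment
deviation (the true G×E distribution in field data is unknown; normal is
a stand-in, not an inference). The polygenic background attaches iid
effects to founder haplotype alleles per block (local haplotypes as the
functional units — the premise of a haplotype-centric analysis), with an
iid-per-marker alternative behind `polygenic_basis="markers"`. QTL can be
single SNPs or whole blocks; a block-level QTL gives every founder
haplotype its own drawn effect, a multi-allelic architecture that
biallelic markers tag only partially. Blocks carrying a planted QTL are
excluded from the polygenic background so a QTL's variance share is
exactly its locus's contribution and recoverable by OLS. Per-environment
QTL effect patterns (constant, one-hot, arbitrary) produce "consistent"
versus "environment-specific" associations.

The residual SD is tuned analytically so the across-environment
entry-mean H² (the formula above) hits `h2_target` (default 0.5, the
middle of the published 0.27–0.63 range); infeasible targets are clamped
with a warning and the realized value recorded in `SimTruth`. Everything
is bit-reproducible under a fixed seed.

What the generator does not emulate: spatial field trends beyond
incomplete-block effects, genotyping error and allele-calling bias,
pedigree/family structure between trial years (population structure
arises only from founder-pool frequencies), selection between cohorts,
and non-normal G×E. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical structure, not robustness to every
property of real field data.

## Problem sizes in the test suite and acceptance script

Simulation-based checks run at desk scale, chosen as the smallest sizes at
which the tested signal is unambiguous: 100–500 lines, 24–2,000 markers,
5 environments, 10–50 seeds, 15–20 cross-validation repeats; the paired
model-comparison check uses the REML backend. The acceptance script
simulates 2 trial years × 400 lines × 400 SNPs and reports heritability,
block counts, association and consistency-group counts, the Pi–yield
correlation, the epistatic ΔR², and paired cross-validated accuracies of
the base marker model versus the haplotype model with GWAS-derived fixed
haplotypes.

## Known limitations

- The GY check adjustment is the additive moving-check correction; the
  original GLM-based adjustment is not recoverable from its description.
- P3D reuses the null-model variance ratio per marker; p-values drift
  slightly from exact per-marker REML (available but slower).
- Proximal contamination: a tested marker also sits in the kinship, which
  shrinks its own signal; leave-one-chromosome-out kinship is the
  standard workaround and is easily composed from `subset_snps`.
- The Gibbs sampler assumes the collapsed balanced representation;
  unbalanced environment coverage within a trial year is approximated by
  available-case means upstream.
- Lines carrying only rare haplotype alleles fall to the reference level
  in the omnibus test rather than forming their own class.
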