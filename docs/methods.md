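# Methods

This note documents the models behind each pipeline stage, the
synthetic-data generator they are exercised on, and the numerical and
design choices that were genuinely open.

## Synthetic study design

The generator emulates a diversity panel of a dioecious, clonally
propagated crop: `n_landraces = 86` farmer landraces plus
`n_elite = 16` elite checks, genotyped at `n_markers = 4432` biallelic
SNPs spread unevenly (Dirichlet-sampled proportions, at least one
marker each) over 20 chromosomes, phenotyped for five traits in a
two-season × two-replicate trial.

**Genotypes.** Ancestral allele frequencies are drawn from
Beta(1.4, 6) clipped to [0.02, 0.98], giving the low-MAF-skewed
spectrum typical of reduced-representation genotyping. Each of
`K_true = 3` clusters gets frequencies from the Balding–Nichols
distribution Beta(p(1−F)/F, (1−p)(1−F)/F) with `F = fst_target`
(default 0.15), so the realized Weir–Cockerham Fst between pure
clusters tracks the divergence parameter (verified: realized ≈ 0.148 at
target 0.15). Pure samples have one-hot ancestry rows; a fraction
`admix_fraction = 6/86` get Dirichlet(1.5) rows. Dosages are
Binomial(2, Σ_k Q_ik f_km) — Hardy–Weinberg within ancestry, which a
clonal panel need not satisfy (see Limitations). Missingness is
missing-completely-at-random at 3 %; read depth is Poisson with mean
12, used only to exercise the depth filter.

**Sex and flowering.** Samples are labeled female / male /
nonflowering by largest-remainder rounding of the configured fractions
within each role stratum, then seeded shuffling. Defaults are the
reference design's landrace accounting (25 female, 36 male, 25
nonflowering of 86), so the default panel yields exactly
25 × 36 = 900 feasible landrace crosses.

**Phenotypes.** Each trait has `qtl_per_trait = 25` QTL; a fraction
`qtl_overlap = 0.4` come from a pool shared across traits with
identical latent effects, which induces positive genetic correlation.
Additive effects are N(0, 1); dominance effects N(0, 0.3²) and apply
only to heterozygotes (genotypic coding {−a, d, a}). The summed genetic
value is standardized and rescaled so that on the trait's natural scale
Vg = H²·sd² and the plot residual variance is (1−H²)·sd²; H² here is
the plot-basis broad-sense heritability Vg/(Vg+Ve), with per-trait
targets 0.43 / 0.33 / 0.39 / 0.44 / 0.47 (yield, YMV AUDPC, vigor,
oxidation, dry matter). Season and rep-within-season effects are
additive normal blocks (25 % and 10 % of the trait SD); the alpha
lattice of a real trial is simplified to this randomized complete block
because block incidence is never used downstream. Trait means/SDs
follow the reference study's scales, except tuber oxidation, whose
printed mean (0.02) makes coefficients of variation meaningless; the
generator uses mean 1.0, SD 0.55 on the 0–3 score scale. Vigor and
oxidation are kept continuous rather than ordinal so
variance-component recovery is clean; real field scores are coarser.

**What passing tests do and do not show.** Markers are exchangeable
given ancestry — there is no linkage-disequilibrium decay — so
single-marker GWAS hits are not smeared across neighbors as in real
data, and power estimates are optimistic. Genotypes are HWE within
cluster, whereas clonal landraces often carry excess heterozygosity
(the reference panel has Ho < He). Recovery results therefore validate
the estimators' algebra and calibration, not their behavior under
linkage or inbreeding.

## QC and diversity

Filters run depth → missingness → MAF: cells with depth < 5 are set
missing, markers with > 10 % missing calls are dropped, then markers
with MAF < 1 % (computed on nonmissing calls, matching standard
VCF-tool behavior) are dropped. Imputation is modal with ties broken
toward the smaller dosage; a seeded allele-frequency Bernoulli imputer
is available for sensitivity checks. Genotype-likelihood imputation is
out of scope — modal filling is sufficient for the downstream algebra.

Per site with alternate-allele frequency p: Ho is the heterozygote
fraction, He = 2p(1−p), MAF = min(p, 1−p), PIC = 1 − p² − q² − 2p²q²
(Botstein), and gene diversity is the Nei small-sample estimator
(n/(n−1))(1 − p² − q²). He and gene diversity coincide up to the
n/(n−1) factor for biallelic sites; both are reported under explicit
labels because field summaries often print the two from different
software defaults. Chromosome rows are unweighted site means; the
Average row is the unweighted mean of chromosome rows.

## Population structure

PCA is a plain SVD of the column-centered dosage matrix (unit-variance
scaling optional), with each component's sign fixed so its
largest-magnitude loading is positive.

The cluster count is chosen by k-means (10 seeded restarts) on the
leading principal components with BIC(k) = n ln(WSS_k/n) + k ln(n),
k_opt = argmin. **PC retention matters:** with only a handful of PCs
the BIC tail stays flat and the argmin drifts; retaining up to 40 PCs
(the find-clusters convention of keeping many components) makes the
argmin recover the true k in ≥ 80 % of seeds at Fst 0.15, n = 90,
m = 2000. The full curve is returned so an elbow can be read as well.

The admixture model maximizes
L = Σ_im [x_im ln π_im + (2−x_im) ln(1−π_im)], π = QF, by standard EM
block updates of Q (ancestry proportions) and F (cluster frequencies,
clamped to [1e−6, 1−1e−6]), initialized from k-means labels softened to
0.9. The log-likelihood is monotone; non-convergence within `max_iter`
returns the best iterate with a flag rather than raising, since the
tail gains are negligible for assignment. Membership uses the 70 %
rule with the boundary counting as assigned (max Q ≥ 0.70).

Distances: `one_minus_ibs` is d = mean |x_i − x_j|/2; `jaccard`
binarizes to alternate-allele presence and is set-based over markers
where either sample carries the allele. Both are offered because field
workflows use either for Ward clustering; the pipeline default is
1−IBS. Ward linkage comes from the Lance–Williams recursion (SciPy)
after a deterministic sample-id sort; Newick branch lengths are merge-
height differences.

AMOVA uses the Excoffier sums of squares from squared distances
(SS_total = Σ_{i<j} d²/N and the within-group analogue), variance
components from the mean squares with
n̄ = (N − Σn_g²/N)/(G−1); negative components are truncated to zero for
the percentage column only, the raw values stay in the table. Fst is
the Weir–Cockerham two-population θ from the a, b, c components with
observed heterozygote counts; per-locus values are kept signed and the
multi-locus estimate is Σa/Σ(a+b+c).

## Trial model and genetic parameters

Genotype means come from value = μ + genotype + env + error with env
the season × rep block: BLUEs are least-squares adjusted means
(predictions averaged over env levels), BLUPs shrink them by
Vg/(Vg + Ve/r_g). Variance components use expected mean squares,
Vg = (MS_genotype − MS_error)/r with r the harmonic mean of plot
counts, and switch to REML (random-genotype mixed model) when counts
vary by more than 10 %. Derived parameters: Vp = Vg + Ve,
H² = Vg/Vp, CVg = 100√Vg/mean, CVp = 100√Vp/mean. The narrow-sense h²
is the REML variance proportion of a kinship mixed model on genotype
means — a genomic definition, chosen because clonal panels have no
pedigree. Reference studies sometimes print H² values inconsistent
with their own Vg/Vp; this package implements the standard plot-basis
ratio and labels it in output headers rather than reverse-engineering
an undisclosed formula.

## GWAS

The kinship is VanRaden's K = MM′/(2Σp(1−p)) with M = dosage − 2p.
The scan eigendecomposes K once, estimates δ = σe²/σg² by REML under
the null model (intercept + 3 structure PCs by default, matching
K = 3) on a ln δ grid over [−10, 10] step 0.1 with bounded local
refinement, and tests each marker by GLS in the rotated space where
the covariance is diagonal (S + δ). δ is held at the null value across
markers (population parameters previously determined); exact
per-marker REML sits behind a flag. Wald t p-values use n − p degrees
of freedom, so with K = I and no PCs the scan reproduces ordinary
regression exactly. Calibration on unstructured nulls gives type-I
error 0.043–0.046 at nominal 0.05; on structured nulls the naive scan
inflates to λ ≈ 4 while the mixed model stays at λ ≈ 1. Significant
SNPs are re-fit jointly; per-SNP R² is the incremental (type-I) sum of
squares in marginal-p order — one documented choice among several
possible attributions.

## Merit index

Per-trait genomic BLUPs feed a principal-component factor analysis of
their correlation matrix: factors with eigenvalue > 1 are retained (at
least one), loadings are varimax-rotated (SVD formulation, tol 1e−8),
communalities are rotation-invariant by construction, and scores use
the regression method Z R⁻¹Λ. The FAI index is the Euclidean distance
from a genotype's rotated score vector to an ideotype; per-factor
contributions are the squared distance components. Two open choices
are resolved as follows: the ideotype coordinate on each factor is the
*observed* score extreme (not a theoretical ±max loading), taken in
the direction favored by the desirability-weighted loadings of that
factor (defaults: yield +, vigor +, dry matter +, YMV −, oxidation −);
and the primary output is the raw distance (lower = better), which
matches the reported scale of FAI-type indices, with a normalized
1/distance probability transform behind a flag. Selection gains are
selected-minus-population means of the genetic values with
desired-direction flags.

## Cross prediction

Marker effects come from a two-kernel REML mixed model. The designs
use the orthogonal parametrization — additive x − 2p (breeding
values), dominance {−2p², 2pq, −2q²} (dominance deviations) — because
with the classical heterozygote-indicator coding the two kernels are
nearly collinear on a low-MAF spectrum (a rare allele's dosage almost
equals its heterozygote indicator) and the variance split is not
identifiable; in additive-only simulations the classical coding leaked
up to 3.7× the additive norm into dominance, while the orthogonal
coding keeps ‖d̂‖/‖â‖ well below 0.3. REML maximizes the restricted
likelihood over (σa², σd², σe²) by Nelder–Mead on log variances;
back-solved substitution effects α and deviations δ convert to
genotypic effects via d = δ, a = α − d(1 − 2p). A dominance variance
at the zero boundary (< 1e−4 of the total) zeroes d with a flag.

The F1 mean per marker is the Falconer population-mean form
M = a(p − q − y) + d[2pq + y(p − q)], p = parent-1 dosage/2,
y = p − p′. The dominance term uses y(p − q): this is the algebraically
correct form — it reproduces the genotype-frequency enumeration
a(pp′ − qq′) + d(pq′ + p′q) exactly for all nine diploid parent-pair
combinations and satisfies the AA × aa = d identity — whereas the
y(q − p) variant seen in print fails that identity; the printed form
is available behind `strict_compat`. Predictions are symmetric in the
parents; sex only gates enumeration (all female × male pairs among
flowering parents). Total cross merit is the desirability-weighted sum
of z-scored predicted F1 means across crosses — the z-scoring is this
package's definition, since "total cross merit" has no standard
formula — and parents are summarized by mean merit and the count of
positive-merit partners.

## Problem sizes and determinism

Tests and the acceptance script run simulations at the scales that make
their statistics stable: structure recovery at n = 90, m = 2000 over
10–20 seeds; GWAS calibration pooling 5,000 marker tests; heritability
recovery over 10–20 seeds at n = 100 with 4 plots each. All randomness
flows through numpy Generators seeded from a single configuration seed
(per-stage streams derived via CRC-tagged SeedSequences), so every
artifact is bit-reproducible under a fixed seed.

## Known limitations

- No linkage disequilibrium, ordinal trait scales, genotype-likelihood
  imputation, or inbreeding in the generator (see above).
- The admixture EM converges slowly near the optimum (tol on the
  log-likelihood increment); assignments stabilize long before the
  likelihood does.
- AMOVA significance is not tested (no permutation p-values); the
  table reports the variance partition only.
- The merit index depends on the observed-extreme ideotype, so adding
  or removing genotypes can move everyone's index value.
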