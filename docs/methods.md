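# Methods

This note records the statistical models the package implements, the
defaults and why, what the simulators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Genotype model and file handling

A dataset is a samples × SNPs matrix of B-allele dosages (0/1/2, −1 for
missing) plus a SNP map and per-sample population labels. Per SNP the
(A, B) alleles are assigned as (major, minor) by observed frequency with a
lexicographic tie-break, so MAF = mean(dosage)/2 in the coding population
and dosage 2 is the minor-allele homozygote. PED/MAP is the only on-disk
format (PLINK text dialect, gzip-transparent); the MAP genetic-position
column is read and ignored — physical bp positions drive every distance.
Half-called genotypes ("A 0") are treated as missing with a warning.
Merging keeps the intersection of SNP ids, anchors the A/B assignment to
the first cohort (flipping dosages x → 2−x where a later cohort assigned
the alleles the other way), and refuses to strand-flip: cohorts genotyped
on the same chip share strand by construction, so a genuinely incompatible
allele pair is an error, not something to repair silently.

## Quality control

The cascade is sample call rate ≥ 0.95, then per-SNP call rate ≥ 0.95,
MAF ≥ 0.05 (strictly-below removed; exactly 0.05 kept), and exact
Hardy-Weinberg p ≥ 0.001, each stage evaluated on the survivors of the
previous one. The HWE test is the exact conditional test: given the allele
counts, the heterozygote count has probability proportional to
n!/(n_AA! n_AB! n_BB!) · 2^{n_AB}, and the two-sided p-value sums all
outcomes no more probable than the observed one (no mid-p). Monomorphic
loci return p = 1 by convention and fall to the MAF filter instead. A SNP
failing several criteria is counted under the first one it fails, which
makes the per-criterion report columns a partition of the removed markers
(report headers state this, since exclusion tables in the literature do not
always say whether their columns overlap).

## Linkage disequilibrium

Haplotype frequencies for a SNP pair are the maximum-likelihood estimates
under random union of gametes, obtained by EM on the 3×3 joint dosage
table: every genotype combination except the double heterozygote fixes its
two haplotypes, and the double-het mass is split between cis and trans
configurations in proportion to p_ab·p_AB vs p_aB·p_Ab at each E-step.
Allele-frequency margins are fully observed from dosages and are preserved
by the updates, so the only free parameter is the coupling frequency.
Initialisation is at linkage equilibrium; convergence when no frequency
moves by ≥ 1e−10, capped at 1 000 iterations. The likelihood is unimodal
in practice; a grid-search maximizer over p_ab serves as the independent
oracle in the tests. Missing data are handled pairwise-complete (samples
missing either genotype are dropped for that pair) rather than imputed.

From the fitted frequencies: D = p_ab − p_a p_b,
r² = D²/(p_a(1−p_a)p_b(1−p_b)), and D′ = |D|/D_max with
D_max = min(p_a p_b, (1−p_a)(1−p_b)) for D < 0 and
min(p_a(1−p_b), (1−p_a)p_b) otherwise; |r| ≤ D′ always holds and is
asserted over all computed pairs in the tests.

Pruning follows the windowed scheme (window 50 SNPs, step 5, threshold
r² > 0.2) with a deterministic removal rule the upstream tools leave
unspecified: the lower-MAF member of a violating pair is dropped, ties
dropping the later map position. Decay tables use half-open distance bins
[lo, hi) over the 0–10/10–20/20–40/40–60/60–100/100–200/200–500/500–1000 kb
grid (half-open because the printed interval labels overlap at their
edges); the pooled column is computed on the merged dataset, not by
averaging population means. Per-chromosome summaries average over adjacent
map-order pairs only — on a 50k chip that spacing (≈50 kb) is what a
per-chromosome "average distance" of that magnitude implies, as opposed to
an all-pairs mean.

## Diversity and relatedness

H_E is the plug-in 2p(1−p) per SNP (Nei's 2n/(2n−1) correction available
but off by default, since plug-in means are what chip reports typically
print); H_O the heterozygote fraction among non-missing calls. The
inbreeding coefficient is the method-of-moments
f = (O_hom − E_hom)/(L − E_hom) over the individual's called SNPs. Allele
frequencies default to the analysed cohort and can be overridden (used with
generative frequencies in the recovery tests; note that pooling
differentiated populations inflates f through the Wahlund effect — the
estimator is reproduced as defined, without correction).

Pairwise IBD uses the classic IBS-inversion: expected counts of IBS 0/1/2
given IBD state z are polynomials in the allele frequency under
Hardy-Weinberg; summed over loci and inverted in cascade for
(Z0, Z1, Z2), then truncated to [0, 1] and renormalised. The truncation is
the standard repair and biases PI_HAT slightly upward near small values
(e.g. first-cousin pairs average ≈0.130 rather than 0.125 at 10k SNPs);
the finite-sample correction factors some tools apply to the expectations
are omitted as negligible at these panel sizes. Pairs with fewer than 100
overlapping SNPs are flagged low-confidence.

## Population structure

**AMOVA.** Each individual contributes two allele copies per locus;
squared deviations of copies from individual, population and grand means
give the within-individual, among-individual and among-population sums of
squares (summed over loci — for biallelic dosage data this squared-
Euclidean decomposition is the allele-mismatch distance up to scale, which
cancels in percentages and F_ST). Variance components come from the nested
mean squares with the unequal-size coefficient n_c computed on gamete
counts; negative component estimates are retained. F_ST is the
among-population fraction of total variance. Missing dosages are imputed
at the locus grand mean with zero within-individual contribution — a
deliberately label-free imputation so the decomposition is invariant under
the permutation null. The permutation p-value permutes individuals across
populations (sizes preserved) and uses the (b+1)/(m+1) estimator; its null
uniformity is checked empirically in the tests.

**F_ST.** The Weir-Cockerham variance-components estimator per SNP, with
the global value as the ratio of summed components — chosen as the de-facto
standard; at these sample sizes it tracks the AMOVA-derived value closely,
and both are reported.

**GRM and PCA.** G_ij averages (x−2p)(x−2p)/(2p(1−p)) over markers called
in both samples; monomorphic SNPs are excluded with a warning. PCA is an
eigendecomposition of the GRM with a deterministic sign convention
(largest-magnitude loading positive); variance fractions are reported over
the retained components, because three-component reports that sum to 100%
are fractions of the retained set, not of the whole spectrum. Equality of
the GRM eigenvectors with the SVD of the standardised genotype matrix is a
test invariant.

**Admixture.** The binomial likelihood with per-sample ancestry fractions
Q and per-cluster frequencies P is maximised by EM (expected cluster
assignments of the 2M allele copies), with parameters clamped to
[1e−6, 1−1e−6] and the log-likelihood asserted non-decreasing at every
iteration. EM is slower than block relaxation but simple and adequate at
desk scale (≲15k SNPs, ≲150 samples); 5 random restarts guard against
local optima (2 inside cross-validation). Model order is chosen by
cell-holdout cross-validation: genotype cells are split into 5 random
folds, each fold predicted by a model fitted to the rest and scored by mean
binomial deviance; a fold that would blank out a whole sample or SNP is
re-drawn. Cell-holdout was preferred to leaving out individuals because
held-out individuals have no fitted Q to predict with.

## Effective population size

All same-chromosome pairs within 0–1 Mb are binned into 20 × 50 kb
intervals. The printed source description of this analysis caps distances
at "1000 Mb", which contradicts its own 20 × 50 kb binning; the cap is
read as 1 Mb. Bin means of the adjusted r² (r²_adj = r² − 1/(βn), β = 1
for genotype-based r², 2 for phased haplotypes) are inverted through
N(t) = (1/(4 f(c)))(1/E[r²_adj] − α) with c = map_rate × mean distance and
t = 1/(2c). Defaults: α = 1 (drift-only equilibrium; 2.2 selectable for
mutation-drift), Sved's mapping f(c) = c(1−c/2)/(1−c)² (the printed form of
this equation in the source literature is typographically corrupted; the
standard mapping is implemented and the identity mapping f(c) = c is
selectable rather than silently assumed), and a constant 1 cM/Mb physical-
to-genetic map (the caprine genome-wide average) — configurable because Ne
scales through it. Bins that are empty or admit no positive Ne
(1/E[r²_adj] ≤ α) are skipped with a warning. The composition of the
equilibrium expectation E[r²] = 1/(α + 4Nc) with this inversion is the
identity on N under the identity mapping — asserted to machine precision in
the tests.

## Simulators: what they emulate and what they do not

The forward Wright-Fisher simulator (discrete generations, monoecious
random mating with selfing, Haldane recombination along a linear map, free
recombination between chromosomes) was chosen over coalescent machinery for
transparency at desk scale (N ≤ 200, chromosomes ≤ 5 Mb); a per-generation
size schedule supports declining-N scenarios. Chip ascertainment is
approximated by bounding initial/founder allele frequencies to
[0.05, 0.5] rather than modelling SNP discovery. Balding-Nichols panels
draw population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral
frequencies uniform on [0.05, 0.95]; pedigree panels gene-drop each pair
through its own minimal pedigree at unlinked loci. Default scenario shapes
mirror the motivating study: 3 populations × ~30 samples, a few thousand
SNPs post-QC. None of the simulators include mutation, selection,
overlapping generations or realistic livestock demography — so passing
recovery tests demonstrates estimator correctness under the stated models,
not robustness to ascertainment bias, genotyping error or pedigree
misspecification in real chip data.

Problem sizes used in the validation suites are the package's own desk
scale: 500 first-cousin pairs × 10k SNPs for relatedness; 3 × 30 samples ×
5k SNPs × 10 seeds for F_ST recovery; N ∈ {50, 100, 200} Wright-Fisher
panels (29 chromosomes × 5 Mb, ~4N generations of burn-in, three seeded
replicates averaged) for Ne recovery, judged on bins within the last ~100
generations where the equilibrium inversion is informative; 10 seeded
3-cluster panels (800 SNPs) for K selection. Single Wright-Fisher
realisations of a small genome share one pedigree, which makes genome-wide
mean LD vary substantially between replicates — hence the replicate
averaging, and a ±30% band on Ne recovery where analytic identities are
held to machine precision.

## Known limitations

* D′ and r² are defined for biallelic loci only; no inter-chromosomal LD.
* No maximum-likelihood kinship, KING-robust estimator or runs of
  homozygosity; the IBS-inversion PI_HAT is the only relatedness measure.
* No confidence intervals on the Ne trajectory (jackknife left as future
  work); Ne estimates inherit the chosen map rate linearly.
* QC has no sex checks, duplicate detection or heterozygosity-outlier
  removal.
* X-chromosome data are carried through I/O but excluded from every
  analysis by the autosome subset (labels "1"–"29").
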