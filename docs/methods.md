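# Methods

`lymphmap` reimplements, as one tested pipeline, the chain of analyses used
to map a recessive cancer-risk locus in a closed pure-breed dog population:
relationship networks, a mixed-linear-model GWAS with Storey q-values,
composite selection signals against a multi-breed reference panel,
haplotype/homozygosity analysis of the associated region, and
recessive-pattern filtering of candidate sequence variants.  Because no
genotype data are distributed with the study it emulates, every stage runs
against a synthetic cohort whose generator is itself first-class, tested
code.  This note records the models, the defaults and why, and what the
synthetic data can and cannot show.

## The synthetic cohort

**Pedigree.** Founders (default 30) form generation 0; each of 4 later
generations adds 75 offspring distributed among a small number of mating
pairs drawn from earlier generations.  Litters are full-sib groups, so a
few ancestors accumulate many case descendants, as in registry pedigrees of
a closed breed.  The defaults give 330 individuals.

**Genotypes.** 38 autosomes (default 150 SNPs each, 60 Mb, evenly spaced —
5,700 SNPs; scans that need more resolution raise `snps_per_chromosome`).
Founder linkage disequilibrium follows a haplotype-block model: within each
block of 10 SNPs, founder haplotypes are drawn from four block haplotypes
with Dirichlet(1,1,1,1) frequencies; blocks are independent.  Meiosis
places exactly one crossover per chromosome at a uniform physical position.
This keeps realistic block LD at desk scale without a genetic map, which
the emulated study also lacked.  Gene dropping is exact, so Mendelian error
is zero by construction and phase is known.

**The planted risk locus.** One block on chromosome 13 (SNP indices 70–79)
has controlled haplotype frequencies (risk haplotype 0.40) and the risk
haplotype carries private marker alleles at the first and last span SNPs —
the analogue of the tag SNPs by which real fine-mapped risk haplotypes are
recognised.  Recombination erodes the exact 10-SNP haplotype by ~6% per
meiosis, so its realized cohort frequency is ~0.30 with seed-to-seed drift;
this is realistic and intentional.

**Phenotypes.** Disease risk is penetrance-based — P(case) = f0/f1/f2 for
0/1/2 copies of the exact risk haplotype — rather than
liability-threshold, because the downstream variant filter is
recessive-genotype-based.  Defaults f0 = 0.04, f1 = 0.12, f2 = 0.75 are
calibrated so the mean case fraction across seeds matches the emulated
cohort (49/330 ≈ 14.8%); individual seeds scatter by a few points with the
haplotype-frequency drift.  Case ages are normal(5.7, 2.0) truncated to
(0, 14]; control ages uniform(7, 12) so the young-onset sub-design (cases
≤ 6 y vs controls > 7 y) is populated.  The cohort study reported no
control age distribution, so the uniform range is a stated choice, not an
inference.

**Reference panel.** 26 breeds × 19 dogs by the Balding–Nichols
construction: breed frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around the
cohort frequency p, with F = 0.10; genotypes in Hardy–Weinberg proportions
within breed, haplotype alleles independent across SNPs.  The panel
deliberately has *no* LD — its role is an allele-frequency and
haplotype-homozygosity baseline, which makes the cross-population EHH
contrast conservative in absolute terms but leaves the rank-based CSS
combination unaffected.

**What the generator does not emulate:** genotyping error, missingness
mechanisms beyond random masking, X chromosome, imputation artefacts,
breed-specific demographic history, and ascertainment bias in case
collection.  Tests that pass on this cohort therefore validate the
statistical machinery and its calibration, not robustness to those
real-data features.

## Kinship and networks

Pedigree kinship uses the recursive tabular method (founders φ = ½ on the
diagonal; φ(i,i) = ½(1+φ(s,d)); φ(i,j) = ½(φ(s,j)+φ(d,j))); an unknown
single parent contributes zero (founder-by-proxy), a pragmatic convention
for open registry pedigrees.  The genotype network is NetView-style: an
identity-by-state distance (d = 1 − shared-allele-fraction, where a dose
pair (a,b) shares 2 − |a−b| copies; a genotype-Hamming alternative sits
behind a switch) reduced to a mutual k-nearest-neighbour graph, k = 10 by
default.  Mutual (not union) kNN matches the NetView construction; ties
break by sample order, deterministically.  Kinship matrices convert to
distances as d = max(φ) − φ.

## Mixed-model association

The scan is EMMAX-style MLMA on the observed 0/1 scale: variance
components are estimated once by REML on the null model and each SNP gets
a generalized-least-squares effect and two-sided Wald χ²(1) test against
V = σ²_g A + σ²_e I, computed in the eigenbasis of the GRM so the scan is
O(n) per SNP after one eigendecomposition.  The candidate SNP stays in the
GRM (no LOCO).  The GRM is the standard frequency-standardized form
A_jk = (1/m) Σ (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i)) with per-SNP
mean imputation of missing doses; SNPs with MAF strictly below 0.02 are
removed first.

One numerical point deserves note: frequency-centering makes the GRM
singular with null vector **1**, which is exactly the intercept.  A naive
restricted likelihood over the full eigenbasis then diverges as h² → 1.
REML is therefore computed EMMA-style on the eigensystem of S·A·S (S the
projection complement of the fixed effects), dropping the p null
directions; the likelihood is profiled over h² on a grid with
golden-section refinement.  A flat likelihood (A = I: components not
separately identifiable) resolves to the σ²_g = 0 boundary by convention,
where the scan reduces exactly to ordinary least squares with a common
residual variance.

Intercept-only is the default design; a covariate matrix can be supplied.
The young-onset subset keeps cases with age ≤ 6 and controls strictly
above 7, matching the emulated design's wording.

## Storey q-values

π0 is estimated on the λ grid 0.05…0.90 (step 0.05) as
#{p > λ}/(m(1−λ)), smoothed by a natural cubic regression spline with 3
degrees of freedom (knots at the grid min/median/max) and read off at
λ = 0.90, clipped to (0, 1].  A regression spline was chosen over a
penalised smoothing spline for determinism.  q-values follow the
cumulative-minimum rule; forcing π0 = 1 reproduces Benjamini–Hochberg
exactly, which is the primary oracle.  Chromosome-wise q-values rerun the
estimator within each chromosome; below 20 SNPs the spline is unstable and
π0 is fixed to 1 with a warning.

## Composite selection signals

Per SNP, three statistics contrast the case cohort with the reference
panel: Weir–Cockerham (1984) two-population θ (negative estimates
retained — only ranks matter), the signed derived-allele frequency
difference ΔDAF (ancestral allele from an annotation if given, otherwise
the reference panel's major allele, logged prominently; an |ΔDAF| switch
exists), and XP-EHH (ln of the ratio of the trapezoid-integrated EHH decay
curves, both populations truncated at the outermost SNP where both still
have EHH ≥ 0.05, standardized to mean 0/sd 1 over valid SNPs; physical bp
serve as the distance proxy, 1 Mb ≈ 1 cM).  Each component is converted to
fractional ranks k/(n+1), ranks to z-scores by the inverse normal CDF,
and the per-SNP mean z̄ of the available components to a one-sided p-value
under z̄ ~ N(0, 1/m), with m reduced at SNPs where a component is invalid;
CSS = −log10 p.  Ties share average ranks.

Smoothing averages raw CSS over a 1 Mb window centred at each SNP (0.5 Mb
each side — the emulated description's "0.5 Kb on either side" is
internally inconsistent with its 1 Mb window, and the leading figure wins;
the window is configurable).  SNPs strictly above the genome-wide 99.5%
empirical quantile of smoothed CSS form significant regions as maximal
runs of consecutive significant SNPs; the regional average is the mean
smoothed CSS of members.  The threshold is genome-wide, not per
chromosome.

The rank construction makes CSS invariant under any strictly monotone
transformation of a component.  Its null uniformity is a property of the
combiner given exchangeable independent components and is validated that
way; the three real components computed on the same SNPs are mutually
correlated, so the composite p-values of a real scan are not individually
calibrated — only their ranking is used.

## Haplotypes and homozygosity

Sliding windows of 2–8 SNPs (step 1) are tallied per cohort directly when
phase is available; otherwise an expectation–maximization phaser over the
window's compatible haplotype pairs (convergence 1e−6, ≤ 200 iterations)
supplies expected counts.  Haplotype strings are written in the SNP map's
allele alphabet.  LD blocks are Gabriel-style: the |D′| confidence
interval comes from the normalized likelihood over a |D′| grid with allele
frequencies at their MLEs (5th/95th percentiles of the likelihood mass);
strong LD = CI ≥ (0.70, 0.98), strong recombination = upper < 0.90, and an
interval is a block when ≥ 95% of its informative pairs are strong LD,
taking maximal non-overlapping intervals longest-first.  Runs of
homozygosity are maximal runs of dose-0/2 SNPs per sample (missing breaks
a run).  The case/control homozygosity test counts samples homozygous at
*every* SNP of a chosen set and applies a two-sided Fisher exact test by
the minimum-likelihood summation rule over the fixed-margin hypergeometric
support; the implementation is checked to 1e−12 against an exact-rational
enumeration.

## Variant filtering

The trio design fixes three roles: affected risk-haplotype homozygote,
carrier parent, unrelated non-risk control.  A variant passes the
recessive filter iff the trio genotypes are (hom-alt, het, hom-ref); a
flag relaxes the carrier to hom-alt for incomplete-penetrance scenarios,
off by default.  Region filtering is 1-based inclusive.  Consequence
classification is deliberately interval-based (no VEP/SIFT): intergenic
outside any gene; 5′/3′ UTR inside annotated UTRs; splice site within 2 bp
of an exon boundary but outside the exon; missense/synonymous by
translating the annotated CDS sequence with the standard codon table; any
CDS variant without sequence/frame annotation degrades to "gene-coding
other" with a warning.  The packaged risk-region variant table reproduces
the published eight exonic/UTR records verbatim, including its gene-symbol
spellings; insertion locations written "a^b" parse to position a with an
insertion flag.

## Validation studies and problem sizes

`lymphmap.studies` packages the replicate experiments the tests assert on:

- planted-locus recovery: 20 default cohorts; the top MLMA SNP must fall
  within the risk span ± 250 kb in ≥ 80% of replicates;
- CSS sweep recovery: paired cohorts sharing a founder block pool, the
  target carrying the risk haplotype at 91%; a span SNP must reach the
  top 0.5% of smoothed CSS in ≥ 80% of 20 replicates;
- null calibration: a founder-dominated, LD-free cohort
  (`block_size_snps = 1`) so p-values are approximately independent.
  Type-I error pools 20 permutation replicates at 10,000 SNPs × 200
  samples (band 0.035–0.065).  The Kolmogorov–Smirnov uniformity check
  uses a continuous phenotype and 2,000 SNPs per replicate: a binary
  trait at this sample size makes low-MAF Wald p-values visibly discrete,
  and at 10,000 dependent SNPs the KS test also resolves the
  fixed-variance χ² approximation itself — both are properties of the
  test statistic at finite n, not implementation defects, so the
  distributional check is run where its premises hold;
- the CSS top-fraction property runs one 10,000-SNP cohort-vs-panel scan.

These sizes keep the whole suite to a few minutes on one CPU while leaving
every assertion at the scale its statistics require.

## Known limitations

Case/control traits are analysed on the observed scale (no liability
transformation), as is conventional for MLMA; effect sizes are therefore
scale-bound.  The EM phaser handles ≤ 8-SNP windows only.  The reference
panel's lack of LD makes absolute XP-EHH values conservative.  The Gabriel
block finder is quadratic in region size and intended for candidate
regions, not genome-wide block maps.  π0 spline smoothing differs in
detail from penalised-spline implementations; q-values agree with BH when
π0 = 1 and are monotone and order-invariant by construction.
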