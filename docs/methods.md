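# Methods

`epigwas` implements an epistasis-aware GWAS workflow for crossbred (admixed)
populations: approximate generalized least squares (AGLS) estimation of one-
and two-locus SNP genotypic values on phenotypes pre-corrected with pedigree
breeding values, followed by a Kempthorne decomposition of the fitted
genotypic values into additive, dominance and pairwise epistasis effects
that remains valid under Hardy–Weinberg disequilibrium (HWD) within loci and
linkage disequilibrium (LD) between loci.

## Model and estimation

The phenotypic model for a SNP pair is

    y = mu·1 + X_g g + Z a + e,      var(y) = sigma_a^2 Z A Z' + sigma_e^2 I

where `y` are yield deviations (phenotypes after removal of fixed
non-genetic effects), `g` the nine two-locus genotypic values (three at one
locus), `a` pedigree breeding values with numerator relationship matrix `A`,
and `e` iid residuals.  Estimating `g` by full GLS needs the inverse of `V`
(or the joint mixed-model equations) for every SNP pair, which is
impractical genome-wide.  The AGLS shortcut replaces `a` by twice the
predicted transmitting ability (PTA) from routine genetic evaluation:

    y* = y − 2·PTA,       ghat = class means of y* (LS on the corrected data)

and uses the LS form of the contrast t statistic

    t_j = s_j ghat / sqrt( v^2 · s_j (X'X)^- s_j' ),
    v^2 = RSS / (n − k),  k = rank of the class-indicator design.

Two approximations are involved: routine PTA stands in for the exact
pedigree BLUP, and the LS rather than GLS variance is used in the test.
Both are exact limits in the package's test suite: with the exact BLUP the
corrected-data LS solution coincides with the explicit-V-inverse GLS
(BLUE/MME identity, checked to 1e-8 on random pedigrees), and with PTA = 0
everything reduces to ordinary least squares.

Each record is one cow (first-lactation design, Z = I).  Fits are
complete-case per SNP or SNP pair; class means use a generalized inverse,
so empty genotype classes reduce the rank instead of failing.  p-values
come from the t distribution with n − k degrees of freedom — at the n of
interest t and normal are indistinguishable, at desk scale t is correct —
and are reported as log10(1/p), capped at 320 to avoid underflow.

## Kempthorne decomposition under HWD and LD

All effects are sequential residuals of *observed-frequency* marginal means
(nothing is fitted to Hardy–Weinberg or linkage equilibrium):

    a_i      = mu_i  − mu
    d_ij     = mu_ij − mu − a_i − a_j
    (aa)_ik  = mu_ik − mu − a_i − a_k
    (ad)_ikl = mu_ikl − mu − a_i − a_k − a_l − d_kl − (aa)_ik − (aa)_il
    (da)_ijk = mu_ijk − mu − a_i − a_j − a_k − d_ij − (aa)_ik − (aa)_jk
    (dd)_ijkl = g_ijkl − mu − [all 14 lower-order terms]

Allele-indexed marginal means weight each genotype by its frequency times
the number of copies of the indexed allele; this is the only convention
under which the frequency-weighted allelic effects sum to zero without
assuming Hardy–Weinberg proportions, and it is tested as an invariant.  The
sum of all terms reconstructs the genotypic values exactly (checked to
1e-10 on random frequency/value draws).

Two properties worth noting because they are easy to get wrong:

* Under LD the classes are *not* orthogonal: a purely additive surface
  acquires nonzero (aa) values when the two-locus frequencies do not
  factorize.  The zero-epistasis property of additive surfaces, and the
  frequency-weighted zero mean of the epistasis classes, hold at linkage
  equilibrium (HWD within loci is fine) and are tested in that regime.
* The decomposition is exact for the *fitted* class means; degenerate
  frequency configurations (an unobserved genotype class) make the affected
  marginals undefined and the dependent effects are reported as NA rather
  than imputed.

### Scalar effect summaries and contrast vectors

One scalar is reported per effect type:

* additive:  alpha = a_1 − a_2 (allele-1 minus allele-2 effect),
* dominance: delta = d_12 − 0.5 (d_11 + d_22); in terms of genotypic values
  this contrast is frequency-free: g_12 − (g_11 + g_22)/2,
* epistasis: the tensor product of the single-locus contrasts applied to the
  corresponding effect grid — the alpha-by-alpha contrast of the (aa) grid
  for A×A, alpha-by-delta for A×D, delta-by-alpha for D×A and
  delta-by-delta of the (dd) grid for D×D.

The tensor-contrast choice reduces exactly to alpha and delta at a single
locus and reproduces the scale of published per-pair scalars (a D×D summary
of ~5 from a (dd) grid whose individual cells lie within ±1.4), which a
max-magnitude-cell summary cannot.  Because every effect is linear in the
genotypic values at fixed frequencies, the contrast-coefficient row vector
s_j is obtained constructively by evaluating the partition on the unit
vectors of the genotypic-value space; agreement between s_j·g and the
directly computed effect is tested to 1e-10.  At HWE and LE with p = 0.5
the six contrasts are mutually orthogonal in the inverse-frequency metric,
recovering the textbook orthogonal partition.

## Scans, thresholds, validation

* Single-locus scan: per SNP, 3-class fit, alpha and delta tests.
* Pairwise scan: intra-chromosome pairs within 3 Mb by default (covering the
  span in which intra-chromosome interactions have been reported);
  inter-chromosome enumeration is supported but opt-in because the pair
  count grows quadratically.  Per pair, 9-class fit and the four epistasis
  contrasts.  Cells with fewer than `min_cell_count` (default 5) individuals
  flag the contrasts that touch them (`low_cell`); empty required cells make
  a contrast non-estimable (NA).
* Significance: fixed log10(1/p) thresholds of 8 (single-locus) and 12
  (pairwise) as configuration constants, alongside the literal Bonferroni
  quantities 0.05/(2m) and 0.05/(4·m(m−1)/2) for reporting.  The fixed
  values are kept as configuration rather than derived because published
  rounding conventions for these quantities are not numerically exact.
* Genotypic-mean validation: per-genotype means of raw y (pedigree additive
  values *not* removed) and corrected y*, with homozygous-advantage and
  heterozygous-disadvantage flags — the check that a dominance pattern is
  not an artefact of the additive adjustment.
* Ranking: log10(1/p) descending, ties by (chromosome, position); scans are
  deterministic functions of their inputs.

## Pedigree machinery

`build_A` uses the tabular recursion A_xy = 0.5(A_x,sire(y) + A_x,dam(y))
with founder diagonal 1 (founders non-inbred and unrelated; descendant
inbreeding handled by the recursion).  `solve_mme` is a dense direct solve
of Henderson's equations, and `gls_blue` the explicit-V-inverse GLS — the
two sides of the BLUE identity.  The module is capped at 5,000 animals by
design: it exists to supply corrections, simulation PTAs and oracles, not
production evaluation.  The PTA proxy in simulation is a_hat/2 (BLUP mode)
or a/2 (true mode, the zero-approximation-error limit).

## Synthetic populations: what they emulate and what they do not

The generator mirrors a two-breed (Jersey-like × Holstein-like) admixed cow
population, the two breeds that dominate U.S. crossbred dairy data:

* Breed allele frequencies follow the Balding–Nichols model around a shared
  ancestral frequency (default divergence F_ST = 0.10, ancestral frequencies
  uniform on (0.1, 0.9)).
* Founders are purebred with Jersey-like probability 0.535 (the two dominant
  breed contributions renormalized); later generations (default 2) draw
  parents from the previous generation and inherit one unrecombined parental
  haplotype per chromosome, so every allele traces to one founder breed and
  realized admixture fractions vary across individuals.
* Founder haplotypes carry optional within-block LD (latent AR(1), default
  block of 5 SNPs with rho = 0.9) so close SNP pairs are correlated as in
  real dense panels.
* Phenotypes follow the analysis model exactly: y = mean + planted
  genotypic values + pedigree-correlated polygenic a + iid e, at a
  first-lactation fertility scale (mean 55, phenotypic SD 33, h² = 0.04).
  Because the generative and analysis models coincide, parameter recovery
  is unbiased by construction and deviations indicate implementation error.

Planted architectures: `additive` (allelic-effect gap alpha), 
`hom_advantage_dominance` (both homozygotes positive, heterozygote negative;
delta = −2.5545 at unit scale — the strongest published dominance pattern),
`axa_one_combination` (exactly one of the four cross-locus allelic combinations
interacts), `dxd_checkerboard` (checkerboard with the four het-by-homozygote cells
negative and the double heterozygote positive), and `null`.  All "true"
effect values in the truth table are re-derived from the planted map and the
*realized* genotype frequencies through the same partition code the analysis
uses — one source of truth.

Not emulated: realistic cattle linkage maps and recombination (haplotypes
pass whole chromosomes), five-breed admixture, imputation error, genotyping
QC artefacts, selection, or non-normal residuals.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data violations of them.

## Numerical and design choices

* Genotype coding 0/1/2 = copies of allele 2; the heterozygote is
  phase-ambiguous and never split.  X chromosome is treated like an
  autosome (all-female study population).  Missing genotypes are kept in
  storage and dropped per test (complete case).
* The PLINK-1 binary codec (.bed/.bim/.fam) is implemented in-package
  (2-bit SNP-major format), alongside .ped/.map text and a genotype TSV.
* Desk-scale test sizes: null calibration runs 2,000 cows × 200 SNPs; the
  recovery suite 50 replicates of 5,000 cows with residual SD ≈ 12, chosen
  so planted effects carry the same non-centrality at n = 5,000 as the
  strongest published effects at full population size.  Recovery replicates
  plant pairs on physically close but LD-free SNPs: under strong LD the
  repulsion-phase two-locus cells can be empty and the D×D contrast is then
  (correctly) non-estimable.
* Degenerate inputs: < 2 occupied classes is an error; zero-variance fits
  report v² = 0 and saturate the significance cap rather than dividing by
  zero; Bonferroni arithmetic is reported alongside, never substituted for,
  the fixed thresholds.
* Tie-breaks in rankings are lexicographic on (chromosome, position) so
  repeated runs are byte-identical.

## Known limitations

* The epistasis scalar summary is one defensible functional of the effect
  grids; other single-number summaries of a 2×2 or 3×3 grid exist, and the
  full grids are therefore carried in the scan output (`value_grid`).
* Variance components for the BLUP correction are assumed known (supplied
  via configuration); no REML estimation.
* No multi-locus (>2) decompositions, no SNP-based (genomic) relationship
  models, no imputation.
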