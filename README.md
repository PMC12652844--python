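# epigwas

Epistasis-aware GWAS for crossbred populations: approximate generalized
least squares (AGLS) estimation of one- and two-locus SNP genotypic values
with pedigree-breeding-value phenotype correction, and a Kempthorne
decomposition of the fitted values into additive (A), dominance (D) and
pairwise epistasis (A×A, A×D, D×A, D×D) effects that stays valid under
Hardy–Weinberg and linkage disequilibria.

The package is aimed at quantitative geneticists studying heterosis in
admixed livestock — the motivating setting is daughter pregnancy rate (DPR)
in Jersey×Holstein crossbred dairy cows — and at anyone who needs a tested,
desk-scale implementation of the Kempthorne effect machinery with known
truth: a synthetic two-breed crossbred generator plants single-locus and
pairwise genotypic-value architectures whose true effects are re-derived
through the same decomposition code the analysis uses.

## The model in brief

For each SNP pair the phenotypic model is

    y = mu·1 + X_g g + Z a + e,    var(y) = sigma_a^2 Z A Z' + sigma_e^2 I

with g the nine genotypic values and a the pedigree breeding values. AGLS
sidesteps per-pair GLS/mixed-model solves by correcting phenotypes with
twice the predicted transmitting ability, y* = y − 2·PTA, fitting g as
least-squares class means of y*, and t-testing effect contrasts

    t_j = s_j ghat / sqrt( v^2 · s_j (X'X)^- s_j' ),   j = A, D, A×A, A×D, D×A, D×D.

Effects follow Kempthorne's sequential-residual definitions computed from
observed genotype frequencies (a_i = mu_i − mu, d_ij = mu_ij − mu − a_i −
a_j, … up to (dd)_ijkl), with scalar summaries alpha = a_1 − a_2, delta =
d_12 − 0.5(d_11 + d_22) and their tensor-product analogues for the four
epistasis classes. Details and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Recompute the strongest published dominance effect from its printed
components and the days-open heterosis arithmetic
(`examples/02_dominance_worked_example.py`):

```text
$ python examples/02_dominance_worked_example.py
dominance values   : [ 0.595 -1.262  1.989]
dominance effect   : -2.555
days-open advantage: 23.6 -> about 24 fewer days open
```

The dominance effect −2.555 (% DPR) is the heterozygote dominance value
minus the average of the two homozygote values — the homozygous-advantage /
heterozygous-disadvantage pattern — recomputed through the partition, not
read off the inputs (the surface fed in carries an arbitrary mean, which the
contrast removes). The 24 days translate the crossbred-vs-Holstein mean DPR
gap at 4 fewer days open per 1% DPR.

A full scan on simulated data (`examples/03_single_locus_scan.py`) plants an
additive SNP (alpha = 2.0) and the dominance pattern above in a 4,000-cow
admixed population and recovers both as the top-ranked records:

```text
top A effects (threshold log10(1/p) = 8.0):
  snp  alpha    se  log10invp
snp21  1.956 0.266     12.624
snp20  1.233 0.264      5.502
...
top D effects (threshold log10(1/p) = 8.0):
  snp  delta    se  log10invp
snp23 -2.951 0.373     14.511
snp22 -1.679 0.442      3.836
```

The planted SNPs head both lists, their estimates sit within ~2 SE of the
planted truths, and the null SNPs stay far below the genome-wide threshold.
Other examples cover the full two-locus partition, the pairwise epistasis
scan with a planted heterozygous-disadvantage checkerboard, and the
BLUE/MME identity behind the AGLS correction.

## Command line

A thin CLI wraps the library for shell pipelines over PLINK files:

```sh
epigwas simulate --out-prefix sim/pop --n 2000 --snps 200 --seed 1 \
    --plant hom_advantage_dominance:snp7
epigwas scan-single --geno sim/pop --pheno sim/pop.pheno.tsv --out single.tsv
epigwas scan-pairs  --geno sim/pop --pheno sim/pop.pheno.tsv --out pairs.tsv
epigwas top --results single.tsv --effect-type D -k 20 --out top_d.tsv
```

Genotypes are read from `.ped/.map`, PLINK-1 `.bed/.bim/.fam`, or a
genotype TSV; phenotypes from a `id  y  pta` TSV; pedigrees from
`animal,sire,dam` CSV. SNPs are filtered at MAF ≥ 5% by default.

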