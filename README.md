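# poetest

A maximum-likelihood test of **parent-of-origin (imprinting) effects** on
quantitative traits in general pedigrees, using haplotypes to resolve the
parental origin of alleles.

Genomic imprinting makes the same allele contribute differently to a trait
depending on whether it was inherited from the father or the mother.
Family-based association data can detect this, but only when the parental
origin of each transmitted allele can be worked out — which a single SNP
often cannot do (a heterozygous child of two heterozygous parents is
completely ambiguous).  `poetest` implements a likelihood that sums over
every haplotype configuration compatible with the observed family
genotypes, so that linkage disequilibrium with flanking SNPs, genotypes of
siblings, and partially missing data all contribute to origin inference.
It is aimed at statistical geneticists analysing family studies
(PED/MAP-style data) and at methodologists running power studies.

## Model

For nonfounder *j* in family *i* with sourced genotype (*g_p*, *g_m*)
(paternal and maternal copies of the minor allele at the testing SNP, each
0/1):

```
y_ij = x_ij' β + γ_p g_p + γ_m g_m + u_ij + ε_ij
     = x_ij' β + γ₁ (g_p + g_m) + γ₂ (g_m − g_p) + u_ij + ε_ij
```

* u_i ~ N(0, σ_g² Φ_i) is the polygenic family effect, Φ_i twice the
  kinship matrix over the family's phenotyped nonfounders;
* ε ~ N(0, σ_e²) is the residual;
* γ₁ = (γ_p + γ_m)/2 is the main additive effect, γ₂ = (γ_m − γ_p)/2 the
  **parent-of-origin effect** (γ₂ > 0: the maternal minor allele raises
  the trait).

The family likelihood sums the multivariate-normal trait density over all
sourced-haplotype configurations compatible with the observed genotypes,
weighted by Hardy–Weinberg founder priors π(h)π(h′)(×2 if heterozygous)
and Mendelian no-recombination transmissions (1, ½, 0).  Parameters
(β, γ₁, γ₂, σ_g², σ_e², haplotype frequencies π) are estimated by an EM
algorithm; H₀: γ₂ = 0 is tested by a likelihood-ratio statistic referred
to χ²₁.  Restricting the block to the testing SNP alone gives the
single-locus special case, in which the haplotype prior reduces to
ρ^{n_a}(1−ρ)^{2f_i−n_a} over founder allele counts.

## Worked example

Simulate 200 nuclear families (2 parents + 3 offspring) on a 5-SNP
haplotype block where the testing SNP (snp5) explains h = 10% of the
trait variance, split 80/20 between the maternal and paternal alleles,
then fit and test:

```python
from poetest import SimDesign, PoeModel, gpx1_like_frequencies, simulate_study

design = SimDesign(n_families=200, n_offspring=3,
                   freqs=gpx1_like_frequencies(), testing_index=4,
                   h=0.1, seed=42)
peds, geno, pheno, truth = simulate_study(design)
print("true gamma2 =", round(design.true_gamma2, 4))

model = PoeModel(peds, geno, pheno, design.block,
                 candidate_haplotypes=design.freqs.haplotypes)
res = model.fit()
print(res.summary())
lrt = model.lrt()
print(f"LRT = {lrt.statistic:.3f}, df = {lrt.df}, p = {lrt.pvalue:.4g}")
```

Output:

```
true gamma2 = 0.1433
Parent-of-origin effect model
==============================================
families:          200
block length:      5 (testing locus snp5)
log-likelihood:    -2751.415850
converged:         True (4 EM cycles)
----------------------------------------------
beta (covariates): [0.0489]
gamma1 (additive):  0.3620
gamma2 (parent-of-origin):  0.1877
  gamma_p =  0.1744   gamma_m =  0.5497
sigma_g^2 (polygenic):  0.0000
sigma_e^2 (residual):   0.9244
----------------------------------------------
haplotype frequencies:
  00000  0.2675
  10010  0.1350
  01100  0.1037
  00110  0.0700
  01011  0.1713
  10101  0.1588
  11001  0.0938

LRT = 11.453, df = 1, p = 0.0007137
```

The fitted γ̂₂ = 0.19 (true 0.14) is detected at p ≈ 7×10⁻⁴; the maternal
effect γ̂_m is, correctly, several times the paternal γ̂_p.  σ̂_g² landed on
the 0 boundary in this draw — a common small-sample outcome for a 10%
polygenic share.  With `single_locus=True` the same model uses only the
testing SNP; on this dataset it loses most of the signal, which is
exactly the power gap the haplotype method exists to close.

A command-line interface mirrors this workflow on files:

```bash
poetest assoc --ped study.ped --map study.map --pheno pheno.tsv \
    --trait glucose --covariates age,bmi --block snp1,snp2,snp3,snp4,snp5 \
    --test-snp snp5 --out result.tsv
poetest simulate --config design.yaml --method haplotype --out power.tsv
```

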