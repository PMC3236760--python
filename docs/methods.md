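# Methods

## The model and its likelihood

The trait of nonfounder *j* in family *i* is modelled as

y_ij = x_ij'β + γ₁(g_p + g_m) + γ₂(g_m − g_p) + u_ij + ε_ij,

where (g_p, g_m) ∈ {0,1}² are the paternal and maternal copies of the
minor allele at the testing SNP, u_i ~ N(0, σ_g²Φ_i) with Φ_i twice the
kinship matrix over the family's phenotyped nonfounders, and
ε ~ N(0, σ_e²) independent.  We fix the kinship scaling at Φ = 2φ
(unit diagonal for non-inbred individuals) so that σ_g² is the polygenic
variance of a single individual.  γ₂ is the parent-of-origin contrast;
we adopt γ_p = γ₁ − γ₂, γ_m = γ₁ + γ₂, so positive γ₂ means the maternal
minor allele is associated with a larger trait value, and γ₂ = −γ₁
silences the maternal allele.  The test of interest is H₀: γ₂ = 0 by a
likelihood-ratio statistic referred to χ² with one degree of freedom.

Sourced genotypes are not observed; what is observed are unphased
genotypes over a haplotype block of L SNPs containing the testing SNP,
possibly with missing entries.  The family likelihood therefore sums,
over every assignment of haplotype pairs to family members compatible
with the observed genotypes and Mendelian transmission (no recombination
within the block), the trait density times the configuration weight:
founders contribute Hardy–Weinberg priors π_h π_h′ (×2 if heterozygous),
nonfounders contribute transmission probabilities (1, ½, or 0 per
haplotype).  Missing genotypes simply enlarge the compatible set; a
fully untyped member is unconstrained.  Founder phenotypes never enter
the density (their allele origins are unidentifiable and carry no
information about γ₂); their genotypes still constrain their offspring's
configurations.  Members with missing phenotype contribute genotype
constraints and transmission weights but are dropped from the density's
dimension.

Blocks are addressed by 0-based index; minor alleles are determined from
founder allele counts (lexicographic tie-break).  Single-parent records
are completed with an ungenotyped, phenotype-less placeholder founder so
every nonfounder has two parental slots.

## Exact evaluation: enumeration, collapsing, peeling

Two independent code paths evaluate the same exact sum:

* **Plain enumeration** (`family_loglik_enumerate`) walks members in
  topological order (founders first), pruning on genotype
  incompatibility and zero transmission, and evaluates a dense
  multivariate-normal density per configuration.
* **Peeling** (`family_loglik_peel` and the fitter) first builds a
  *collapsed configuration table*: two configurations are equivalent if
  they agree on the multiset of founder haplotypes, the number of
  heterozygous founders, and the sourced alleles at the testing locus of
  every phenotyped nonfounder — the only features the likelihood sees.
  The table is assembled bottom-up over nuclear units from the latest
  generation upward, merging equivalent partial configurations at each
  step (pedigree shapes that defeat the unit decomposition, e.g.
  marriages between two nonfounders, fall back to a depth-first
  traversal with the same collapsing).  Because the merge keys carry
  founder haplotype *counts* rather than priors, the table depends only
  on the candidate haplotype list, not on the frequencies, and is built
  once and reused across all EM iterations — and, in simulations, cached
  across replicates by genotype pattern.

Density evaluation uses the eigendecomposition Φ = UΛU′, which
diagonalizes σ_g²Φ + σ_e²I: in the rotated basis each family contributes
independent 1-D Gaussian terms with variances σ_g²λ_j + σ_e², so the
whole dataset flattens into a few numpy arrays and one EM iteration
costs a handful of vectorized operations regardless of family count.
Configuration weights are combined by log-sum-exp; weights below 1e−300
are dropped; a frequency of exactly zero enters the log-prior as a large
negative constant so that affected configurations vanish from every
posterior without producing NaNs.

The exactness contract — peeling ≡ enumeration ≡ an independently coded
brute force over the raw assignment space — is enforced in the test
suite on randomized families (≤ 8 members, L ≤ 3, mixed missingness) to
1e−8 relative, and the single-locus closed form (founder allele-count
prior ρ^{n_a}(1−ρ)^{2f−n_a}) is checked to equal the haplotype
likelihood at L = 1 to 1e−10.

## Estimation

Fitting is by EM, treating the configuration label as missing data.
Each cycle at the current parameters:

1. **E-step.**  Posterior weight of every collapsed configuration class
   within its family (the weight includes the phenotype density — the
   statistically correct choice for joint ML, rather than
   genotype-only compatibility).
2. **Frequency update.**  π_k ← expected founder-haplotype count of k,
   normalized; this is the exact conditional maximizer.
3. **Effects update.**  (β, γ₁[, γ₂]) by weighted generalized least
   squares in the whitened basis, the exact conditional maximizer given
   the variances.  The γ-update is folded into this joint GLS step: it
   has the same fixed points as a separate γ-maximization and keeps
   every sub-step a conditional ascent.
4. **Variance update.**  (σ_g², σ_e²) by one or two damped Newton steps
   on the expected complete-data objective in the eigenbasis, with an
   explicit ascent check (a step is only accepted if the objective does
   not decrease), σ_g² ≥ 0 and σ_e² ≥ 1e−8 (a fit at the σ_e² floor is
   flagged).

Every sub-step increases the same expected complete-data objective, so
the observed log-likelihood is non-decreasing (asserted to 1e−8 slack in
tests); convergence is declared when it changes by less than `tol`
(default 1e−6, `max_iter` 500).  Starting values: OLS of the trait on
covariates plus additive dosage over complete cases (γ₂ = 0); haplotype
frequencies by founder-genotype counting with ambiguous mass split
uniformly across a founder's compatible diplotypes (fully untyped
founders are skipped — they would only dilute the counts toward
uniform); σ_g² = σ_e² = half the OLS residual variance.  If counting
zeroes out a haplotype some family needs, the initial frequencies fall
back to uniform.  The EM fixed point is verified against direct
numerical maximization of the observed likelihood (Nelder–Mead over all
parameters) to 1e−3 in log-likelihood.

When every family has at most one phenotyped nonfounder (trio-style
data) σ_g² is unidentifiable and is constrained to 0; the density then
uses σ_e² alone.  In richer data σ_g² may legitimately land on the 0
boundary in small samples; the LRT for γ₂ is interior and unaffected.

The LRT fits the null (γ₂ ≡ 0), then the alternative warm-started from
the null MLE (ascent from a feasible point guarantees l_alt ≥ l_null);
the statistic 2(l_alt − l_null) is floored at 0 and referred to χ²₁.
Candidate haplotype lists default to all 2^L haplotypes for L ≤ 6;
longer blocks require an explicit list.  A configurable enumeration
budget (default 5×10⁶ partial states) guards combinatorial blowup on
large families with extensive missingness, in place of trimming
pedigrees by hand.  P-values are reported per test; no multiple-testing
adjustment is applied by the tool.

## The synthetic-data generator

The generator emulates the study conditions under which the method's
operating characteristics are assessed:

* Founder diplotypes i.i.d. from a haplotype frequency table under HWE;
  offspring inherit one uniformly chosen haplotype per parent, no
  recombination.  Nuclear families with 1–5 offspring and 1 or 2
  genotyped parents (the missing parent of a single-parent family is a
  placeholder founder, genetically present but untyped and
  unphenotyped).
* Total phenotypic variance normalized to 1.  The testing SNP explains
  h, split `maternal_share` (default 0.8) / 0.2 between maternal and
  paternal alleles: γ_m = √(0.8h/ρ(1−ρ)), γ_p = √(0.2h/ρ(1−ρ)), both
  non-negative (same direction).  The polygenic share is 0.10 by
  default; the residual is 1 − h − 0.10.  (The residual share is not
  fixed independently anywhere; it is defined as the remainder.)  For
  trios the polygenic term is omitted from generation and analysis
  (residual 1 − h), matching the degenerate trio model; keeping u in the
  generative model while dropping it from analysis is selectable.
* Covariates default to intercept-only with β = 0.
* Missingness: `one_parent_all_loci` untypes one uniformly chosen parent
  per family; `random_10pct` drops each (person, locus) genotype with
  probability 0.10; phenotype missingness applies to offspring only.
* Single-SNP designs default to MAF ρ = 0.3 (the middle of the 0.1 /
  0.3 / 0.5 grid used for power sweeps), configurable.
* All randomness flows from a single seed through per-replicate
  `SeedSequence` spawns: identical designs give byte-identical datasets
  and experiment results.

`gpx1_like_frequencies()` provides a synthetic 5-SNP, 7-haplotype block
standing in for a short gene-sized region: pairwise r² spans ~0.001–0.3
and the default testing SNP (index 4, MAF 0.42) has average r² ≈ 0.09
with its neighbours, with its minor-allele carriers distributed over
haplotypes that differ at flanking loci.  That last property is what
makes a block informative for origin inference: when both parents are
heterozygous at the testing SNP (the configuration that is completely
ambiguous to a single-locus analysis), the flanking loci usually
identify which whole haplotype each parent transmitted.  A user-supplied
haplotype/frequency list reproduces any other block structure.

What the generator does **not** emulate: genotyping error (missingness
is clean, not miscalled), non-Gaussian traits, ascertainment or
selection of families, recombination within the block, assortative
mating, or departures from HWE.  Passing tests therefore demonstrate
correctness and calibration *under the model's own assumptions*; on real
data, HWE and random-mating violations can bias estimates and inflate
type-I error and should be checked beforehand.

## Simulation results and problem sizes

The acceptance script (`scripts/acceptance.py`) recomputes type-I error
rates at α = 0.05 with 200 families per replicate: 2000 replicates for
the trio and 2-offspring single-locus designs, 1000 replicates for the
4-offspring/untyped-parent and haplotype/10%-missing designs — replicate
counts chosen to put the Monte-Carlo standard error near 0.005–0.007,
i.e. the binomial-noise scale at which the original 5000-replicate
experiments were reported.  The test suite additionally verifies the
χ²₁ null distribution (Kolmogorov–Smirnov at 2000 replicates), unbiased
recovery of γ₂ (200 replicates at h = 0.1), antisymmetry of γ̂₂ under
swapping parental roles with an invariant LRT, and the power structure
(monotone in h and family size at 300 replicates; haplotype ≥
single-locus with a ≥ 10-percentage-point mean gain at family sizes 4–5
over 400 matched-seed replicates).

## Numerical choices and limitations

* Convergence: |Δ log-likelihood| < 1e−6; EM typically converges in
  4–10 cycles on these designs because the GLS and frequency sub-steps
  are exact conditional maximizers.
* ML (not REML) variance estimation gives the usual small-sample
  downward bias in σ̂_e², and the χ²₁ reference is asymptotic: measured
  over 10⁴ null trio replicates the rejection rate at α = 0.05 is
  ≈ 0.054, a mild finite-sample tail inflation that shrinks with family
  size and information content (the 4-offspring design measures
  ≈ 0.047).
* Zero-frequency haplotypes are retained in the candidate list (their
  configurations get zero posterior automatically); no pruning/
  re-expansion machinery is needed with the flat table layout.
* Standard errors / confidence intervals for γ₂ are not provided; the
  inference instrument is the LRT.
* Computation scales linearly in families and in configuration classes;
  large pedigrees with many untyped members can exhaust the enumeration
  budget, which is a deliberate, configurable guard rather than a
  silent approximation.
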