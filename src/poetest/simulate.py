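"""Synthetic pedigree studies and power / type-I-error experiments.

The generative model: founder diplotypes are drawn i.i.d. from a
haplotype frequency table under Hardy-Weinberg equilibrium; offspring
inherit one uniformly chosen haplotype from each parent with no
recombination within the block.  Offspring traits follow

    y = gamma_p g_p + gamma_m g_m + u + e,

with total phenotypic variance normalized to 1: the maternal and
paternal alleles at the causal (testing) SNP explain maternal_share*h
and (1-maternal_share)*h of the variance (so gamma_m =
sqrt(maternal_share*h / (rho(1-rho))) with rho the causal minor-allele
frequency, both effects in the same direction), the polygenic effect u
(shared within a family through the kinship matrix) explains
``polygenic_var``, and the residual e the remainder.  Parent-offspring
trios carry no polygenic term (it is unidentifiable with one offspring
per family) and residual variance 1 - h.

Founders receive no phenotype.  Missingness schemes: untype one parent
per family entirely, or drop each (person, locus) genotype
independently with probability 0.10; phenotype missingness applies to
offspring only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimation import FitOptions, lrt_poe
from .haplotypes import (
    MISSING,
    Haplotype,
    HaplotypeFrequencies,
    SourcedDiplotype,
)
from .io import GenotypeTable, PhenotypeTable
from .likelihood import FamilyData, PreparedData
from .pedigree import Individual, KinshipMatrix, MarkerBlock, Pedigree

__all__ = [
    "SimDesign",
    "ExperimentResult",
    "effects_from_h",
    "simulate_genotypes",
    "simulate_phenotypes",
    "apply_missing",
    "simulate_study",
    "run_experiment",
    "compare_designs",
    "gpx1_like_frequencies",
]


def gpx1_like_frequencies() -> HaplotypeFrequencies:
    """Synthetic 5-SNP, 7-haplotype block with mixed pairwise LD.

    A stand-in (synthetic, not transcribed from any published table)
    for a short gene-sized haplotype block: seven common haplotypes
    whose pairwise r^2 spans roughly 0.001-0.3, with the default
    testing SNP (index 4) in intermediate LD with its neighbours
    (average r^2 about 0.09).  Minor-allele carriers at the testing
    SNP ride on haplotypes that differ at flanking loci, so the block
    is informative about parental origin without being redundant.
    """
    haps = ["00000", "10010", "01100", "00110", "01011", "10101", "11001"]
    freq = [0.26, 0.14, 0.10, 0.08, 0.17, 0.15, 0.10]
    return HaplotypeFrequencies([Haplotype.from_string(h) for h in haps], freq)


def effects_from_h(
    h: float, rho: float, maternal_share: float = 0.8
) -> tuple[float, float]:
    """Allelic effects (gamma_p, gamma_m) from locus heritability h.

    With unit total phenotypic variance, the maternal allele explains
    maternal_share*h = rho(1-rho) gamma_m^2 and the paternal allele the
    rest of h; both effects are non-negative (same direction).
    """
    if not 0 <= h < 1:
        raise ValueError("h must be in [0, 1)")
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if not 0 <= maternal_share <= 1:
        raise ValueError("maternal_share must be in [0, 1]")
    denom = rho * (1.0 - rho)
    gamma_m = math.sqrt(maternal_share * h / denom)
    gamma_p = math.sqrt((1.0 - maternal_share) * h / denom)
    return gamma_p, gamma_m


@dataclass
class SimDesign:
    """A simulation design: family structure, genetics, and experiment
    bookkeeping.

    ``freqs`` is a haplotype frequency table, or a scalar minor-allele
    frequency for a single-SNP design.  ``h`` is the share of unit
    phenotypic variance explained by the testing SNP, split
    ``maternal_share`` / (1 - maternal_share) between the maternal and
    paternal alleles; ``polygenic_var`` is the residual familial share.
    Either ``n_families`` or ``total_individuals`` (with the family
    template implied by ``n_parents`` + ``n_offspring``) must be given.
    """

    n_families: Optional[int] = None
    total_individuals: Optional[int] = None
    n_offspring: int = 1
    n_parents: int = 2
    freqs: Union[HaplotypeFrequencies, float] = 0.3
    testing_index: int = 0
    h: float = 0.0
    maternal_share: float = 0.8
    polygenic_var: float = 0.10
    missing_scheme: str = "none"
    pheno_missing_rate: float = 0.0
    alpha: float = 0.05
    reps: int = 1
    seed: int = 0
    trio_polygenic: bool = False

    def __post_init__(self):
        if isinstance(self.freqs, (int, float)):
            self.freqs = HaplotypeFrequencies.single_locus(float(self.freqs))
            self.testing_index = 0
        if not 1 <= self.n_offspring <= 5:
            raise ValueError("n_offspring must be between 1 and 5")
        if self.n_parents not in (1, 2):
            raise ValueError("n_parents must be 1 or 2")
        fam_size = self.n_parents + self.n_offspring
        if self.n_families is None:
            if self.total_individuals is None:
                raise ValueError("give n_families or total_individuals")
            if self.total_individuals % fam_size:
                raise ValueError(
                    f"total_individuals {self.total_individuals} not divisible "
                    f"by family size {fam_size}"
                )
            self.n_families = self.total_individuals // fam_size
        if self.missing_scheme not in ("none", "one_parent_all_loci", "random_10pct"):
            raise ValueError(f"unknown missing scheme {self.missing_scheme!r}")
        if not 0 <= self.maternal_share <= 1:
            raise ValueError("maternal_share must be in [0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if self.h + self.effective_polygenic >= 1:
            raise ValueError("h + polygenic variance must be below 1")

    @property
    def effective_polygenic(self) -> float:
        if self.n_offspring == 1 and not self.trio_polygenic:
            return 0.0
        return self.polygenic_var

    @property
    def causal_maf(self) -> float:
        al = self.freqs.allele_matrix()[:, self.testing_index]
        return float(self.freqs.frequencies @ al)

    @property
    def true_effects(self) -> tuple[float, float]:
        return effects_from_h(self.h, self.causal_maf, self.maternal_share)

    @property
    def true_gamma2(self) -> float:
        gp, gm = self.true_effects
        return (gm - gp) / 2.0

    @property
    def block(self) -> MarkerBlock:
        names = tuple(f"snp{i + 1}" for i in range(self.freqs.n_loci))
        return MarkerBlock(names, self.testing_index)


@dataclass
class ExperimentResult:
    """Monte-Carlo rejection summary for one design and method."""

    rejection_count: int
    reps: int
    rejection_rate: float
    mc_se: float
    statistics: np.ndarray = field(repr=False, default=None)
    pvalues: np.ndarray = field(repr=False, default=None)
    gamma2_hats: np.ndarray = field(repr=False, default=None)
    n_failures: int = 0
    n_nonconverged: int = 0


def _family_ids(design: SimDesign) -> list[tuple[str, str, str, list[str]]]:
    out = []
    for i in range(design.n_families):
        fam = f"F{i + 1}"
        out.append(
            (
                fam,
                f"{fam}_fa",
                f"{fam}_mo",
                [f"{fam}_c{j + 1}" for j in range(design.n_offspring)],
            )
        )
    return out


def _build_pedigrees(design: SimDesign) -> list[Pedigree]:
    peds = []
    for fam, fa, mo, kids in _family_ids(design):
        members = [
            Individual(fa, fam, None, None, "male"),
            Individual(mo, fam, None, None, "female"),
        ] + [Individual(c, fam, fa, mo, "unknown") for c in kids]
        peds.append(Pedigree(fam, members))
    return peds


class _RawDataset:
    """Genotype/phenotype arrays for one replicate, before table
    wrapping (kept as arrays for the experiment fast path)."""

    def __init__(self, design, hap_idx, geno, y, pheno_missing):
        self.design = design
        self.hap_idx = hap_idx  # (F, 2 + m, 2) haplotype indices
        self.geno = geno  # (F, 2 + m, L) dosage codes
        self.y = y  # (F, m) offspring traits
        self.pheno_missing = pheno_missing  # (F, m) bool


def _draw_genotypes(design: SimDesign, rng: np.random.Generator):
    F, m = design.n_families, design.n_offspring
    t = len(design.freqs)
    al = design.freqs.allele_matrix()
    pi = design.freqs.frequencies
    founders = rng.choice(t, size=(F, 2, 2), p=pi)
    picks = rng.integers(2, size=(F, m, 2))
    idx = np.arange(F)[:, None]
    pat = founders[idx, 0, picks[:, :, 0]]  # (F, m)
    mat = founders[idx, 1, picks[:, :, 1]]
    hap_idx = np.concatenate(
        [founders, np.stack([pat, mat], axis=2)], axis=1
    )  # (F, 2 + m, 2): father, mother, children (paternal, maternal)
    geno = al[hap_idx[..., 0]] + al[hap_idx[..., 1]]  # (F, 2 + m, L)
    return hap_idx, geno.astype(np.int8)


def _draw_phenotypes(design: SimDesign, hap_idx, rng: np.random.Generator):
    F, m = design.n_families, design.n_offspring
    al = design.freqs.allele_matrix()[:, design.testing_index]
    gp = al[hap_idx[:, 2:, 0]].astype(float)  # (F, m)
    gm = al[hap_idx[:, 2:, 1]].astype(float)
    gamma_p, gamma_m = design.true_effects
    sg2 = design.effective_polygenic
    se2 = 1.0 - design.h - sg2
    y = gamma_p * gp + gamma_m * gm
    if sg2 > 0:
        # full sibs: u = shared + individual, each half the polygenic var
        shared = rng.normal(scale=math.sqrt(sg2 / 2.0), size=(F, 1))
        own = rng.normal(scale=math.sqrt(sg2 / 2.0), size=(F, m))
        y = y + shared + own
    y = y + rng.normal(scale=math.sqrt(se2), size=(F, m))
    return y


def simulate_genotypes(
    design: SimDesign, rng: Optional[np.random.Generator] = None
) -> tuple[list[Pedigree], GenotypeTable, dict[str, SourcedDiplotype]]:
    """Generate pedigrees, genotypes, and the true sourced diplotypes.

    Deterministic given ``design.seed`` (or an explicit generator).
    """
    rng = rng or np.random.default_rng(design.seed)
    hap_idx, geno = _draw_genotypes(design, rng)
    peds = _build_pedigrees(design)
    haps = design.freqs.haplotypes
    truth: dict[str, SourcedDiplotype] = {}
    person_ids: list[str] = []
    rows: list[np.ndarray] = []
    for i, (fam, fa, mo, kids) in enumerate(_family_ids(design)):
        for j, pid in enumerate([fa, mo] + kids):
            truth[pid] = SourcedDiplotype(
                haps[hap_idx[i, j, 0]], haps[hap_idx[i, j, 1]]
            )
            person_ids.append(pid)
            rows.append(geno[i, j])
    table = GenotypeTable(person_ids, design.block.locus_names, np.vstack(rows))
    return peds, table, truth


def simulate_phenotypes(
    pedigrees: Sequence[Pedigree],
    truth: dict[str, SourcedDiplotype],
    design: SimDesign,
    covariates: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeTable:
    """Offspring traits under the generative model; founders get none."""
    rng = rng or np.random.default_rng(design.seed + 1)
    F, m = design.n_families, design.n_offspring
    hap_idx = np.zeros((F, 2 + m, 2), dtype=int)
    index_of = {h: i for i, h in enumerate(design.freqs.haplotypes)}
    ids = _family_ids(design)
    for i, (fam, fa, mo, kids) in enumerate(ids):
        for j, pid in enumerate([fa, mo] + kids):
            sd = truth[pid]
            hap_idx[i, j] = (index_of[sd.paternal], index_of[sd.maternal])
    y = _draw_phenotypes(design, hap_idx, rng)
    records = []
    for i, (fam, fa, mo, kids) in enumerate(ids):
        for j, pid in enumerate(kids):
            records.append((pid, y[i, j]))
    df = pd.DataFrame(records, columns=["person_id", "trait"]).set_index(
        "person_id"
    )
    if covariates is not None:
        df = df.join(covariates)
    return PhenotypeTable(df, "trait", tuple(covariates.columns) if covariates is not None else ())


def apply_missing(
    dataset, scheme: str, seed: int, pheno_missing_rate: float = 0.0
):
    """Apply a genotype/phenotype missingness scheme to a dataset
    (pedigrees, GenotypeTable, PhenotypeTable); deterministic in seed."""
    pedigrees, geno, pheno = dataset
    rng = np.random.default_rng(seed)
    codes = geno.codes.copy()
    rowix = {p: i for i, p in enumerate(geno.person_ids)}
    if scheme == "one_parent_all_loci":
        for ped in pedigrees:
            typed = [
                f.person_id
                for f in ped.founders
                if f.person_id in rowix
                and not np.all(codes[rowix[f.person_id]] == MISSING)
            ]
            if typed:
                victim = typed[rng.integers(len(typed))]
                codes[rowix[victim]] = MISSING
    elif scheme == "random_10pct":
        mask = rng.random(codes.shape) < 0.10
        codes[mask] = MISSING
    elif scheme != "none":
        raise ValueError(f"unknown missing scheme {scheme!r}")
    data = pheno.data.copy()
    if pheno_missing_rate > 0:
        offspring = [
            m.person_id
            for ped in pedigrees
            for m in ped.nonfounders
            if m.person_id in data.index
        ]
        drop = rng.random(len(offspring)) < pheno_missing_rate
        data.loc[np.array(offspring)[drop], pheno.trait] = np.nan
    return (
        pedigrees,
        GenotypeTable(geno.person_ids, geno.locus_names, codes),
        PhenotypeTable(data, pheno.trait, pheno.covariates),
    )


def simulate_study(design: SimDesign, rng: Optional[np.random.Generator] = None):
    """One full synthetic dataset: genotypes, phenotypes, missingness."""
    rng = rng or np.random.default_rng(design.seed)
    peds, geno, truth = simulate_genotypes(design, rng)
    pheno = simulate_phenotypes(peds, truth, design, rng=rng)
    seed2 = int(rng.integers(2**31 - 1))
    peds, geno, pheno = apply_missing(
        (peds, geno, pheno),
        design.missing_scheme,
        seed2,
        design.pheno_missing_rate,
    )
    return peds, geno, pheno, truth


# ---------------------------------------------------------------------------
# experiment fast path


def _sib_kinship(ids: Sequence[str]) -> KinshipMatrix:
    k = len(ids)
    v = 0.5 * np.ones((k, k)) + 0.5 * np.eye(k)
    return KinshipMatrix(tuple(ids), v)


def _replicate_families(
    design: SimDesign,
    block: MarkerBlock,
    loci: np.ndarray,
    rng: np.random.Generator,
    struct_key,
    peds: Sequence[Pedigree],
) -> list[FamilyData]:
    """Generate one replicate's families directly as FamilyData."""
    F, m = design.n_families, design.n_offspring
    hap_idx, geno = _draw_genotypes(design, rng)
    y = _draw_phenotypes(design, hap_idx, rng)
    geno = geno[:, :, loci]

    untyped_father = design.n_parents == 1
    if design.missing_scheme == "one_parent_all_loci":
        victims = rng.integers(2, size=F)
    if design.missing_scheme == "random_10pct":
        mask = rng.random(geno.shape) < 0.10
        geno = np.where(mask, np.int8(MISSING), geno)
    if design.pheno_missing_rate > 0:
        pheno_drop = rng.random((F, m)) < design.pheno_missing_rate
    else:
        pheno_drop = None

    fam_ids = _family_ids(design)
    families = []
    for i in range(F):
        fam, fa, mo, kids = fam_ids[i]
        people = [fa, mo] + kids
        gdict = {}
        for j, pid in enumerate(people):
            if untyped_father and j == 0:
                continue
            if design.missing_scheme == "one_parent_all_loci" and j == victims[i]:
                continue
            row = geno[i, j]
            if np.all(row == MISSING):
                continue
            gdict[pid] = tuple(int(g) for g in row)
        trait = {}
        for j, pid in enumerate(kids):
            if pheno_drop is not None and pheno_drop[i, j]:
                continue
            trait[pid] = float(y[i, j])
        phen_ids = [pid for pid in kids if pid in trait]
        families.append(
            FamilyData(
                pedigree=peds[i],
                block=block,
                genotypes=gdict,
                trait=trait,
                covariates={pid: np.ones(1) for pid in phen_ids},
                kinship=_sib_kinship(phen_ids),
                structure_key=struct_key,
            )
        )
    return families


def run_experiment(
    design: SimDesign,
    method: str = "haplotype",
    fit_options: Optional[FitOptions] = None,
    progress: bool = False,
) -> ExperimentResult:
    """Monte-Carlo rejection rate of the parent-of-origin LRT.

    Per replicate: simulate genotypes and phenotypes, apply the
    missingness scheme, fit null and alternative models with the chosen
    method ('haplotype' uses the whole block, 'single_locus' only the
    testing SNP) and reject when the LRT p-value falls below
    ``design.alpha``.  Replicates are seeded reproducibly from
    ``design.seed``; fit failures are counted, never silently dropped.
    """
    if method not in ("haplotype", "single_locus"):
        raise ValueError(f"unknown method {method!r}")
    full_block = design.block
    if method == "single_locus":
        block = MarkerBlock((full_block.testing_locus,), 0)
        loci = np.array([design.testing_index])
        haplotypes = (Haplotype((0,)), Haplotype((1,)))
    else:
        block = full_block
        loci = np.arange(full_block.n_loci)
        haplotypes = design.freqs.haplotypes
    peds = _build_pedigrees(design)
    struct_key = (design.n_parents, design.n_offspring, method)
    opts = fit_options or FitOptions()
    config_cache: dict = {}
    eig_cache: dict = {}
    ss = np.random.SeedSequence(design.seed)
    child_seeds = ss.spawn(design.reps)

    stats = np.full(design.reps, np.nan)
    pvals = np.full(design.reps, np.nan)
    g2 = np.full(design.reps, np.nan)
    n_fail = 0
    n_nonconv = 0
    rejections = 0
    for r in range(design.reps):
        rng = np.random.default_rng(child_seeds[r])
        families = _replicate_families(design, block, loci, rng, struct_key, peds)
        try:
            prepared = PreparedData(
                families,
                haplotypes,
                config_cache=config_cache,
                eig_cache=eig_cache,
            )
            res = lrt_poe(prepared, opts)
        except Exception:
            n_fail += 1
            continue
        if not res.converged:
            n_nonconv += 1
        stats[r] = res.statistic
        pvals[r] = res.pvalue
        g2[r] = res.fit_alt.params.gamma2
        if res.pvalue < design.alpha:
            rejections += 1
        if progress and (r + 1) % 100 == 0:
            print(f"  replicate {r + 1}/{design.reps}", flush=True)
    rate = rejections / design.reps
    return ExperimentResult(
        rejection_count=rejections,
        reps=design.reps,
        rejection_rate=rate,
        mc_se=math.sqrt(rate * (1.0 - rate) / design.reps),
        statistics=stats,
        pvalues=pvals,
        gamma2_hats=g2,
        n_failures=n_fail,
        n_nonconverged=n_nonconv,
    )


def compare_designs(
    total_individuals: int,
    designs: Sequence[SimDesign],
    method: str = "haplotype",
) -> pd.DataFrame:
    """Rejection counts across family structures at a fixed total
    sample size (the design-efficiency comparison)."""
    rows = []
    for d in designs:
        size = d.n_parents + d.n_offspring
        if d.n_families * size != total_individuals:
            raise ValueError(
                f"design with {d.n_families} families of size {size} does not "
                f"total {total_individuals} individuals"
            )
        res = run_experiment(d, method)
        rows.append(
            {
                "n_parents": d.n_parents,
                "n_offspring": d.n_offspring,
                "n_families": d.n_families,
                "method": method,
                "reps": res.reps,
                "rejections": res.rejection_count,
                "rate": res.rejection_rate,
                "mc_se": res.mc_se,
                "fit_failures": res.n_failures,
            }
        )
    return pd.DataFrame(rows)
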