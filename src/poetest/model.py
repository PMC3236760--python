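"""Model/Results interface to the parent-of-origin test.

`PoeModel` is built from study data (or from PED/MAP/phenotype files);
``fit()`` returns a :class:`PoeResults` carrying the MLEs and a
``summary()`` table, and ``lrt()`` runs the 1-df likelihood-ratio test
of the parent-of-origin effect gamma2.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimation import FitOptions, FitResult, LrtResult, fit_mle, init_params, lrt_poe
from .haplotypes import Haplotype, HaplotypeFrequencies
from .io import GenotypeTable, PhenotypeTable, load_study
from .likelihood import FamilyData, PoeParams, PreparedData
from .pedigree import MarkerBlock, Pedigree, kinship_matrix

__all__ = ["PoeModel", "PoeResults"]


class PoeModel:
    """Parent-of-origin effect model for a family study.

    Parameters
    ----------
    pedigrees, genotypes, phenotypes, block
        Validated study components (see :func:`poetest.io.load_study`).
    candidate_haplotypes
        Candidate haplotype list for the block; defaults to all 2^L
        haplotypes for L <= 6.
    single_locus
        Restrict the analysis to the testing SNP only (the L = 1
        special case of the haplotype method).
    """

    def __init__(
        self,
        pedigrees: Sequence[Pedigree],
        genotypes: GenotypeTable,
        phenotypes: PhenotypeTable,
        block: MarkerBlock,
        candidate_haplotypes: Optional[Sequence[Union[Haplotype, str]]] = None,
        single_locus: bool = False,
        enum_budget: int = 5_000_000,
    ):
        if single_locus:
            genotypes = genotypes.subset_loci([block.testing_locus])
            block = MarkerBlock((block.testing_locus,), 0)
            candidate_haplotypes = (Haplotype((0,)), Haplotype((1,)))
        if candidate_haplotypes is None:
            if block.n_loci > 6:
                raise ValueError(
                    "supply candidate_haplotypes for blocks longer than 6 loci"
                )
            candidate_haplotypes = HaplotypeFrequencies.exhaustive(
                block.n_loci
            ).haplotypes
        self.block = block
        self.single_locus = single_locus
        self.families = []
        for ped in pedigrees:
            kin = kinship_matrix(ped)
            geno = {}
            for m in ped.members:
                row = genotypes.row(m.person_id)
                if row is not None and not np.all(row < 0):
                    geno[m.person_id] = tuple(int(g) for g in row)
            trait = {}
            covs = {}
            for m in ped.nonfounders:
                v = phenotypes.trait_value(m.person_id)
                x = phenotypes.design_row(m.person_id)
                if not np.isnan(v) and x is not None:
                    trait[m.person_id] = v
                    covs[m.person_id] = x
            self.families.append(
                FamilyData.build(
                    ped, block, geno, trait, covs or None, full_kinship=kin
                )
            )
        self.data = PreparedData(
            self.families, candidate_haplotypes, budget=enum_budget
        )

    @classmethod
    def from_files(
        cls,
        ped_path,
        map_path,
        pheno_path,
        block: Sequence[str],
        test_snp: str,
        trait: Optional[str] = None,
        covariates: Sequence[str] = (),
        **kw,
    ) -> "PoeModel":
        peds, mb, geno, pheno = load_study(
            ped_path, map_path, pheno_path, block, test_snp, trait, covariates
        )
        return cls(peds, geno, pheno, mb, **kw)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def start_params(self) -> PoeParams:
        return init_params(self.data)

    def loglik(self, params: PoeParams) -> float:
        """Observed-data log-likelihood at arbitrary parameter values."""
        return self.data.loglik_parts(params)[0]

    def fit(
        self,
        constrain_gamma2_zero: bool = False,
        tol: float = 1e-6,
        max_iter: int = 500,
        start: Optional[PoeParams] = None,
    ) -> "PoeResults":
        opts = FitOptions(
            tol=tol,
            max_iter=max_iter,
            constrain_gamma2_zero=constrain_gamma2_zero,
            init=start,
        )
        return PoeResults(self, fit_mle(self.data, opts))

    def lrt(self, tol: float = 1e-6, max_iter: int = 500) -> LrtResult:
        """Likelihood-ratio test of gamma2 = 0 (null vs alternative fit)."""
        return lrt_poe(self.data, FitOptions(tol=tol, max_iter=max_iter))


class PoeResults:
    """Fitted parent-of-origin model.

    Exposes the MLEs (`params`), the log-likelihood, convergence
    diagnostics, and a human-readable ``summary()``.
    """

    def __init__(self, model: PoeModel, fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> PoeParams:
        return self._fit.params

    @property
    def loglik(self) -> float:
        return self._fit.loglik

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def n_iter(self) -> int:
        return self._fit.n_iter

    @property
    def loglik_trace(self) -> list:
        return self._fit.loglik_trace

    def frequencies_frame(self) -> pd.DataFrame:
        f = self.params.freqs
        return pd.DataFrame(
            {"haplotype": [str(h) for h in f.haplotypes], "frequency": f.frequencies}
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Parent-of-origin effect model",
            "=" * 46,
            f"families:          {self.model.n_families}",
            f"block length:      {self.model.block.n_loci} "
            f"(testing locus {self.model.block.testing_locus})",
            f"log-likelihood:    {self.loglik:.6f}",
            f"converged:         {self.converged} ({self.n_iter} EM cycles)",
            "-" * 46,
            f"beta (covariates): {np.array2string(p.beta, precision=4)}",
            f"gamma1 (additive): {p.gamma1: .4f}",
            f"gamma2 (parent-of-origin): {p.gamma2: .4f}",
            f"  gamma_p = {p.gamma_p: .4f}   gamma_m = {p.gamma_m: .4f}",
            f"sigma_g^2 (polygenic): {p.sigma_g2: .4f}",
            f"sigma_e^2 (residual):  {p.sigma_e2: .4f}",
            "-" * 46,
            "haplotype frequencies:",
        ]
        for h, f in p.freqs:
            if f > 1e-6:
                lines.append(f"  {h}  {f:.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<PoeResults loglik={self.loglik:.3f} gamma2={self.params.gamma2:.4f} "
            f"converged={self.converged}>"
        )
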