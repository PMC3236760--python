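"""Observed-data log-likelihood of the parent-of-origin model.

For nonfounder j of family i with sourced genotype (g_p, g_m) at the
testing locus the trait model is

    y_ij = x_ij' beta + gamma1 (g_p + g_m) + gamma2 (g_m - g_p)
           + u_ij + e_ij,

with family random effect u_i ~ N(0, sigma_g^2 Phi_i) (Phi = twice the
kinship matrix over the family's phenotyped nonfounders) and
independent residual e ~ N(0, sigma_e^2).  gamma1 is the main additive
genetic effect; gamma2 is the parent-of-origin effect (gamma_p =
gamma1 - gamma2, gamma_m = gamma1 + gamma2, so gamma2 > 0 means the
maternal minor allele raises the trait).  The observed-data likelihood
of a family sums the multivariate-normal trait density over every
haplotype configuration compatible with the observed genotypes,
weighted by HWE founder priors and Mendelian transmission
probabilities.

Three exact evaluation routes are provided: plain configuration
enumeration, generation-wise peeling over collapsed configuration
classes (the production path), and the single-locus closed form that
replaces haplotype priors with founder allele counts.  All agree to
floating-point accuracy; the test suite cross-checks them against an
independent brute force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .configs import DEFAULT_BUDGET, HapSpace, build_config_table
from .haplotypes import (
    MISSING,
    HaplotypeFrequencies,
    enumerate_family_configs,
    sourced_alleles_at,
)
from .pedigree import KinshipMatrix, MarkerBlock, Pedigree, kinship_matrix

__all__ = [
    "PoeParams",
    "FamilyData",
    "LogLik",
    "mean_value",
    "family_loglik_enumerate",
    "family_loglik_peel",
    "single_locus_loglik",
    "total_loglik",
    "PreparedData",
]

LOG2PI = math.log(2.0 * math.pi)
LOG2 = math.log(2.0)
_WEIGHT_FLOOR = 1e-300
_NEG_INF = float("-inf")


@dataclass
class PoeParams:
    """Model parameters: covariate effects, genetic effects, variance
    components, and haplotype (or single-locus allele) frequencies."""

    beta: np.ndarray
    gamma1: float
    gamma2: float
    sigma_g2: float
    sigma_e2: float
    freqs: HaplotypeFrequencies

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")
        if self.sigma_g2 < 0:
            raise ValueError("sigma_g2 must be non-negative")

    @property
    def gamma_p(self) -> float:
        return self.gamma1 - self.gamma2

    @property
    def gamma_m(self) -> float:
        return self.gamma1 + self.gamma2

    def replace(self, **kw) -> "PoeParams":
        d = dict(
            beta=self.beta,
            gamma1=self.gamma1,
            gamma2=self.gamma2,
            sigma_g2=self.sigma_g2,
            sigma_e2=self.sigma_e2,
            freqs=self.freqs,
        )
        d.update(kw)
        return PoeParams(**d)


def mean_value(
    x: Sequence[float], g_p: int, g_m: int, params: PoeParams
) -> float:
    """Trait mean for one individual: x'beta + gamma1 (g_p + g_m) +
    gamma2 (g_m - g_p)."""
    x = np.asarray(x, dtype=float)
    if x.shape != params.beta.shape:
        raise ValueError("covariate vector does not match beta length")
    return float(
        x @ params.beta
        + params.gamma1 * (g_p + g_m)
        + params.gamma2 * (g_m - g_p)
    )


@dataclass
class LogLik:
    """A log-likelihood value plus the number of configurations summed."""

    value: float
    n_configs: int


@dataclass
class FamilyData:
    """One family's pedigree, block genotypes, phenotypes and kinship.

    ``genotypes`` maps person_id to a length-L dosage tuple (-1 =
    missing); persons absent from the mapping are fully untyped.
    ``trait``/``covariates`` cover phenotyped nonfounders (founder
    phenotypes never enter the likelihood).  ``kinship`` holds 2*phi
    over the phenotyped nonfounders, whose order defines the trait
    vector layout.
    """

    pedigree: Pedigree
    block: MarkerBlock
    genotypes: dict
    trait: dict
    covariates: dict
    kinship: KinshipMatrix
    structure_key: tuple = field(default=None, repr=False)

    @classmethod
    def build(
        cls,
        pedigree: Pedigree,
        block: MarkerBlock,
        genotypes: dict,
        trait: dict,
        covariates: Optional[dict] = None,
        full_kinship: Optional[KinshipMatrix] = None,
    ) -> "FamilyData":
        """Assemble family data, restricting the kinship matrix to the
        nonfounders with an observed trait value."""
        phen = [
            m.person_id
            for m in pedigree.members
            if not m.is_founder
            and m.person_id in trait
            and trait[m.person_id] is not None
            and not (
                isinstance(trait[m.person_id], float)
                and math.isnan(trait[m.person_id])
            )
        ]
        kin = full_kinship if full_kinship is not None else kinship_matrix(pedigree)
        if covariates is None:
            covariates = {p: np.ones(1) for p in phen}
        return cls(
            pedigree=pedigree,
            block=block,
            genotypes=genotypes,
            trait={p: float(trait[p]) for p in phen},
            covariates=covariates,
            kinship=kin.restrict(phen),
        )

    @property
    def phenotyped_ids(self) -> tuple[str, ...]:
        return self.kinship.person_ids

    def trait_vector(self) -> np.ndarray:
        return np.array([self.trait[p] for p in self.phenotyped_ids])

    def design_matrix(self) -> np.ndarray:
        if not self.phenotyped_ids:
            return np.zeros((0, 1))
        return np.array(
            [np.atleast_1d(self.covariates[p]) for p in self.phenotyped_ids],
            dtype=float,
        )


def _mvn_logpdf(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    k = len(y)
    if k == 0:
        return 0.0
    sign, logdet = np.linalg.slogdet(cov)
    resid = y - mean
    quad = resid @ np.linalg.solve(cov, resid)
    return -0.5 * (k * LOG2PI + logdet + quad)


def family_loglik_enumerate(
    fam: FamilyData, params: PoeParams, budget: int = DEFAULT_BUDGET
) -> LogLik:
    """Exact family log-likelihood by plain configuration enumeration.

    Sums, over every compatible haplotype configuration, the
    multivariate-normal density of the phenotyped nonfounders' traits
    times the configuration weight (founder priors x transmissions).
    Members with missing phenotype constrain the genotype configurations
    but are dropped from the density's dimension.
    """
    tl = fam.block.testing_index
    y = fam.trait_vector()
    X = fam.design_matrix()
    phen = fam.phenotyped_ids
    k = len(phen)
    cov = params.sigma_g2 * fam.kinship.values + params.sigma_e2 * np.eye(k)
    terms = []
    n = 0
    for cfg in enumerate_family_configs(
        fam.pedigree, fam.genotypes, params.freqs, budget=budget
    ):
        if cfg.weight < _WEIGHT_FLOOR:
            continue
        n += 1
        mean = np.array(
            [
                mean_value(X[i], *sourced_alleles_at(cfg.assignment[p], tl), params)
                for i, p in enumerate(phen)
            ]
        )
        terms.append(math.log(cfg.weight) + _mvn_logpdf(y, mean, cov))
    if not terms:
        return LogLik(_NEG_INF, 0)
    return LogLik(float(logsumexp(terms)), n)


def _log_freqs(freqs: np.ndarray) -> np.ndarray:
    # exact zeros become ~exp(-736): impossible in any posterior but
    # free of 0 * (-inf) = nan pitfalls in the counts inner product
    return np.log(np.clip(freqs, 1e-320, None))


def _table_loglik(table, fam: FamilyData, params: PoeParams) -> float:
    y = fam.trait_vector()
    X = fam.design_matrix()
    k = len(y)
    logpi = _log_freqs(params.freqs.frequencies)
    cfg_ll = (
        np.log(table.trans)
        + table.counts @ logpi
        + table.het * LOG2
    )
    if k:
        lam, U = np.linalg.eigh(fam.kinship.values)
        v = params.sigma_g2 * lam + params.sigma_e2
        yt = U.T @ y
        mu = (X @ params.beta) @ U + params.gamma1 * (table.s @ U) + params.gamma2 * (
            table.d @ U
        )
        resid = yt[None, :] - mu
        cfg_ll = cfg_ll - 0.5 * np.sum(
            np.log(2.0 * np.pi * v)[None, :] + resid**2 / v[None, :], axis=1
        )
    return float(logsumexp(cfg_ll)) if len(cfg_ll) else _NEG_INF


def family_loglik_peel(
    fam: FamilyData,
    params: PoeParams,
    budget: int = DEFAULT_BUDGET,
    strategy: str = "auto",
) -> LogLik:
    """Exact family log-likelihood via generation-wise peeling.

    Organizes the identical sum as :func:`family_loglik_enumerate`
    bottom-up over nuclear units, merging equivalent partial
    configurations; exactness (not approximation) is the contract.
    """
    space = HapSpace(params.freqs.allele_matrix())
    slots = {p: i for i, p in enumerate(fam.phenotyped_ids)}
    table = build_config_table(
        fam.pedigree,
        fam.genotypes,
        space,
        slots,
        fam.block.testing_index,
        budget=budget,
        strategy=strategy,
    )
    if table.n_configs == 0:
        return LogLik(_NEG_INF, 0)
    return LogLik(_table_loglik(table, fam, params), table.total_raw)


def single_locus_loglik(
    fam: FamilyData, params: PoeParams, budget: int = DEFAULT_BUDGET
) -> LogLik:
    """Family log-likelihood using the testing locus only.

    Sums over sourced single-SNP allele assignments compatible with the
    observed genotypes: founder genotype priors are rho^{n_a} (1 -
    rho)^{2 f_i - n_a} (times 2 per heterozygous founder), transmissions
    are Mendelian, and the trait density is as in the block likelihood.
    Equals the haplotype-based likelihood at L = 1.
    """
    if params.freqs.n_loci != 1:
        raise ValueError("single-locus likelihood requires L = 1 frequencies")
    rho = params.freqs.frequency((1,))
    tl = fam.block.testing_index
    order = fam.pedigree.topological_order()
    phen = fam.phenotyped_ids
    slot = {p: i for i, p in enumerate(phen)}
    k = len(phen)
    obs = {
        m.person_id: fam.genotypes.get(m.person_id, (MISSING,))[tl]
        if fam.genotypes.get(m.person_id) is not None
        else MISSING
        for m in order
    }

    leaves: list[tuple[int, int, float, tuple]] = []  # (n_a, het, trans, sd)
    states = [0]

    def recurse(i, n_a, het, trans, sd, assigned):
        states[0] += 1
        if states[0] > budget:
            raise RuntimeError(
                f"enumeration budget exceeded for family {fam.pedigree.family_id!r}"
            )
        if i == len(order):
            leaves.append((n_a, het, trans, sd))
            return
        m = order[i]
        g_obs = obs[m.person_id]
        if m.is_founder:
            for g in (0, 1, 2) if g_obs == MISSING else (g_obs,):
                pair = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
                assigned[m.person_id] = pair
                recurse(i + 1, n_a + g, het + int(g == 1), trans, sd, assigned)
            assigned.pop(m.person_id, None)
            return
        fp = assigned[m.father_id]
        mp = assigned[m.mother_id]
        pat = (fp[0],) if fp[0] == fp[1] else fp
        mat = (mp[0],) if mp[0] == mp[1] else mp
        tp = 1.0 / len(pat)
        tm = 1.0 / len(mat)
        for gp in pat:
            for gm in mat:
                if g_obs != MISSING and gp + gm != g_obs:
                    continue
                nsd = (
                    sd + ((slot[m.person_id], gp + gm, gm - gp),)
                    if m.person_id in slot
                    else sd
                )
                assigned[m.person_id] = (gp, gm)
                recurse(i + 1, n_a, het, trans * tp * tm, nsd, assigned)
        assigned.pop(m.person_id, None)

    recurse(0, 0, 0, 1.0, (), {})
    if not leaves:
        return LogLik(_NEG_INF, 0)

    f_i = len(fam.pedigree.founders)
    log_rho = math.log(rho) if rho > 0 else -1e30
    log_1mr = math.log(1 - rho) if rho < 1 else -1e30
    y = fam.trait_vector()
    X = fam.design_matrix()
    if k:
        lam, U = np.linalg.eigh(fam.kinship.values)
        v = params.sigma_g2 * lam + params.sigma_e2
        yt = U.T @ y
        xb = (X @ params.beta) @ U
    terms = []
    for n_a, het, trans, sd in leaves:
        ll = (
            n_a * log_rho
            + (2 * f_i - n_a) * log_1mr
            + het * LOG2
            + math.log(trans)
        )
        if k:
            s = np.zeros(k)
            d = np.zeros(k)
            for j, sv, dv in sd:
                s[j] = sv
                d[j] = dv
            mu = xb + params.gamma1 * (s @ U) + params.gamma2 * (d @ U)
            resid = yt - mu
            ll -= 0.5 * float(np.sum(np.log(2 * np.pi * v) + resid**2 / v))
        terms.append(ll)
    return LogLik(float(logsumexp(terms)), len(leaves))


def total_loglik(
    families: Sequence[FamilyData],
    params: PoeParams,
    budget: int = DEFAULT_BUDGET,
    method: str = "peel",
) -> float:
    """Sum of family log-likelihoods over independent families."""
    fn = {
        "peel": family_loglik_peel,
        "enumerate": family_loglik_enumerate,
        "single_locus": single_locus_loglik,
    }[method]
    total = 0.0
    for fam in families:
        v = fn(fam, params).value
        if v == _NEG_INF:
            return _NEG_INF
        total += v
    return total


# ---------------------------------------------------------------------------
# flattened dataset for iterative fitting


class PreparedData:
    """A dataset flattened for vectorized likelihood evaluation.

    Concatenates every family's collapsed configuration classes and,
    per class, the per-eigencomponent rows of the whitened trait model
    (the kinship eigendecomposition diagonalizes sigma_g^2 Phi +
    sigma_e^2 I, so each row contributes an independent 1-D Gaussian).
    Configuration tables depend only on the candidate haplotype list
    and are cached across replicates by genotype pattern.
    """

    def __init__(
        self,
        families: Sequence[FamilyData],
        haplotypes,
        budget: int = DEFAULT_BUDGET,
        config_cache: Optional[dict] = None,
        eig_cache: Optional[dict] = None,
    ):
        from .haplotypes import _as_haplotype

        self.families = list(families)
        if not self.families:
            raise ValueError("no families to analyze")
        self.haplotypes = tuple(_as_haplotype(h) for h in haplotypes)
        self.block = self.families[0].block
        self.space = HapSpace(
            np.array([h.alleles for h in self.haplotypes], dtype=np.int8)
        )
        t = self.space.t
        tl = self.block.testing_index
        if config_cache is None:
            config_cache = {}
        if eig_cache is None:
            eig_cache = {}

        cfg_trans, cfg_counts, cfg_het, cfg_fam, cfg_nraw = [], [], [], [], []
        row_lam, row_yt, row_Xt, row_St, row_Dt, row_cfg_len = [], [], [], [], [], []
        self.fam_cfg_start = np.zeros(len(self.families) + 1, dtype=np.int64)
        self.impossible: list[str] = []
        self.n_founders = 0
        self.max_phenotyped = 0
        self.k_per_family = []
        n_cfg = 0
        p = None

        for fi, fam in enumerate(self.families):
            ped = fam.pedigree
            phen = fam.phenotyped_ids
            slots = {pid: i for i, pid in enumerate(phen)}
            k = len(phen)
            self.k_per_family.append(k)
            self.max_phenotyped = max(self.max_phenotyped, k)
            self.n_founders += len(ped.founders)
            key = None
            if fam.structure_key is not None:
                gkey = tuple(
                    tuple(fam.genotypes[m.person_id])
                    if m.person_id in fam.genotypes
                    else None
                    for m in ped.members
                )
                pkey = tuple(pid in slots for pid in (m.person_id for m in ped.members))
                key = (fam.structure_key, gkey, pkey)
            table = config_cache.get(key) if key is not None else None
            if table is None:
                table = build_config_table(
                    ped, fam.genotypes, self.space, slots, tl, budget=budget
                )
                if key is not None:
                    config_cache[key] = table
            C = table.n_configs
            if C == 0:
                self.impossible.append(ped.family_id)
            y = fam.trait_vector()
            X = fam.design_matrix()
            if p is None and k:
                p = X.shape[1]
            if k:
                ek = fam.kinship.values.round(12).tobytes()
                eig = eig_cache.get(ek)
                if eig is None:
                    eig = np.linalg.eigh(fam.kinship.values)
                    eig_cache[ek] = eig
                lam, U = eig
                yt = U.T @ y
                Xt = U.T @ X
                St = table.s @ U
                Dt = table.d @ U
                row_lam.append(np.tile(lam, C))
                row_yt.append(np.tile(yt, C))
                row_Xt.append(np.tile(Xt, (C, 1)))
                row_St.append(St.ravel())
                row_Dt.append(Dt.ravel())
                row_cfg_len.append(np.full(C, k, dtype=np.int64))
            else:
                row_cfg_len.append(np.zeros(C, dtype=np.int64))
            cfg_trans.append(table.trans)
            cfg_counts.append(table.counts)
            cfg_het.append(table.het.astype(float))
            cfg_nraw.append(table.n_raw)
            cfg_fam.append(np.full(C, fi, dtype=np.int64))
            n_cfg += C
            self.fam_cfg_start[fi + 1] = n_cfg

        self.p = p if p is not None else 1
        self.n_cfg = n_cfg
        self.cfg_logtrans = np.log(np.concatenate(cfg_trans)) if n_cfg else np.zeros(0)
        self.cfg_counts = (
            np.concatenate(cfg_counts) if n_cfg else np.zeros((0, t))
        )
        self.cfg_het = np.concatenate(cfg_het) if n_cfg else np.zeros(0)
        self.cfg_nraw = np.concatenate(cfg_nraw) if n_cfg else np.zeros(0, dtype=int)
        self.cfg_fam = np.concatenate(cfg_fam) if n_cfg else np.zeros(0, dtype=int)
        lens = np.concatenate(row_cfg_len) if n_cfg else np.zeros(0, dtype=int)
        self.cfg_row_start = np.concatenate([[0], np.cumsum(lens)])
        self.row_cfg = np.repeat(np.arange(n_cfg, dtype=np.int64), lens)
        if row_lam:
            self.row_lam = np.concatenate(row_lam)
            self.row_yt = np.concatenate(row_yt)
            self.row_Xt = np.vstack(row_Xt)
            self.row_St = np.concatenate(row_St)
            self.row_Dt = np.concatenate(row_Dt)
        else:
            self.row_lam = np.zeros(0)
            self.row_yt = np.zeros(0)
            self.row_Xt = np.zeros((0, p or 1))
            self.row_St = np.zeros(0)
            self.row_Dt = np.zeros(0)
        # fixed regression design [X | s | d] in the whitened basis
        self.A = np.column_stack([self.row_Xt, self.row_St, self.row_Dt])
        self.n_rows = len(self.row_lam)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def loglik_parts(self, params: PoeParams):
        """Per-configuration and per-family log-likelihood terms.

        Returns (total, fam_ll, cfg_ll, resid, v) with resid/v over the
        flattened whitened rows, for reuse by the E-step and M-step.
        """
        logpi = _log_freqs(params.freqs.frequencies)
        cfg_ll = self.cfg_logtrans + self.cfg_counts @ logpi + self.cfg_het * LOG2
        v = params.sigma_g2 * self.row_lam + params.sigma_e2
        mu = (
            self.row_Xt @ params.beta
            + params.gamma1 * self.row_St
            + params.gamma2 * self.row_Dt
        )
        resid = self.row_yt - mu
        rowll = -0.5 * (np.log(2.0 * np.pi * v) + resid**2 / v)
        cs = np.concatenate([[0.0], np.cumsum(rowll)])
        cfg_ll = cfg_ll + (cs[self.cfg_row_start[1:]] - cs[self.cfg_row_start[:-1]])
        fam_ll = _segment_logsumexp(cfg_ll, self.fam_cfg_start)
        total = float(fam_ll.sum()) if np.all(np.isfinite(fam_ll)) else _NEG_INF
        return total, fam_ll, cfg_ll, resid, v

    def posterior_weights(self, fam_ll: np.ndarray, cfg_ll: np.ndarray) -> np.ndarray:
        """Posterior probability of each configuration class within its
        family, at the parameters used to compute the inputs."""
        shift = cfg_ll - fam_ll[self.cfg_fam]
        w = np.exp(np.clip(shift, -745.0, 0.0))
        return w


def _segment_logsumexp(x: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Log-sum-exp over contiguous segments given boundary indices
    (length n_seg + 1).  Empty segments yield -inf."""
    n = len(starts) - 1
    out = np.full(n, _NEG_INF)
    nonempty = starts[:-1] < starts[1:]
    if not np.any(nonempty):
        return out
    m = np.full(n, _NEG_INF)
    m[nonempty] = np.maximum.reduceat(x, starts[:-1][nonempty])
    shift = x - np.where(np.isfinite(m), m, 0.0)[_seg_ids(starts, len(x))]
    ex = np.exp(np.clip(shift, -745.0, 50.0))
    cs = np.concatenate([[0.0], np.cumsum(ex)])
    sums = cs[starts[1:]] - cs[starts[:-1]]
    with np.errstate(divide="ignore"):
        out = np.where(sums > 0, m + np.log(np.maximum(sums, 1e-320)), _NEG_INF)
    return out


def _seg_ids(starts: np.ndarray, n: int) -> np.ndarray:
    ids = np.zeros(n, dtype=np.int64)
    np.add.at(ids, starts[1:-1][starts[1:-1] < n], 1)
    return np.cumsum(ids)
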