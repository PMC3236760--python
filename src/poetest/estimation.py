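"""Maximum-likelihood estimation by EM, and the 1-df likelihood-ratio
test of the parent-of-origin effect.

Each EM cycle: (E) posterior weights of the collapsed haplotype
configurations given genotypes AND phenotypes at the current
parameters; (M) closed-form update of the haplotype frequencies from
expected founder-haplotype counts, weighted generalized-least-squares
update of (beta, gamma1[, gamma2]) in the kinship eigenbasis, and a
damped-Newton ascent step on the variance components (sigma_g^2,
sigma_e^2) of the expected complete-data objective.  Every sub-step
maximizes (or increases) the same expected complete-data objective, so
the observed-data log-likelihood never decreases.

The LRT statistic is twice the log-likelihood difference between the
unconstrained fit and the fit with gamma2 = 0, referred to chi-square
with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .haplotypes import HaplotypeFrequencies
from .likelihood import FamilyData, PoeParams, PreparedData

__all__ = [
    "FitOptions",
    "FitResult",
    "LrtResult",
    "EigenKinship",
    "init_params",
    "em_estep_freqs",
    "em_mstep_effects_variances",
    "fit_mle",
    "lrt_poe",
]

SE2_FLOOR = 1e-8
_VAR_INIT_FLOOR = 1e-6


@dataclass
class FitOptions:
    """Convergence controls for the EM fit."""

    tol: float = 1e-6
    max_iter: int = 500
    constrain_gamma2_zero: bool = False
    init: Optional[PoeParams] = None
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class FitResult:
    """MLE output: parameters, log-likelihood, and convergence record."""

    params: PoeParams
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list = field(repr=False, default_factory=list)
    se2_at_floor: bool = False


@dataclass
class LrtResult:
    """1-df likelihood-ratio test of gamma2 = 0."""

    statistic: float
    df: int
    pvalue: float
    fit_null: FitResult
    fit_alt: FitResult

    @property
    def converged(self) -> bool:
        return self.fit_null.converged and self.fit_alt.converged


@dataclass
class EigenKinship:
    """Per-family eigendecompositions of the kinship matrices."""

    eigenvalues: list
    eigenvectors: list

    @classmethod
    def from_families(cls, families: Sequence[FamilyData]) -> "EigenKinship":
        vals, vecs = [], []
        for fam in families:
            lam, U = np.linalg.eigh(fam.kinship.values)
            if np.any(lam < -1e-10):
                raise ValueError(
                    f"kinship matrix of family {fam.pedigree.family_id!r} "
                    "is not positive semidefinite"
                )
            vals.append(lam)
            vecs.append(U)
        return cls(vals, vecs)


def _as_prepared(data, haplotypes=None, **kw) -> PreparedData:
    if isinstance(data, PreparedData):
        return data
    if haplotypes is None:
        L = data[0].block.n_loci
        if L > 6:
            raise ValueError(
                "supply a candidate haplotype list for blocks longer than 6 loci"
            )
        haplotypes = HaplotypeFrequencies.exhaustive(L).haplotypes
    return PreparedData(data, haplotypes, **kw)


def init_params(data, haplotypes=None) -> PoeParams:
    """Starting values: OLS of the trait on covariates and additive
    dosage (complete cases, gamma2 = 0), haplotype frequencies from
    founder-genotype counting with ambiguous mass split uniformly, and
    sigma_g^2 = sigma_e^2 = half the OLS residual variance.
    """
    prepared = _as_prepared(data, haplotypes)
    tl = prepared.block.testing_index
    ys, xs = [], []
    for fam in prepared.families:
        X = fam.design_matrix()
        for i, pid in enumerate(fam.phenotyped_ids):
            row = fam.genotypes.get(pid)
            if row is None or row[tl] < 0:
                continue
            ys.append(fam.trait[pid])
            xs.append(np.concatenate([X[i], [row[tl]]]))
    p = prepared.p
    trio_only = prepared.max_phenotyped <= 1
    if ys:
        y = np.asarray(ys)
        Xd = np.vstack(xs)
        coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ coef
        dof = max(len(y) - Xd.shape[1], 1)
        s2 = max(float(resid @ resid) / dof, _VAR_INIT_FLOOR)
        beta = coef[:p]
        gamma1 = float(coef[p])
    else:
        all_y = [v for fam in prepared.families for v in fam.trait.values()]
        beta = np.zeros(p)
        beta[0] = float(np.mean(all_y)) if all_y else 0.0
        s2 = max(float(np.var(all_y)) if all_y else 1.0, _VAR_INIT_FLOOR)
        gamma1 = 0.0
    if trio_only:
        sg2, se2 = 0.0, s2
    else:
        sg2 = se2 = s2 / 2.0

    counts = _founder_phase_counts(prepared)
    if ys and counts.sum() > 0:
        pi = counts / counts.sum()
    else:
        pi = np.full(len(prepared.haplotypes), 1.0 / len(prepared.haplotypes))
    freqs = HaplotypeFrequencies(prepared.haplotypes, pi)
    params = PoeParams(beta, gamma1, 0.0, sg2, se2, freqs)
    # counting can zero out a haplotype that some family still needs;
    # fall back to uniform frequencies if the data are impossible
    total = prepared.loglik_parts(params)[0]
    if not np.isfinite(total):
        params = params.replace(
            freqs=HaplotypeFrequencies(
                prepared.haplotypes,
                np.full(len(prepared.haplotypes), 1.0 / len(prepared.haplotypes)),
            )
        )
    return params


def _founder_phase_counts(prepared: PreparedData) -> np.ndarray:
    counts = np.zeros(prepared.space.t)
    missing_row = (-1,) * prepared.space.n_loci
    for fam in prepared.families:
        for m in fam.pedigree.founders:
            g = tuple(fam.genotypes.get(m.person_id, missing_row))
            if all(a < 0 for a in g):
                continue  # untyped founders carry no phase information
            pairs = prepared.space.compat_pairs(g)
            if not pairs:
                continue
            mass = 1.0 / len(pairs)
            for i, j in pairs:
                counts[i] += mass
                counts[j] += mass
    return counts


def em_estep_freqs(data, params: PoeParams, haplotypes=None) -> HaplotypeFrequencies:
    """Expected haplotype frequencies given genotypes and phenotypes.

    pi_k <- expected count of haplotype k among founder haplotypes
    under the posterior over configurations at ``params`` (the
    posterior weight includes the phenotype density), normalized to
    sum to 1.
    """
    prepared = _as_prepared(data, haplotypes)
    total, fam_ll, cfg_ll, _, _ = prepared.loglik_parts(params)
    bad = np.where(~np.isfinite(fam_ll))[0]
    if len(bad):
        fid = prepared.families[bad[0]].pedigree.family_id
        raise ValueError(
            f"family {fid!r} has zero posterior weight at the current parameters"
        )
    w = prepared.posterior_weights(fam_ll, cfg_ll)
    counts = w @ prepared.cfg_counts
    return HaplotypeFrequencies(prepared.haplotypes, counts / counts.sum())


def _gls_effects(prepared: PreparedData, w_row, v, with_gamma2: bool):
    p = prepared.p
    ncol = p + 2 if with_gamma2 else p + 1
    A = prepared.A[:, :ncol]
    wr = w_row / v
    M = A.T @ (A * wr[:, None])
    b = A.T @ (wr * prepared.row_yt)
    try:
        coef = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(M, b, rcond=None)[0]
    if not with_gamma2:
        coef = np.concatenate([coef, [0.0]])
    return coef


def _q_variances(w_row, lam, e2, sg2, se2):
    v = sg2 * lam + se2
    return -0.5 * float(np.sum(w_row * (np.log(v) + e2 / v)))


def _newton_variances(w_row, lam, e2, sg2, se2, fix_sg, n_steps=2):
    """Damped Newton ascent on the expected complete-data objective in
    the kinship eigenbasis; never decreases the objective."""
    q0 = _q_variances(w_row, lam, e2, sg2, se2)
    for _ in range(n_steps):
        v = sg2 * lam + se2
        iv = 1.0 / v
        r = e2 * iv * iv - iv  # d/dv of -(log v + e2/v), times 1
        h = iv * iv - 2.0 * e2 * iv * iv * iv
        if fix_sg:
            g = 0.5 * float(np.sum(w_row * r))
            H = 0.5 * float(np.sum(w_row * h))
            step = np.array([0.0, -g / H if H < 0 else g])
        else:
            wl = w_row * lam
            g = 0.5 * np.array([float(np.sum(wl * r)), float(np.sum(w_row * r))])
            H = 0.5 * np.array(
                [
                    [float(np.sum(wl * lam * h)), float(np.sum(wl * h))],
                    [float(np.sum(wl * h)), float(np.sum(w_row * h))],
                ]
            )
            try:
                step_core = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                step_core = g
            if g @ step_core < 0:  # not an ascent direction, fall back
                step_core = g
            step = np.array([step_core[0], step_core[1]])
        scale = 1.0
        improved = False
        for _bt in range(12):
            sg_new = sg2 if fix_sg else max(sg2 + scale * step[0], 0.0)
            se_new = max(se2 + scale * step[1], SE2_FLOOR)
            q1 = _q_variances(w_row, lam, e2, sg_new, se_new)
            if q1 >= q0 - 1e-12:
                improved = q1 > q0
                sg2, se2, q0 = sg_new, se_new, q1
                break
            scale *= 0.5
        if not improved:
            break
    return sg2, se2


def em_mstep_effects_variances(
    data, params: PoeParams, eig: Optional[EigenKinship] = None, haplotypes=None
) -> PoeParams:
    """One M-step at the posterior of ``params``: weighted GLS for
    (beta, gamma1, gamma2) and a Newton ascent for the variances,
    holding frequencies fixed.  The kinship eigenbases are carried
    inside the prepared dataset; ``eig`` is accepted for signature
    compatibility."""
    prepared = _as_prepared(data, haplotypes)
    total, fam_ll, cfg_ll, _, v = prepared.loglik_parts(params)
    w = prepared.posterior_weights(fam_ll, cfg_ll)
    w_row = w[prepared.row_cfg]
    coef = _gls_effects(prepared, w_row, v, with_gamma2=True)
    p = prepared.p
    e = prepared.row_yt - prepared.A @ coef
    sg2, se2 = _newton_variances(
        w_row,
        prepared.row_lam,
        e * e,
        params.sigma_g2,
        params.sigma_e2,
        fix_sg=prepared.max_phenotyped <= 1,
    )
    return params.replace(
        beta=coef[:p],
        gamma1=float(coef[p]),
        gamma2=float(coef[p + 1]),
        sigma_g2=sg2,
        sigma_e2=max(se2, SE2_FLOOR),
    )


def fit_mle(data, opts: Optional[FitOptions] = None, haplotypes=None) -> FitResult:
    """EM fit of the parent-of-origin model.

    Cycles the frequency E/M update, the effects GLS, and the variance
    Newton step until the log-likelihood changes by less than
    ``opts.tol`` or ``opts.max_iter`` cycles elapse.  With
    ``constrain_gamma2_zero`` the null model (gamma2 = 0) is fitted.
    Deterministic given options.
    """
    opts = opts or FitOptions()
    prepared = _as_prepared(data, haplotypes)
    params = opts.init if opts.init is not None else init_params(prepared)
    if opts.constrain_gamma2_zero:
        params = params.replace(gamma2=0.0)
    with_g2 = not opts.constrain_gamma2_zero
    fix_sg = prepared.max_phenotyped <= 1
    if fix_sg:
        params = params.replace(sigma_g2=0.0)

    trace: list[float] = []
    converged = False
    n_iter = 0
    prev = -np.inf
    for it in range(opts.max_iter + 1):
        total, fam_ll, cfg_ll, _, v = prepared.loglik_parts(params)
        if not np.isfinite(total):
            bad = np.where(~np.isfinite(fam_ll))[0]
            fid = (
                prepared.families[bad[0]].pedigree.family_id if len(bad) else "?"
            )
            raise ValueError(
                f"data impossible at the current parameters (family {fid!r})"
            )
        trace.append(total)
        if it > 0 and abs(total - prev) < opts.tol:
            converged = True
            break
        if it == opts.max_iter:
            break
        prev = total
        n_iter += 1
        w = prepared.posterior_weights(fam_ll, cfg_ll)
        counts = w @ prepared.cfg_counts
        pi = counts / counts.sum()
        w_row = w[prepared.row_cfg]
        coef = _gls_effects(prepared, w_row, v, with_gamma2=with_g2)
        e = prepared.row_yt - prepared.A @ coef
        sg2, se2 = _newton_variances(
            w_row,
            prepared.row_lam,
            e * e,
            params.sigma_g2,
            params.sigma_e2,
            fix_sg=fix_sg,
        )
        params = PoeParams(
            beta=coef[: prepared.p],
            gamma1=float(coef[prepared.p]),
            gamma2=float(coef[prepared.p + 1]),
            sigma_g2=sg2,
            sigma_e2=max(se2, SE2_FLOOR),
            freqs=HaplotypeFrequencies(prepared.haplotypes, pi),
        )
    return FitResult(
        params=params,
        loglik=trace[-1],
        n_iter=n_iter,
        converged=converged,
        loglik_trace=trace,
        se2_at_floor=params.sigma_e2 <= SE2_FLOOR * (1 + 1e-9),
    )


def lrt_poe(data, opts: Optional[FitOptions] = None, haplotypes=None) -> LrtResult:
    """Likelihood-ratio test of gamma2 = 0.

    Fits the null (gamma2 constrained to 0) and the alternative (warm
    started from the null MLE); the statistic 2 * (l_alt - l_null) is
    floored at 0 and referred to chi-square with 1 df.
    """
    opts = opts or FitOptions()
    prepared = _as_prepared(data, haplotypes)
    null_opts = FitOptions(
        tol=opts.tol,
        max_iter=opts.max_iter,
        constrain_gamma2_zero=True,
        init=opts.init,
        seed=opts.seed,
    )
    fit_null = fit_mle(prepared, null_opts)
    alt_opts = FitOptions(
        tol=opts.tol,
        max_iter=opts.max_iter,
        constrain_gamma2_zero=False,
        init=fit_null.params,
        seed=opts.seed,
    )
    fit_alt = fit_mle(prepared, alt_opts)
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    pvalue = float(stats.chi2.sf(stat, df=1))
    return LrtResult(
        statistic=stat, df=1, pvalue=pvalue, fit_null=fit_null, fit_alt=fit_alt
    )
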