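"""EM estimation and the likelihood-ratio test."""

import numpy as np
import pytest
from scipy import optimize, stats

from poetest import (
    FamilyData,
    FitOptions,
    HaplotypeFrequencies,
    MarkerBlock,
    PoeParams,
    PreparedData,
    em_estep_freqs,
    em_mstep_effects_variances,
    fit_mle,
    init_params,
    lrt_poe,
    total_loglik,
)
from poetest.pedigree import Individual, Pedigree
from poetest.simulate import SimDesign, _build_pedigrees, _replicate_families

from conftest import make_nuclear, make_trio


def simulated_prepared(
    seed, n_families=60, n_offspring=2, h=0.0, maf=0.3, L1=True, **kw
):
    design = SimDesign(
        n_families=n_families, n_offspring=n_offspring, freqs=maf, h=h, seed=seed, **kw
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fams = _replicate_families(
        design, design.block, np.array([0]), rng, None, _build_pedigrees(design)
    )
    return PreparedData(fams, [(0,), (1,)]), design


def swap_parent_roles(families):
    out = []
    for fam in families:
        ped = fam.pedigree
        swapped = Pedigree(
            ped.family_id,
            [
                Individual(
                    m.person_id,
                    m.family_id,
                    m.mother_id,
                    m.father_id,
                    {"male": "female", "female": "male"}.get(m.sex, m.sex),
                )
                for m in ped.members
            ],
        )
        out.append(
            FamilyData(
                pedigree=swapped,
                block=fam.block,
                genotypes=fam.genotypes,
                trait=fam.trait,
                covariates=fam.covariates,
                kinship=fam.kinship,
            )
        )
    return out


class TestInit:
    def test_monomorphic_founders_fix_frequency(self):
        ped = make_nuclear("F", 2)
        block = MarkerBlock(("s0", "s1"), 0)
        geno = {p.person_id: (0, 0) for p in ped.members}
        trait = {"F_c1": 0.1, "F_c2": -0.2}
        fam = FamilyData.build(ped, block, geno, trait)
        params = init_params([fam], HaplotypeFrequencies.exhaustive(2).haplotypes)
        assert params.freqs.frequency((0, 0)) == pytest.approx(1.0)

    def test_null_data_gamma1_near_truth(self):
        prepared, _ = simulated_prepared(seed=3, n_families=150)
        params = init_params(prepared)
        # OLS oracle on the same complete cases
        ys, gs = [], []
        for fam in prepared.families:
            for pid in fam.phenotyped_ids:
                row = fam.genotypes.get(pid)
                if row is not None and row[0] >= 0:
                    ys.append(fam.trait[pid])
                    gs.append(row[0])
        X = np.column_stack([np.ones(len(ys)), gs])
        coef, *_ = np.linalg.lstsq(X, np.array(ys), rcond=None)
        se = np.sqrt(np.var(ys) / (len(ys) * np.var(gs)))
        assert params.gamma1 == pytest.approx(coef[1], abs=1e-9)
        assert abs(params.gamma1 - 0.0) < 3 * se
        assert params.gamma2 == 0.0

    def test_constant_phenotype_variance_floored(self):
        ped = make_trio("T")
        block = MarkerBlock(("s0",), 0)
        fam = FamilyData.build(
            ped, block, {"T_fa": (0,), "T_mo": (1,), "T_c1": (0,)}, {"T_c1": 1.0}
        )
        params = init_params([fam, fam], [(0,), (1,)])
        assert params.sigma_e2 >= 1e-6


class TestEstepFrequencies:
    def test_unambiguous_founders_reduce_to_counting(self):
        ped = make_trio("T")
        block = MarkerBlock(("s0",), 0)
        fam = FamilyData.build(
            ped, block, {"T_fa": (2,), "T_mo": (1,), "T_c1": (1,)}, {"T_c1": 0.0}
        )
        params = PoeParams(
            np.zeros(1), 0.0, 0.0, 0.0, 1.0, HaplotypeFrequencies.single_locus(0.4)
        )
        freqs = em_estep_freqs([fam], params, haplotypes=[(0,), (1,)])
        # founder alleles: fa = aa (2 minor), mo = Aa -> 3 of 4 minor
        assert freqs.frequency((1,)) == pytest.approx(0.75)

    def test_two_equal_resolutions_split_half(self):
        # one founder genotype 1 at two loci (phase ambiguous between
        # 00/11 and 01/10), flat phenotype contribution
        ped = Pedigree(
            "U",
            [
                Individual("fa", "U", None, None, "male"),
                Individual("mo", "U", None, None, "female"),
                Individual("c", "U", "fa", "mo", "unknown"),
            ],
        )
        block = MarkerBlock(("a", "b"), 0)
        fam = FamilyData.build(ped, block, {"fa": (1, 1)}, {"c": 0.0})
        haps = HaplotypeFrequencies.exhaustive(2)
        params = PoeParams(np.zeros(1), 0.0, 0.0, 0.0, 1.0, haps)
        freqs = em_estep_freqs([fam], params, haplotypes=haps.haplotypes)
        # father contributes 1/2 to each resolution; mother untyped
        # contributes the HWE-uniform posterior; all frequencies sum to 1
        assert freqs.frequencies.sum() == pytest.approx(1.0)
        assert freqs.frequency((0, 0)) == pytest.approx(freqs.frequency((1, 1)))
        assert freqs.frequency((0, 1)) == pytest.approx(freqs.frequency((1, 0)))

    def test_updated_frequencies_sum_to_one(self, rng):
        prepared, _ = simulated_prepared(seed=8, n_families=30)
        params = init_params(prepared)
        freqs = em_estep_freqs(prepared, params)
        assert freqs.frequencies.sum() == pytest.approx(1.0)


class TestMstep:
    def test_mstep_never_decreases_loglik(self):
        for seed in range(6):
            prepared, _ = simulated_prepared(seed=seed, n_families=40)
            params = init_params(prepared)
            before = prepared.loglik_parts(params)[0]
            after_params = em_mstep_effects_variances(prepared, params)
            after = prepared.loglik_parts(after_params)[0]
            assert after >= before - 1e-8

    def test_degenerate_posterior_collapses_to_ols(self, rng):
        # fully informative genotypes (homozygous parents) make the
        # posterior degenerate; with sigma_g2 fixed at 0 the fit must
        # equal the exact OLS solution and sigma_e2 the mean squared
        # residual
        block = MarkerBlock(("s0",), 0)
        fams, rows = [], []
        parent_geno = [(0, 0), (0, 2), (2, 0), (2, 2)]
        for i in range(40):
            gf, gm_ = parent_geno[i % 4]
            fid = f"D{i}"
            ped = Pedigree(
                fid,
                [
                    Individual(f"{fid}_fa", fid, None, None, "male"),
                    Individual(f"{fid}_mo", fid, None, None, "female"),
                    Individual(f"{fid}_c1", fid, f"{fid}_fa", f"{fid}_mo", "unknown"),
                ],
            )
            gp, gmm = gf // 2, gm_ // 2
            y = float(rng.normal(0.2 + 0.5 * (gp + gmm) + 0.3 * (gmm - gp)))
            fams.append(
                FamilyData.build(
                    ped,
                    block,
                    {f"{fid}_fa": (gf,), f"{fid}_mo": (gm_,), f"{fid}_c1": (gp + gmm,)},
                    {f"{fid}_c1": y},
                )
            )
            rows.append((y, 1.0, gp + gmm, gmm - gp))
        fit = fit_mle(fams, FitOptions(tol=1e-10), haplotypes=[(0,), (1,)])
        arr = np.array(rows)
        y, X = arr[:, 0], arr[:, 1:]
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        assert fit.params.sigma_g2 == 0.0
        assert fit.params.beta[0] == pytest.approx(coef[0], abs=1e-5)
        assert fit.params.gamma1 == pytest.approx(coef[1], abs=1e-5)
        assert fit.params.gamma2 == pytest.approx(coef[2], abs=1e-5)
        assert fit.params.sigma_e2 == pytest.approx(np.mean(resid**2), rel=1e-4)


class TestFit:
    def test_trace_monotone_and_converged(self):
        for seed in (0, 1):
            prepared, _ = simulated_prepared(seed=seed, n_families=50, h=0.05)
            fit = fit_mle(prepared, FitOptions())
            trace = np.array(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8)
            assert fit.converged
            assert fit.loglik == trace[-1]
            # reported loglik agrees with a from-scratch evaluation
            assert total_loglik(prepared.families, fit.params) == pytest.approx(
                fit.loglik, abs=1e-6
            )

    def test_null_fit_never_beats_alternative(self):
        for seed in range(4):
            prepared, _ = simulated_prepared(seed=seed + 10, n_families=40, h=0.1)
            null = fit_mle(prepared, FitOptions(constrain_gamma2_zero=True))
            alt = fit_mle(prepared, FitOptions(init=null.params))
            assert null.params.gamma2 == 0.0
            assert alt.loglik >= null.loglik - 1e-9

    def test_em_matches_direct_numerical_maximization(self):
        prepared, _ = simulated_prepared(seed=5, n_families=40, n_offspring=3, h=0.1)
        fit = fit_mle(prepared, FitOptions(tol=1e-9))

        def nll(v):
            rho = 1.0 / (1.0 + np.exp(-v[5]))
            p = PoeParams(
                v[:1],
                v[1],
                v[2],
                np.exp(v[3]),
                np.exp(v[4]),
                HaplotypeFrequencies([(0,), (1,)], [1 - rho, rho]),
            )
            return -prepared.loglik_parts(p)[0]

        x0 = np.array([0.0, 0.1, 0.0, np.log(0.3), np.log(0.6), 0.0])
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options=dict(maxiter=8000, xatol=1e-8, fatol=1e-11),
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-3)
        assert fit.loglik >= -res.fun - 1e-3  # EM is not worse

    def test_haplotype_fit_equals_single_locus_fit_at_L1(self):
        prepared, _ = simulated_prepared(seed=6, n_families=50, n_offspring=2)
        fit = fit_mle(prepared, FitOptions())
        via_single = total_loglik(prepared.families, fit.params, method="single_locus")
        assert via_single == pytest.approx(fit.loglik, abs=1e-8)


class TestLrt:
    def test_flat_phenotypes_give_null_result(self):
        ped = make_nuclear("F", 2)
        block = MarkerBlock(("s0",), 0)
        fams = []
        for i, g in enumerate([(0,), (1,), (2,), (1,), (0,), (2,)]):
            fam = FamilyData.build(
                Pedigree(
                    f"F{i}",
                    [
                        Individual(f"F{i}_fa", f"F{i}", None, None, "male"),
                        Individual(f"F{i}_mo", f"F{i}", None, None, "female"),
                        Individual(f"F{i}_c1", f"F{i}", f"F{i}_fa", f"F{i}_mo", "unknown"),
                    ],
                ),
                block,
                {f"F{i}_fa": g, f"F{i}_mo": (1,), f"F{i}_c1": (1,)},
                {f"F{i}_c1": 2.5},
            )
            fams.append(fam)
        res = lrt_poe(fams, haplotypes=[(0,), (1,)])
        assert res.statistic < 1e-6
        assert res.pvalue > 0.999

    def test_statistic_definition_and_pvalue(self):
        prepared, _ = simulated_prepared(seed=7, n_families=60, h=0.1)
        res = lrt_poe(prepared)
        assert res.df == 1
        assert res.statistic == pytest.approx(
            max(0.0, 2 * (res.fit_alt.loglik - res.fit_null.loglik))
        )
        assert res.pvalue == pytest.approx(stats.chi2.sf(res.statistic, 1))

    def test_parent_role_swap_flips_gamma2_and_preserves_lrt(self):
        prepared, _ = simulated_prepared(
            seed=9, n_families=120, n_offspring=2, h=0.1
        )
        res = lrt_poe(prepared)
        swapped = PreparedData(swap_parent_roles(prepared.families), [(0,), (1,)])
        res2 = lrt_poe(swapped)
        assert res2.fit_alt.params.gamma2 == pytest.approx(
            -res.fit_alt.params.gamma2, abs=1e-5
        )
        assert res2.statistic == pytest.approx(res.statistic, abs=1e-6)


class TestFitOptions:
    @pytest.mark.parametrize("kw", [dict(tol=0.0), dict(max_iter=0)])
    def test_invalid_options_rejected(self, kw):
        with pytest.raises(ValueError):
            FitOptions(**kw)
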