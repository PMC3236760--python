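"""Family likelihood: enumeration, peeling, and the single-locus form.

The module's central oracle: peeling == enumeration == an independent
brute force, on randomized small families.
"""

import math

import numpy as np
import pytest
from scipy.stats import norm

from poetest import (
    FamilyData,
    HaplotypeFrequencies,
    MarkerBlock,
    PoeParams,
    family_loglik_enumerate,
    family_loglik_peel,
    mean_value,
    single_locus_loglik,
    total_loglik,
)
from poetest.pedigree import Individual, Pedigree

from conftest import (
    brute_force_family_loglik,
    make_nuclear,
    make_trio,
    random_family_and_params,
)


def sl_freqs(rho):
    return HaplotypeFrequencies.single_locus(rho)


def sl_params(rho=0.3, beta=0.0, g1=0.0, g2=0.0, sg2=0.0, se2=1.0):
    return PoeParams(np.array([beta]), g1, g2, sg2, se2, sl_freqs(rho))


class TestMeanValue:
    def test_substitution(self):
        p = sl_params(g1=1.0, g2=0.5)
        assert mean_value([1.0], 0, 1, p) == pytest.approx(1.5)

    def test_additive_when_gamma2_zero(self):
        p = sl_params(g1=0.7)
        assert mean_value([1.0], 0, 1, p) == mean_value([1.0], 1, 0, p)

    def test_parent_swap_with_sign_flip(self, rng):
        for _ in range(10):
            g1, g2, b = rng.normal(size=3)
            p1 = sl_params(g1=g1, g2=g2, beta=b)
            p2 = sl_params(g1=g1, g2=-g2, beta=b)
            gp, gm = rng.integers(0, 2, 2)
            assert mean_value([1.0], gp, gm, p1) == pytest.approx(
                mean_value([1.0], gm, gp, p2)
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mean_value([1.0, 2.0], 0, 0, sl_params())


class TestClosedFormCases:
    def test_fully_informative_trio(self):
        # father homozygous major, mother homozygous minor: child's
        # sourced genotype is (0, 1); a single configuration remains
        ped = make_trio("T")
        block = MarkerBlock(("s0",), 0)
        y = 0.37
        fam = FamilyData.build(
            ped, block, {"T_fa": (0,), "T_mo": (2,), "T_c1": (1,)}, {"T_c1": y}
        )
        p = sl_params(rho=0.3, g1=0.4, g2=0.25, se2=0.8)
        expect = (
            math.log((1 - 0.3) ** 2)  # father prior
            + math.log(0.3**2)  # mother prior
            + norm.logpdf(y, loc=0.4 + 0.25, scale=math.sqrt(0.8))
        )
        for fn in (family_loglik_enumerate, family_loglik_peel, single_locus_loglik):
            res = fn(fam, p)
            assert res.value == pytest.approx(expect, abs=1e-10)
            assert res.n_configs == 1

    def test_het_by_het_founder_prior_and_transmission(self):
        # Aa x Aa parents, child AA at rho = 0.3: prior (2*0.3*0.7)^2,
        # transmission 1/4, child's sourced genotype (0, 0)
        ped = make_trio("T")
        block = MarkerBlock(("s0",), 0)
        y = -0.5
        fam = FamilyData.build(
            ped, block, {"T_fa": (1,), "T_mo": (1,), "T_c1": (0,)}, {"T_c1": y}
        )
        p = sl_params(rho=0.3, g1=0.6, g2=0.2, se2=1.1)
        expect = math.log((2 * 0.3 * 0.7) ** 2 * 0.25) + norm.logpdf(
            y, loc=0.0, scale=math.sqrt(1.1)
        )
        assert single_locus_loglik(fam, p).value == pytest.approx(expect, abs=1e-10)
        assert family_loglik_enumerate(fam, p).value == pytest.approx(expect, abs=1e-10)

    def test_mendelian_impossibility(self):
        ped = make_trio("T")
        block = MarkerBlock(("s0",), 0)
        fam = FamilyData.build(
            ped, block, {"T_fa": (0,), "T_mo": (0,), "T_c1": (2,)}, {"T_c1": 0.0}
        )
        p = sl_params()
        assert single_locus_loglik(fam, p).value == -np.inf
        assert family_loglik_enumerate(fam, p).value == -np.inf
        assert family_loglik_peel(fam, p).value == -np.inf


class TestOracleEquivalence:
    def test_peel_equals_enumeration_equals_brute_force(self, rng):
        """The central exactness contract on randomized small families."""
        n_checked = 0
        for trial in range(40):
            kind = ("trio", "nuclear", "three_gen")[trial % 3]
            t = int(rng.integers(2, 5))
            L = int(rng.integers(1, 4))
            fam, params = random_family_and_params(rng, L=L, t=min(t, 2**L), members=kind)
            l_enum = family_loglik_enumerate(fam, params)
            l_peel = family_loglik_peel(fam, params)
            l_bf = brute_force_family_loglik(fam, params)
            if l_bf == -np.inf:
                assert l_enum.value == -np.inf and l_peel.value == -np.inf
                continue
            scale = max(1.0, abs(l_bf))
            assert abs(l_enum.value - l_bf) / scale < 1e-8
            assert abs(l_peel.value - l_enum.value) / scale < 1e-8
            n_checked += 1
        assert n_checked >= 25

    def test_peel_raw_config_count_matches_enumeration(self, rng):
        for _ in range(10):
            fam, params = random_family_and_params(rng, members="nuclear")
            l_enum = family_loglik_enumerate(fam, params)
            l_peel = family_loglik_peel(fam, params)
            assert l_peel.n_configs == l_enum.n_configs

    def test_three_generation_with_untyped_founder(self, rng):
        from conftest import make_three_generation

        ped = make_three_generation("G", 3)  # 7 members
        freqs = HaplotypeFrequencies(["00", "01", "10"], [0.5, 0.3, 0.2])
        al = freqs.allele_matrix()
        assign = {}
        for m in ped.topological_order():
            if m.is_founder:
                assign[m.person_id] = tuple(rng.choice(3, 2, p=freqs.frequencies))
            else:
                assign[m.person_id] = (
                    assign[m.father_id][rng.integers(2)],
                    assign[m.mother_id][rng.integers(2)],
                )
        geno = {
            pid: tuple(int(x) for x in al[i] + al[j])
            for pid, (i, j) in assign.items()
            if pid != "G_gf"  # untyped founder
        }
        trait = {m.person_id: float(rng.normal()) for m in ped.nonfounders}
        fam = FamilyData.build(ped, MarkerBlock(("a", "b"), 1), geno, trait)
        p = PoeParams(np.array([0.1]), 0.3, -0.2, 0.2, 0.9, freqs)
        l_enum = family_loglik_enumerate(fam, p)
        l_peel = family_loglik_peel(fam, p)
        assert l_peel.value == pytest.approx(l_enum.value, rel=1e-10)

    def test_single_locus_equals_haplotype_at_L1(self, rng):
        checked = 0
        for _ in range(25):
            fam, params = random_family_and_params(rng, L=1, t=2, members="nuclear")
            l_sl = single_locus_loglik(fam, params)
            l_hap = family_loglik_enumerate(fam, params)
            if l_sl.value == -np.inf:
                assert l_hap.value == -np.inf
                continue
            assert abs(l_sl.value - l_hap.value) <= 1e-10 * max(1, abs(l_sl.value))
            checked += 1
        assert checked >= 15

    def test_member_order_invariance(self, rng):
        fam, params = random_family_and_params(rng, members="three_gen")
        v1 = family_loglik_peel(fam, params).value
        shuffled = FamilyData(
            pedigree=Pedigree(
                fam.pedigree.family_id, list(reversed(fam.pedigree.members))
            ),
            block=fam.block,
            genotypes=fam.genotypes,
            trait=fam.trait,
            covariates=fam.covariates,
            kinship=fam.kinship,
        )
        v2 = family_loglik_peel(shuffled, params).value
        if np.isfinite(v1):
            assert v2 == pytest.approx(v1, abs=1e-10)


class TestSymmetries:
    @staticmethod
    def _swap_parent_roles(fam):
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
        return FamilyData(
            pedigree=swapped,
            block=fam.block,
            genotypes=fam.genotypes,
            trait=fam.trait,
            covariates=fam.covariates,
            kinship=fam.kinship,
        )

    def test_parent_swap_with_gamma2_flip_preserves_likelihood(self, rng):
        for _ in range(8):
            fam, params = random_family_and_params(rng, members="nuclear")
            v1 = family_loglik_peel(fam, params).value
            v2 = family_loglik_peel(
                self._swap_parent_roles(fam), params.replace(gamma2=-params.gamma2)
            ).value
            if np.isfinite(v1):
                assert v2 == pytest.approx(v1, abs=1e-9)

    def test_parent_swap_invariance_when_gamma2_zero(self, rng):
        for _ in range(8):
            fam, params = random_family_and_params(rng, members="nuclear")
            params = params.replace(gamma2=0.0)
            v1 = family_loglik_peel(fam, params).value
            v2 = family_loglik_peel(self._swap_parent_roles(fam), params).value
            if np.isfinite(v1):
                assert v2 == pytest.approx(v1, abs=1e-9)


class TestTotalLoglik:
    def test_duplication_doubles(self, rng):
        fam, params = random_family_and_params(rng, members="nuclear", miss=0.1)
        v = family_loglik_peel(fam, params).value
        if not np.isfinite(v):
            pytest.skip("random draw incompatible")
        assert total_loglik([fam, fam], params) == pytest.approx(2 * v, rel=1e-12)

    def test_order_invariance_and_single(self, rng):
        fams = []
        params = None
        while len(fams) < 3:
            fam, p = random_family_and_params(rng, L=1, t=2, members="trio", miss=0.0)
            if params is None:
                params = p
            if np.isfinite(family_loglik_peel(fam, params).value):
                fams.append(fam)
        assert total_loglik(fams, params) == pytest.approx(
            total_loglik(list(reversed(fams)), params), rel=1e-12
        )
        assert total_loglik([fams[0]], params) == pytest.approx(
            family_loglik_peel(fams[0], params).value
        )

    def test_impossible_family_gives_minus_inf(self):
        ped = make_trio("T")
        block = MarkerBlock(("s0",), 0)
        fam = FamilyData.build(
            ped, block, {"T_fa": (0,), "T_mo": (0,), "T_c1": (2,)}, {"T_c1": 0.0}
        )
        assert total_loglik([fam], sl_params()) == -np.inf


class TestInformationMonotonicity:
    def test_genotyped_sibling_never_expands_others_configurations(self, rng):
        """Adding a genotyped sib can only restrict the compatible
        assignments of the existing members."""
        from poetest import enumerate_family_configs

        for _ in range(10):
            freqs = HaplotypeFrequencies(["00", "01", "10", "11"], [0.4, 0.3, 0.2, 0.1])
            al = freqs.allele_matrix()
            ped3 = make_nuclear("M", 3)
            assign = {}
            for m in ped3.topological_order():
                if m.is_founder:
                    assign[m.person_id] = tuple(rng.choice(4, 2, p=freqs.frequencies))
                else:
                    assign[m.person_id] = (
                        assign[m.father_id][rng.integers(2)],
                        assign[m.mother_id][rng.integers(2)],
                    )
            geno = {
                pid: tuple(int(x) for x in al[i] + al[j])
                for pid, (i, j) in assign.items()
            }
            geno["M_fa"] = (-1, -1)  # hide a parent to create ambiguity
            base = set(ped3.members[:4])  # parents + 2 children
            ped2 = Pedigree("M", [m for m in ped3.members if m in base])
            g2 = {pid: g for pid, g in geno.items() if pid != "M_c3"}
            before = {
                tuple(str(c.assignment[p.person_id]) for p in ped2.members)
                for c in enumerate_family_configs(ped2, g2, freqs)
            }
            after = {
                tuple(str(c.assignment[p.person_id]) for p in ped2.members)
                for c in enumerate_family_configs(ped3, geno, freqs)
            }
            assert after <= before
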