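"""Shared fixtures and independent oracles.

The brute-force likelihood here is deliberately independent of the
package's enumeration/peeling machinery: it iterates the raw product
space of per-person diplotype assignments (founders unordered,
nonfounders ordered) filtered only by each person's own genotype, and
applies HWE priors, Mendelian transmission probabilities, and a dense
multivariate-normal density directly.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from poetest import (
    FamilyData,
    Haplotype,
    HaplotypeFrequencies,
    MarkerBlock,
    PoeParams,
    mean_value,
)
from poetest.pedigree import Individual, Pedigree


def make_trio(fam="T", child_sex="unknown"):
    return Pedigree(
        fam,
        [
            Individual(f"{fam}_fa", fam, None, None, "male"),
            Individual(f"{fam}_mo", fam, None, None, "female"),
            Individual(f"{fam}_c1", fam, f"{fam}_fa", f"{fam}_mo", child_sex),
        ],
    )


def make_nuclear(fam="N", n_children=2):
    members = [
        Individual(f"{fam}_fa", fam, None, None, "male"),
        Individual(f"{fam}_mo", fam, None, None, "female"),
    ]
    for j in range(n_children):
        members.append(
            Individual(f"{fam}_c{j + 1}", fam, f"{fam}_fa", f"{fam}_mo", "unknown")
        )
    return Pedigree(fam, members)


def make_three_generation(fam="G", n_grandchildren=2):
    """Grandparents -> mother; married-in founder father; grandchildren."""
    members = [
        Individual(f"{fam}_gf", fam, None, None, "male"),
        Individual(f"{fam}_gm", fam, None, None, "female"),
        Individual(f"{fam}_mo", fam, f"{fam}_gf", f"{fam}_gm", "female"),
        Individual(f"{fam}_fa", fam, None, None, "male"),
    ]
    for j in range(n_grandchildren):
        members.append(
            Individual(f"{fam}_c{j + 1}", fam, f"{fam}_fa", f"{fam}_mo", "unknown")
        )
    return Pedigree(fam, members)


def brute_force_family_loglik(fam: FamilyData, params: PoeParams) -> float:
    """Independent dense-MVN brute force over all diplotype assignments."""
    freqs = params.freqs
    haps = freqs.haplotypes
    t = len(haps)
    ped = fam.pedigree
    tl = fam.block.testing_index
    y = fam.trait_vector()
    X = fam.design_matrix()
    k = len(y)
    cov = params.sigma_g2 * fam.kinship.values + params.sigma_e2 * np.eye(k)
    phen = fam.phenotyped_ids
    founders = ped.founders
    nonf = ped.nonfounders

    def person_opts(m, ordered):
        g = fam.genotypes.get(m.person_id)
        pairs = (
            itertools.product(range(t), repeat=2)
            if ordered
            else itertools.combinations_with_replacement(range(t), 2)
        )
        out = []
        for i, j in pairs:
            dos = tuple(a + b for a, b in zip(haps[i].alleles, haps[j].alleles))
            if g is None or all(gg < 0 or gg == dd for gg, dd in zip(g, dos)):
                out.append((i, j))
        return out

    f_opts = [person_opts(m, ordered=False) for m in founders]
    n_opts = [person_opts(m, ordered=True) for m in nonf]
    terms = []
    for f_assign in itertools.product(*f_opts):
        assign = {}
        w0 = 1.0
        for m, (i, j) in zip(founders, f_assign):
            assign[m.person_id] = (i, j)
            pi, pj = freqs.frequencies[i], freqs.frequencies[j]
            w0 *= pi * pj * (2.0 if i != j else 1.0)
        if w0 == 0.0:
            continue
        for n_assign in itertools.product(*n_opts):
            w = w0
            for m, (i, j) in zip(nonf, n_assign):
                assign[m.person_id] = (i, j)
            ok = True
            for m, (i, j) in zip(nonf, n_assign):
                fa = assign[m.father_id]
                mo = assign[m.mother_id]
                tp = (int(i == fa[0]) + int(i == fa[1])) / 2.0
                tm = (int(j == mo[0]) + int(j == mo[1])) / 2.0
                w *= tp * tm
                if w == 0.0:
                    ok = False
                    break
            if not ok:
                continue
            if k:
                mean = np.array(
                    [
                        mean_value(
                            X[ii],
                            haps[assign[pp][0]].alleles[tl],
                            haps[assign[pp][1]].alleles[tl],
                            params,
                        )
                        for ii, pp in enumerate(phen)
                    ]
                )
                dens = multivariate_normal.logpdf(y, mean, cov)
            else:
                dens = 0.0
            terms.append(math.log(w) + dens)
    return float(logsumexp(terms)) if terms else -np.inf


def random_family_and_params(rng, L=2, t=3, members="three_gen", miss=0.2):
    """A random small family with genotypes drawn from the generative
    model (so configurations exist), random missingness, and random
    parameters."""
    all_haps = list(itertools.product((0, 1), repeat=L))
    rng.shuffle(all_haps)
    haps = all_haps[:t]
    f = rng.dirichlet(np.ones(t) * 2.0)
    freqs = HaplotypeFrequencies([Haplotype(h) for h in haps], f)
    al = freqs.allele_matrix()
    if members == "three_gen":
        ped = make_three_generation(n_grandchildren=int(rng.integers(1, 3)))
    elif members == "nuclear":
        ped = make_nuclear(n_children=int(rng.integers(1, 4)))
    else:
        ped = make_trio()
    assign = {}
    for m in ped.topological_order():
        if m.is_founder:
            assign[m.person_id] = tuple(rng.choice(t, 2, p=f))
        else:
            fa = assign[m.father_id]
            mo = assign[m.mother_id]
            assign[m.person_id] = (
                fa[rng.integers(2)],
                mo[rng.integers(2)],
            )
    geno = {}
    for pid, (i, j) in assign.items():
        row = [int(x) for x in al[i] + al[j]]
        for li in range(L):
            if rng.random() < miss:
                row[li] = -1
        if rng.random() < 0.12:
            continue  # fully untyped member
        geno[pid] = tuple(row)
    trait = {
        m.person_id: float(rng.normal())
        for m in ped.nonfounders
        if rng.random() < 0.85
    }
    block = MarkerBlock(tuple(f"s{i}" for i in range(L)), int(rng.integers(L)))
    fam = FamilyData.build(ped, block, geno, trait)
    params = PoeParams(
        beta=np.array([0.3 * rng.normal()]),
        gamma1=0.3 * rng.normal(),
        gamma2=0.3 * rng.normal(),
        sigma_g2=abs(0.3 * rng.normal()),
        sigma_e2=0.5 + abs(rng.normal()),
        freqs=freqs,
    )
    return fam, params


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
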