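"""Haplotypes, diplotypes, HWE priors, Mendelian transmission, and
enumeration of family haplotype configurations.

Alleles within a block are coded 0 (major) / 1 (minor), so a haplotype
is a binary vector, e.g. ``"110"``.  An individual's unordered pair of
haplotypes is a *diplotype* ``h/h'``; the ordered pair ``(paternal,
maternal)`` is a *sourced diplotype*.  Parental origin of a founder's
own haplotypes is unidentifiable, so founders carry unordered
diplotypes internally and only nonfounders receive sourced pairs.

Configuration enumeration assumes no recombination within the block:
a parent transmits one of its two haplotypes intact, with probability
1/2 each (1 if homozygous).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "Haplotype",
    "HaplotypeFrequencies",
    "Diplotype",
    "SourcedDiplotype",
    "FamilyConfiguration",
    "CapacityError",
    "genotype_of",
    "compatible_diplotypes",
    "hwe_prior",
    "transmission_prob",
    "sourced_alleles_at",
    "enumerate_family_configs",
    "read_haplotype_list",
]


class CapacityError(RuntimeError):
    """Configuration enumeration exceeded its budget for a family."""


@dataclass(frozen=True, order=True)
class Haplotype:
    """A binary haplotype over the block's L loci."""

    alleles: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(int(a) for a in self.alleles))
        if any(a not in (0, 1) for a in self.alleles):
            raise ValueError("haplotype alleles must be 0/1")

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        return cls(tuple(int(c) for c in s))

    def __len__(self) -> int:
        return len(self.alleles)

    def __str__(self) -> str:
        return "".join(str(a) for a in self.alleles)


def _as_haplotype(h: Union[Haplotype, str, Sequence[int]]) -> Haplotype:
    if isinstance(h, Haplotype):
        return h
    if isinstance(h, str):
        return Haplotype.from_string(h)
    return Haplotype(tuple(h))


@dataclass(frozen=True)
class Diplotype:
    """Unordered haplotype pair h/h', stored in lexicographic order."""

    first: Haplotype
    second: Haplotype

    def __post_init__(self):
        a = _as_haplotype(self.first)
        b = _as_haplotype(self.second)
        if b < a:
            a, b = b, a
        object.__setattr__(self, "first", a)
        object.__setattr__(self, "second", b)

    @property
    def is_homozygous(self) -> bool:
        return self.first == self.second

    def __str__(self) -> str:
        return f"{self.first}/{self.second}"


@dataclass(frozen=True)
class SourcedDiplotype:
    """Ordered haplotype pair (paternal, maternal)."""

    paternal: Haplotype
    maternal: Haplotype

    def __post_init__(self):
        object.__setattr__(self, "paternal", _as_haplotype(self.paternal))
        object.__setattr__(self, "maternal", _as_haplotype(self.maternal))

    def unordered(self) -> Diplotype:
        return Diplotype(self.paternal, self.maternal)

    def __str__(self) -> str:
        return f"({self.paternal}, {self.maternal})"


class HaplotypeFrequencies:
    """An ordered candidate haplotype list with population frequencies.

    Frequencies are non-negative and sum to 1 (tolerance 1e-9).
    Haplotypes absent from the list are treated as frequency 0.
    """

    def __init__(
        self,
        haplotypes: Iterable[Union[Haplotype, str, Sequence[int]]],
        frequencies: Iterable[float],
    ):
        self.haplotypes: tuple[Haplotype, ...] = tuple(
            _as_haplotype(h) for h in haplotypes
        )
        self.frequencies = np.asarray(list(frequencies), dtype=float)
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotypes")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) > 1:
            raise ValueError("haplotypes of differing lengths")
        if np.any(self.frequencies < -1e-12):
            raise ValueError("negative haplotype frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        self._index = {h: i for i, h in enumerate(self.haplotypes)}

    @classmethod
    def exhaustive(cls, n_loci: int) -> "HaplotypeFrequencies":
        """All 2^L haplotypes, uniform frequencies."""
        haps = [Haplotype(bits) for bits in itertools.product((0, 1), repeat=n_loci)]
        return cls(haps, np.full(len(haps), 1.0 / len(haps)))

    @classmethod
    def single_locus(cls, maf: float) -> "HaplotypeFrequencies":
        """L = 1 frequencies (1 - rho, rho) for minor allele frequency rho."""
        return cls([Haplotype((0,)), Haplotype((1,))], [1.0 - maf, maf])

    @property
    def n_loci(self) -> int:
        return len(self.haplotypes[0])

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(zip(self.haplotypes, self.frequencies))

    def index(self, h: Union[Haplotype, str]) -> Optional[int]:
        return self._index.get(_as_haplotype(h))

    def frequency(self, h: Union[Haplotype, str]) -> float:
        i = self.index(h)
        return 0.0 if i is None else float(self.frequencies[i])

    def with_frequencies(self, freqs: np.ndarray) -> "HaplotypeFrequencies":
        return HaplotypeFrequencies(self.haplotypes, freqs)

    def allele_matrix(self) -> np.ndarray:
        """(t, L) matrix of haplotype alleles."""
        return np.array([h.alleles for h in self.haplotypes], dtype=np.int8)


def read_haplotype_list(path) -> HaplotypeFrequencies:
    """Read a candidate haplotype file: one haplotype string per line,
    optionally followed by an initial frequency; '#' starts a comment.
    Missing frequencies are filled uniformly from the leftover mass."""
    haps: list[Haplotype] = []
    freqs: list[Optional[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            haps.append(Haplotype.from_string(fields[0]))
            freqs.append(float(fields[1]) if len(fields) > 1 else None)
    if not haps:
        raise ValueError(f"{path}: no haplotypes")
    given = [f for f in freqs if f is not None]
    leftover = 1.0 - sum(given)
    n_free = len(freqs) - len(given)
    if n_free:
        fill = max(leftover, 0.0) / n_free
        freqs = [fill if f is None else f for f in freqs]
    total = sum(freqs)
    if total <= 0:
        raise ValueError(f"{path}: frequencies sum to zero")
    return HaplotypeFrequencies(haps, [f / total for f in freqs])


def genotype_of(
    d: Union[SourcedDiplotype, Diplotype],
) -> tuple[int, ...]:
    """Per-locus minor-allele dosage of a diplotype (order-invariant)."""
    if isinstance(d, SourcedDiplotype):
        a, b = d.paternal, d.maternal
    else:
        a, b = d.first, d.second
    return tuple(x + y for x, y in zip(a.alleles, b.alleles))


def sourced_alleles_at(d: SourcedDiplotype, locus: int) -> tuple[int, int]:
    """(paternal allele, maternal allele) at one locus."""
    return d.paternal.alleles[locus], d.maternal.alleles[locus]


def _matches(geno: Sequence[int], dosages: Sequence[int]) -> bool:
    return all(g == MISSING or g == d for g, d in zip(geno, dosages))


def compatible_diplotypes(
    genotype: Sequence[int], candidates: HaplotypeFrequencies
) -> set[Diplotype]:
    """Unordered candidate pairs matching a genotype at its typed loci.

    ``genotype`` is a per-locus dosage vector; ``MISSING`` (-1) entries
    are unconstrained.  An empty result signals a genotype incompatible
    with the candidate haplotype list.
    """
    if len(genotype) != candidates.n_loci:
        raise ValueError("genotype length does not match block length")
    out: set[Diplotype] = set()
    haps = candidates.haplotypes
    for i, h in enumerate(haps):
        for hp in haps[i:]:
            if _matches(genotype, tuple(x + y for x, y in zip(h.alleles, hp.alleles))):
                out.add(Diplotype(h, hp))
    return out


def hwe_prior(d: Diplotype, freqs: HaplotypeFrequencies) -> float:
    """Hardy-Weinberg diplotype prior: pi_h^2, or 2 pi_h pi_h' if heterozygous."""
    p = freqs.frequency(d.first)
    q = freqs.frequency(d.second)
    return p * q if d.is_homozygous else 2.0 * p * q


def transmission_prob(
    parent: Union[Diplotype, SourcedDiplotype],
    transmitted: Union[Haplotype, str],
) -> float:
    """Mendelian probability of transmitting a haplotype, no recombination."""
    t = _as_haplotype(transmitted)
    if isinstance(parent, SourcedDiplotype):
        a, b = parent.paternal, parent.maternal
    else:
        a, b = parent.first, parent.second
    if a == b:
        return 1.0 if t == a else 0.0
    hit = (t == a) + (t == b)
    return 0.5 * hit


@dataclass
class FamilyConfiguration:
    """One compatible assignment of diplotypes to every family member.

    ``assignment`` maps person_id to a :class:`SourcedDiplotype`;
    founders' pairs are stored in canonical (unordered) order since
    their own parental origin is unidentifiable.  ``weight`` is the
    product of founder HWE priors and nonfounder transmission
    probabilities; zero-weight assignments are never produced.
    """

    assignment: dict[str, SourcedDiplotype]
    weight: float


def enumerate_family_configs(
    ped,
    genotypes: dict[str, Sequence[int]],
    freqs: HaplotypeFrequencies,
    budget: int = 5_000_000,
) -> Iterator[FamilyConfiguration]:
    """Depth-first enumeration of all compatible family configurations.

    Members are processed in topological order (founders first); a
    branch is pruned as soon as a member has no diplotype compatible
    with its observed genotype and its parents' assigned haplotypes.
    Founder diplotypes are enumerated unordered (each unordered pair
    once, with the heterozygous HWE factor 2 in the prior), so the sum
    of weights over all yielded configurations equals the probability
    of the observed genotype data under the haplotype-frequency model.

    ``budget`` bounds the number of partial states visited; exceeding
    it raises :class:`CapacityError` naming the family.
    """
    order = ped.topological_order()
    L = freqs.n_loci
    missing_row = (MISSING,) * L

    # per-founder candidate unordered pairs with their HWE priors
    founder_opts: dict[str, list[tuple[Diplotype, float]]] = {}
    for m in order:
        if m.is_founder:
            g = tuple(genotypes.get(m.person_id, missing_row))
            opts = []
            for d in sorted(compatible_diplotypes(g, freqs), key=str):
                w = hwe_prior(d, freqs)
                if w > 0.0:
                    opts.append((d, w))
            founder_opts[m.person_id] = opts

    states = 0

    def recurse(i: int, assigned: dict[str, SourcedDiplotype], weight: float):
        nonlocal states
        if i == len(order):
            yield FamilyConfiguration(dict(assigned), weight)
            return
        m = order[i]
        states += 1
        if states > budget:
            raise CapacityError(
                f"enumeration budget exceeded for family {ped.family_id!r}"
            )
        if m.is_founder:
            for d, w in founder_opts[m.person_id]:
                assigned[m.person_id] = SourcedDiplotype(d.first, d.second)
                yield from recurse(i + 1, assigned, weight * w)
            assigned.pop(m.person_id, None)
            return
        g = tuple(genotypes.get(m.person_id, missing_row))
        fa = assigned[m.father_id]
        mo = assigned[m.mother_id]
        pat_opts = {fa.paternal, fa.maternal}
        mat_opts = {mo.paternal, mo.maternal}
        for hp in sorted(pat_opts):
            tp = transmission_prob(fa, hp)
            for hm in sorted(mat_opts):
                tm = transmission_prob(mo, hm)
                if not _matches(g, tuple(x + y for x, y in zip(hp.alleles, hm.alleles))):
                    continue
                assigned[m.person_id] = SourcedDiplotype(hp, hm)
                yield from recurse(i + 1, assigned, weight * tp * tm)
        assigned.pop(m.person_id, None)

    yield from recurse(0, {}, 1.0)
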