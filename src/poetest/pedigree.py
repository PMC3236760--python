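"""Pedigree structures, validation, and kinship computation.

A pedigree is a single family: an ordered collection of individuals in
which every nonfounder's two parents are either both present in the same
family or both absent (founder).  Parent-of-origin inference needs both
parental slots, so single-parent records are completed upstream with
placeholder founders (see :mod:`poetest.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "MarkerBlock",
    "KinshipMatrix",
    "validate_pedigree",
    "kinship_matrix",
]


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are either both set or both ``None``;
    an individual with no parents in the family is a founder.
    """

    person_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"  # {male, female, unknown}

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A single family's members, ordered.

    Provides id lookup, founder/nonfounder partition, a topological
    (parents-before-children) processing order and generation depths.
    """

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members = list(members)
        self._by_id = {m.person_id: m for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self._by_id

    def __getitem__(self, person_id: str) -> Individual:
        return self._by_id[person_id]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def topological_order(self) -> list[Individual]:
        """Members ordered with parents before children.

        Raises ``ValueError`` on cyclic parentage; run
        :func:`validate_pedigree` first for a descriptive report.
        """
        indeg = {}
        children: dict[str, list[str]] = {m.person_id: [] for m in self.members}
        for m in self.members:
            n = 0
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid in self._by_id:
                    children[pid].append(m.person_id)
                    n += 1
            indeg[m.person_id] = n
        queue = [m.person_id for m in self.members if indeg[m.person_id] == 0]
        order: list[Individual] = []
        while queue:
            pid = queue.pop()
            order.append(self._by_id[pid])
            for c in children[pid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.members):
            raise ValueError(
                f"cyclic parentage in family {self.family_id!r}"
            )
        return order

    def generation_depth(self) -> dict[str, int]:
        """Founders at depth 0; child depth = max(parent depths) + 1."""
        depth: dict[str, int] = {}
        for m in self.topological_order():
            if m.is_founder:
                depth[m.person_id] = 0
            else:
                depth[m.person_id] = 1 + max(
                    depth.get(m.father_id, 0), depth.get(m.mother_id, 0)
                )
        return depth


@dataclass(frozen=True)
class MarkerBlock:
    """An ordered haplotype block of SNPs with one designated testing SNP.

    Loci are addressed by 0-based index within the block; no genomic
    position arithmetic is performed.
    """

    locus_names: tuple[str, ...]
    testing_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "locus_names", tuple(self.locus_names))
        if len(self.locus_names) < 1:
            raise ValueError("block must contain at least one locus")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("locus names must be unique")
        if not 0 <= self.testing_index < len(self.locus_names):
            raise ValueError("testing_index outside block")

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def testing_locus(self) -> str:
        return self.locus_names[self.testing_index]


@dataclass
class KinshipMatrix:
    """Twice the kinship coefficients (2*phi) over a family's nonfounders.

    Diagonal is 1 for non-inbred individuals; the matrix scales the
    polygenic covariance so that sigma_g^2 is one individual's polygenic
    variance.
    """

    person_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def restrict(self, person_ids: Iterable[str]) -> "KinshipMatrix":
        ids = list(person_ids)
        idx = [self.person_ids.index(p) for p in ids]
        return KinshipMatrix(tuple(ids), self.values[np.ix_(idx, idx)])


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Check the pedigree invariants; return violations (empty = valid).

    Violations are data, not exceptions: each message names the
    individual and the rule it breaks.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for m in ped.members:
        if m.person_id in seen:
            violations.append(f"{m.person_id}: duplicated person_id")
        seen.add(m.person_id)
        if (m.father_id is None) != (m.mother_id is None):
            violations.append(f"{m.person_id}: one parent missing from record")
            continue
        if m.is_founder:
            continue
        for role, pid in (("father", m.father_id), ("mother", m.mother_id)):
            if pid not in ped:
                violations.append(
                    f"{m.person_id}: {role} {pid!r} not found in family "
                    f"{ped.family_id!r}"
                )
            elif pid == m.person_id:
                violations.append(f"{m.person_id}: individual is its own {role}")
        fa = ped[m.father_id] if m.father_id in ped else None
        mo = ped[m.mother_id] if m.mother_id in ped else None
        if fa is not None and fa.sex == "female":
            violations.append(f"{m.person_id}: father {fa.person_id} recorded as female")
        if mo is not None and mo.sex == "male":
            violations.append(f"{m.person_id}: mother {mo.person_id} recorded as male")
    # cycle detection (only meaningful if parent references resolve)
    if not violations:
        try:
            ped.topological_order()
        except ValueError:
            violations.append(
                f"{ped.family_id}: cyclic parentage (an individual is its own ancestor)"
            )
    elif _has_cycle(ped):
        violations.append(
            f"{ped.family_id}: cyclic parentage (an individual is its own ancestor)"
        )
    if not ped.nonfounders:
        violations.append(f"{ped.family_id}: family has no nonfounders")
    return violations


def _has_cycle(ped: Pedigree) -> bool:
    try:
        ped.topological_order()
        return False
    except ValueError:
        return True


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Numerator-relationship entries 2*phi over the family's nonfounders.

    Computed by the standard recursion over the whole pedigree in
    topological order, then restricted to nonfounders.  With A = 2*phi:
    founders have A_ii = 1 and A_ij = 0 among themselves; for a
    nonfounder i with parents f, m processed earlier,
    A_ij = (A_jf + A_jm) / 2 for earlier j, and A_ii = 1 + A_fm / 2.
    """
    if validate_pedigree(ped):
        raise ValueError(
            f"pedigree {ped.family_id!r} failed validation; "
            "run validate_pedigree for details"
        )
    order = ped.topological_order()
    pos = {m.person_id: k for k, m in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, m in enumerate(order):
        if m.is_founder:
            A[i, i] = 1.0
            continue
        f, g = pos[m.father_id], pos[m.mother_id]
        A[i, i] = 1.0 + 0.5 * A[f, g]
        for j in range(i):
            A[i, j] = A[j, i] = 0.5 * (A[j, f] + A[j, g])
    ids = [m.person_id for m in order if not m.is_founder]
    idx = [pos[p] for p in ids]
    return KinshipMatrix(tuple(ids), A[np.ix_(idx, idx)])
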