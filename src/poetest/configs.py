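"""Collapsed family-configuration tables.

The pedigree likelihood is a sum over every assignment of haplotype
pairs to family members that is compatible with observed genotypes and
Mendelian transmission.  Two assignments contribute identically to the
likelihood whenever they agree on (a) the multiset of founder
haplotypes (which fixes the HWE prior), (b) the number of heterozygous
founders, and (c) the sourced alleles at the testing locus of every
phenotyped nonfounder (which fix the trait means).  This module builds,
per family, the table of such equivalence classes with their summed
transmission weights.  The table depends on the candidate haplotype
list but not on the haplotype frequencies, so it is built once and
reused across EM iterations; frequency-dependent founder priors are
reconstructed from the stored counts.

Tables are built bottom-up over nuclear units from the latest
generation upward (Elston-Stewart-style peeling), merging equivalent
partial configurations as generations are absorbed; pedigrees whose
structure defeats the unit decomposition (e.g. marriages between two
nonfounders) fall back to a depth-first enumeration with the same
collapsing.  Both organizations compute the identical exact sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotypes import MISSING, CapacityError

__all__ = ["HapSpace", "ConfigTable", "build_config_table"]

DEFAULT_BUDGET = 5_000_000


class _Unsupported(Exception):
    """Pedigree shape outside the nuclear-unit peeling scheme."""


class HapSpace:
    """Candidate haplotypes as an indexed allele matrix with memoised
    genotype-compatibility lookups (shared across families and
    replicates)."""

    def __init__(self, alleles: np.ndarray):
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.t, self.n_loci = self.alleles.shape
        self._rows = [tuple(int(a) for a in r) for r in self.alleles]
        self._compat: dict[tuple, list[tuple[int, int]]] = {}

    def compat_pairs(self, geno: tuple) -> list[tuple[int, int]]:
        """Unordered candidate index pairs matching ``geno`` at typed loci."""
        hit = self._compat.get(geno)
        if hit is not None:
            return hit
        rows = self._rows
        out = []
        for i in range(self.t):
            ri = rows[i]
            for j in range(i, self.t):
                rj = rows[j]
                if all(g == MISSING or g == a + b for g, a, b in zip(geno, ri, rj)):
                    out.append((i, j))
        self._compat[geno] = out
        return out

    def pair_matches(self, geno: tuple, p: int, m: int) -> bool:
        rp = self._rows[p]
        rm = self._rows[m]
        return all(g == MISSING or g == a + b for g, a, b in zip(geno, rp, rm))


@dataclass
class ConfigTable:
    """Collapsed configuration classes for one family.

    ``trans``: summed transmission-probability weights per class;
    ``counts``: (C, t) founder haplotype counts; ``het``: heterozygous
    founder count; ``s``/``d``: per phenotyped nonfounder, g_p + g_m
    and g_m - g_p at the testing locus; ``n_raw``: raw (uncollapsed)
    configurations merged into each class.
    """

    trans: np.ndarray
    counts: np.ndarray
    het: np.ndarray
    s: np.ndarray
    d: np.ndarray
    n_raw: np.ndarray

    @property
    def n_configs(self) -> int:
        return len(self.trans)

    @property
    def total_raw(self) -> int:
        return int(self.n_raw.sum())


def build_config_table(
    ped,
    genotypes: dict,
    space: HapSpace,
    phenotyped_slots: dict[str, int],
    testing_index: int,
    budget: int = DEFAULT_BUDGET,
    strategy: str = "auto",
) -> ConfigTable:
    """Build the collapsed configuration table for one family.

    ``phenotyped_slots`` maps phenotyped-nonfounder person_ids to their
    row index in the family's trait vector.  ``strategy`` forces the
    traversal ('peel' or 'dfs'); 'auto' prefers peeling.
    """
    missing_row = (MISSING,) * space.n_loci
    geno = {
        m.person_id: tuple(genotypes.get(m.person_id, missing_row))
        for m in ped.members
    }
    if strategy not in ("auto", "peel", "dfs"):
        raise ValueError(f"unknown strategy {strategy!r}")
    entries = None
    if strategy in ("auto", "peel"):
        try:
            entries = _peel_entries(
                ped, geno, space, phenotyped_slots, testing_index, budget
            )
        except _Unsupported:
            if strategy == "peel":
                entries = None  # fall through to exact DFS below
    if entries is None:
        entries = _dfs_entries(
            ped, geno, space, phenotyped_slots, testing_index, budget
        )
    return _assemble(entries, space.t, len(phenotyped_slots))


def _assemble(entries: dict, t: int, k: int) -> ConfigTable:
    C = len(entries)
    trans = np.empty(C)
    counts = np.zeros((C, t))
    het = np.empty(C, dtype=np.int16)
    S = np.zeros((C, k))
    D = np.zeros((C, k))
    nraw = np.empty(C, dtype=np.int64)
    for c, ((fkey, h, sd), (w, raw)) in enumerate(entries.items()):
        trans[c] = w
        het[c] = h
        nraw[c] = raw
        for idx in fkey:
            counts[c, idx] += 1.0
        for slot, s_val, d_val in sd:
            S[c, slot] = s_val
            D[c, slot] = d_val
    return ConfigTable(trans, counts, het, S, D, nraw)


# ---------------------------------------------------------------------------
# child sourced-allele options under a fixed parental pair of pairs


def _child_options(space, cg, fa_pair, mo_pair, slot, tl):
    """Reduced sourced options for one (leaf) child: distinct (s, d)
    outcomes at the testing locus with summed transmission weights.

    Returns list of (key, weight, raw) where key is None for a child
    whose phenotype is missing (its identity is irrelevant), or
    (g_p + g_m, g_m - g_p).
    """
    fi, fj = fa_pair
    mi, mj = mo_pair
    opts: dict = {}
    raws: dict = {}
    pat = (fi,) if fi == fj else (fi, fj)
    mat = (mi,) if mi == mj else (mi, mj)
    tp = 1.0 / len(pat)
    tm = 1.0 / len(mat)
    al = space.alleles
    for p in pat:
        for m in mat:
            if not space.pair_matches(cg, p, m):
                continue
            if slot is None:
                key = None
            else:
                gp = int(al[p, tl])
                gm = int(al[m, tl])
                key = (gp + gm, gm - gp)
            opts[key] = opts.get(key, 0.0) + tp * tm
            raws[key] = raws.get(key, 0) + 1
    return [(key, opts[key], raws[key]) for key in opts]


# ---------------------------------------------------------------------------
# fast path: one nuclear unit (two founder parents, leaf children)


def _nuclear_entries(ped, geno, space, slots, tl, budget):
    founders = ped.founders
    nonf = ped.nonfounders
    father, mother = None, None
    for m in nonf:
        fa, mo = m.father_id, m.mother_id
        if father is None:
            father, mother = fa, mo
        elif (fa, mo) != (father, mother):
            raise _Unsupported
    if {f.person_id for f in founders} != {father, mother}:
        raise _Unsupported
    f_pairs = space.compat_pairs(geno[father])
    m_pairs = space.compat_pairs(geno[mother])
    children = [(geno[m.person_id], slots.get(m.person_id)) for m in nonf]
    out: dict = {}
    states = 0
    for fi, fj in f_pairs:
        for mi, mj in m_pairs:
            states += 1
            if states > budget:
                raise CapacityError(
                    f"enumeration budget exceeded for family {ped.family_id!r}"
                )
            fkey = tuple(sorted((fi, fj, mi, mj)))
            het = int(fi != fj) + int(mi != mj)
            tw = 1.0
            raw_mult = 1
            phen_opts = []
            ok = True
            for cg, slot in children:
                olist = _child_options(space, cg, (fi, fj), (mi, mj), slot, tl)
                if not olist:
                    ok = False
                    break
                if slot is None:
                    tw *= sum(o[1] for o in olist)
                    raw_mult *= sum(o[2] for o in olist)
                else:
                    phen_opts.append((slot, olist))
            if not ok:
                continue
            combos = [((), tw, raw_mult)]
            for slot, olist in phen_opts:
                combos = [
                    (sd + ((slot, key[0], key[1]),), w * ow, r * oraw)
                    for (sd, w, r) in combos
                    for (key, ow, oraw) in olist
                ]
                states += len(combos)
                if states > budget:
                    raise CapacityError(
                        f"enumeration budget exceeded for family {ped.family_id!r}"
                    )
            for sd, w, r in combos:
                k = (fkey, het, sd)
                if k in out:
                    w0, r0 = out[k]
                    out[k] = (w0 + w, r0 + r)
                else:
                    out[k] = (w, r)
    return out


# ---------------------------------------------------------------------------
# general peeling over nuclear units, latest generation first

_EMPTY_KEY = ((), 0, ())


def _merge_tables(t1: dict, t2: dict, budget_state) -> dict:
    """Cross-product of two partial-configuration tables (disjoint
    member sets), merging equivalent results."""
    if not t1 or not t2:
        return {}
    out: dict = {}
    for (f1, h1, sd1), (w1, r1) in t1.items():
        for (f2, h2, sd2), (w2, r2) in t2.items():
            budget_state[0] += 1
            if budget_state[0] > budget_state[1]:
                raise CapacityError(
                    f"enumeration budget exceeded for family {budget_state[2]!r}"
                )
            key = (
                tuple(sorted(f1 + f2)),
                h1 + h2,
                tuple(sorted(sd1 + sd2)),
            )
            if key in out:
                w0, r0 = out[key]
                out[key] = (w0 + w1 * w2, r0 + r1 * r2)
            else:
                out[key] = (w1 * w2, r1 * r2)
    return out


def _add_into(acc: dict, tab: dict, scale: float = 1.0, raw_scale: int = 1):
    for key, (w, r) in tab.items():
        if key in acc:
            w0, r0 = acc[key]
            acc[key] = (w0 + scale * w, r0 + raw_scale * r)
        else:
            acc[key] = (scale * w, raw_scale * r)


def _peel_entries(ped, geno, space, slots, tl, budget):
    members = {m.person_id: m for m in ped.members}
    units: dict[tuple[str, str], list[str]] = {}
    for m in ped.members:
        if not m.is_founder:
            units.setdefault((m.father_id, m.mother_id), []).append(m.person_id)
    if not units:
        raise _Unsupported
    # fast path for the overwhelmingly common case
    try:
        return _nuclear_entries(ped, geno, space, slots, tl, budget)
    except _Unsupported:
        pass

    parent_units: dict[str, list[tuple[str, str]]] = {}
    for couple in units:
        for pid in couple:
            parent_units.setdefault(pid, []).append(couple)
    depth = ped.generation_depth()
    # process each parent's units deepest-children-first so that the
    # recursion absorbs the latest generations before earlier ones
    for pid in parent_units:
        parent_units[pid].sort(key=lambda u: -max(depth[c] for c in units[u]))

    visited_units: set[tuple[str, str]] = set()
    bstate = [0, budget, ped.family_id]

    def founder_base(pair) -> dict:
        i, j = pair
        return {(tuple(sorted(pair)), int(i != j), ()): (1.0, 1)}

    def child_table(cid, fa_pair, mo_pair) -> dict:
        """Sum over the child's sourced options, each combined with the
        subtree hanging below the child."""
        fi, fj = fa_pair
        mi, mj = mo_pair
        pat = (fi,) if fi == fj else (fi, fj)
        mat = (mi,) if mi == mj else (mi, mj)
        tp = 1.0 / len(pat)
        tm = 1.0 / len(mat)
        cg = geno[cid]
        slot = slots.get(cid)
        al = space.alleles
        acc: dict = {}
        for p in pat:
            for m in mat:
                if not space.pair_matches(cg, p, m):
                    continue
                if slot is None:
                    sd = ()
                else:
                    gp = int(al[p, tl])
                    gm = int(al[m, tl])
                    sd = ((slot, gp + gm, gm - gp),)
                base = {((), 0, sd): (tp * tm, 1)}
                down = person_units_table(cid, tuple(sorted((p, m))), None)
                _add_into(acc, _merge_tables(base, down, bstate))
        return acc

    def person_units_table(pid, pair, exclude) -> dict:
        """All units in which ``pid`` is a parent (except ``exclude``),
        conditioned on pid's haplotype pair."""
        result = {_EMPTY_KEY: (1.0, 1)}
        for couple in parent_units.get(pid, ()):  # noqa: B007
            if couple == exclude:
                continue
            result = _merge_tables(
                result, unit_table(couple, pid, pair), bstate
            )
            if not result:
                return {}
        return result

    def unit_table(couple, via, via_pair) -> dict:
        if couple in visited_units:
            raise _Unsupported  # loop: unit reachable twice
        visited_units.add(couple)
        father, mother = couple
        spouse = mother if via == father else father
        sp = members.get(spouse)
        if sp is None or not sp.is_founder:
            raise _Unsupported  # both parents nonfounders (or absent)
        out: dict = {}
        for s_pair in space.compat_pairs(geno[spouse]):
            bstate[0] += 1
            if bstate[0] > bstate[1]:
                raise CapacityError(
                    f"enumeration budget exceeded for family {ped.family_id!r}"
                )
            fa_pair = via_pair if via == father else s_pair
            mo_pair = s_pair if via == father else via_pair
            acc = _merge_tables(
                founder_base(s_pair),
                person_units_table(spouse, s_pair, couple),
                bstate,
            )
            for cid in units[couple]:
                if not acc:
                    break
                acc = _merge_tables(acc, child_table(cid, fa_pair, mo_pair), bstate)
            if acc:
                _add_into(out, acc)
        return out

    # connected components over the union-member graph
    comp: dict[str, str] = {}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for m in ped.members:
        comp[m.person_id] = m.person_id
    for (fa, mo), kids in units.items():
        for pid in kids + [fa, mo]:
            ra, rb = find(fa), find(pid)
            if ra != rb:
                comp[rb] = ra

    roots: dict[str, list[str]] = {}
    for m in ped.members:
        roots.setdefault(find(m.person_id), []).append(m.person_id)

    total = {_EMPTY_KEY: (1.0, 1)}
    for group in roots.values():
        # root the component at a founder who is a parent; childless
        # loner founders contribute only their own diplotype prior
        root = next(
            (p for p in group if members[p].is_founder and p in parent_units),
            None,
        )
        if root is None:
            if len(group) == 1 and members[group[0]].is_founder:
                tab: dict = {}
                for pair in space.compat_pairs(geno[group[0]]):
                    _add_into(tab, founder_base(pair))
            else:
                raise _Unsupported
        else:
            tab = {}
            for pair in space.compat_pairs(geno[root]):
                sub = _merge_tables(
                    founder_base(pair),
                    person_units_table(root, pair, None),
                    bstate,
                )
                _add_into(tab, sub)
        if not tab:
            return {}
        total = _merge_tables(total, tab, bstate)

    if visited_units != set(units):
        raise _Unsupported
    return total


# ---------------------------------------------------------------------------
# fallback: depth-first traversal in topological order with collapsing


def _dfs_entries(ped, geno, space, slots, tl, budget):
    order = ped.topological_order()
    al = space.alleles
    out: dict = {}
    states = [0]
    assigned: dict[str, tuple[int, int]] = {}

    def recurse(i, het, founders, sd, weight, raw):
        states[0] += 1
        if states[0] > budget:
            raise CapacityError(
                f"enumeration budget exceeded for family {ped.family_id!r}"
            )
        if i == len(order):
            key = (tuple(sorted(founders)), het, tuple(sorted(sd)))
            if key in out:
                w0, r0 = out[key]
                out[key] = (w0 + weight, r0 + raw)
            else:
                out[key] = (weight, raw)
            return
        m = order[i]
        pid = m.person_id
        g = geno[pid]
        if m.is_founder:
            for pair in space.compat_pairs(g):
                a, b = pair
                assigned[pid] = pair
                recurse(
                    i + 1,
                    het + int(a != b),
                    founders + [a, b],
                    sd,
                    weight,
                    raw,
                )
            assigned.pop(pid, None)
            return
        fi, fj = assigned[m.father_id]
        mi, mj = assigned[m.mother_id]
        pat = (fi,) if fi == fj else (fi, fj)
        mat = (mi,) if mi == mj else (mi, mj)
        tp = 1.0 / len(pat)
        tm = 1.0 / len(mat)
        slot = slots.get(pid)
        for p in pat:
            for mm in mat:
                if not space.pair_matches(g, p, mm):
                    continue
                if slot is None:
                    nsd = sd
                else:
                    gp = int(al[p, tl])
                    gm = int(al[mm, tl])
                    nsd = sd + ((slot, gp + gm, gm - gp),)
                assigned[pid] = (p, mm)
                recurse(i + 1, het, founders, nsd, weight * tp * tm, raw)
        assigned.pop(pid, None)

    recurse(0, 0, [], (), 1.0, 1)
    return out
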