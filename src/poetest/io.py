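"""Reading and writing study files.

PED/MAP follow the PLINK text dialect: whitespace-delimited PED columns
family, person, father, mother, sex (1 = male, 2 = female, 0 =
unknown), then two allele columns per SNP; parent id "0" means absent;
allele pair "0 0" means missing genotype.  Allele pairs are converted
to minor-allele dosage codes {0, 1, 2, -1 = missing}, the minor allele
being determined from founder allele counts (ties broken by
lexicographic allele name).

The phenotype table is a TSV with a header row: person_id, trait
column(s), covariate columns; empty cells are missing.

Single-parent records are completed with an ungenotyped,
phenotype-less placeholder founder so that every nonfounder has two
parent slots for transmission bookkeeping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .haplotypes import MISSING
from .pedigree import Individual, MarkerBlock, Pedigree, validate_pedigree

__all__ = [
    "FormatError",
    "StructuralError",
    "GenotypeTable",
    "PhenotypeTable",
    "read_map",
    "read_ped",
    "read_phenotypes",
    "load_study",
    "write_ped",
    "write_map",
    "write_phenotypes",
]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


class FormatError(ValueError):
    """Malformed input file (column counts, duplicates, codes)."""


class StructuralError(ValueError):
    """Pedigree structure error (e.g. a parent reference that does not
    resolve)."""


class GenotypeTable:
    """Minor-allele dosage codes per (person, locus); -1 = missing."""

    MISSING = MISSING

    def __init__(
        self,
        person_ids: Sequence[str],
        locus_names: Sequence[str],
        codes: np.ndarray,
    ):
        self.person_ids = tuple(person_ids)
        self.locus_names = tuple(locus_names)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.shape != (len(self.person_ids), len(self.locus_names)):
            raise FormatError("genotype matrix shape does not match labels")
        valid = np.isin(self.codes, (-1, 0, 1, 2))
        if not valid.all():
            raise FormatError("genotype codes must be in {0, 1, 2, missing}")
        self._row = {p: i for i, p in enumerate(self.person_ids)}

    def row(self, person_id: str) -> Optional[np.ndarray]:
        i = self._row.get(person_id)
        return None if i is None else self.codes[i]

    def subset_loci(self, locus_names: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_names.index(n) for n in locus_names]
        return GenotypeTable(self.person_ids, locus_names, self.codes[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes, index=list(self.person_ids), columns=list(self.locus_names)
        )


class PhenotypeTable:
    """Trait and covariate values per person; missing allowed.

    The covariate design row for a person is (1, covariates...) so the
    first entry is always the intercept.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str,
        covariates: Sequence[str] = (),
    ):
        if trait not in data.columns:
            raise FormatError(f"trait column {trait!r} not found")
        for c in covariates:
            if c not in data.columns:
                raise FormatError(f"covariate column {c!r} not found")
        self.data = data
        self.trait = trait
        self.covariates = tuple(covariates)

    def trait_value(self, person_id: str) -> float:
        if person_id not in self.data.index:
            return float("nan")
        return float(self.data.loc[person_id, self.trait])

    def design_row(self, person_id: str) -> Optional[np.ndarray]:
        """(1, covariates...) or None if any covariate is missing."""
        if person_id not in self.data.index:
            return None
        vals = [1.0]
        for c in self.covariates:
            v = self.data.loc[person_id, c]
            if pd.isna(v):
                return None
            vals.append(float(v))
        return np.array(vals)

    @property
    def n_covariates(self) -> int:
        return 1 + len(self.covariates)


def read_map(map_path: Union[str, Path]) -> list[str]:
    """SNP names in file order (PLINK .map: chrom, name, [cM,] pos)."""
    names = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) not in (3, 4):
            raise FormatError(f"{map_path}:{ln}: expected 3 or 4 columns")
        names.append(fields[1])
    if len(set(names)) != len(names):
        raise FormatError(f"{map_path}: duplicated SNP names")
    return names


def read_ped(
    ped_path: Union[str, Path], locus_names: Sequence[str]
) -> tuple[list[Pedigree], GenotypeTable]:
    """Parse a PED file against the MAP's SNP order.

    Returns the pedigrees (with placeholder founders inserted for
    single-parent records) and the dosage-coded genotype table.
    """
    L = len(locus_names)
    rows = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 5 + 2 * L:
            raise FormatError(
                f"{ped_path}:{ln}: expected {5 + 2 * L} columns "
                f"(5 + 2 alleles x {L} SNPs), got {len(fields)}"
            )
        rows.append(fields)

    seen = set()
    for f in rows:
        if f[1] in seen:
            raise FormatError(f"{ped_path}: duplicated person_id {f[1]!r}")
        seen.add(f[1])

    by_family: dict[str, list[list[str]]] = {}
    for f in rows:
        by_family.setdefault(f[0], []).append(f)

    # minor allele per locus from founder allele counts
    founder_rows = [f for f in rows if f[2] == "0" and f[3] == "0"]
    minor: list[str] = []
    alleles_per_locus: list[tuple[str, str]] = []
    for j in range(L):
        counts: dict[str, int] = {}
        for f in rows:
            for a in (f[5 + 2 * j], f[6 + 2 * j]):
                if a != "0":
                    counts.setdefault(a, 0)
        for f in founder_rows or rows:
            for a in (f[5 + 2 * j], f[6 + 2 * j]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise FormatError(
                f"{ped_path}: more than two alleles at SNP {locus_names[j]!r}"
            )
        if not counts:
            minor.append(None)
            alleles_per_locus.append((None, None))
            continue
        named = sorted(counts)  # lexicographic tie-break
        if len(named) == 1:
            # monomorphic: the observed allele is the major one
            minor.append(None)
            alleles_per_locus.append((named[0], None))
            continue
        else:
            a, b = named
            if counts[a] == counts[b]:
                major, minor_a = b, a  # tie: lexicographically first is minor
            elif counts[a] < counts[b]:
                major, minor_a = b, a
            else:
                major, minor_a = a, b
        minor.append(minor_a)
        alleles_per_locus.append((major, minor_a))

    pedigrees: list[Pedigree] = []
    person_ids: list[str] = []
    codes_rows: list[np.ndarray] = []
    for fam_id, fam_rows in by_family.items():
        members: list[Individual] = []
        present = {f[1] for f in fam_rows}
        ph = itertools.count(1)
        for f in fam_rows:
            father = None if f[2] == "0" else f[2]
            mother = None if f[3] == "0" else f[3]
            if (father is None) != (mother is None):
                # single-parent record: complete with a placeholder founder
                pid = f"{fam_id}__placeholder{next(ph)}"
                sex = "male" if father is None else "female"
                members.append(Individual(pid, fam_id, None, None, sex))
                if father is None:
                    father = pid
                else:
                    mother = pid
            for role, par in (("father", f[2]), ("mother", f[3])):
                if par != "0" and par not in present:
                    raise StructuralError(
                        f"{ped_path}: {role} {par!r} of individual {f[1]!r} "
                        f"not found in family {fam_id!r}"
                    )
            members.append(
                Individual(
                    f[1], fam_id, father, mother, _SEX_CODES.get(f[4], "unknown")
                )
            )
            dosg = np.empty(L, dtype=np.int8)
            for j in range(L):
                a1, a2 = f[5 + 2 * j], f[6 + 2 * j]
                if a1 == "0" or a2 == "0":
                    dosg[j] = MISSING
                else:
                    dosg[j] = (a1 == minor[j]) + (a2 == minor[j])
            person_ids.append(f[1])
            codes_rows.append(dosg)
        pedigrees.append(Pedigree(fam_id, members))
    table = GenotypeTable(person_ids, locus_names, np.vstack(codes_rows))
    table.alleles_per_locus = alleles_per_locus
    return pedigrees, table


def read_phenotypes(
    pheno_path: Union[str, Path], trait: str = None, covariates: Sequence[str] = ()
) -> PhenotypeTable:
    df = pd.read_csv(pheno_path, sep="\t", dtype={0: str})
    if df.columns[0] != "person_id":
        raise FormatError(
            f"{pheno_path}: first phenotype column must be 'person_id'"
        )
    if df["person_id"].duplicated().any():
        raise FormatError(f"{pheno_path}: duplicated person_id")
    df = df.set_index("person_id")
    if trait is None:
        trait = df.columns[0]
    return PhenotypeTable(df, trait, covariates)


def load_study(
    ped_path: Union[str, Path],
    map_path: Union[str, Path],
    pheno_path: Union[str, Path],
    block: Union[MarkerBlock, Sequence[str]],
    test_snp: Optional[str] = None,
    trait: Optional[str] = None,
    covariates: Sequence[str] = (),
) -> tuple[list[Pedigree], MarkerBlock, GenotypeTable, PhenotypeTable]:
    """Load and validate a full study.

    ``block`` is either a MarkerBlock or an ordered list of SNP names
    (a subset of the MAP), with ``test_snp`` naming the testing SNP.
    Genotypes are returned restricted to the block's loci, in block
    order.
    """
    snps = read_map(map_path)
    if isinstance(block, MarkerBlock):
        mb = block
    else:
        names = list(block)
        if test_snp is None:
            raise ValueError("test_snp required when block is a name list")
        if test_snp not in names:
            raise ValueError(f"test SNP {test_snp!r} not in block")
        mb = MarkerBlock(tuple(names), names.index(test_snp))
    for n in mb.locus_names:
        if n not in snps:
            raise FormatError(f"block SNP {n!r} not present in {map_path}")
    pedigrees, geno = read_ped(ped_path, snps)
    geno = geno.subset_loci(mb.locus_names)
    pheno = read_phenotypes(pheno_path, trait, covariates)
    for ped in pedigrees:
        violations = validate_pedigree(ped)
        if violations:
            raise StructuralError(
                f"family {ped.family_id!r}: " + "; ".join(violations)
            )
    return pedigrees, mb, geno, pheno


# ---------------------------------------------------------------------------
# writers (round-tripping and simulator output)


def write_map(path: Union[str, Path], locus_names: Iterable[str]):
    with open(path, "w") as fh:
        for i, n in enumerate(locus_names, 1):
            fh.write(f"1 {n} 0 {i}\n")


def write_ped(
    path: Union[str, Path],
    pedigrees: Sequence[Pedigree],
    geno: GenotypeTable,
    major_minor: Optional[Sequence[tuple[str, str]]] = None,
):
    """Write PED rows with dosage codes re-expanded to allele pairs.

    Placeholder founders (inserted for single-parent records) are
    skipped so the file round-trips.  Default allele names are A
    (major) / B (minor).
    """
    L = len(geno.locus_names)
    if major_minor is None:
        major_minor = [("A", "B")] * L
    with open(path, "w") as fh:
        for ped in pedigrees:
            placeholder = {
                m.person_id for m in ped.members if "__placeholder" in m.person_id
            }
            for m in ped.members:
                if m.person_id in placeholder:
                    continue
                father = m.father_id if m.father_id not in placeholder else None
                mother = m.mother_id if m.mother_id not in placeholder else None
                row = geno.row(m.person_id)
                alleles = []
                for j in range(L):
                    d = MISSING if row is None else int(row[j])
                    maj, mnr = major_minor[j]
                    if d == MISSING:
                        alleles += ["0", "0"]
                    else:
                        alleles += [mnr] * d + [maj] * (2 - d)
                fh.write(
                    " ".join(
                        [
                            ped.family_id,
                            m.person_id,
                            father or "0",
                            mother or "0",
                            _SEX_OUT.get(m.sex, "0"),
                        ]
                        + alleles
                    )
                    + "\n"
                )


def write_phenotypes(
    path: Union[str, Path], pheno: PhenotypeTable
):
    df = pheno.data.reset_index()
    df = df.rename(columns={df.columns[0]: "person_id"})
    df.to_csv(path, sep="\t", index=False)
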