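"""Case-control genotype tables and the sufficient statistics used for scoring.

The on-disk format is the tab-delimited "MDR-style" table widely used for
epistasis benchmarks: a header row, one column per biallelic SNP coded as
minor-allele dosage 0/1/2, and a final binary class column (1 = case).  An
equivalent comma-separated dialect is accepted.  Missing genotypes are not
supported: every cell must be a literal 0, 1 or 2 (0/1 for the class column).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "DDAG",
    "FamilyCounts",
    "GenotypeParseError",
    "MalformedGenotypeError",
    "MalformedClassError",
    "read_genotype_table",
    "write_genotype_table",
    "family_counts",
    "snp_marginal_counts",
]

_DIALECT_SEP = {"tab": "\t", "csv": ","}


class GenotypeParseError(ValueError):
    """A genotype table could not be parsed (ragged rows, non-numeric cells...)."""


class MalformedGenotypeError(GenotypeParseError):
    """A genotype value outside {0, 1, 2}."""


class MalformedClassError(GenotypeParseError):
    """A class (phenotype) value outside {0, 1}."""


@dataclass
class GenotypeDataset:
    """A complete case-control genotype matrix.

    Attributes
    ----------
    snp_names : list of str
        One identifier per SNP column.
    genotypes : ndarray of shape (m, n), values in {0, 1, 2}
        Minor-allele dosage per individual and SNP.  The three states are
        treated categorically by every scoring criterion, so the dosage
        coding is only a file convention.
    phenotype : ndarray of shape (m,), values in {0, 1}
        Disease status, 1 = case.
    """

    snp_names: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(np.asarray(self.genotypes), dtype=np.int8)
        self.phenotype = np.ascontiguousarray(np.asarray(self.phenotype), dtype=np.int8)
        self.snp_names = list(self.snp_names)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.phenotype.ndim != 1:
            raise ValueError("phenotype must be a 1-D vector")
        m, n = self.genotypes.shape
        if m < 1 or n < 1:
            raise ValueError("dataset needs at least one individual and one SNP")
        if len(self.phenotype) != m:
            raise ValueError("phenotype length does not match genotype rows")
        if len(self.snp_names) != n:
            raise ValueError("number of snp_names does not match genotype columns")
        if self.genotypes.min() < 0 or self.genotypes.max() > 2:
            raise MalformedGenotypeError("genotype values must be in {0, 1, 2}")
        if self.phenotype.min() < 0 or self.phenotype.max() > 1:
            raise MalformedClassError("phenotype values must be in {0, 1}")

    @property
    def m(self) -> int:
        """Number of individuals (rows)."""
        return self.genotypes.shape[0]

    @property
    def n(self) -> int:
        """Number of SNPs (columns)."""
        return self.genotypes.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_names == other.snp_names
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
        )


@dataclass(frozen=True)
class DDAG:
    """A direct DAG: the only edges run from SNP nodes into the disease node.

    A DDAG is fully identified by the disease node's parent set, stored as a
    sorted tuple of SNP column indices.  ``k = 0`` is the empty model in
    which the disease has no parents.
    """

    parent_set: tuple[int, ...]

    def __init__(self, parent_set=()) -> None:
        parents = tuple(sorted(int(i) for i in parent_set))
        if len(set(parents)) != len(parents):
            raise ValueError(f"duplicate parent indices in {parents}")
        if parents and parents[0] < 0:
            raise IndexError(f"negative SNP index in {parents}")
        object.__setattr__(self, "parent_set", parents)

    @property
    def k(self) -> int:
        return len(self.parent_set)

    def __iter__(self):
        return iter(self.parent_set)


@dataclass
class FamilyCounts:
    """Sufficient statistics for one node given its parents.

    ``s[child_state, parent_state]`` counts the data items in which the child
    took its ``k``-th value while its parents jointly took their ``j``-th
    value.  Joint parent states are indexed in mixed radix with the lowest
    SNP column index most significant, so scores are reproducible.
    """

    r: int
    q: int
    s: np.ndarray  # shape (r, q)
    parent_state_index: dict[tuple[int, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.int64)
        if self.s.shape != (self.r, self.q):
            raise ValueError(f"counts shape {self.s.shape} != ({self.r}, {self.q})")
        if (self.s < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def m(self) -> int:
        return int(self.s.sum())


def read_genotype_table(path, dialect: str = "tab") -> GenotypeDataset:
    """Read an MDR-style genotype table.

    The last column is taken as the binary class column regardless of its
    header name; all preceding columns are SNPs.
    """
    sep = _DIALECT_SEP[dialect]
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, header=0)
    except pd.errors.ParserError as exc:
        raise GenotypeParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise GenotypeParseError(f"{path}: need at least one SNP column plus a class column")
    raw = df.to_numpy()
    values = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    values = values.reshape(raw.shape)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise GenotypeParseError(
            f"{path}: non-numeric or missing cell at data row {r + 1}, column {df.columns[c]!r}"
        )
    if (values != np.floor(values)).any():
        r, c = np.argwhere(values != np.floor(values))[0]
        raise GenotypeParseError(
            f"{path}: non-integer cell at data row {r + 1}, column {df.columns[c]!r}"
        )
    values = values.astype(np.int64)
    geno, pheno = values[:, :-1], values[:, -1]
    bad = (geno < 0) | (geno > 2)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise MalformedGenotypeError(
            f"{path}: genotype {geno[r, c]} outside {{0,1,2}} at data row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    if ((pheno < 0) | (pheno > 1)).any():
        r = int(np.argwhere((pheno < 0) | (pheno > 1))[0][0])
        raise MalformedClassError(
            f"{path}: class value {pheno[r]} outside {{0,1}} at data row {r + 1}"
        )
    return GenotypeDataset(list(df.columns[:-1]), geno, pheno)


def write_genotype_table(dataset: GenotypeDataset, path, dialect: str = "tab",
                         class_name: str = "Class") -> None:
    """Write a dataset in a dialect readable by :func:`read_genotype_table`."""
    sep = _DIALECT_SEP[dialect]
    df = pd.DataFrame(dataset.genotypes, columns=dataset.snp_names)
    df[class_name] = dataset.phenotype
    df.to_csv(path, sep=sep, index=False)


def family_counts(dataset: GenotypeDataset, ddag: DDAG) -> FamilyCounts:
    """Sufficient statistics for the disease node given a DDAG's parent set.

    The child is the binary phenotype (r = 2); the joint parent state over
    the k parent SNPs has q = 3**k values, indexed in mixed radix with the
    first (lowest-index) parent most significant.
    """
    parents = ddag.parent_set
    if parents and (parents[0] < 0 or parents[-1] >= dataset.n):
        raise IndexError(f"parent index out of range for {dataset.n} SNPs: {parents}")
    k = len(parents)
    q = 3 ** k
    if k:
        radix = 3 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        codes = dataset.genotypes[:, list(parents)].astype(np.int64) @ radix
    else:
        codes = np.zeros(dataset.m, dtype=np.int64)
    s = np.bincount(dataset.phenotype.astype(np.int64) * q + codes,
                    minlength=2 * q).reshape(2, q)
    index = {
        state: int(sum(v * 3 ** (k - 1 - i) for i, v in enumerate(state)))
        for state in itertools.product(range(3), repeat=k)
    }
    return FamilyCounts(r=2, q=q, s=s, parent_state_index=index)


def snp_marginal_counts(dataset: GenotypeDataset) -> np.ndarray:
    """Per-SNP genotype counts, shape (n, 3): the root-family statistics."""
    out = np.zeros((dataset.n, 3), dtype=np.int64)
    for g in range(3):
        out[:, g] = (dataset.genotypes == g).sum(axis=0)
    return out
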