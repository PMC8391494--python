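"""Core data containers shared across the package.

Genotypes are coded ordinally per variant: ``1`` = homozygote for the major
allele (AA), ``2`` = heterozygote (AB), ``3`` = homozygote for the minor
allele (BB), and ``0`` = missing.  Phenotypes are binary: ``1`` = case,
``0`` = control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

CASE = 1
CONTROL = 0

MISSING = 0
GENOTYPE_CODES = (1, 2, 3)


@dataclass(frozen=True)
class VariantInfo:
    """Metadata for one biallelic variant.

    ``allele_a`` is the major allele in the analyzed sample (ties broken
    lexicographically); ``allele_b`` the minor allele, or ``"0"`` when the
    variant is monomorphic and no second allele was observed.
    """

    id: str
    chromosome: str = "0"
    position: int = 0
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("variant id must be nonempty")
        if self.position < 0:
            raise ValueError(f"variant {self.id}: position must be >= 0")
        if self.allele_a == self.allele_b and self.allele_a != "0":
            raise ValueError(f"variant {self.id}: alleles must differ")


@dataclass
class GenotypeMatrix:
    """Individuals x variants genotype codes with phenotype labels.

    Attributes
    ----------
    genotypes : ndarray of shape (n_individuals, n_variants)
        Integer codes in {0, 1, 2, 3}; 0 means missing.
    phenotype : ndarray of shape (n_individuals,)
        1 for cases, 0 for controls.
    variants : list of VariantInfo
    individual_ids : list of str
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    variants: list[VariantInfo]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, v = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} genotype rows"
            )
        if len(self.variants) != v:
            raise ValueError(
                f"{len(self.variants)} variant records for {v} genotype columns"
            )
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if self.genotypes.size and (
            self.genotypes.min() < 0 or self.genotypes.max() > 3
        ):
            raise ValueError("genotype codes must lie in {0,1,2,3}")
        if not np.isin(self.phenotype, (CASE, CONTROL)).all():
            raise ValueError("phenotype labels must be 0 (control) or 1 (case)")
        ids = [vi.id for vi in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == CONTROL).sum())

    def variant_index(self, variant_id: str) -> int:
        for i, vi in enumerate(self.variants):
            if vi.id == variant_id:
                return i
        raise KeyError(f"unknown variant id {variant_id!r}")

    def take_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            phenotype=self.phenotype.copy(),
            variants=[self.variants[i] for i in idx],
            individual_ids=list(self.individual_ids),
        )

    def take_individuals(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            genotypes=self.genotypes[idx, :],
            phenotype=self.phenotype[idx],
            variants=list(self.variants),
            individual_ids=[self.individual_ids[i] for i in idx],
        )


@dataclass(frozen=True, order=True)
class GenotypePattern:
    """A set of (variant index, genotype code) pairs over distinct variants.

    Entries are stored sorted by variant index, which fixes a canonical
    representation used for identity, hashing and deterministic ordering.
    """

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.entries))
        object.__setattr__(self, "entries", ordered)
        variants = [v for v, _ in ordered]
        if len(set(variants)) != len(variants):
            raise ValueError("pattern entries must lie on distinct variants")
        if not 1 <= len(ordered) <= 3:
            raise ValueError("pattern length must be 1-3")
        for v, g in ordered:
            if g not in GENOTYPE_CODES:
                raise ValueError(f"genotype code {g} not in {{1,2,3}}")
            if v < 0:
                raise ValueError("variant index must be >= 0")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "GenotypePattern":
        return cls(entries=tuple(pairs))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def variant_indices(self) -> tuple[int, ...]:
        return tuple(v for v, _ in self.entries)

    @property
    def genotype_codes(self) -> tuple[int, ...]:
        return tuple(g for _, g in self.entries)

    def label(self, variants: Sequence[VariantInfo] | None = None) -> str:
        if variants is None:
            return ";".join(f"v{v}={g}" for v, g in self.entries)
        return ";".join(f"{variants[v].id}={g}" for v, g in self.entries)


@dataclass
class PatternStats:
    """Scored genotype pattern.

    ``support`` counts carriers over all individuals (an individual with a
    missing genotype at a pattern variant demonstrably does not carry the
    pattern, so it contributes to the denominator of nothing but is not a
    carrier).  ``confidence`` is the fraction of carriers belonging to the
    mining target class (cases by default).
    """

    pattern: GenotypePattern
    support: int
    case_count: int
    control_count: int
    confidence: float
    chi2: float
    nominal_p: float
    corrected_p: float | None = None

    def __post_init__(self) -> None:
        if self.support != self.case_count + self.control_count:
            raise ValueError("support must equal case_count + control_count")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds for the pattern search.

    min_support is an absolute carrier count; min_confidence a fraction;
    max_length the maximal number of variants per pattern (1-3);
    target_class the phenotype the confidence filter is computed against.
    """

    min_support: int = 5
    min_confidence: float = 0.8
    max_length: int = 2
    target_class: int = CASE

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must lie in [0, 1]; 0 disables the filter")
        if self.max_length not in (1, 2, 3):
            raise ValueError("max_length must be 1, 2 or 3")
        if self.target_class not in (CASE, CONTROL):
            raise ValueError("target_class must be 0 or 1")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Phenotype x pattern-carrier 2x2 table.

    Individuals missing any genotype of the pattern are excluded entirely,
    so the four cells need not sum to the full sample size.
    """

    cases_with: int
    cases_without: int
    controls_with: int
    controls_without: int

    def __post_init__(self) -> None:
        for c in (
            self.cases_with,
            self.cases_without,
            self.controls_with,
            self.controls_without,
        ):
            if c < 0:
                raise ValueError("counts must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                [self.cases_with, self.cases_without],
                [self.controls_with, self.controls_without],
            ],
            dtype=np.int64,
        )

    @property
    def total(self) -> int:
        return (
            self.cases_with
            + self.cases_without
            + self.controls_with
            + self.controls_without
        )


@dataclass
class TwoLocusTable:
    """Paired 3x3 genotype count tables for cases and controls.

    Rows index the genotype (1/2/3) at the first variant, columns the
    genotype at the second; flattened row-major this is the 2x9
    phenotype-by-genotype-pair contingency table.
    """

    case_counts: np.ndarray
    control_counts: np.ndarray
    variant_ids: tuple[str, str] = ("v1", "v2")

    def __post_init__(self) -> None:
        self.case_counts = np.asarray(self.case_counts, dtype=np.int64)
        self.control_counts = np.asarray(self.control_counts, dtype=np.int64)
        if self.case_counts.shape != (3, 3) or self.control_counts.shape != (3, 3):
            raise ValueError("count tables must be 3x3")
        if (self.case_counts < 0).any() or (self.control_counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())

    def as_2x9(self) -> np.ndarray:
        return np.vstack(
            [self.case_counts.ravel(), self.control_counts.ravel()]
        )
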