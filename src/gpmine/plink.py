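"""Reading and writing PLINK text genotype data (.ped / .map).

The PED dialect is PLINK's whitespace-delimited text default: six mandatory
leading columns (family, individual, father, mother, sex, phenotype)
followed by two allele tokens per variant.  Phenotype is coded 1 = control,
2 = case; 0 or -9 marks a missing phenotype and the individual is dropped.
Sex, family structure and the MAP genetic-distance column are parsed but
ignored.

Alleles are recoded to ordinal genotype codes with ``1``/``2``/``3`` for
major homozygote / heterozygote / minor homozygote and ``0`` for missing;
the major allele is the one with the higher sample allele frequency, ties
broken lexicographically.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from collections import Counter
from typing import IO, Iterable, Sequence

import numpy as np

from .containers import CASE, CONTROL, GenotypeMatrix, VariantInfo

__all__ = [
    "TransactionSet",
    "read_ped_map",
    "write_ped_map",
    "recode_genotypes",
    "filter_missing",
    "itemize",
    "encode_item",
    "decode_item",
    "write_transactions",
]

_PHENOTYPE_CODES = {"1": CONTROL, "2": CASE}
_MISSING_PHENOTYPE = {"0", "-9"}


def encode_item(variant_index: int, genotype_code: int) -> int:
    """Map a (variant, genotype) cell to its integer item code."""
    return variant_index * 3 + (genotype_code - 1)


def decode_item(item: int) -> tuple[int, int]:
    """Inverse of :func:`encode_item`."""
    return item // 3, item % 3 + 1


@dataclass
class TransactionSet:
    """Per-individual genotype items for the frequent-itemset engine.

    Each non-missing genotype cell becomes one integer item,
    ``variant_index * 3 + (code - 1)``; missing cells emit nothing, so
    transaction lengths may differ.  The phenotype travels alongside the
    transaction as its label — it is never itself a minable item, because
    it plays the role of the rule consequent.
    """

    transactions: list[list[int]]
    phenotype: np.ndarray
    n_variants: int

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if len(self.transactions) != self.phenotype.shape[0]:
            raise ValueError("one phenotype label per transaction required")


def _open(source, mode: str = "r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


def recode_genotypes(
    allele_pairs: Sequence[tuple[str, str]], variant_id: str = "?"
) -> tuple[np.ndarray, str, str]:
    """Recode one variant's allele pairs to ordinal genotype codes.

    Returns ``(codes, allele_a, allele_b)`` where ``allele_a`` is the major
    allele (higher sample frequency, ties broken lexicographically) and
    codes are 1 (major hom), 2 (het), 3 (minor hom), 0 (missing: any pair
    containing the token "0").

    Raises
    ------
    ValueError
        If more than two distinct non-missing alleles are observed.
    """
    freq: Counter[str] = Counter()
    for a1, a2 in allele_pairs:
        if a1 != "0" and a2 != "0":
            freq[a1] += 1
            freq[a2] += 1
    alleles = sorted(freq)
    if len(alleles) > 2:
        raise ValueError(
            f"variant {variant_id}: more than two alleles observed ({alleles})"
        )
    if not alleles:
        major, minor = "0", "0"
    elif len(alleles) == 1:
        major, minor = alleles[0], "0"
    else:
        # higher count wins; lexicographically smaller wins ties
        major = min(alleles, key=lambda a: (-freq[a], a))
        minor = alleles[0] if major == alleles[1] else alleles[1]

    codes = np.zeros(len(allele_pairs), dtype=np.int8)
    for i, (a1, a2) in enumerate(allele_pairs):
        if a1 == "0" or a2 == "0":
            codes[i] = 0
        elif a1 == a2:
            codes[i] = 1 if a1 == major else 3
        else:
            codes[i] = 2
    return codes, major, minor


def read_ped_map(ped_source, map_source) -> GenotypeMatrix:
    """Read PLINK text files into a :class:`GenotypeMatrix`.

    Parameters are file paths or open text streams.  Individuals with a
    missing phenotype (0 or -9) are excluded; any other phenotype token
    besides 1/2 is a fatal error reporting the PED line number.
    """
    map_fh, close_map = _open(map_source)
    try:
        map_rows = []
        for line in map_fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ValueError(
                    f"MAP line needs 4 fields (chrom id cM position), got: {line!r}"
                )
            map_rows.append((fields[0], fields[1], int(fields[3])))
    finally:
        if close_map:
            map_fh.close()
    n_variants = len(map_rows)

    ped_fh, close_ped = _open(ped_source)
    ids: list[str] = []
    phenos: list[int] = []
    allele_rows: list[list[str]] = []
    try:
        for lineno, line in enumerate(ped_fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_variants:
                raise ValueError(
                    f"PED line {lineno}: {len(fields) - 6} allele columns do not "
                    f"match 2 x {n_variants} MAP variants"
                )
            pheno_tok = fields[5]
            if pheno_tok in _MISSING_PHENOTYPE:
                continue
            if pheno_tok not in _PHENOTYPE_CODES:
                raise ValueError(
                    f"PED line {lineno}: unknown phenotype code {pheno_tok!r} "
                    "(expected 1=control, 2=case, 0/-9=missing)"
                )
            ids.append(fields[1])
            phenos.append(_PHENOTYPE_CODES[pheno_tok])
            allele_rows.append(fields[6:])
    finally:
        if close_ped:
            ped_fh.close()

    n = len(ids)
    genotypes = np.zeros((n, n_variants), dtype=np.int8)
    variants: list[VariantInfo] = []
    for j, (chrom, vid, pos) in enumerate(map_rows):
        pairs = [(row[2 * j], row[2 * j + 1]) for row in allele_rows]
        codes, major, minor = recode_genotypes(pairs, variant_id=vid)
        genotypes[:, j] = codes
        variants.append(
            VariantInfo(
                id=vid, chromosome=chrom, position=pos,
                allele_a=major, allele_b=minor,
            )
        )
    return GenotypeMatrix(
        genotypes=genotypes,
        phenotype=np.array(phenos, dtype=np.int8),
        variants=variants,
        individual_ids=ids,
    )


def write_ped_map(m: GenotypeMatrix, ped_target, map_target) -> None:
    """Write a :class:`GenotypeMatrix` as PLINK text PED/MAP."""
    map_fh, close_map = _open(map_target, "w")
    try:
        for vi in m.variants:
            map_fh.write(f"{vi.chromosome}\t{vi.id}\t0\t{vi.position}\n")
    finally:
        if close_map:
            map_fh.close()

    code_to_pair = {}
    ped_fh, close_ped = _open(ped_target, "w")
    try:
        for i, iid in enumerate(m.individual_ids):
            pheno = "2" if m.phenotype[i] == CASE else "1"
            tokens = [iid, iid, "0", "0", "0", pheno]
            row = m.genotypes[i]
            for j, vi in enumerate(m.variants):
                g = int(row[j])
                if g == 0:
                    tokens += ["0", "0"]
                elif g == 1:
                    tokens += [vi.allele_a, vi.allele_a]
                elif g == 2:
                    tokens += [vi.allele_a, vi.allele_b]
                else:
                    tokens += [vi.allele_b, vi.allele_b]
            ped_fh.write(" ".join(tokens) + "\n")
    finally:
        if close_ped:
            ped_fh.close()


def filter_missing(
    m: GenotypeMatrix,
    max_variant_missing: float,
    max_individual_missing: float,
) -> GenotypeMatrix:
    """Drop variants then individuals exceeding a missing-genotype fraction.

    Variants with missing fraction strictly above ``max_variant_missing``
    are removed first; individual missingness is then recomputed on the
    surviving variants.  Thresholds of 0 reproduce PLINK's ``--geno 0`` /
    ``--mind 0`` behavior.  Survivor order is preserved.
    """
    for t in (max_variant_missing, max_individual_missing):
        if not 0.0 <= t <= 1.0:
            raise ValueError("missingness thresholds must lie in [0, 1]")
    missing = m.genotypes == 0
    var_frac = missing.mean(axis=0) if m.n_individuals else np.zeros(m.n_variants)
    keep_vars = np.flatnonzero(var_frac <= max_variant_missing)
    if keep_vars.size == 0:
        raise ValueError("missingness filter removed every variant")
    reduced = m.take_variants(keep_vars)
    ind_frac = (reduced.genotypes == 0).mean(axis=1)
    keep_inds = np.flatnonzero(ind_frac <= max_individual_missing)
    if keep_inds.size == 0:
        raise ValueError("missingness filter removed every individual")
    return reduced.take_individuals(keep_inds)


def itemize(m: GenotypeMatrix) -> TransactionSet:
    """Convert individuals into transactions of genotype items.

    Every non-missing (individual, variant) cell emits exactly one item
    ``variant_index * 3 + (code - 1)``; missing cells emit nothing.
    """
    if m.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    transactions = []
    for row in m.genotypes:
        nz = np.flatnonzero(row)
        transactions.append((nz * 3 + (row[nz] - 1)).tolist())
    return TransactionSet(
        transactions=transactions,
        phenotype=m.phenotype.copy(),
        n_variants=m.n_variants,
    )


def write_transactions(m: GenotypeMatrix, target) -> None:
    """Write a tab-separated transaction file: id, phenotype, item list."""
    ts = itemize(m)
    fh, close = _open(target, "w")
    try:
        for iid, pheno, items in zip(
            m.individual_ids, ts.phenotype, ts.transactions
        ):
            label = "case" if pheno == CASE else "control"
            fh.write(f"{iid}\t{label}\t{' '.join(map(str, items))}\n")
    finally:
        if close:
            fh.close()
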