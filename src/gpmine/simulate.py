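"""Synthetic case-control genotype data under two-locus penetrance models.

The generator emulates digenic inheritance: two causal variants whose
genotype pair determines disease risk through an arbitrary 3x3 penetrance
matrix (e.g., elevated penetrance confined to the double heterozygote),
surrounded by unassociated background variants.  All variants are in
Hardy-Weinberg equilibrium and mutual linkage equilibrium; case/control
ascertainment uses rejection sampling; missing genotypes are masked
completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CASE, CONTROL, GenotypeMatrix, TwoLocusTable, VariantInfo

__all__ = [
    "PenetranceModel",
    "hwe_genotype_probs",
    "simulate_digenic",
    "reconstruct_from_counts",
]

# rejection-sampling guard: draws per requested individual before giving up
_MAX_DRAW_FACTOR = 10_000


@dataclass
class PenetranceModel:
    """Two-locus disease model for the simulator.

    Attributes
    ----------
    maf1, maf2 : float
        Minor-allele frequencies of the two causal variants, in (0, 0.5].
    penetrance : (3, 3) array
        Disease probability given the genotype pair; rows index the
        genotype code (1/2/3) at variant 1, columns at variant 2.
    n_cases, n_controls : int
        Target sample sizes (ascertained by rejection sampling).
    n_null_variants : int
        Unassociated background variants, MAFs drawn uniformly from
        ``null_maf_range``.
    missing_rate : float
        Per-cell probability of masking a genotype to missing (MCAR).
    """

    maf1: float
    maf2: float
    penetrance: np.ndarray
    n_cases: int
    n_controls: int
    n_null_variants: int = 0
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        if self.penetrance.shape != (3, 3):
            raise ValueError("penetrance must be a 3x3 matrix")
        if (self.penetrance < 0).any() or (self.penetrance > 1).any():
            raise ValueError("penetrance entries must lie in [0, 1]")
        for q in (self.maf1, self.maf2):
            if not 0.0 < q <= 0.5:
                raise ValueError("MAFs must lie in (0, 0.5]")
        lo, hi = self.null_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("null MAF range must lie within (0, 0.5]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample targets must be >= 1")
        if self.n_null_variants < 0:
            raise ValueError("n_null_variants must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def hwe_genotype_probs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities (major hom, het, minor hom)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    q = maf
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)


def _draw_genotypes(
    rng: np.random.Generator, maf: float, n: int
) -> np.ndarray:
    return rng.choice(
        np.array([1, 2, 3], dtype=np.int8), size=n, p=hwe_genotype_probs(maf)
    )


def simulate_digenic(model: PenetranceModel, seed: int) -> GenotypeMatrix:
    """Simulate a case-control sample under a two-locus penetrance model.

    Individuals are rejection-sampled: causal genotypes drawn from HWE,
    disease assigned with the penetrance cell's probability, and the
    individual kept only while its phenotype's quota is unfilled.  The
    two causal variants occupy columns 0 and 1; background variants
    follow.  Deterministic given ``seed``.
    """
    if not (model.penetrance > 0).any():
        raise ValueError("no penetrance > 0: cases are unattainable")
    if not (model.penetrance < 1).any():
        raise ValueError("no penetrance < 1: controls are unattainable")
    rng = np.random.default_rng(seed)
    need = model.n_cases + model.n_controls
    case_rows: list[tuple[int, int]] = []
    ctrl_rows: list[tuple[int, int]] = []
    drawn = 0
    batch = max(256, 2 * need)
    while (
        len(case_rows) < model.n_cases or len(ctrl_rows) < model.n_controls
    ):
        if drawn > _MAX_DRAW_FACTOR * need:
            raise RuntimeError(
                "rejection sampling did not reach the requested sample "
                "sizes; penetrance model is too extreme"
            )
        g1 = _draw_genotypes(rng, model.maf1, batch)
        g2 = _draw_genotypes(rng, model.maf2, batch)
        affected = rng.random(batch) < model.penetrance[g1 - 1, g2 - 1]
        drawn += batch
        for a, b, dis in zip(g1, g2, affected):
            if dis and len(case_rows) < model.n_cases:
                case_rows.append((a, b))
            elif not dis and len(ctrl_rows) < model.n_controls:
                ctrl_rows.append((a, b))

    causal = np.array(case_rows + ctrl_rows, dtype=np.int8)
    phenotype = np.array(
        [CASE] * model.n_cases + [CONTROL] * model.n_controls, dtype=np.int8
    )
    n = need
    columns = [causal]
    variants = [
        VariantInfo(id="causal1", chromosome="1", position=1000,
                    allele_a="A", allele_b="B"),
        VariantInfo(id="causal2", chromosome="2", position=2000,
                    allele_a="A", allele_b="B"),
    ]
    if model.n_null_variants:
        lo, hi = model.null_maf_range
        null_mafs = rng.uniform(lo, hi, model.n_null_variants)
        null_geno = np.column_stack(
            [_draw_genotypes(rng, q, n) for q in null_mafs]
        )
        columns.append(null_geno)
        width = len(str(model.n_null_variants))
        variants += [
            VariantInfo(
                id=f"null{j + 1:0{width}d}", chromosome="3",
                position=3000 + j, allele_a="A", allele_b="B",
            )
            for j in range(model.n_null_variants)
        ]
    genotypes = np.column_stack(columns)
    if model.missing_rate > 0:
        mask = rng.random(genotypes.shape) < model.missing_rate
        genotypes[mask] = 0
    ids = [f"ind{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(
        genotypes=genotypes,
        phenotype=phenotype,
        variants=variants,
        individual_ids=ids,
    )


def reconstruct_from_counts(
    table: TwoLocusTable,
    variants: list[VariantInfo] | None = None,
) -> GenotypeMatrix:
    """Expand printed two-locus genotype counts into individuals.

    Emits one individual per count unit, cases first, cells in row-major
    order, so re-tabulating the output reproduces the input counts exactly.
    """
    if variants is None:
        variants = [
            VariantInfo(id=table.variant_ids[0], chromosome="0", position=1),
            VariantInfo(id=table.variant_ids[1], chromosome="0", position=2),
        ]
    rows: list[tuple[int, int]] = []
    phenos: list[int] = []
    for counts, label in (
        (table.case_counts, CASE),
        (table.control_counts, CONTROL),
    ):
        for r in range(3):
            for c in range(3):
                k = int(counts[r, c])
                rows.extend([(r + 1, c + 1)] * k)
                phenos.extend([label] * k)
    genotypes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, 2), dtype=np.int8)
    )
    prefix = {CASE: "case", CONTROL: "ctrl"}
    counter = {CASE: 0, CONTROL: 0}
    ids = []
    for ph in phenos:
        counter[ph] += 1
        ids.append(f"{prefix[ph]}{counter[ph]:04d}")
    return GenotypeMatrix(
        genotypes=genotypes,
        phenotype=np.array(phenos, dtype=np.int8),
        variants=variants,
        individual_ids=ids,
    )
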