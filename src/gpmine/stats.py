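"""Contingency-table statistics for genotype patterns.

The workhorse is the likelihood-ratio chi-square (G-test),
``G = 2 * sum O * ln(O / E)``, chosen over the Pearson statistic because G
is exactly additive under nested partitioning of a table: the 8 df of a
2 x 9 phenotype-by-genotype-pair table decompose into 2 df per single-variant
main effect plus 4 df of interaction, with the G statistics summing exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import xlogy

from .containers import (
    CASE,
    CONTROL,
    GenotypeMatrix,
    GenotypePattern,
    TwoByTwoTable,
    TwoLocusTable,
)

__all__ = [
    "lr_chisq",
    "chisq_sf",
    "pattern_table",
    "two_locus_table",
    "partition_two_locus",
    "trend_test",
    "trend_rank",
    "joint_effect",
    "pattern_cell_counts",
    "EffectTest",
    "PartitionResult",
]

# numerical clamp for interaction G computed by subtraction
_NEG_TOL = 1e-9


def lr_chisq(table: np.ndarray) -> tuple[float, int]:
    """Likelihood-ratio chi-square of an r x k count table.

    Expected counts come from the row/column margins; cells with an observed
    zero contribute 0 (the 0*ln 0 = 0 convention).  Degrees of freedom are
    ``(r' - 1) * (k' - 1)`` counting only rows and columns with positive
    totals.  A degenerate table (fewer than two positive rows or columns)
    returns ``(0.0, 0)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    if (t < 0).any():
        raise ValueError("counts must be >= 0")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    r_pos = int((row > 0).sum())
    k_pos = int((col > 0).sum())
    if r_pos < 2 or k_pos < 2:
        return 0.0, 0
    total = t.sum()
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(t, t) - xlogy(t, expected)
    g = 2.0 * float(np.nansum(terms))
    return max(g, 0.0), (r_pos - 1) * (k_pos - 1)


def g_2x2_from_counts(a, b, c, d) -> np.ndarray:
    """Vectorized G statistic of 2x2 tables [[a, b], [c, d]].

    Uses the entropy identity
    ``G/2 = sum O ln O - sum R ln R - sum C ln C + N ln N``;
    degenerate margins yield 0 automatically.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    g = 2.0 * (
        xlogy(a, a) + xlogy(b, b) + xlogy(c, c) + xlogy(d, d)
        - xlogy(a + b, a + b) - xlogy(c + d, c + d)
        - xlogy(a + c, a + c) - xlogy(b + d, b + d)
        + xlogy(n, n)
    )
    return np.maximum(g, 0.0)


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be >= 0")
    return float(sps.chi2.sf(x, df))


def pattern_table(m: GenotypeMatrix, p: GenotypePattern) -> TwoByTwoTable:
    """Phenotype x carrier 2x2 table for a genotype pattern.

    An individual is a carrier iff it matches every (variant, genotype)
    entry of the pattern.  Individuals with a missing genotype at any of the
    pattern's variants are excluded from the table entirely, so the table
    total can be smaller than the sample size.
    """
    for v, _ in p.entries:
        if v >= m.n_variants:
            raise KeyError(f"pattern references unknown variant index {v}")
    sub = m.genotypes[:, list(p.variant_indices)]
    codes = np.array(p.genotype_codes, dtype=np.int8)
    carrier = (sub == codes).all(axis=1)
    excluded = (sub == 0).any(axis=1)
    case = m.phenotype == CASE
    return TwoByTwoTable(
        cases_with=int((carrier & case).sum()),
        cases_without=int((~carrier & ~excluded & case).sum()),
        controls_with=int((carrier & ~case).sum()),
        controls_without=int((~carrier & ~excluded & ~case).sum()),
    )


def two_locus_table(
    m: GenotypeMatrix, variant1: int | str, variant2: int | str
) -> TwoLocusTable:
    """Tabulate the 3x3 genotype distributions at a variant pair.

    Individuals missing either genotype are excluded from both tables.
    """
    i1 = m.variant_index(variant1) if isinstance(variant1, str) else variant1
    i2 = m.variant_index(variant2) if isinstance(variant2, str) else variant2
    g1 = m.genotypes[:, i1]
    g2 = m.genotypes[:, i2]
    ok = (g1 != 0) & (g2 != 0)
    case = m.phenotype == CASE
    cases = np.zeros((3, 3), dtype=np.int64)
    ctrls = np.zeros((3, 3), dtype=np.int64)
    for r in range(3):
        for c in range(3):
            cell = ok & (g1 == r + 1) & (g2 == c + 1)
            cases[r, c] = int((cell & case).sum())
            ctrls[r, c] = int((cell & ~case).sum())
    return TwoLocusTable(
        case_counts=cases,
        control_counts=ctrls,
        variant_ids=(m.variants[i1].id, m.variants[i2].id),
    )


class EffectTest(NamedTuple):
    G: float
    df: int
    p: float


@dataclass
class PartitionResult:
    """Chi-square partition of a two-locus table.

    ``total.G == main1.G + main2.G + interaction.G`` holds exactly (to
    floating-point precision) and 2 + 2 + 4 = 8 df.  ``degenerate`` flags
    tables whose margins collapse below two positive categories.
    """

    main1: EffectTest
    main2: EffectTest
    interaction: EffectTest
    total: EffectTest
    variant_ids: tuple[str, str] = ("v1", "v2")
    degenerate: bool = False

    def to_rows(self) -> list[tuple[str, float, int, float]]:
        v1, v2 = self.variant_ids
        return [
            (f"{v1} main", self.main1.G, self.main1.df, self.main1.p),
            (f"{v2} main", self.main2.G, self.main2.df, self.main2.p),
            ("interaction", self.interaction.G, self.interaction.df,
             self.interaction.p),
            ("Total table", self.total.G, self.total.df, self.total.p),
        ]


def partition_two_locus(t: TwoLocusTable) -> PartitionResult:
    """Partition the 2x9 table's G into main effects and interaction.

    Main effects are the G statistics of phenotype x single-variant margins
    (2 df each); the total is the G of the full 2x9 table with df held at 8
    even when some genotype-pair columns are structurally empty; the
    interaction is obtained by subtraction (4 df), a valid decomposition
    because LR statistics on nested margins are additive.
    """
    main1_tab = np.vstack([t.case_counts.sum(axis=1), t.control_counts.sum(axis=1)])
    main2_tab = np.vstack([t.case_counts.sum(axis=0), t.control_counts.sum(axis=0)])
    g1, df1 = lr_chisq(main1_tab)
    g2, df2 = lr_chisq(main2_tab)
    g_tot, df_tot = lr_chisq(t.as_2x9())
    degenerate = df1 == 0 or df2 == 0 or df_tot == 0
    g_int = g_tot - g1 - g2
    if -_NEG_TOL < g_int < 0:
        g_int = 0.0
    return PartitionResult(
        main1=EffectTest(g1, 2, chisq_sf(g1, 2)),
        main2=EffectTest(g2, 2, chisq_sf(g2, 2)),
        interaction=EffectTest(g_int, 4, chisq_sf(max(g_int, 0.0), 4)),
        total=EffectTest(g_tot, 8, chisq_sf(g_tot, 8)),
        variant_ids=t.variant_ids,
        degenerate=degenerate,
    )


def trend_test(
    case_counts: Sequence[int], control_counts: Sequence[int]
) -> tuple[float, int]:
    """Cochran-Armitage trend chi-square with scores (0, 1, 2).

    Genotype categories are the ordinal codes 1/2/3 scored additively.
    Returns ``(chi2, 1)``; a table with zero score variance (all individuals
    in one genotype class) returns ``(0.0, 0)``.
    """
    r = np.asarray(case_counts, dtype=float)
    u = np.asarray(control_counts, dtype=float)
    if r.shape != (3,) or u.shape != (3,):
        raise ValueError("expected 3-vectors of genotype counts")
    if (r < 0).any() or (u < 0).any():
        raise ValueError("counts must be >= 0")
    n_i = r + u
    n = n_i.sum()
    big_r = r.sum()
    if n <= 0 or big_r <= 0 or big_r >= n:
        return 0.0, 0
    s = np.array([0.0, 1.0, 2.0])
    sn = (s * n_i).sum()
    var_term = n * (s * s * n_i).sum() - sn * sn
    if var_term <= 0:
        return 0.0, 0
    num = n * (s * r).sum() - big_r * sn
    chi2 = n * num * num / (big_r * (n - big_r) * var_term)
    return float(chi2), 1


def trend_rank(m: GenotypeMatrix, top_k: int | None = None) -> np.ndarray:
    """Rank variants by trend-test chi-square, descending.

    Missing genotypes are excluded per variant.  Ties keep the original
    variant order (stable sort).  Returns the indices of the ``top_k``
    best-ranked variants (all, if None).
    """
    case = m.phenotype == CASE
    chis = np.empty(m.n_variants)
    for j in range(m.n_variants):
        g = m.genotypes[:, j]
        r = [int(((g == c) & case).sum()) for c in (1, 2, 3)]
        u = [int(((g == c) & ~case).sum()) for c in (1, 2, 3)]
        chis[j], _ = trend_test(r, u)
    order = np.argsort(-chis, kind="stable")
    return order if top_k is None else order[:top_k]


def pattern_cell_counts(
    m: GenotypeMatrix, variant_indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype-pattern case and control counts over 1-3 fixed variants.

    Returns ``(case_counts, control_counts)``, each of length ``3**n`` in
    row-major cell order; individuals missing any of the variants are
    excluded.
    """
    idx = list(variant_indices)
    n_loci = len(idx)
    if not 1 <= n_loci <= 3:
        raise ValueError("need 1-3 variants")
    sub = m.genotypes[:, idx]
    ok = (sub != 0).all(axis=1)
    cell = np.zeros(m.n_individuals, dtype=np.int64)
    for col in range(n_loci):
        cell = cell * 3 + (sub[:, col] - 1)
    case = m.phenotype == CASE
    n_cells = 3 ** n_loci
    case_counts = np.bincount(cell[ok & case], minlength=n_cells)
    ctrl_counts = np.bincount(cell[ok & ~case], minlength=n_cells)
    return case_counts, ctrl_counts


def joint_effect(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    n_cases: int,
    n_controls: int,
) -> float:
    """Joint effect of 1-3 variants: sum of squared case/control
    frequency differences over all genotype patterns.

    ``t_k = (n_Dk / n_D - n_Uk / n_U)**2`` summed over the ``3**n`` cells;
    cells empty in both groups contribute 0.  Cell sums may fall short of
    the totals when individuals with missing genotypes were excluded.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("need at least one case and one control")
    d = np.asarray(case_counts, dtype=float)
    u = np.asarray(control_counts, dtype=float)
    if d.shape != u.shape:
        raise ValueError("count vectors must have equal length")
    if d.sum() > n_cases or u.sum() > n_controls:
        raise ValueError("cell counts exceed group totals")
    diff = d / n_cases - u / n_controls
    return float((diff * diff).sum())
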