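"""Bundled example data.

The worked example throughout the documentation is a candidate-gene study
of opioid dependence (eight opioid-system genes, 82 variants, 143 cases in
methadone maintenance and 153 healthy controls).  Its strongest finding is
the double-heterozygote pattern at rs1918760 and rs6136667: present in 14
cases and absent from all controls.  The published bivariate genotype
counts at that variant pair — 141 cases with complete genotypes at both
variants and all 153 controls — are bundled here, and expanding them into
individuals reconstructs every statistic of the example.
"""

from __future__ import annotations

from .containers import GenotypeMatrix, TwoLocusTable, VariantInfo
from .simulate import reconstruct_from_counts

__all__ = ["opioid_counts", "opioid_genotypes"]

_CASE_COUNTS = [
    [0, 1, 4],
    [1, 14, 39],
    [1, 16, 65],
]
_CONTROL_COUNTS = [
    [0, 1, 4],
    [1, 0, 45],
    [1, 15, 86],
]


def opioid_counts() -> TwoLocusTable:
    """3x3 case and control genotype counts at rs1918760 x rs6136667.

    Rows index the rs1918760 genotype (1/2/3), columns the rs6136667
    genotype.  Case total 141, control total 153.
    """
    return TwoLocusTable(
        case_counts=_CASE_COUNTS,
        control_counts=_CONTROL_COUNTS,
        variant_ids=("rs1918760", "rs6136667"),
    )


def opioid_genotypes() -> GenotypeMatrix:
    """The 294-individual two-variant dataset expanded from the counts."""
    variants = [
        VariantInfo(id="rs1918760", chromosome="1", position=1,
                    allele_a="A", allele_b="B"),
        VariantInfo(id="rs6136667", chromosome="20", position=2,
                    allele_a="A", allele_b="B"),
    ]
    return reconstruct_from_counts(opioid_counts(), variants=variants)
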