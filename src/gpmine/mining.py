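"""Genotype-pattern search: the :class:`GenotypePatternMiner` estimator.

A genotype pattern is a combination of specific genotypes at one to three
distinct variants (9 candidate patterns per variant pair).  The miner finds
every pattern meeting a minimum carrier count (support) and a minimum
fraction of target-class individuals among carriers (confidence), scores
each with the likelihood-ratio chi-square of its phenotype x carrier 2x2
table, and ranks patterns by that statistic.

Support is counted over all individuals: a person with a missing genotype
at a pattern variant demonstrably does not carry the pattern, so it is a
non-carrier for support purposes, but it is excluded from the pattern's
2x2 table (its carrier status among observed categories is unknowable).

Two engines are provided: FP-growth (the production path) and an exhaustive
brute-force enumerator whose output contract is identical and which serves
as a correctness oracle.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import (
    CASE,
    GenotypeMatrix,
    GenotypePattern,
    MiningConfig,
    PatternStats,
)
from .fpgrowth import fpgrowth_core
from .plink import decode_item, itemize
from .stats import chisq_sf, g_2x2_from_counts

__all__ = [
    "GenotypePatternMiner",
    "mine_patterns",
    "enumerate_bruteforce",
    "all_candidate_patterns",
    "patterns_to_frame",
]


def all_candidate_patterns(
    n_variants: int, max_length: int
) -> Iterator[GenotypePattern]:
    """Yield every genotype pattern of length <= max_length over V variants.

    3V singletons, 9 * C(V,2) pairs and 27 * C(V,3) triples, in canonical
    order.
    """
    for lng in range(1, max_length + 1):
        for variants in combinations(range(n_variants), lng):
            for codes in product((1, 2, 3), repeat=lng):
                yield GenotypePattern.from_pairs(zip(variants, codes))


def _score_patterns(
    X: np.ndarray, y: np.ndarray, patterns: Sequence[GenotypePattern]
) -> pd.DataFrame:
    """Carrier census and 2x2 G statistic for each pattern."""
    case = y == CASE
    n_cases = int(case.sum())
    n_controls = int((~case).sum())
    support = np.empty(len(patterns), dtype=np.int64)
    case_count = np.empty(len(patterns), dtype=np.int64)
    excl_case = np.empty(len(patterns), dtype=np.int64)
    excl_ctrl = np.empty(len(patterns), dtype=np.int64)
    for i, p in enumerate(patterns):
        sub = X[:, list(p.variant_indices)]
        codes = np.asarray(p.genotype_codes, dtype=X.dtype)
        carrier = (sub == codes).all(axis=1)
        missing = (sub == 0).any(axis=1)
        support[i] = carrier.sum()
        case_count[i] = (carrier & case).sum()
        excl_case[i] = (missing & case).sum()
        excl_ctrl[i] = (missing & ~case).sum()
    control_count = support - case_count
    a = case_count
    b = n_cases - excl_case - case_count
    c = control_count
    d = n_controls - excl_ctrl - control_count
    chi2 = g_2x2_from_counts(a, b, c, d)
    degenerate = (
        (a + b == 0) | (c + d == 0) | (a + c == 0) | (b + d == 0)
    )
    from scipy.stats import chi2 as chi2_dist

    nominal_p = np.where(degenerate, 1.0, chi2_dist.sf(chi2, 1))
    return pd.DataFrame(
        {
            "pattern": list(patterns),
            "support": support,
            "case_count": case_count,
            "control_count": control_count,
            "chi2": chi2,
            "nominal_p": nominal_p,
        }
    )


def _validate_genotype_X(X) -> np.ndarray:
    X = check_array(X, dtype=None, ensure_2d=True)
    X = np.asarray(X)
    if not np.issubdtype(X.dtype, np.integer):
        Xi = X.astype(np.int64)
        if not np.array_equal(Xi, X):
            raise ValueError("genotype codes must be integers")
        X = Xi
    if X.size and (X.min() < 0 or X.max() > 3):
        raise ValueError("genotype codes must lie in {0,1,2,3}")
    return X.astype(np.int8)


def _validate_phenotype_y(y, n: int) -> np.ndarray:
    y = np.asarray(y)
    if y.shape != (n,):
        raise ValueError("y must have one label per row of X")
    if y.dtype == bool:
        y = y.astype(np.int8)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary: 1 = case, 0 = control")
    return y.astype(np.int8)


class GenotypePatternMiner(TransformerMixin, BaseEstimator):
    """Mine case-enriched genotype patterns from coded genotype data.

    Parameters
    ----------
    min_support : int, default=5
        Minimal number of carriers (over all individuals).
    min_confidence : float, default=0.8
        Minimal fraction of target-class individuals among carriers.
    max_length : int, default=2
        Maximal number of variants per pattern (1-3).  The default follows
        the observation that the length-3 search space is so much larger
        that, at fixed sample size, multiplicity-corrected significance
        collapses; length-2 scans are the intended working mode.
    target_class : int, default=1
        Phenotype label the confidence is computed against (1 = case).
        Setting 0 mines control-enriched patterns, symmetric by relabeling.
    method : {'fpgrowth', 'bruteforce'}, default='fpgrowth'
        Search engine.  Both satisfy the identical output contract; the
        brute-force enumerator exists as an oracle for small instances.

    Attributes
    ----------
    patterns_ : list of PatternStats
        Passing patterns sorted by chi2 descending, ties broken by support
        descending then canonical pattern order; deterministic.
    n_candidates_ : int
        Number of candidate patterns examined by the engine.
    n_features_in_ : int

    Examples
    --------
    >>> miner = GenotypePatternMiner(min_support=5, min_confidence=0.8)
    >>> miner.fit(X, y).patterns_[0].pattern.entries  # doctest: +SKIP
    ((0, 2), (1, 2))
    """

    def __init__(
        self,
        min_support: int = 5,
        min_confidence: float = 0.8,
        max_length: int = 2,
        target_class: int = CASE,
        method: str = "fpgrowth",
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.max_length = max_length
        self.target_class = target_class
        self.method = method

    def _config(self) -> MiningConfig:
        return MiningConfig(
            min_support=self.min_support,
            min_confidence=self.min_confidence,
            max_length=self.max_length,
            target_class=self.target_class,
        )

    def _support_passing_patterns(
        self, X: np.ndarray
    ) -> tuple[list[GenotypePattern], int]:
        """All patterns with support >= min_support, plus candidate count."""
        cfg = self._config()
        if self.method == "fpgrowth":
            transactions = []
            for row in X:
                nz = np.flatnonzero(row)
                transactions.append((nz * 3 + (row[nz] - 1)).tolist())
            itemsets = fpgrowth_core(
                transactions, cfg.min_support, cfg.max_length
            )
            patterns = [
                GenotypePattern.from_pairs(decode_item(i) for i in items)
                for items in itemsets
            ]
            n_candidates = len(itemsets)
        elif self.method == "bruteforce":
            candidates = list(
                all_candidate_patterns(X.shape[1], cfg.max_length)
            )
            n_candidates = len(candidates)
            codes_ok = []
            for p in candidates:
                sub = X[:, list(p.variant_indices)]
                codes = np.asarray(p.genotype_codes, dtype=X.dtype)
                if int((sub == codes).all(axis=1).sum()) >= cfg.min_support:
                    codes_ok.append(p)
            patterns = codes_ok
        else:
            raise ValueError(f"unknown method {self.method!r}")
        patterns.sort(key=lambda p: p.entries)
        return patterns, n_candidates

    def fit(self, X, y):
        """Mine and score patterns; sets ``patterns_``."""
        cfg = self._config()  # validates parameters
        X = _validate_genotype_X(X)
        y = _validate_phenotype_y(y, X.shape[0])
        if X.shape[0] == 0:
            raise ValueError("empty genotype matrix")
        self.n_features_in_ = X.shape[1]
        patterns, self.n_candidates_ = self._support_passing_patterns(X)
        stats = _score_patterns(X, y, patterns)
        target = (
            stats["case_count"]
            if cfg.target_class == CASE
            else stats["control_count"]
        )
        with np.errstate(invalid="ignore"):
            conf = np.where(
                stats["support"] > 0, target / stats["support"], 0.0
            )
        keep = (stats["support"] >= cfg.min_support) & (
            conf >= cfg.min_confidence
        )
        result = [
            PatternStats(
                pattern=row.pattern,
                support=int(row.support),
                case_count=int(row.case_count),
                control_count=int(row.control_count),
                confidence=float(cf),
                chi2=float(row.chi2),
                nominal_p=float(row.nominal_p),
            )
            for row, cf, k in zip(stats.itertuples(index=False), conf, keep)
            if k
        ]
        result.sort(key=lambda s: (-s.chi2, -s.support, s.pattern.entries))
        self.patterns_ = result
        return self

    def transform(self, X) -> np.ndarray:
        """Binary carrier-indicator matrix, one column per mined pattern."""
        check_is_fitted(self, "patterns_")
        X = _validate_genotype_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of variants than fit")
        out = np.zeros((X.shape[0], len(self.patterns_)), dtype=np.uint8)
        for j, ps in enumerate(self.patterns_):
            sub = X[:, list(ps.pattern.variant_indices)]
            codes = np.asarray(ps.pattern.genotype_codes, dtype=X.dtype)
            out[:, j] = (sub == codes).all(axis=1)
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "patterns_")
        return np.asarray(
            [ps.pattern.label() for ps in self.patterns_], dtype=object
        )


def mine_patterns(m: GenotypeMatrix, cfg: MiningConfig) -> list[PatternStats]:
    """FP-growth search over a :class:`GenotypeMatrix`; see
    :class:`GenotypePatternMiner`."""
    miner = GenotypePatternMiner(
        min_support=cfg.min_support,
        min_confidence=cfg.min_confidence,
        max_length=cfg.max_length,
        target_class=cfg.target_class,
        method="fpgrowth",
    )
    return miner.fit(m.genotypes, m.phenotype).patterns_


def enumerate_bruteforce(
    m: GenotypeMatrix, cfg: MiningConfig
) -> list[PatternStats]:
    """Exhaustive enumeration with the same filters, scoring and ordering
    contract as :func:`mine_patterns`; intended as a small-instance oracle."""
    miner = GenotypePatternMiner(
        min_support=cfg.min_support,
        min_confidence=cfg.min_confidence,
        max_length=cfg.max_length,
        target_class=cfg.target_class,
        method="bruteforce",
    )
    return miner.fit(m.genotypes, m.phenotype).patterns_


def patterns_to_frame(
    results: Sequence[PatternStats],
    variants=None,
) -> pd.DataFrame:
    """Tabular report of mined patterns (TSV-ready)."""
    rows = []
    for ps in results:
        rows.append(
            {
                "pattern": ps.pattern.label(variants),
                "length": len(ps.pattern),
                "support": ps.support,
                "case_count": ps.case_count,
                "control_count": ps.control_count,
                "confidence": ps.confidence,
                "chi2": ps.chi2,
                "nominal_p": ps.nominal_p,
                "corrected_p": (
                    np.nan if ps.corrected_p is None else ps.corrected_p
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pattern", "length", "support", "case_count", "control_count",
            "confidence", "chi2", "nominal_p", "corrected_p",
        ],
    )
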