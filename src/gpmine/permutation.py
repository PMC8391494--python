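"""Westfall-Young max-statistic permutation correction.

Permuting phenotype labels creates proper null samples with no
genotype-phenotype association while preserving the genotype (and
missingness) structure.  For each permuted replicate the whole pattern
scan is re-run and the maximum chi-square over passing patterns recorded;
the family-wise corrected p-value of an observed pattern is

    p = (1 + #{replicates with null max >= observed chi2}) / (R + 1)

with the +1 smoothing, so p is never 0 and never below 1/(R+1).

Because pattern support does not depend on phenotype labels, the set of
support-passing patterns is invariant under permutation; the replicate
loop therefore re-tabulates only carrier-by-phenotype counts (a matrix
product), applies the confidence filter, and recomputes the G statistics.
This is algebraically identical to re-mining from scratch each replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import (
    CASE,
    GenotypeMatrix,
    GenotypePattern,
    MiningConfig,
    PatternStats,
)
from .mining import GenotypePatternMiner
from .stats import g_2x2_from_counts, joint_effect, pattern_cell_counts

__all__ = [
    "permute_phenotypes",
    "corrected_pvalues",
    "joint_effect_permutation",
    "PermutationResult",
    "PatternPermutationTest",
]

_CHUNK = 4096  # patterns per block in the vectorized replicate sweep


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent substream per replicate: growing the replicate count
    never changes earlier replicates."""
    return np.random.default_rng(np.random.SeedSequence((seed, replicate)))


def permute_phenotypes(
    phenotype: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random permutation of the label vector (multiset preserved)."""
    phenotype = np.asarray(phenotype)
    if phenotype.size == 0:
        raise ValueError("phenotype vector must be nonempty")
    return phenotype[rng.permutation(phenotype.size)]


@dataclass
class PermutationResult:
    """Null distribution and corrected p-values from a permutation run."""

    n_replicates: int
    seed: int
    null_max_chi2: np.ndarray
    observed: list[PatternStats] = field(default_factory=list)

    @property
    def per_pattern_corrected_p(self) -> dict[GenotypePattern, float]:
        return {ps.pattern: ps.corrected_p for ps in self.observed}

    def corrected_p_for(self, chi2: float) -> float:
        return float(
            (1 + int((self.null_max_chi2 >= chi2).sum()))
            / (self.n_replicates + 1)
        )


class PatternPermutationTest(GenotypePatternMiner):
    """Pattern miner with family-wise corrected empirical p-values.

    Extends :class:`GenotypePatternMiner`: after the observed scan, ``fit``
    permutes phenotype labels ``n_replicates`` times, repeats the scan on
    each replicate, and assigns each observed pattern the corrected p-value
    defined by the max-statistic scheme.

    Parameters
    ----------
    n_replicates : int, default=1000
        Number of label permutations; corrected p-values have granularity
        1/(n_replicates + 1).
    random_state : int, default=0
        Seed; identical (data, parameters, seed) gives identical results.
    null_confidence : {'match', 'symmetric'}, default='match'
        How the confidence filter is applied inside replicates.  'match'
        re-applies the same one-sided target-class filter as the observed
        scan, which makes the construction exact under exchangeability.
        'symmetric' requires max(case, control confidence) >= threshold,
        inflating the null maximum and giving conservative p-values; it is
        offered for scans meant to be agnostic to effect direction.

    Attributes
    ----------
    patterns_ : list of PatternStats, with ``corrected_p`` filled in.
    null_max_chi2_ : ndarray of shape (n_replicates,)
    result_ : PermutationResult
    """

    def __init__(
        self,
        min_support: int = 5,
        min_confidence: float = 0.8,
        max_length: int = 2,
        target_class: int = CASE,
        method: str = "fpgrowth",
        n_replicates: int = 1000,
        random_state: int = 0,
        null_confidence: str = "match",
    ):
        super().__init__(
            min_support=min_support,
            min_confidence=min_confidence,
            max_length=max_length,
            target_class=target_class,
            method=method,
        )
        self.n_replicates = n_replicates
        self.random_state = random_state
        self.null_confidence = null_confidence

    def fit(self, X, y):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.null_confidence not in ("match", "symmetric"):
            raise ValueError("null_confidence must be 'match' or 'symmetric'")
        if self.n_replicates < 100:
            warnings.warn(
                f"only {self.n_replicates} replicates: corrected p-values "
                f"have granularity 1/{self.n_replicates + 1}",
                stacklevel=2,
            )
        super().fit(X, y)
        X = np.asarray(X, dtype=np.int8)
        y = np.asarray(y, dtype=np.int8)
        self.null_max_chi2_ = self._null_max_distribution(X, y)
        for ps in self.patterns_:
            ps.corrected_p = float(
                (1 + int((self.null_max_chi2_ >= ps.chi2).sum()))
                / (self.n_replicates + 1)
            )
        self.result_ = PermutationResult(
            n_replicates=self.n_replicates,
            seed=self.random_state,
            null_max_chi2=self.null_max_chi2_,
            observed=self.patterns_,
        )
        return self

    # -- replicate sweep ---------------------------------------------------

    def _null_max_distribution(
        self, X: np.ndarray, y: np.ndarray
    ) -> np.ndarray:
        R = self.n_replicates
        n = X.shape[0]
        support_patterns, _ = self._support_passing_patterns(X)
        if not support_patterns:
            return np.zeros(R)
        perms = np.empty((R, n), dtype=np.float64)
        for r in range(R):
            rng = _replicate_rng(self.random_state, r)
            perms[r] = permute_phenotypes(y, rng)
        null_max = np.zeros(R)
        n_cases_tot = float(y.sum())
        n_controls_tot = float(n - y.sum())
        for start in range(0, len(support_patterns), _CHUNK):
            block = support_patterns[start:start + _CHUNK]
            carrier = np.empty((n, len(block)), dtype=np.float64)
            miss_any = np.empty((n, len(block)), dtype=np.float64)
            support = np.empty(len(block))
            for j, p in enumerate(block):
                sub = X[:, list(p.variant_indices)]
                codes = np.asarray(p.genotype_codes, dtype=X.dtype)
                carrier[:, j] = (sub == codes).all(axis=1)
                miss_any[:, j] = (sub == 0).any(axis=1)
                support[j] = carrier[:, j].sum()
            n_missing = miss_any.sum(axis=0)
            # per replicate: cases among carriers / among excluded
            a = perms @ carrier                     # cases_with
            excl_case = perms @ miss_any
            b = n_cases_tot - excl_case - a         # cases_without
            c = support[None, :] - a                # controls_with
            d = (n_controls_tot - (n_missing - excl_case)) - c
            if self.null_confidence == "match":
                target = a if self.target_class == CASE else c
                conf = target / support[None, :]
            else:
                conf = np.maximum(a, c) / support[None, :]
            passing = conf >= self.min_confidence
            chi2 = g_2x2_from_counts(a, b, c, d)
            chi2[~passing] = 0.0
            block_max = chi2.max(axis=1)
            np.maximum(null_max, block_max, out=null_max)
        return null_max


def corrected_pvalues(
    m: GenotypeMatrix,
    cfg: MiningConfig,
    n_replicates: int,
    seed: int,
    null_confidence: str = "match",
) -> PermutationResult:
    """Run the full mine-and-permute pipeline on a genotype matrix."""
    test = PatternPermutationTest(
        min_support=cfg.min_support,
        min_confidence=cfg.min_confidence,
        max_length=cfg.max_length,
        target_class=cfg.target_class,
        n_replicates=n_replicates,
        random_state=seed,
        null_confidence=null_confidence,
    )
    test.fit(m.genotypes, m.phenotype)
    return test.result_


def joint_effect_permutation(
    m: GenotypeMatrix,
    variant_indices: Sequence[int],
    n_replicates: int,
    seed: int,
) -> tuple[float, float]:
    """Permutation p-value for the joint effect of 1-3 fixed variants.

    Returns ``(observed statistic, empirical p)`` where the statistic is
    the sum over all genotype patterns of squared case/control frequency
    differences and p uses the same +1-smoothed formula as pattern
    correction.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    idx = list(variant_indices)
    n_cases, n_controls = m.n_cases, m.n_controls
    d_obs, u_obs = pattern_cell_counts(m, idx)
    observed = joint_effect(d_obs, u_obs, n_cases, n_controls)

    # one-hot cell membership for a vectorized replicate sweep
    sub = m.genotypes[:, idx]
    ok = (sub != 0).all(axis=1)
    cell = np.zeros(m.n_individuals, dtype=np.int64)
    for col in range(len(idx)):
        cell = cell * 3 + (sub[:, col] - 1)
    n_cells = 3 ** len(idx)
    onehot = np.zeros((m.n_individuals, n_cells))
    onehot[np.arange(m.n_individuals)[ok], cell[ok]] = 1.0
    totals = onehot.sum(axis=0)

    exceed = 0
    for r in range(n_replicates):
        rng = _replicate_rng(seed, r)
        y_perm = permute_phenotypes(m.phenotype, rng).astype(float)
        d = y_perm @ onehot
        u = totals - d
        t = float((((d / n_cases) - (u / n_controls)) ** 2).sum())
        if t >= observed:
            exceed += 1
    p = (1 + exceed) / (n_replicates + 1)
    return observed, p
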