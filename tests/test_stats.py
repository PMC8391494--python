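import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpmine.containers import GenotypePattern, TwoLocusTable
from gpmine.stats import (
    chisq_sf,
    joint_effect,
    lr_chisq,
    partition_two_locus,
    pattern_cell_counts,
    pattern_table,
    trend_rank,
    trend_test,
    two_locus_table,
)


def _random_2x9(rng):
    return TwoLocusTable(
        case_counts=rng.integers(0, 40, (3, 3)),
        control_counts=rng.integers(0, 40, (3, 3)),
    )


class TestLrChisq:
    def test_published_row_margins(self):
        g, df = lr_chisq([[5, 54, 82], [5, 46, 102]])
        assert g == pytest.approx(2.329, abs=5e-4)
        assert df == 2

    def test_published_column_margins(self):
        g, df = lr_chisq([[2, 31, 108], [2, 16, 135]])
        assert g == pytest.approx(7.388, abs=5e-4)
        assert df == 2

    def test_proportional_rows_give_zero(self):
        g, df = lr_chisq([[10, 20, 30], [20, 40, 60]])
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_table_flagged(self):
        assert lr_chisq([[0, 0], [3, 4]]) == (0.0, 0)
        assert lr_chisq([[5, 0], [3, 0]]) == (0.0, 0)

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=25)
    def test_invariances(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 50, (2, 4))
        t[0, 0] += 1
        t[1, 1] += 1  # ensure two positive rows/cols
        g, df = lr_chisq(t)
        g_perm, _ = lr_chisq(t[::-1, rng.permutation(4)])
        assert g_perm == pytest.approx(g, abs=1e-9)
        g2, _ = lr_chisq(2 * t)
        assert g2 == pytest.approx(2 * g, rel=1e-9)


class TestPatternTable:
    def test_worked_example_counts(self, opioid):
        p = GenotypePattern.from_pairs([(0, 2), (1, 2)])
        t = pattern_table(opioid, p)
        assert (t.cases_with, t.cases_without, t.controls_with,
                t.controls_without) == (14, 127, 0, 153)

    def test_all_missing_variant_gives_zero_table(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(0), 30, 3)
        m.genotypes[:, 1] = 0
        t = pattern_table(m, GenotypePattern.from_pairs([(1, 2)]))
        assert t.total == 0

    def test_unknown_variant_is_fatal(self, opioid):
        with pytest.raises(KeyError):
            pattern_table(opioid, GenotypePattern.from_pairs([(5, 1)]))

    def test_matches_per_individual_scan(self, random_matrix_factory):
        rng = np.random.default_rng(42)
        for rep in range(20):
            m = random_matrix_factory(rng, 60, 6, missing_rate=0.07)
            v1, v2 = rng.choice(6, size=2, replace=False)
            g1, g2 = rng.integers(1, 4, 2)
            p = GenotypePattern.from_pairs([(int(v1), int(g1)),
                                            (int(v2), int(g2))])
            t = pattern_table(m, p)
            counts = {(1, True): 0, (1, False): 0, (0, True): 0, (0, False): 0}
            for i in range(m.n_individuals):
                a, b = m.genotypes[i, v1], m.genotypes[i, v2]
                if a == 0 or b == 0:
                    continue
                counts[(int(m.phenotype[i]), (a, b) == (g1, g2))] += 1
            assert (t.cases_with, t.cases_without) == (
                counts[(1, True)], counts[(1, False)])
            assert (t.controls_with, t.controls_without) == (
                counts[(0, True)], counts[(0, False)])


class TestPartition:
    def test_worked_example_partition(self, opioid_table):
        part = partition_two_locus(opioid_table)
        assert part.main1.G == pytest.approx(2.329, abs=5e-4)
        assert part.main2.G == pytest.approx(7.388, abs=5e-4)
        assert part.interaction.G == pytest.approx(12.592, abs=5e-4)
        assert part.total.G == pytest.approx(22.309, abs=5e-4)
        assert (part.main1.df, part.main2.df,
                part.interaction.df, part.total.df) == (2, 2, 4, 8)

    def test_identical_distributions_give_zero(self):
        c = np.arange(9).reshape(3, 3) + 1
        part = partition_two_locus(TwoLocusTable(c, c))
        for eff in (part.main1, part.main2, part.interaction, part.total):
            assert eff.G == pytest.approx(0.0, abs=1e-9)

    def test_additivity_sweep(self):
        # additivity is exact by construction; the interaction term itself
        # may be negative when the two loci carry redundant signal, so only
        # the decomposition identity and a valid p-value are asserted
        rng = np.random.default_rng(9)
        for _ in range(200):
            part = partition_two_locus(_random_2x9(rng))
            resid = part.total.G - (
                part.main1.G + part.main2.G + part.interaction.G
            )
            assert abs(resid) < 1e-9
            assert 0.0 <= part.interaction.p <= 1.0

    def test_table_reconstruction_round_trip(self, opioid, opioid_table):
        t = two_locus_table(opioid, "rs1918760", "rs6136667")
        assert np.array_equal(t.case_counts, opioid_table.case_counts)
        assert np.array_equal(t.control_counts, opioid_table.control_counts)


class TestTrendTest:
    def test_proportional_vectors_give_zero(self):
        chi2, df = trend_test([10, 20, 30], [20, 40, 60])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_n_times_rsquared(self):
        # CA trend chi-square equals N * corr(score, outcome)^2
        cases, ctrls = [10, 20, 70], [70, 20, 10]
        chi2, df = trend_test(cases, ctrls)
        assert df == 1
        scores, outcome = [], []
        for s, (r, u) in enumerate(zip(cases, ctrls)):
            scores += [s] * (r + u)
            outcome += [1] * r + [0] * u
        r_coef = np.corrcoef(scores, outcome)[0, 1]
        assert chi2 == pytest.approx(len(scores) * r_coef**2, rel=1e-12)

    def test_zero_variance_flagged(self):
        assert trend_test([0, 50, 0], [0, 30, 0]) == (0.0, 0)

    def test_ranking_matches_bruteforce_sort(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(10), 120, 50)
        order = trend_rank(m)
        case = m.phenotype == 1
        chis = []
        for j in range(50):
            g = m.genotypes[:, j]
            chis.append(trend_test(
                [int(((g == c) & case).sum()) for c in (1, 2, 3)],
                [int(((g == c) & ~case).sum()) for c in (1, 2, 3)],
            )[0])
        expected = sorted(range(50), key=lambda j: (-chis[j], j))
        assert order.tolist() == expected
        assert trend_rank(m, top_k=10).tolist() == expected[:10]


class TestJointEffect:
    def test_identical_proportions_give_zero(self):
        assert joint_effect([10, 20], [10, 20], 30, 30) == pytest.approx(0.0)

    def test_single_pattern_all_cases_gives_one(self):
        assert joint_effect([50, 0], [0, 0], 50, 40) == pytest.approx(1.0)

    def test_worked_example_hand_sum(self, opioid):
        d, u = pattern_cell_counts(opioid, [0, 1])
        got = joint_effect(d, u, 141, 153)
        expected = sum(
            (dk / 141 - uk / 153) ** 2 for dk, uk in zip(d, u)
        )
        assert got == pytest.approx(expected, rel=1e-12)
        assert len(d) == 9

    def test_zero_group_is_fatal(self):
        with pytest.raises(ValueError):
            joint_effect([1], [1], 0, 10)


class TestChisqSf:
    @pytest.mark.parametrize(
        "x,df,p",
        [(2.329, 2, 0.3121), (7.388, 2, 0.0249), (12.592, 4, 0.0135)],
    )
    def test_published_tail_probabilities(self, x, df, p):
        assert chisq_sf(x, df) == pytest.approx(p, abs=5e-5)

    def test_df2_closed_form(self):
        for x in (0.1, 1.0, 2.329, 10.0):
            assert chisq_sf(x, 2) == pytest.approx(np.exp(-x / 2), abs=1e-12)

    def test_zero_statistic_gives_one(self):
        assert chisq_sf(0.0, 3) == 1.0
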