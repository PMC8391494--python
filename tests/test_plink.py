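import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpmine.plink import (
    decode_item,
    encode_item,
    filter_missing,
    itemize,
    read_ped_map,
    recode_genotypes,
    write_ped_map,
    write_transactions,
)
from gpmine.simulate import PenetranceModel, simulate_digenic
from tests.conftest import make_random_matrix

MAP2 = "1 rs1 0 100\n2 rs2 0 200\n"


def _read(ped, map_=MAP2):
    return read_ped_map(io.StringIO(ped), io.StringIO(map_))


class TestRecode:
    def test_major_allele_forced_by_majority(self):
        codes, major, minor = recode_genotypes([("A", "A"), ("A", "A"), ("A", "G")])
        assert codes.tolist() == [1, 1, 2]
        assert (major, minor) == ("A", "G")

    def test_missing_allele_passes_through(self):
        codes, major, _ = recode_genotypes([("G", "G"), ("0", "0"), ("A", "G"),
                                            ("A", "A"), ("A", "A")])
        assert major == "A"
        assert codes.tolist() == [3, 0, 2, 1, 1]

    def test_tie_broken_lexicographically(self):
        codes, major, minor = recode_genotypes([("A", "G"), ("G", "A")])
        assert (major, minor) == ("A", "G")
        assert codes.tolist() == [2, 2]

    def test_triallelic_is_fatal(self):
        with pytest.raises(ValueError, match="rs99"):
            recode_genotypes([("A", "G"), ("C", "C")], variant_id="rs99")

    def test_hwe_code_frequencies(self):
        # MAF 0.3 -> HWE (0.49, 0.42, 0.09); 4-SD binomial band at n=1000
        rng = np.random.default_rng(7)
        q = 0.3
        alleles = rng.choice(["A", "B"], p=[1 - q, q], size=(1000, 2))
        codes, major, _ = recode_genotypes([tuple(p) for p in alleles])
        assert major == "A"
        n = len(codes)
        for code, expected in zip((1, 2, 3), (0.49, 0.42, 0.09)):
            obs = (codes == code).mean()
            sd = np.sqrt(expected * (1 - expected) / n)
            assert abs(obs - expected) < 4 * sd

    def test_minor_homozygote_never_beats_major(self):
        # under the major-allele convention code 3 cannot outnumber code 1
        rng = np.random.default_rng(11)
        for _ in range(20):
            q = rng.uniform(0.05, 0.45)
            alleles = rng.choice(["A", "B"], p=[1 - q, q], size=(400, 2))
            codes, _, _ = recode_genotypes([tuple(p) for p in alleles])
            assert (codes == 3).sum() <= (codes == 1).sum()


class TestReadPedMap:
    def test_minimal_two_by_two(self):
        ped = "f1 i1 0 0 1 2 A A G T\nf2 i2 0 0 2 1 A G T T\n"
        m = _read(ped)
        assert m.genotypes.shape == (2, 2)
        assert m.phenotype.tolist() == [1, 0]
        # variant 1: A major -> AA=1, AG=2; variant 2: T major -> GT=2, TT=1
        assert m.genotypes.tolist() == [[1, 2], [2, 1]]
        assert [v.id for v in m.variants] == ["rs1", "rs2"]

    def test_zero_pair_is_missing(self):
        ped = "f1 i1 0 0 1 2 0 0 G T\nf2 i2 0 0 2 1 A G T T\n"
        m = _read(ped)
        assert m.genotypes[0, 0] == 0

    def test_missing_phenotype_excluded(self):
        ped = "f1 i1 0 0 1 0 A A G T\nf2 i2 0 0 2 1 A G T T\n"
        m = _read(ped)
        assert m.n_individuals == 1
        assert m.individual_ids == ["i2"]

    def test_column_mismatch_names_counts(self):
        ped = "f1 i1 0 0 1 2 A A\n"
        with pytest.raises(ValueError, match="2 x 2"):
            _read(ped)

    def test_unknown_phenotype_reports_line(self):
        ped = "f1 i1 0 0 1 2 A A G T\nf2 i2 0 0 2 7 A G T T\n"
        with pytest.raises(ValueError, match="line 2"):
            _read(ped)

    def test_roundtrip_of_simulated_data(self, tmp_path):
        model = PenetranceModel(
            maf1=0.3, maf2=0.2,
            penetrance=np.full((3, 3), 0.3),
            n_cases=60, n_controls=60,
            n_null_variants=5, missing_rate=0.05,
        )
        m = simulate_digenic(model, seed=5)
        write_ped_map(m, tmp_path / "a.ped", tmp_path / "a.map")
        back = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map")
        assert np.array_equal(back.genotypes, m.genotypes)
        assert np.array_equal(back.phenotype, m.phenotype)
        assert back.individual_ids == m.individual_ids
        assert [v.id for v in back.variants] == [v.id for v in m.variants]


class TestFilterMissing:
    def test_geno_zero_drops_offending_variants(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(1), 40, 82)
        m.genotypes[3, 10] = 0
        out = filter_missing(m, 0.0, 1.0)
        assert out.n_variants == 81
        assert [v.id for v in out.variants] == [
            v.id for i, v in enumerate(m.variants) if i != 10
        ]

    def test_mind_zero_drops_offending_individuals(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(2), 50, 10)
        bad = [1, 7, 12, 20, 33, 41, 44, 45, 46, 47, 48, 49]
        for i in bad:
            m.genotypes[i, i % 10] = 0
        out = filter_missing(m, 1.0, 0.0)
        assert out.n_individuals == 50 - len(bad)
        assert all(out.individual_ids[k] == m.individual_ids[i]
                   for k, i in enumerate(sorted(set(range(50)) - set(bad))))

    def test_matches_bruteforce_recount(self, random_matrix_factory):
        rng = np.random.default_rng(3)
        m = random_matrix_factory(rng, 80, 30, missing_rate=0.05)
        tv, ti = 0.06, 0.1
        out = filter_missing(m, tv, ti)
        miss = m.genotypes == 0
        keep_v = [j for j in range(30) if miss[:, j].mean() <= tv]
        keep_i = [i for i in range(80)
                  if miss[i, keep_v].mean() <= ti]
        assert [v.id for v in out.variants] == [m.variants[j].id for j in keep_v]
        assert out.individual_ids == [m.individual_ids[i] for i in keep_i]

    def test_idempotent(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(4), 60, 20,
                                  missing_rate=0.08)
        once = filter_missing(m, 0.05, 0.1)
        twice = filter_missing(once, 0.05, 0.1)
        assert np.array_equal(once.genotypes, twice.genotypes)
        assert once.individual_ids == twice.individual_ids

    def test_everything_removed_is_fatal(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(5), 10, 4)
        m.genotypes[:, :] = 0
        with pytest.raises(ValueError):
            filter_missing(m, 0.5, 0.5)


class TestItemize:
    def test_item_encoding_arithmetic(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(6), 1, 2)
        m.genotypes[0] = [2, 3]
        ts = itemize(m)
        assert ts.transactions == [[1, 5]]

    def test_missing_emits_nothing(self, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(6), 1, 2)
        m.genotypes[0] = [2, 0]
        assert itemize(m).transactions == [[1]]

    @given(st.integers(0, 9), st.integers(1, 3))
    @settings(derandomize=True)
    def test_encode_decode_bijection(self, v, g):
        assert decode_item(encode_item(v, g)) == (v, g)

    def test_transaction_file_layout(self, tmp_path, random_matrix_factory):
        m = random_matrix_factory(np.random.default_rng(8), 5, 3)
        path = tmp_path / "tx.tsv"
        write_transactions(m, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 5
        iid, label, items = lines[0].split("\t")
        assert label in ("case", "control")
        assert all(tok.isdigit() for tok in items.split())
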