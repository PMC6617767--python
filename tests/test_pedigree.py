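"""Pedigree reading, relatedness, Henderson inverse and gene dropping."""

import io

import numpy as np
import pytest

from wildqg.pedigree import (
    PedigreeError,
    a_inverse,
    gene_drop,
    gene_drop_bivariate,
    inbreeding,
    mendelian_variance,
    read_pedigree,
    relationship_matrix,
    write_pedigree,
)

from conftest import make_pedigree, random_pedigree


class TestReadPedigree:
    def test_minimal_trio(self, trio):
        assert trio.n == 3
        assert trio.founders.sum() == 2
        # topological: parents first
        c = list(trio.ids).index("C")
        assert c == 2

    def test_reorders_child_listed_first(self):
        ped = make_pedigree("id,dam,sire,cohort,sex\nC,A,B,5,F\nA,,,1,F\nB,,,1,M\n")
        order = list(ped.ids)
        assert order.index("A") < order.index("C")
        assert order.index("B") < order.index("C")

    def test_parent_only_ids_promoted_to_founders(self):
        ped = make_pedigree("id,dam,sire,cohort,sex\nC,A,B,5,F\n")
        assert ped.n == 3
        assert ped.founders.sum() == 2
        promoted = {ped.ids[i]: ped.sex[i] for i in range(3) if ped.ids[i] != "C"}
        assert promoted == {"A": "F", "B": "M"}
        assert np.isnan(ped.cohort[list(ped.ids).index("A")])

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            make_pedigree("id,dam,sire,cohort,sex\nX,Y,,1,F\nY,X,,1,F\n")

    def test_self_parentage_rejected(self):
        with pytest.raises(PedigreeError, match="own parent"):
            make_pedigree("id,dam,sire,cohort,sex\nX,X,,1,F\n")

    def test_duplicate_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            make_pedigree("id,dam,sire,cohort,sex\nX,,,1,F\nX,,,2,F\n")

    def test_bad_cohort_rejected_with_row(self):
        with pytest.raises(PedigreeError, match="row 1"):
            make_pedigree("id,dam,sire,cohort,sex\nX,,,198x,F\n")

    def test_round_trip(self, tmp_path, full_sib_family):
        path = tmp_path / "ped.csv"
        write_pedigree(full_sib_family, path)
        back = read_pedigree(path)
        assert list(back.ids) == list(full_sib_family.ids)
        assert np.array_equal(back.dam, full_sib_family.dam)
        assert np.array_equal(back.sire, full_sib_family.sire)


class TestRelatedness:
    def test_parent_offspring_and_full_sibs(self, full_sib_family):
        A, F = relationship_matrix(full_sib_family)
        ids = list(full_sib_family.ids)
        a, s1, s2, x = ids.index("A"), ids.index("S1"), ids.index("S2"), ids.index("X")
        assert A[a, s1] == pytest.approx(0.5)      # parent-offspring
        assert A[s1, s2] == pytest.approx(0.5)     # full sibs
        assert A[x, x] == pytest.approx(1.25)      # 1 + F, F = 0.25
        assert F[x] == pytest.approx(0.25)

    def test_founders_unrelated_and_diag_one(self, trio):
        A, F = relationship_matrix(trio)
        assert A[0, 1] == 0.0
        assert np.allclose(np.diag(A), 1 + F)
        assert np.all(F == 0)

    def test_inbreeding_matches_tabular_oracle(self):
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, 100)
        A, F_tab = relationship_matrix(ped)
        F_rec = inbreeding(ped)
        assert np.allclose(F_rec, F_tab, atol=1e-12)
        # definitional identity F_i = 0.5 A_{dam,sire}
        for i in range(ped.n):
            d, s = ped.dam[i], ped.sire[i]
            expected = 0.5 * A[d, s] if (d >= 0 and s >= 0) else 0.0
            assert F_rec[i] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_A_is_psd_on_random_pedigrees(self, seed):
        ped = random_pedigree(np.random.default_rng(seed), 150)
        A, _ = relationship_matrix(ped)
        assert np.linalg.eigvalsh(A).min() >= -1e-10


class TestAInverse:
    def test_single_founder(self):
        ped = make_pedigree("id,dam,sire,cohort,sex\nA,,,1,F\n")
        assert a_inverse(ped).toarray() == pytest.approx(np.array([[1.0]]))

    def test_trio_henderson_values(self, trio):
        Ai = a_inverse(trio).toarray()
        assert np.allclose(np.diag(Ai), [1.5, 1.5, 2.0])
        assert Ai[0, 2] == pytest.approx(-1.0)
        assert Ai[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed,n", [(0, 50), (1, 120), (2, 200)])
    def test_inverse_times_A_is_identity(self, seed, n):
        ped = random_pedigree(np.random.default_rng(seed), n)
        A, _ = relationship_matrix(ped)
        Ai = a_inverse(ped).toarray()
        assert np.abs(Ai @ A - np.eye(n)).max() < 1e-8

    def test_one_known_parent_mendelian_variance(self):
        ped = make_pedigree("id,dam,sire,cohort,sex\nA,,,1,F\nK,A,,2,F\n")
        d = mendelian_variance(ped)
        assert d[list(ped.ids).index("K")] == pytest.approx(0.75)


class TestGeneDrop:
    def test_zero_variance_gives_zero(self, full_sib_family):
        bv = gene_drop(full_sib_family, 0.0, rng=1, n_reps=5)
        assert np.all(bv == 0)

    def test_negative_variance_rejected(self, trio):
        with pytest.raises(ValueError):
            gene_drop(trio, -0.1)

    def test_founder_variance(self):
        rows = "id,dam,sire,cohort,sex\n" + "\n".join(
            f"f{i},,,1,F" for i in range(10000)
        )
        ped = make_pedigree(rows + "\n")
        bv = gene_drop(ped, 1.0, rng=3)[0]
        # 3 SE sampling band around unit variance
        assert 0.94 < bv.var() < 1.06

    def test_replicate_covariance_matches_vA_times_A(self):
        ped = random_pedigree(np.random.default_rng(5), 50)
        A, _ = relationship_matrix(ped)
        bv = gene_drop(ped, 1.0, rng=11, n_reps=2000)
        emp = np.cov(bv, rowvar=False)
        assert np.abs(emp - A).max() < 0.1

    def test_deterministic_given_seed(self, full_sib_family):
        a = gene_drop(full_sib_family, 0.5, rng=9, n_reps=3)
        b = gene_drop(full_sib_family, 0.5, rng=9, n_reps=3)
        assert np.array_equal(a, b)

    def test_bivariate_drop_covariance(self):
        ped = random_pedigree(np.random.default_rng(2), 40, n_founders=40)
        G = np.array([[1.0, 0.4], [0.4, 0.5]])
        reps = np.stack([gene_drop_bivariate(ped, G, rng=k) for k in range(4000)])
        # founders only: per-individual covariance should be G
        emp = np.mean([np.cov(reps[:, i, :], rowvar=False) for i in range(40)], axis=0)
        assert np.abs(emp - G).max() < 0.1
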