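import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epibn import (
    DDAG,
    FamilyCounts,
    GenotypeDataset,
    Hyperparameters,
    bdeu_hyper,
    dag_penalty_bits,
    encoding_length_bits,
    family_counts,
    k2_hyper,
    log_family_marginal,
    score_bayesian,
    score_mdl,
    score_mml,
)
from epibn.scoring import get_criterion

from .conftest import loop_family_logml, prequential_logml, random_dataset


class TestHyperparameters:
    def test_k2_is_all_ones(self):
        assert np.array_equal(k2_hyper(2, 3).a, np.ones((2, 3)))
        assert k2_hyper(1, 1).a.sum() == 1
        assert k2_hyper(4, 7).a.sum() == 28

    def test_bdeu_entries_sum_to_alpha(self):
        h = bdeu_hyper(15, 2, 9)
        assert np.allclose(h.a, 15 / 18)
        assert h.a.sum() == pytest.approx(15)
        assert np.array_equal(bdeu_hyper(6, 2, 3).a, np.ones((2, 3)))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bdeu_hyper(0, 2, 3)
        with pytest.raises(ValueError):
            bdeu_hyper(-1, 2, 3)
        with pytest.raises(ValueError):
            Hyperparameters(np.array([[1.0, 0.0]]))


class TestFamilyMarginal:
    def test_empty_data_scores_zero(self):
        fc = FamilyCounts(2, 3, np.zeros((2, 3), dtype=int))
        assert log_family_marginal(fc, k2_hyper(2, 3)) == pytest.approx(0.0)

    def test_one_case_one_control(self):
        # prequential product: P(x1) * P(x2 | x1) = (1/2)(1/3)
        fc = FamilyCounts(2, 1, np.array([[1], [1]]))
        assert log_family_marginal(fc, k2_hyper(2, 1)) == pytest.approx(math.log(1 / 6))

    def test_shape_mismatch(self):
        fc = FamilyCounts(2, 3, np.zeros((2, 3), dtype=int))
        with pytest.raises(ValueError):
            log_family_marginal(fc, k2_hyper(2, 2))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([None, 2.0, 15.0]))
    def test_prequential_equivalence_any_ordering(self, seed, alpha):
        """Eq-style closed form equals the sequential predictive product."""
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, m=int(rng.integers(1, 7)), n=2)
        parents = (0, 1)
        hyper = k2_hyper(2, 9) if alpha is None else bdeu_hyper(alpha, 2, 9)
        closed = log_family_marginal(family_counts(ds, DDAG(parents)), hyper)
        for _ in range(3):
            perm = rng.permutation(ds.m)
            seq = prequential_logml(ds.genotypes[perm], ds.phenotype[perm],
                                    parents, hyper.a)
            assert closed == pytest.approx(seq, abs=1e-10)


class TestBayesianScore:
    def test_parentless_balanced_pair(self):
        ds = GenotypeDataset(["S1"], [[0], [2]], [1, 0])
        rep = score_bayesian(ds, DDAG(), "k2")
        assert rep.value == pytest.approx(math.log(1 / 6))
        assert rep.orientation == "higher-better"

    def test_bdeu_alpha2_matches_k2_for_empty_model(self):
        ds = GenotypeDataset(["S1"], [[0], [2], [1]], [1, 0, 0])
        assert score_bayesian(ds, DDAG(), "bdeu:2").value == pytest.approx(
            score_bayesian(ds, DDAG(), "k2").value)

    def test_matches_loop_oracle(self, rng):
        ds = random_dataset(rng, m=25, n=4)
        for scheme, a in (("k2", np.ones((2, 9))), ("bdeu:7", np.full((2, 9), 7 / 18))):
            got = score_bayesian(ds, DDAG((1, 3)), scheme).value
            want = loop_family_logml(family_counts(ds, DDAG((1, 3))).s, a)
            assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_row_order_and_column_relabeling(self, rng):
        ds = random_dataset(rng, m=40, n=5)
        perm_rows = rng.permutation(ds.m)
        shuffled = GenotypeDataset(ds.snp_names, ds.genotypes[perm_rows],
                                   ds.phenotype[perm_rows])
        col_perm = rng.permutation(ds.n)
        relabeled = GenotypeDataset([ds.snp_names[j] for j in col_perm],
                                    ds.genotypes[:, col_perm], ds.phenotype)
        inverse = np.argsort(col_perm)
        for cid in ("k2", "bdeu:15", "mdl-epi-v2", "mml-v1"):
            crit = get_criterion(cid)
            base = crit.score(ds, DDAG((0, 3))).value
            assert crit.score(shuffled, DDAG((0, 3))).value == pytest.approx(base)
            mapped = DDAG((int(inverse[0]), int(inverse[3])))
            assert crit.score(relabeled, mapped).value == pytest.approx(base)


class TestEncodingLength:
    def test_deterministic_child_is_free(self):
        fc = FamilyCounts(2, 3, np.array([[5, 0, 2], [0, 4, 0]]))
        assert encoding_length_bits(fc) == pytest.approx(0.0)

    def test_balanced_split_costs_one_bit_per_item(self):
        fc = FamilyCounts(2, 1, np.array([[2], [2]]))
        assert encoding_length_bits(fc) == pytest.approx(4.0)

    def test_matches_double_sum_oracle(self, rng):
        s = rng.integers(0, 9, size=(2, 9))
        s[0, 0] += 1  # nonempty
        total = 0.0
        for j in range(9):
            col = s[:, j].sum()
            for k in range(2):
                if s[k, j]:
                    total -= s[k, j] * math.log2(s[k, j] / col)
        fc = FamilyCounts(2, 9, s)
        assert encoding_length_bits(fc) == pytest.approx(total, abs=1e-12)
        assert encoding_length_bits(fc) >= 0


# independently derived: d_D = 3^k, d_S = 2 per parent SNP;
# suzuki charges (d/2) log2 m per node, aic charges d, the BNMBL (epi)
# disease term prices precision at m/3^k
PENALTY_TABLE = {
    ("suzuki", "v1", 2, 200): 34.39735285398626,
    ("suzuki", "v2", 2, 200): 49.68506523353571,
    ("suzuki", "v2", 4, 1600): 473.65160044497526,
    ("aic", "v1", 3, 200): 27.0,
    ("aic", "v2", 3, 1600): 33.0,
    ("aic", "v2", 4, 200): 89.0,
    ("epi", "v1", 1, 200): 9.088340533580352,
    ("epi", "v2", 2, 200): 35.42040272704531,
    ("epi", "v2", 3, 1600): 111.43264585207615,
    ("epi", "v2", 4, 1600): 216.88767532814794,
    ("none", "v1", 4, 1600): 0.0,
    ("none", "v2", 2, 200): 0.0,
}


class TestDagPenalty:
    @pytest.mark.parametrize(("variant", "version", "k", "m"), sorted(PENALTY_TABLE))
    def test_hand_computed_values(self, variant, version, k, m):
        expected = PENALTY_TABLE[(variant, version, k, m)]
        assert dag_penalty_bits(k, m, variant, version) == pytest.approx(expected, abs=1e-9)

    def test_plugin_examples(self):
        assert dag_penalty_bits(1, 8, "suzuki", "v2") == pytest.approx(7.5)
        assert dag_penalty_bits(1, 9, "epi", "v2") == pytest.approx(
            1.5 * math.log2(3) + math.log2(9))

    def test_parentless_model(self):
        for variant in ("suzuki", "epi"):
            assert dag_penalty_bits(0, 256, variant, "v1") == pytest.approx(4.0)
            assert dag_penalty_bits(0, 256, variant, "v2") == pytest.approx(4.0)
        assert dag_penalty_bits(0, 256, "aic", "v2") == pytest.approx(1.0)

    def test_warns_when_cells_outnumber_data(self):
        with pytest.warns(RuntimeWarning):
            out = dag_penalty_bits(4, 50, "epi", "v1")
        assert out < 0  # negative disease term is permitted but flagged

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 3), st.sampled_from([100, 200, 812, 1600]),
           st.sampled_from(["suzuki", "aic", "epi"]), st.sampled_from(["v1", "v2"]))
    def test_monotone_in_k_and_m(self, k, m, variant, version):
        # the BNMBL disease term (3^k/2)·log2(m/3^k) grows with k only while
        # the expected cell occupancy m/3^k stays above 3^1.5
        if variant != "epi" or m >= 3 ** 1.5 * 3 ** (k + 1):
            assert dag_penalty_bits(k + 1, m, variant, version) >= dag_penalty_bits(
                k, m, variant, version)
        if variant != "aic":
            assert dag_penalty_bits(k, 2 * m, variant, version) >= dag_penalty_bits(
                k, m, variant, version)


class TestMdlScore:
    def test_none_variant_is_pure_encoding(self, rng):
        ds = random_dataset(rng, m=30, n=4)
        ddag = DDAG((0, 2))
        rep = score_mdl(ds, ddag, "none")
        assert rep.criterion_id == "mdl-none"
        assert rep.orientation == "lower-better"
        assert rep.value == pytest.approx(encoding_length_bits(family_counts(ds, ddag)))

    def test_deterministic_disease_scores_penalty_alone(self, rng):
        geno = rng.integers(0, 3, size=(400, 4))
        pheno = ((geno[:, 0] + geno[:, 1]) % 2).astype(int)
        ds = GenotypeDataset(list("abcd"), geno, pheno)
        rep = score_mdl(ds, DDAG((0, 1)), "suzuki", "v2")
        assert rep.value == pytest.approx(dag_penalty_bits(2, 400, "suzuki", "v2"))

    def test_components_add_up(self, rng):
        ds = random_dataset(rng, m=50, n=5)
        for variant in ("suzuki", "aic", "epi"):
            for version in ("v1", "v2"):
                ddag = DDAG((1, 2, 4))
                rep = score_mdl(ds, ddag, variant, version)
                expected = dag_penalty_bits(3, 50, variant, version) + \
                    encoding_length_bits(family_counts(ds, ddag))
                assert rep.value == pytest.approx(expected, abs=1e-9)


class TestMmlScore:
    def test_offset_from_k2_is_closed_form(self, rng):
        ds = random_dataset(rng, m=64, n=5)
        for k, ddag in ((0, DDAG()), (1, DDAG((2,))), (3, DDAG((0, 1, 4)))):
            k2_log2 = score_bayesian(ds, ddag, "k2").value / math.log(2)
            v1 = score_mml(ds, ddag, "v1").value
            v2 = score_mml(ds, ddag, "v2").value
            assert v1 - k2_log2 == pytest.approx(-(3 ** k / 2) * math.log2(64))
            assert v2 - v1 == pytest.approx(-k * math.log2(64))

    def test_single_item_penalty_vanishes(self):
        ds = GenotypeDataset(["S1"], [[1]], [1])
        assert score_mml(ds, DDAG((0,)), "v1").value == pytest.approx(
            score_bayesian(ds, DDAG((0,)), "k2").value / math.log(2))

    def test_ranks_equal_size_models_like_k2(self, rng):
        ds = random_dataset(rng, m=80, n=6)
        pairs = [DDAG((0, 1)), DDAG((2, 5)), DDAG((3, 4))]
        k2_order = sorted(pairs, key=lambda d: score_bayesian(ds, d, "k2").value)
        mml_order = sorted(pairs, key=lambda d: score_mml(ds, d, "v1").value)
        assert k2_order == mml_order


class TestCriterionRegistry:
    @pytest.mark.parametrize("cid,resolved", [
        ("k2", "k2"),
        ("bdeu:15", "bdeu:15"),
        ("bdeu:alpha=54", "bdeu:54"),
        ("MDL-EPI-V2", "mdl-epi-v2"),
        ("mdl-none", "mdl-none"),
        ("mml-v2", "mml-v2"),
    ])
    def test_parses_ids(self, cid, resolved):
        assert get_criterion(cid).id == resolved

    def test_rejects_unknown(self):
        with pytest.raises(ValueError):
            get_criterion("bic")
        with pytest.raises(ValueError):
            get_criterion("bdeu:0")
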