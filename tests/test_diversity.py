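"""Distances, AMOVA variance components, PhiST, diversity summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from uniparent.diversity import (DistanceMatrix, amova, amova_from_table,
                                 diversity_summary, pairwise_differences,
                                 pairwise_phist, subsample_balance)
from uniparent.errors import DegenerateInputError
from uniparent.sequence_io import HaploidAlignment

from conftest import make_alignment, make_table, random_alignment


# ---------------------------------------------------------------------------
# independent oracles: plain-loop evaluation of the published SS equations


def oracle_one_level(d2, pops):
    N = sum(len(p) for p in pops)
    P = len(pops)
    everyone = [i for p in pops for i in p]
    ss_total = sum(d2[i][j] for i in everyone for j in everyone) / (2 * N)
    ss_wp = sum(
        sum(d2[i][j] for i in p for j in p) / (2 * len(p)) for p in pops
    )
    ss_ap = ss_total - ss_wp
    ms_ap = ss_ap / (P - 1)
    ms_wp = ss_wp / (N - P)
    n_c = (N - sum(len(p) ** 2 for p in pops) / N) / (P - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - ms_wp) / n_c
    phi = sigma_b / (sigma_b + sigma_c)
    return {"among": sigma_b, "within": sigma_c, "phi_st": phi}


def oracle_two_level(d2, groups_of_pops):
    """groups_of_pops: list of groups, each a list of populations (index lists)."""
    pops = [p for g in groups_of_pops for p in g]
    N = sum(len(p) for p in pops)
    P = len(pops)
    G = len(groups_of_pops)
    everyone = [i for p in pops for i in p]
    ss_total = sum(d2[i][j] for i in everyone for j in everyone) / (2 * N)
    ss_wp = sum(sum(d2[i][j] for i in p for j in p) / (2 * len(p)) for p in pops)
    ss_wg = 0.0
    for g in groups_of_pops:
        idx = [i for p in g for i in p]
        ss_wg += sum(d2[i][j] for i in idx for j in idx) / (2 * len(idx))
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    ms_ag, ms_ap, ms_wp = ss_ag / (G - 1), ss_ap / (P - G), ss_wp / (N - P)
    Ng = [sum(len(p) for p in g) for g in groups_of_pops]
    sum_n2_over_g = sum(
        sum(len(p) ** 2 for p in g) / ng for g, ng in zip(groups_of_pops, Ng)
    )
    sum_n2 = sum(len(p) ** 2 for p in pops)
    n1 = (N - sum_n2_over_g) / (P - G)
    n2 = (sum_n2_over_g - sum_n2 / N) / (G - 1)
    n3 = (N - sum(ng ** 2 for ng in Ng) / N) / (G - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    tot = sigma_a + sigma_b + sigma_c
    return {
        "a": sigma_a, "b": sigma_b, "c": sigma_c,
        "phi_st": (sigma_a + sigma_b) / tot,
        "phi_ct": sigma_a / tot,
        "phi_sc": sigma_b / (sigma_b + sigma_c),
    }


class TestPairwiseDifferences:
    def test_identical_sequences_all_zero(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        assert pairwise_differences(aln).values.sum() == 0

    def test_single_difference(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA"})
        assert pairwise_differences(aln).values[0, 1] == 1

    def test_missing_states_skipped_pairwise(self):
        aln = make_alignment({"a": "ANGT", "b": "AC-A"})
        # comparable sites: 1 (A=A) and 4 (T!=A) -> distance 1
        assert pairwise_differences(aln).values[0, 1] == 1

    def test_matches_column_by_column_oracle(self, rng):
        aln = random_alignment(rng, 5, 20)
        got = pairwise_differences(aln).values
        for i in range(5):
            for j in range(5):
                expected = sum(
                    aln.matrix[i, k] != aln.matrix[j, k] for k in range(20)
                )
                assert got[i, j] == expected


class TestAmova:
    def test_complete_differentiation(self):
        # two internally monomorphic populations at distance d
        aln = make_alignment({
            "a1": "AAAA", "a2": "AAAA", "a3": "AAAA",
            "b1": "CCCC", "b2": "CCCC", "b3": "CCCC",
        })
        dm = pairwise_differences(aln)
        res = amova(dm, ["A"] * 3 + ["B"] * 3, n_perm=99, seed=0)
        assert res.phi["Phi_ST"] == pytest.approx(1.0)
        assert res.percentages["among_populations"] == pytest.approx(100.0)

    def test_one_level_components_match_oracle(self, rng):
        aln = random_alignment(rng, 10, 40)
        dm = pairwise_differences(aln)
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 4
        res = amova(dm, pops, n_perm=10, seed=0)
        d2 = (dm.values ** 2).tolist()
        exp = oracle_one_level(d2, [[0, 1, 2], [3, 4, 5], [6, 7, 8, 9]])
        assert res.components["among_populations"] == pytest.approx(exp["among"], abs=1e-9)
        assert res.components["within_populations"] == pytest.approx(exp["within"], abs=1e-9)
        assert res.phi["Phi_ST"] == pytest.approx(exp["phi_st"], abs=1e-9)

    def test_two_level_components_match_oracle(self, rng):
        # 2 groups x 2 populations x 3 samples
        aln = random_alignment(rng, 12, 60)
        dm = pairwise_differences(aln)
        pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3
        groups = ["g1"] * 6 + ["g2"] * 6
        res = amova(dm, pops, groups, n_perm=10, seed=0)
        d2 = (dm.values ** 2).tolist()
        exp = oracle_two_level(
            d2, [[[0, 1, 2], [3, 4, 5]], [[6, 7, 8], [9, 10, 11]]]
        )
        assert res.components["among_groups"] == pytest.approx(exp["a"], abs=1e-9)
        assert res.components["among_populations_within_groups"] == pytest.approx(
            exp["b"], abs=1e-9)
        assert res.components["within_populations"] == pytest.approx(exp["c"], abs=1e-9)
        for key, val in (("Phi_ST", exp["phi_st"]), ("Phi_CT", exp["phi_ct"]),
                         ("Phi_SC", exp["phi_sc"])):
            assert res.phi[key] == pytest.approx(val, abs=1e-9)

    def test_percentages_sum_to_100_and_phi_bounded(self, rng):
        for trial in range(5):
            aln = random_alignment(np.random.default_rng(trial), 9, 30)
            dm = pairwise_differences(aln)
            res = amova(dm, ["A"] * 3 + ["B"] * 3 + ["C"] * 3, n_perm=10, seed=1)
            assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-9)
            assert all(-1 <= v <= 1 for v in res.phi.values())

    def test_exact_permutation_p_matches_enumeration(self, rng):
        aln = random_alignment(rng, 6, 25)
        dm = pairwise_differences(aln)
        pops = np.array(["A", "A", "A", "B", "B", "B"])
        res = amova(dm, pops, exact=True)
        # independent enumeration over all 6! index permutations
        d2 = (dm.values ** 2).tolist()
        obs = oracle_one_level(d2, [[0, 1, 2], [3, 4, 5]])["phi_st"]
        null = []
        for perm in itertools.permutations(range(6)):
            lab = pops[list(perm)]
            pa = [i for i in range(6) if lab[i] == "A"]
            pb = [i for i in range(6) if lab[i] == "B"]
            null.append(oracle_one_level(d2, [pa, pb])["phi_st"])
        expected_p = sum(v >= obs - 1e-12 for v in null) / len(null)
        assert res.p_values["Phi_ST"] == pytest.approx(expected_p, abs=1e-12)

    def test_monte_carlo_p_approaches_exact(self, rng):
        aln = random_alignment(rng, 6, 25)
        dm = pairwise_differences(aln)
        pops = ["A"] * 3 + ["B"] * 3
        exact = amova(dm, pops, exact=True).p_values["Phi_ST"]
        mc = amova(dm, pops, n_perm=4000, seed=5).p_values["Phi_ST"]
        assert mc == pytest.approx(exact, abs=0.05)

    def test_single_population_rejected(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA", "c": "ACGG"})
        dm = pairwise_differences(aln)
        with pytest.raises(DegenerateInputError):
            amova(dm, ["A", "A", "A"], n_perm=10)

    def test_grouping_scenarios_dispatch(self, rng):
        aln = random_alignment(rng, 12, 50)
        groups = (["Macedonia:Balkan"] * 3 + ["Romania:Vlax"] * 3
                  + ["Hungary:Vlax"] * 3 + ["Hungary:Romungro"] * 3)
        table = make_table(aln.sample_ids, groups)
        dm = pairwise_differences(aln)
        combined = amova_from_table(dm, table, "combined", n_perm=20, seed=0)
        country = amova_from_table(dm, table, "country", n_perm=20, seed=0)
        assert combined.design == "one-level"
        assert country.design == "two-level"
        assert {"Phi_ST", "Phi_CT", "Phi_SC"} <= set(country.phi)


class TestPairwisePhist:
    def test_panmictic_split_is_near_zero(self, rng):
        aln = random_alignment(rng, 16, 60)
        dm = pairwise_differences(aln)
        labels = ["A"] * 8 + ["B"] * 8
        out = pairwise_phist(dm, labels)
        assert out.values[0, 1] < 0.1

    def test_fixed_haplotypes_give_one(self):
        aln = make_alignment({
            "a1": "AAAA", "a2": "AAAA", "b1": "CCCC", "b2": "CCCC",
        })
        dm = pairwise_differences(aln)
        out = pairwise_phist(dm, ["A", "A", "B", "B"])
        assert out.values[0, 1] == pytest.approx(1.0)

    def test_three_population_matrix_matches_per_pair_oracle(self, rng):
        aln = random_alignment(rng, 9, 40)
        dm = pairwise_differences(aln)
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        out = pairwise_phist(dm, labels)
        idx = {"A": [0, 1, 2], "B": [3, 4, 5], "C": [6, 7, 8]}
        d2 = (dm.values ** 2).tolist()
        for (a, b) in itertools.combinations("ABC", 2):
            sub = [[d2[i][j] for j in idx[a] + idx[b]] for i in idx[a] + idx[b]]
            exp = oracle_one_level(
                sub, [list(range(3)), list(range(3, 6))])["phi_st"]
            i, j = out.labels.index(a), out.labels.index(b)
            assert out.values[i, j] == pytest.approx(max(exp, 0.0), abs=1e-9)

    def test_singleton_pair_flagged_missing(self):
        aln = make_alignment({"a": "AAAA", "b": "CCCC", "c1": "GGGG", "c2": "GGGG"})
        dm = pairwise_differences(aln)
        out = pairwise_phist(dm, ["A", "B", "C", "C"])
        i, j = out.labels.index("A"), out.labels.index("B")
        assert np.isnan(out.values[i, j])


class TestDiversitySummary:
    def test_monomorphic_population(self):
        aln = make_alignment({f"s{i}": "ACGT" for i in range(4)})
        (s,) = diversity_summary(aln, n_boot=20, seed=0)
        assert (s.segregating_sites, s.nucleotide_diversity,
                s.haplotype_diversity) == (0, 0.0, 0.0)

    def test_all_unique_haplotypes_have_h_one(self):
        aln = make_alignment({"a": "AAAA", "b": "CCCC", "c": "GGGG", "d": "TTTT"})
        (s,) = diversity_summary(aln, n_boot=20, seed=0)
        assert s.haplotype_diversity == pytest.approx(1.0)

    def test_four_sequence_hand_computation(self):
        # haplotypes: AAA x2, AAC, ACC; pairwise diffs:
        # (1,2)=0 (1,3)=1 (1,4)=2 (2,3)=1 (2,4)=2 (3,4)=1 -> pi = 7/6
        aln = make_alignment({"a": "AAA", "b": "AAA", "c": "AAC", "d": "ACC"})
        (s,) = diversity_summary(aln, n_boot=20, seed=0)
        assert s.segregating_sites == 2
        assert s.nucleotide_diversity == pytest.approx(7 / 6)
        # h = 4/3 * (1 - (2/4)^2 - (1/4)^2 - (1/4)^2) = 4/3 * 5/8
        assert s.haplotype_diversity == pytest.approx(4 / 3 * 5 / 8)
        for lo, hi in s.ci.values():
            assert lo <= hi

    def test_n_below_two_rejected(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        table = make_table(["a", "b"], ["X:1", "Y:2"])
        with pytest.raises(DegenerateInputError):
            diversity_summary(aln, table, n_boot=5, seed=0)


class TestSubsampleBalance:
    def _table(self, n=36):
        ids = [f"r{i}" for i in range(n)] + ["m1", "m2"]
        groups = ["Romania:Vlax"] * n + ["Macedonia:Balkan"] * 2
        return make_table(ids, groups)

    def test_draws_k_members_of_named_population(self):
        out = subsample_balance(self._table(), "Romania:Vlax", 15, seed=3)
        assert len(out.df) == 15
        assert set(out.df["group"]) == {"Romania:Vlax"}

    def test_k_equal_to_population_size_is_identity_set(self):
        table = self._table(5)
        out = subsample_balance(table, "Romania:Vlax", 5, seed=1)
        assert sorted(out.df["sample_id"]) == sorted(
            table.df.loc[table.df["group"] == "Romania:Vlax", "sample_id"])

    def test_seeded_reproducibility(self):
        a = subsample_balance(self._table(), "Romania:Vlax", 15, seed=9)
        b = subsample_balance(self._table(), "Romania:Vlax", 15, seed=9)
        assert a.df["sample_id"].tolist() == b.df["sample_id"].tolist()

    def test_oversized_k_rejected(self):
        with pytest.raises(DegenerateInputError):
            subsample_balance(self._table(5), "Romania:Vlax", 6, seed=0)
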