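"""Diversity, informativeness, match-probability and census statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from microhap.stats import (AlleleCensus, FrequencyTable, allele_census,
                            allele_frequencies, ae_table, effective_alleles,
                            informativeness, min_contributors,
                            most_common_genotype, random_match_probability,
                            regional_ae_ranking)

positive_vectors = arrays(
    float, st.integers(min_value=1, max_value=8),
    elements=st.floats(min_value=0.01, max_value=1.0)).map(
        lambda v: v / v.sum())


def _freq_table(cells):
    """cells: {(pop, locus): {allele: freq}} with n_copies=100."""
    rows = [(pop, locus, allele, f, 100)
            for (pop, locus), d in cells.items()
            for allele, f in d.items()]
    return FrequencyTable(pd.DataFrame(
        rows, columns=["population", "locus", "allele", "frequency",
                       "n_copies"]))


class TestEffectiveAlleles:
    @pytest.mark.parametrize("p,expected", [
        ((0.25, 0.25, 0.25, 0.25), 4.0),
        ((1.0,), 1.0),
        ((0.5, 0.3, 0.2), 1.0 / 0.38),
    ])
    def test_known_values(self, p, expected):
        assert effective_alleles(p) == pytest.approx(expected, rel=1e-9)

    @given(positive_vectors)
    def test_bounded_by_allele_count(self, p):
        ae = effective_alleles(p)
        assert 1.0 - 1e-9 <= ae <= len(p) + 1e-9

    @given(st.integers(min_value=1, max_value=20))
    def test_uniform_attains_the_bound(self, k):
        assert effective_alleles(np.full(k, 1 / k)) == pytest.approx(k)


class TestInformativeness:
    def test_identical_populations_carry_no_information(self):
        m = np.tile([0.2, 0.3, 0.5], (4, 1))
        assert informativeness(m) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_attains_ln2(self):
        assert informativeness([[1, 0], [0, 1]]) == pytest.approx(
            math.log(2))

    def test_hand_evaluated_two_population_case(self):
        # pbar = (0.375, 0.625); I_n = 0.0338206...
        m = [[0.5, 0.5], [0.25, 0.75]]
        assert informativeness(m) == pytest.approx(0.03382, abs=5e-6)

    def test_single_population_is_an_error(self):
        with pytest.raises(ValueError):
            informativeness([[0.5, 0.5]])

    @given(st.integers(min_value=2, max_value=6), st.integers(0, 2 ** 32 - 1))
    def test_bounds_zero_to_ln_k(self, k, seed):
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.full(4, 0.5), size=k)
        i_n = informativeness(m)
        assert -1e-9 <= i_n <= math.log(k) + 1e-9


class TestMatchProbability:
    def test_single_biallelic_locus(self):
        ft = _freq_table({("P1", "L1"): {"A": 0.5, "B": 0.5}})
        # genotype freqs 0.25/0.5/0.25 -> sum of squares 0.375
        assert random_match_probability(ft, "P1") == pytest.approx(
            math.log10(0.375))

    def test_monomorphic_locus_gives_probability_one(self):
        ft = _freq_table({("P1", "L1"): {"A": 1.0}})
        assert random_match_probability(ft, "P1") == 0.0

    def test_product_rule_over_independent_loci(self):
        ft = _freq_table({("P1", "L1"): {"A": 0.5, "B": 0.5},
                          ("P1", "L2"): {"A": 0.5, "B": 0.5}})
        assert random_match_probability(ft, "P1") == pytest.approx(
            2 * math.log10(0.375))

    def test_log10_rmp_additive_over_disjoint_subsets(self):
        ft = _freq_table({("P1", "L1"): {"A": 0.7, "B": 0.3},
                          ("P1", "L2"): {"A": 0.5, "B": 0.25, "C": 0.25},
                          ("P1", "L3"): {"A": 0.9, "B": 0.1}})
        whole = random_match_probability(ft, "P1")
        parts = (random_match_probability(ft, "P1", ["L1"])
                 + random_match_probability(ft, "P1", ["L2", "L3"]))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_skipped_locus_warns(self):
        ft = _freq_table({("P1", "L1"): {"A": 1.0},
                          ("P2", "L1"): {"A": 1.0},
                          ("P2", "L2"): {"A": 1.0}})
        with pytest.warns(UserWarning, match="skipped"):
            random_match_probability(ft, "P1", ["L1", "L2"])


class TestMostCommonGenotype:
    def test_heterozygote_is_most_common_at_half_half(self):
        ft = _freq_table({("P1", "L1"): {"A": 0.5, "B": 0.5}})
        assert most_common_genotype(ft, "P1") == pytest.approx(
            math.log10(0.5))

    def test_monomorphic_panel_gives_zero(self):
        ft = _freq_table({("P1", "L1"): {"A": 1.0},
                          ("P1", "L2"): {"B": 1.0}})
        assert most_common_genotype(ft, "P1") == 0.0

    @given(positive_vectors, st.just(None))
    def test_dominates_rmp_per_locus(self, p, _):
        # max_g f_g >= sum_g f_g^2  (weighted mean <= max)
        ft = _freq_table({("P1", "L1"):
                          {f"A{i}": f for i, f in enumerate(p)}})
        assert most_common_genotype(ft, "P1") >= \
            random_match_probability(ft, "P1") - 1e-12


class TestAlleleFrequencies:
    @staticmethod
    def _genotypes(rows):
        return pd.DataFrame(rows, columns=["sample", "population", "locus",
                                           "allele1", "allele2"])

    def test_homozygous_population(self):
        g = self._genotypes([(f"S{i}", "P1", "L1", "A", "A")
                             for i in range(10)])
        ft = allele_frequencies(g)
        assert ft.vector("P1", "L1").to_dict() == {"A": 1.0}
        assert ft.n_copies("P1", "L1") == 20

    def test_mixed_genotypes(self):
        g = self._genotypes([("S1", "P1", "L1", "A", "B"),
                             ("S2", "P1", "L1", "B", "B")])
        v = ft = allele_frequencies(g).vector("P1", "L1")
        assert v["A"] == pytest.approx(0.25)
        assert v["B"] == pytest.approx(0.75)

    def test_all_missing_cell_warns_and_is_absent(self):
        g = self._genotypes([("S1", "P1", "L1", ".", "."),
                             ("S1", "P1", "L2", "A", "A")])
        with pytest.warns(UserWarning, match="no called genotypes"):
            ft = allele_frequencies(g)
        assert not ft.has_cell("P1", "L1")
        assert ft.has_cell("P1", "L2")


class TestRegionalRanking:
    def test_single_region_full_k_is_a_permutation(self):
        ae = pd.DataFrame(np.random.default_rng(0).uniform(1, 9, (4, 6)),
                          index=[f"P{i}" for i in range(4)],
                          columns=[f"L{i}" for i in range(6)])
        out = regional_ae_ranking(ae, {p: "R1" for p in ae.index}, k=6)
        assert sorted(out["per_region"]["R1"]) == sorted(ae.columns)

    def test_globally_dominant_locus_is_in_the_intersection(self):
        rng = np.random.default_rng(1)
        ae = pd.DataFrame(rng.uniform(1, 5, (6, 10)),
                          index=[f"P{i}" for i in range(6)],
                          columns=[f"L{i}" for i in range(10)])
        ae["L9"] = 50.0
        regions = {f"P{i}": f"R{i % 3}" for i in range(6)}
        out = regional_ae_ranking(ae, regions, k=3)
        assert "L9" in out["intersection"]

    def test_matches_brute_force_reranking_oracle(self):
        rng = np.random.default_rng(2)
        pops = [f"P{i}" for i in range(12)]
        loci = [f"L{i:02d}" for i in range(30)]
        ae = pd.DataFrame(rng.uniform(1, 9, (12, 30)), index=pops,
                          columns=loci)
        regions = {p: f"R{i % 6}" for i, p in enumerate(pops)}
        k = 5
        out = regional_ae_ranking(ae, regions, k=k)
        oracle_lists = {}
        for region in set(regions.values()):
            members = [p for p in pops if regions[p] == region]
            means = [(ae.loc[members, l].mean(), l) for l in loci]
            oracle_lists[region] = [l for _, l in
                                    sorted(means, reverse=True)[:k]]
        assert out["per_region"] == oracle_lists
        union = set().union(*oracle_lists.values())
        inter = set.intersection(*map(set, oracle_lists.values()))
        assert set(out["union"]) == union
        assert set(out["intersection"]) == inter


class TestCensus:
    def test_single_population_all_common(self):
        ft = _freq_table({("P1", "L1"): {"A": 0.5, "B": 0.3, "C": 0.2}})
        census = allele_census(ft)
        assert census == AlleleCensus(total=3, common_ge_5pct=3,
                                      over_2pct=3, copies_le_2=0)

    def test_singleton_heterozygote_counts_in_rare_class(self):
        n = 1000  # 2000 copies; one B copy
        rows = [("P1", "L1", "A", 1999 / 2000, 2000),
                ("P1", "L1", "B", 1 / 2000, 2000)]
        ft = FrequencyTable(pd.DataFrame(
            rows, columns=["population", "locus", "allele", "frequency",
                           "n_copies"]))
        census = allele_census(ft)
        assert census.copies_le_2 == 1
        assert census.total == 2

    @given(st.integers(0, 2 ** 32 - 1))
    def test_census_classes_are_nested(self, seed):
        rng = np.random.default_rng(seed)
        cells = {}
        for pop in ("P1", "P2"):
            for locus in ("L1", "L2"):
                p = rng.dirichlet(np.full(6, 0.3))
                cells[(pop, locus)] = {f"A{i}": f for i, f in enumerate(p)
                                       if f > 0}
        ft = _freq_table(cells)
        census = allele_census(ft)
        assert census.common_ge_5pct <= census.over_2pct <= census.total


class TestMinContributors:
    @pytest.mark.parametrize("k,expected", [(5, 3), (6, 3), (1, 1), (2, 1),
                                            (7, 4)])
    def test_ceiling_rule(self, k, expected):
        per_locus, overall = min_contributors(k)
        assert overall == expected

    def test_overall_is_max_over_loci(self):
        per_locus, overall = min_contributors({"L1": 2, "L2": 5, "L3": 4})
        assert per_locus == {"L1": 1, "L2": 3, "L3": 2}
        assert overall == 3

    def test_zero_alleles_rejected(self):
        with pytest.raises(ValueError):
            min_contributors({"L1": 0})


def test_ae_table_matches_elementwise_computation(small_world):
    from microhap.stats import allele_frequencies
    ft = allele_frequencies(small_world["genotypes"])
    ae = ae_table(ft)
    pop, locus = ft.populations[0], ft.loci[0]
    assert ae.loc[pop, locus] == pytest.approx(
        effective_alleles(ft.vector(pop, locus).to_numpy()))


def test_low_drift_region_keeps_higher_ae_than_high_drift(small_world):
    # the diversity cline: region R1 (drift 0.02) vs R3 (drift 0.2)
    ft = allele_frequencies(small_world["genotypes"])
    ae = ae_table(ft)
    by_region = ae.mean(axis=1).groupby(
        lambda p: p.split("P")[0]).mean()
    assert by_region["R1"] > by_region["R3"]
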