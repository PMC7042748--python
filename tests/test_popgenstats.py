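"""Genotype I/O, diversity summaries, HWE, theta and the QC filters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from asymflow.popgenstats import (
    GenotypeTable,
    GenepopParseError,
    filter_individuals,
    fis_by_group_locus,
    flag_problem_loci,
    fst_permutation_p,
    hwe_test,
    linearize_fst,
    pool_temporal_samples,
    rarefied_allelic_richness,
    read_genepop,
    sequential_bonferroni,
    summarize_group,
    weir_cockerham_theta,
    write_genepop,
)
from conftest import random_table


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

class TestGenepopIO:
    def test_round_trip_lossless_including_missing(self, tmp_path):
        rng = np.random.default_rng(0)
        table = random_table(rng, {"popA": 6, "popB": 5}, n_loci=3)
        table.alleles[0, 1] = 0  # a missing genotype
        table.alleles[3, 0] = 0
        path = tmp_path / "x.gen"
        write_genepop(table, path)
        back = read_genepop(path)
        assert back == table

    def test_minimal_two_pop_file(self, tmp_path):
        text = "title\nLocA\nLocB\nPop\nind1 ,010010 020000\nPop\nind2 ,020020 010010\n"
        p = tmp_path / "m.gen"
        p.write_text(text)
        table = read_genepop(p)
        assert len(table.group_names()) == 2
        assert table.loci == ["LocA", "LocB"]
        # 0-codes parse to missing
        assert table.alleles[0, 1, 1] == 0

    def test_ragged_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gen"
        p.write_text("t\nL1\nL2\nPop\nind1 ,010101\n")
        with pytest.raises(GenepopParseError, match="line 5"):
            read_genepop(p)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

class TestFilters:
    def test_min_scored_loci_is_strict_less_than(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, {"g": 3}, n_loci=12)
        table.alleles[0, :3] = 0   # 9 scored -> removed
        table.alleles[1, :2] = 0   # 10 scored -> retained
        filtered, report = filter_individuals(table, min_scored=10)
        assert report == {"retained": 2, "removed": 1}
        assert filtered.ids == table.ids[1:]

    def test_empty_table_passes_through(self):
        table = GenotypeTable(ids=[], groups=[], loci=["L1"], alleles=np.empty((0, 1, 2), dtype=int))
        filtered, report = filter_individuals(table)
        assert filtered.n_individuals == 0 and report["removed"] == 0

    def test_fis_locus_flagging_rule(self):
        groups = [f"g{i}" for i in range(11)]
        fis = pd.DataFrame(0.0, index=groups, columns=["bad", "edge", "fine"])
        fis.loc[groups[:6], "bad"] = 0.2       # >0.15 in 6 groups -> flagged
        fis.loc[:, "edge"] = 0.15              # exactly 0.15 -> strict >
        flagged = flag_problem_loci(fis, fis_threshold=0.15, min_groups=6)
        assert flagged == {"bad"}

    def test_all_zero_fis_flags_nothing(self):
        fis = pd.DataFrame(0.0, index=["a", "b"], columns=["L1", "L2"])
        assert flag_problem_loci(fis) == set()


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class TestGroupSummary:
    def test_unbiased_he_all_heterozygotes(self):
        # 10 diploids all 'ab': Ho=1, unbiased He = (20/19)*0.5 = 0.5263, FIS<0
        alleles = np.array([[(1, 2)]] * 10)
        t = GenotypeTable(ids=[f"i{k}" for k in range(10)], groups=["g"] * 10,
                          loci=["L1"], alleles=alleles)
        s = summarize_group(t, "g")
        assert s.ho == 1.0
        assert s.he == pytest.approx((20 / 19) * 0.5, abs=1e-12)
        assert s.fis < 0

    def test_rarefaction_hand_value(self):
        # counts {A:5, B:5}, g=2 -> 2*(1 - C(5,2)/C(10,2)) = 2*(1-10/45)
        ar = rarefied_allelic_richness({1: 5, 2: 5}, g=2)
        assert ar == pytest.approx(2 * (1 - 10 / 45), abs=1e-12)

    def test_rarefaction_matches_exhaustive_enumeration(self):
        counts = {1: 4, 2: 3, 3: 2}
        pool = [a for a, c in counts.items() for _ in range(c)]
        for g in (2, 3, 5):
            expected = np.mean(
                [len(set(sub)) for sub in itertools.combinations(pool, g)]
            )
            assert rarefied_allelic_richness(counts, g) == pytest.approx(
                expected, abs=1e-10
            )

    def test_rarefaction_at_full_sample_is_allele_count(self):
        counts = {1: 4, 2: 3, 3: 2}
        assert rarefied_allelic_richness(counts, g=9) == pytest.approx(3.0)

    def test_rarefaction_increases_with_g(self):
        counts = {1: 6, 2: 3, 3: 1}
        values = [rarefied_allelic_richness(counts, g) for g in range(1, 11)]
        assert all(b > a - 1e-12 for a, b in zip(values, values[1:]))

    def test_private_alleles_and_totals(self):
        # group g1 carries allele 3 privately
        a1 = np.array([[(1, 3)], [(1, 2)]])
        a2 = np.array([[(1, 2)], [(2, 2)]])
        t = GenotypeTable(ids=["a", "b", "c", "d"], groups=["g1", "g1", "g2", "g2"],
                          loci=["L1"], alleles=np.vstack([a1, a2]))
        s1 = summarize_group(t, "g1")
        s2 = summarize_group(t, "g2")
        assert s1.private_alleles == 1
        assert s2.private_alleles == 0
        assert s1.allelic_richness <= s1.n_alleles


# ---------------------------------------------------------------------------
# HWE
# ---------------------------------------------------------------------------

class TestHwe:
    def test_monomorphic_locus_returns_one(self):
        alleles = np.array([[(1, 1)]] * 8)
        t = GenotypeTable(ids=[f"i{k}" for k in range(8)], groups=["g"] * 8,
                          loci=["L1"], alleles=alleles)
        assert hwe_test(t, "g", "L1") == 1.0

    def test_all_heterozygotes_matches_enumeration_oracle(self):
        # 4 individuals all 'ab': exact null from enumerating all orderings
        # of the 8 alleles paired sequentially
        alleles = np.array([[(1, 2)]] * 4)
        t = GenotypeTable(ids=list("abcd"), groups=["g"] * 4, loci=["L1"],
                          alleles=alleles)
        pool = [1, 1, 1, 1, 2, 2, 2, 2]
        hets = []
        for perm in itertools.permutations(range(8)):
            arr = [pool[i] for i in perm]
            hets.append(sum(arr[2 * i] != arr[2 * i + 1] for i in range(4)))
        hets = np.array(hets)
        center = hets.mean()
        obs = 4
        q = np.mean(np.abs(hets - center) >= abs(obs - center) - 1e-12)
        n_mc = 4000
        p = hwe_test(t, "g", "L1", n_montecarlo=n_mc, rng=np.random.default_rng(3))
        se = math.sqrt(q * (1 - q) / n_mc)
        assert abs(p - q) < 4 * se + 2 / n_mc

    def test_type_i_error_under_hw_proportions(self):
        rng = np.random.default_rng(4)
        false_pos = 0
        n_rep = 120
        for _ in range(n_rep):
            t = random_table(rng, {"g": 40}, n_loci=1, n_alleles=4)
            p = hwe_test(t, "g", "L0", n_montecarlo=200, rng=rng)
            false_pos += p <= 0.05
        # >= 94% of HW datasets should not be rejected
        assert false_pos / n_rep <= 0.06 + 0.04


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def wc_theta_oracle(table: GenotypeTable, ga: str, gb: str) -> float:
    """Brute-force WC84 variance components, written independently with
    plain Python loops over alleles and populations."""
    num = den = 0.0
    subs = [table.group_table(g) for g in (ga, gb)]
    r = 2
    for j in range(table.n_loci):
        genos = []
        for sub in subs:
            g = sub.alleles[:, j, :]
            g = g[(g != 0).all(axis=1)]
            genos.append(g)
        if any(len(g) < 1 for g in genos):
            continue
        alleles = sorted({int(x) for g in genos for x in g.ravel()})
        if len(alleles) < 2:
            continue
        ns = [len(g) for g in genos]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        for al in alleles:
            ps = [np.mean(g == al) for g in genos]
            hs = [np.mean((g[:, 0] == al) != (g[:, 1] == al)) for g in genos]
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestTheta:
    def test_fixed_difference_gives_one(self, fixed_demes_table):
        assert weir_cockerham_theta(fixed_demes_table, "d1", "d2") == pytest.approx(1.0)

    def test_identical_samples_give_small_negative(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, {"g1": 15}, n_loci=4)
        dup = GenotypeTable(
            ids=t.ids + [f"c_{i}" for i in t.ids],
            groups=["g1"] * 15 + ["g2"] * 15,
            loci=t.loci,
            alleles=np.vstack([t.alleles, t.alleles]),
        )
        assert weir_cockerham_theta(dup, "g1", "g2") <= 0

    def test_toy_matches_brute_force_oracle(self, two_group_table):
        theta = weir_cockerham_theta(two_group_table, "g1", "g2")
        assert theta == pytest.approx(
            wc_theta_oracle(two_group_table, "g1", "g2"), abs=1e-12
        )

    def test_invariant_to_relabelling_and_group_order(self):
        rng = np.random.default_rng(6)
        t = random_table(rng, {"g1": 12, "g2": 9}, n_loci=3, n_alleles=4)
        theta = weir_cockerham_theta(t, "g1", "g2")
        assert weir_cockerham_theta(t, "g2", "g1") == pytest.approx(theta)
        relabelled = GenotypeTable(
            ids=t.ids, groups=t.groups, loci=t.loci, alleles=t.alleles + 100
        )
        assert weir_cockerham_theta(relabelled, "g1", "g2") == pytest.approx(theta)

    def test_multilocus_theta_between_per_locus_extremes(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, {"g1": 12, "g2": 12}, n_loci=4, n_alleles=4)
        full = weir_cockerham_theta(t, "g1", "g2")
        singles = []
        for j, locus in enumerate(t.loci):
            sub = t.drop_loci([l for l in t.loci if l != locus])
            singles.append(weir_cockerham_theta(sub, "g1", "g2"))
        assert min(singles) - 1e-12 <= full <= max(singles) + 1e-12


class TestLinearizeAndBonferroni:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 0.0), (0.5, 1.0), (-0.00166, -0.00166 / 1.00166)],
    )
    def test_linearize_values(self, theta, expected):
        assert linearize_fst(theta) == pytest.approx(expected, abs=1e-9)

    def test_linearize_pole_rejected(self):
        with pytest.raises(ValueError):
            linearize_fst(1.0)

    @pytest.mark.parametrize(
        "ps,expected",
        [
            ([0.001, 0.02, 0.04], [True, True, True]),
            ([0.04, 0.04, 0.04], [False, False, False]),
            ([0.04], [True]),
            ([0.01, 0.2, 0.03], [True, False, False]),
        ],
    )
    def test_holm_step_down(self, ps, expected):
        assert sequential_bonferroni(ps) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.5, 1.2])


class TestPermutationP:
    def test_fixed_difference_minimal_p(self, fixed_demes_table):
        theta, p = fst_permutation_p(
            fixed_demes_table, "d1", "d2", n_perm=999,
            rng=np.random.default_rng(8),
        )
        assert theta == pytest.approx(1.0)
        # permuted tables can tie theta=1 only if the split is reproduced
        assert p < 0.01

    def test_null_case_large_p(self):
        rng = np.random.default_rng(9)
        t = random_table(rng, {"g1": 15, "g2": 15}, n_loci=4)
        _, p = fst_permutation_p(t, "g1", "g2", n_perm=199, rng=rng)
        assert p > 0.05

    def test_small_n_perm_warns(self, fixed_demes_table):
        with pytest.warns(UserWarning):
            fst_permutation_p(fixed_demes_table, "d1", "d2", n_perm=9,
                              rng=np.random.default_rng(0))


class TestTemporalPooling:
    def test_same_site_years_merge_when_not_differentiated(self):
        rng = np.random.default_rng(10)
        freqs = rng.dirichlet(np.ones(6), size=4)
        t = random_table(
            rng, {"siteA_2017": 15, "siteA_2018": 15}, n_loci=4, freqs=freqs
        )
        pooled, report = pool_temporal_samples(
            t, {"siteA_2017": "siteA", "siteA_2018": "siteA"},
            n_perm=199, seed=1,
        )
        assert pooled.group_names() == ["siteA"]
        assert len(report) == 1

    def test_differentiated_years_stay_separate(self):
        a = np.array([[(1, 1)]] * 12)
        b = np.array([[(2, 2)]] * 12)
        t = GenotypeTable(
            ids=[f"i{k}" for k in range(24)],
            groups=["s_2017"] * 12 + ["s_2018"] * 12,
            loci=["L1"],
            alleles=np.vstack([a, b]),
        )
        pooled, _ = pool_temporal_samples(
            t, {"s_2017": "s", "s_2018": "s"}, n_perm=199, seed=1
        )
        assert set(pooled.group_names()) == {"s_2017", "s_2018"}


def test_fis_table_shape_and_monomorphic_nan():
    rng = np.random.default_rng(11)
    t = random_table(rng, {"g1": 8, "g2": 8}, n_loci=3)
    t.alleles[:, 2, :] = 1  # monomorphic locus
    fis = fis_by_group_locus(t)
    assert fis.shape == (2, 3)
    assert fis["L2"].isna().all()
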