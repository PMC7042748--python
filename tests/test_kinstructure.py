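"""k-coefficient dyad likelihoods, classification, the mixed-site
proportion comparison, and full-sib deduplication."""

import numpy as np
import pytest

from asymflow.kinstructure import (
    K_PRESETS,
    DyadResult,
    classify_dyads,
    dedupe_full_sibs,
    dyad_likelihood,
    dyad_locus_likelihoods,
    mixed_site_proportion_test,
    two_proportion_test,
)
from asymflow.popgenstats import GenotypeTable
from asymflow.synthcatch import (
    SimulationConfig,
    _draw_parent_genotype,
    _mendelian_offspring,
    simulate_allele_frequencies,
)


def single_locus_table(genos, groups=None):
    n = len(genos)
    return GenotypeTable(
        ids=[f"i{k}" for k in range(n)],
        groups=groups or ["x"] * n,
        loci=["L1"],
        alleles=np.array([[g] for g in genos]),
    )


class TestLocusKernels:
    def test_both_homozygous_mixture_hand_values(self):
        # p_a = 0.5, both genotypes 'aa'
        p = {1: 0.5, 2: 0.5}
        p0, p1, p2 = dyad_locus_likelihoods((1, 1), (1, 1), p)
        assert p0 == pytest.approx(0.0625)
        assert p1 == pytest.approx(0.125)
        assert p2 == pytest.approx(0.25)
        like = {
            cat: k[0] * p0 + k[1] * p1 + k[2] * p2
            for cat, k in K_PRESETS.items()
        }
        assert like["U"] == pytest.approx(0.0625)
        assert like["HS"] == pytest.approx(0.09375)
        assert like["FS"] == pytest.approx(0.140625)
        assert like["PO"] == pytest.approx(0.125)

    def test_unrelated_likelihood_is_product_of_hwe_probabilities(self):
        rng = np.random.default_rng(0)
        p = dict(enumerate(rng.dirichlet(np.ones(4)), start=1))
        g1, g2 = (1, 3), (2, 2)
        p0, _, _ = dyad_locus_likelihoods(g1, g2, p)
        assert p0 == pytest.approx((2 * p[1] * p[3]) * (p[2] ** 2))

    def test_opposite_homozygotes_exclude_parent_offspring(self):
        p = {1: 0.5, 2: 0.5}
        _, p1, p2 = dyad_locus_likelihoods((1, 1), (2, 2), p)
        assert p1 == 0.0 and p2 == 0.0

    def test_kernel_rows_sum_to_one_over_second_genotype(self):
        rng = np.random.default_rng(1)
        freq_vec = rng.dirichlet(np.ones(3))
        p = dict(enumerate(freq_vec, start=1))
        genotypes = [(a, b) for a in p for b in p if a <= b]
        for g1 in genotypes:
            tot0 = tot1 = 0.0
            for g2 in genotypes:
                p0, p1, _ = dyad_locus_likelihoods(g1, g2, p)
                tot0 += p0
                tot1 += p1
            hwe_g1 = p[g1[0]] ** 2 if g1[0] == g1[1] else 2 * p[g1[0]] * p[g1[1]]
            assert tot0 == pytest.approx(hwe_g1, abs=1e-12)
            assert tot1 == pytest.approx(hwe_g1, abs=1e-12)

    def test_unknown_allele_rejected(self):
        with pytest.raises(KeyError):
            dyad_locus_likelihoods((1, 9), (1, 1), {1: 1.0})


class TestDyadLikelihood:
    def test_missing_loci_skipped_and_empty_overlap_rejected(self):
        freqs = [{1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}]
        g1 = np.array([(1, 1), (0, 0)])
        g2 = np.array([(1, 1), (1, 2)])
        per_locus, total = dyad_likelihood(g1, g2, freqs, K_PRESETS["U"])
        assert len(per_locus) == 1
        g3 = np.array([(0, 0), (1, 2)])
        g4 = np.array([(1, 1), (0, 0)])
        with pytest.raises(ValueError):
            dyad_likelihood(g3, g4, freqs, K_PRESETS["U"])


class TestClassification:
    def test_duplicate_individuals_flagged_not_classified(self):
        genos = [(1, 2), (1, 2), (3, 4)]
        t = single_locus_table(genos)
        res = classify_dyads(t)
        first = next(r for r in res if {r.id1, r.id2} == {"i0", "i1"})
        assert first.duplicate and first.category == "DUP" and not first.accepted

    def test_posterior_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        cfg = SimulationConfig(seed=2)
        freqs = simulate_allele_frequencies(cfg, rng)["inflow"]
        rows = [
            _draw_parent_genotype(freqs, rng) for _ in range(6)
        ]
        t = GenotypeTable(
            ids=[f"i{k}" for k in range(6)], groups=["x"] * 6,
            loci=[f"L{j}" for j in range(cfg.n_loci)], alleles=np.stack(rows),
        )
        res = classify_dyads(t)
        for r in res:
            lls = np.array([r.log_likelihoods[c] for c in ("U", "HS", "FS", "PO")])
            w = np.exp(lls - lls.max())
            w /= w.sum()
            assert r.weight == pytest.approx(w.max(), abs=1e-9)

    def test_fullsib_recall_and_unrelated_specificity(self):
        """ML category recovers most true full-sib dyads; the 0.9 weight
        gate keeps unrelated dyads out of FS/HS almost entirely."""
        recalls, fps = [], []
        for seed in (11, 37, 51):
            cfg = SimulationConfig(seed=seed)
            rng = np.random.default_rng(seed)
            freqs = simulate_allele_frequencies(cfg, rng)["inflow"]
            rows, pairs_fs, pairs_u = [], [], []
            def add(g):
                rows.append(g)
                return len(rows) - 1
            for _ in range(80):
                s, d = _draw_parent_genotype(freqs, rng), _draw_parent_genotype(freqs, rng)
                pairs_fs.append((add(_mendelian_offspring(s, d, rng)),
                                 add(_mendelian_offspring(s, d, rng))))
                pairs_u.append((add(_draw_parent_genotype(freqs, rng)),
                                add(_draw_parent_genotype(freqs, rng))))
            t = GenotypeTable(
                ids=[f"i{k}" for k in range(len(rows))],
                groups=["x"] * len(rows),
                loci=[f"L{j}" for j in range(cfg.n_loci)],
                alleles=np.stack(rows),
            )
            res = classify_dyads(
                t, categories=("U", "HS", "FS"), pairs=pairs_fs + pairs_u
            )
            by = {(r.id1, r.id2): r for r in res}
            ids = t.ids
            fs = [by[(ids[i], ids[j])] for i, j in pairs_fs]
            un = [by[(ids[i], ids[j])] for i, j in pairs_u]
            recalls.append(np.mean([r.category == "FS" for r in fs]))
            fps.append(np.mean([
                r.accepted and r.category in ("FS", "HS") for r in un
            ]))
        assert np.mean(recalls) >= 0.75
        assert np.mean(fps) <= 0.05

    def test_classification_power_grows_with_loci(self):
        rng = np.random.default_rng(3)
        mean_weights = []
        for n_loci in (6, 14):
            cfg = SimulationConfig(seed=3, n_loci=n_loci)
            freqs = simulate_allele_frequencies(cfg, rng)["inflow"]
            rows, pairs = [], []
            for _ in range(60):
                s, d = _draw_parent_genotype(freqs, rng), _draw_parent_genotype(freqs, rng)
                rows.extend([
                    _mendelian_offspring(s, d, rng), _mendelian_offspring(s, d, rng)
                ])
                pairs.append((len(rows) - 2, len(rows) - 1))
            t = GenotypeTable(
                ids=[f"i{k}" for k in range(len(rows))], groups=["x"] * len(rows),
                loci=[f"L{j}" for j in range(n_loci)], alleles=np.stack(rows),
            )
            res = classify_dyads(t, categories=("U", "HS", "FS"), pairs=pairs)
            mean_weights.append(np.mean([
                r.weight for r in res if r.category == "FS"
            ]))
        assert mean_weights[1] > mean_weights[0]


class TestProportionTest:
    def test_study_counts_give_p_049(self):
        res = two_proportion_test(11, 44, 0, 18)
        assert res.p == pytest.approx(0.049, abs=5e-4)

    def test_identical_proportions_give_p_one(self):
        assert two_proportion_test(5, 10, 5, 10).p == 1.0

    def test_yates_hand_computation(self):
        res = two_proportion_test(20, 40, 10, 40)
        assert res.chi2 == pytest.approx(4.32, abs=0.01)
        assert res.p == pytest.approx(0.038, abs=0.001)

    def test_reduces_to_uncorrected_chi_square_at_large_counts(self):
        from scipy.stats import chi2_contingency

        x1, n1, x2, n2 = 5200, 10000, 4800, 10000
        res = two_proportion_test(x1, n1, x2, n2)
        chi2, p, *_ = chi2_contingency(
            [[x1, n1 - x1], [x2, n2 - x2]], correction=False
        )
        assert res.chi2 == pytest.approx(chi2, rel=0.02)
        assert np.log(res.p) == pytest.approx(np.log(p), rel=0.02)

    def test_lake_groups_excluded_from_comparison(self):
        site_of = {
            "a": "upper_inflow", "b": "upper_outflow",
            "c": "bunaveela_lake", "d": "lower_inflow",
            "e": "middle_inflow", "f": "upper_outflow",
        }
        half_sib = [["a", "b"], ["c", "d"], ["d", "e"]]  # second has lake
        full_sib = [["e", "a"], ["b", "f"]]
        res = mixed_site_proportion_test(half_sib, site_of, full_sib)
        assert (res.x1, res.n1) == (1, 2)
        assert (res.x2, res.n2) == (0, 2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(1, 0, 1, 2)


class TestDedupe:
    @staticmethod
    def fs_dyad(a, b):
        return DyadResult(
            id1=a, id2=b, site1="inflow", site2="inflow",
            log_likelihoods={}, category="FS", accepted=True,
            weight=0.99, lr_vs_runner_up=5.0,
        )

    def test_detected_member_retained(self):
        t = single_locus_table([(1, 2)] * 3)
        dyads = [self.fs_dyad("i0", "i1"), self.fs_dyad("i1", "i2")]
        reduced, removed = dedupe_full_sibs(t, dyads, detected_tags={"i1"})
        assert reduced.ids == ["i1"]
        assert set(removed) == {"i0", "i2"}

    def test_tie_broken_by_highest_id(self):
        t = single_locus_table([(1, 2)] * 3)
        dyads = [self.fs_dyad("i0", "i1"), self.fs_dyad("i1", "i2")]
        reduced, removed = dedupe_full_sibs(t, dyads)
        assert reduced.ids == ["i2"]

    def test_scored_loci_preferred_over_id(self):
        genos = np.array([
            [(1, 2), (1, 1)],
            [(1, 2), (0, 0)],
            [(1, 1), (2, 2)],
        ])
        t = GenotypeTable(ids=["i0", "i1", "i2"], groups=["x"] * 3,
                          loci=["L1", "L2"], alleles=genos)
        dyads = [self.fs_dyad("i0", "i1")]
        reduced, removed = dedupe_full_sibs(t, dyads)
        assert "i0" in reduced.ids and removed == ["i1"]

    def test_no_dyads_leaves_table_unchanged(self):
        t = single_locus_table([(1, 2), (3, 4)])
        reduced, removed = dedupe_full_sibs(t, [])
        assert reduced == t and removed == []
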