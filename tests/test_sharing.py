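"""Cross-population sharing statistics and the F_ST-tree parsimony analysis."""

import math

import numpy as np
import pandas as pd
import pytest

import popeqtl as pq


class TestSharingMatrix:
    def test_single_population_gene_in_histogram_bin_one(self):
        s = pq.sharing_matrix({"CEU": {"g1"}, "CHB": set()})
        assert s.histogram[1] == 1
        assert s.pair_counts.loc["CEU", "CHB"] == 0
        assert s.n_shared_ge2 == 0

    def test_gene_in_all_populations_hits_every_pair(self):
        pops = [f"P{i}" for i in range(8)]
        s = pq.sharing_matrix({p: {"g1"} for p in pops})
        off_diag = s.pair_counts.to_numpy()[~np.eye(8, dtype=bool)]
        assert (off_diag == 1).all()  # all 28 pairs (x2 symmetric)
        assert s.histogram[8] == 1 and s.pct_all == 100

    @pytest.mark.parametrize(
        "k,n,expected",
        [(1074, 3130, 34), (3240, 5691, 57), (547, 1132, 48),
         (957, 2900, 33), (63, 3130, 2)],
    )
    def test_reported_sharing_percentages(self, k, n, expected):
        assert pq.percent(k, n) == expected

    @pytest.mark.parametrize("k,n,nd,expected", [(1401, 21_800, 1, 6.4),
                                                 (33, 21_800, 2, 0.15)])
    def test_reported_rates(self, k, n, nd, expected):
        assert pq.percent(k, n, ndigits=nd) == expected

    def test_counts_consistent(self, rng):
        pops = ["A", "B", "C"]
        sets = {p: set(rng.choice([f"g{i}" for i in range(30)], size=12,
                                  replace=False)) for p in pops}
        s = pq.sharing_matrix(sets)
        assert s.histogram.sum() == s.n_nonredundant == len(set().union(*sets.values()))
        level = pq.sharing_level(sets)
        assert (level.value_counts().sort_index()
                == s.histogram[s.histogram > 0]).all()


class TestHarmonize:
    def test_dosage_anchored_to_alphabetically_smaller_allele(self):
        snps = pd.DataFrame({"chrom": ["1", "1"], "pos": [1, 2],
                             "ref": ["A", "T"], "alt": ["G", "C"]},
                            index=["s0", "s1"])
        dos = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        gm = pq.GenotypeMatrix("P1", ["a", "b", "c"], snps, dos)
        out = pq.harmonize_alleles({"P1": gm})["P1"]
        # s0: alt G > ref A -> dosage flips to count A... no: dosage counted
        # alt=G which is larger, so flip; s1: alt C < ref T, dosage kept
        np.testing.assert_array_equal(out.dosages[:, 0], [2.0, 1.0, 0.0])
        np.testing.assert_array_equal(out.dosages[:, 1], [2.0, 1.0, 0.0])

    def test_mismatched_allele_pairs_dropped(self):
        def gm_with(ref, alt, pop):
            snps = pd.DataFrame({"chrom": ["1"], "pos": [1], "ref": [ref],
                                 "alt": [alt]}, index=["s0"])
            return pq.GenotypeMatrix(pop, ["a", "b"], snps, np.zeros((2, 1)))
        out = pq.harmonize_alleles({"P1": gm_with("A", "G", "P1"),
                                    "P2": gm_with("A", "C", "P2")})
        assert out["P1"].n_snps == 0 and out["P2"].n_snps == 0


class TestDirectionConcordance:
    def _best(self, rhos):
        return pd.DataFrame({"probe_id": [f"p{i}" for i in range(len(rhos))],
                             "snp_id": [f"s{i}" for i in range(len(rhos))],
                             "rho": rhos})

    def test_all_same_sign(self):
        c, n = pq.direction_concordance(self._best([0.5, -0.3]),
                                        self._best([0.8, -0.1]))
        assert c == 1.0 and n == 2

    def test_one_of_two_flipped(self):
        c, n = pq.direction_concordance(self._best([0.5, 0.3]),
                                        self._best([0.8, -0.1]))
        assert c == 0.5

    def test_symmetric(self):
        a, b = self._best([0.5, -0.3, 0.2]), self._best([0.8, 0.1, -0.2])
        assert pq.direction_concordance(a, b) == pq.direction_concordance(b, a)

    def test_no_shared_pairs_is_na(self):
        a = self._best([0.5])
        b = pd.DataFrame({"probe_id": ["px"], "snp_id": ["sx"], "rho": [0.1]})
        c, n = pq.direction_concordance(a, b)
        assert math.isnan(c) and n == 0


class TestFoldChange:
    def test_median_difference(self):
        expr = np.array([3.0, 3.2, 2.8, 5.0, 5.2, 4.8, 4.0])
        dos = np.array([0, 0, 0, 2, 2, 2, 1.0])
        assert pq.homozygote_fold_change(expr, dos) == pytest.approx(2.0)

    def test_identical_medians_give_zero(self):
        expr = np.array([1.0, 2.0, 1.0, 2.0])
        dos = np.array([0, 0, 2, 2.0])
        assert pq.homozygote_fold_change(expr, dos) == 0.0

    def test_small_homozygote_class_is_na(self):
        expr = np.arange(6.0)
        dos = np.array([0, 0, 1, 1, 1, 2.0])
        assert math.isnan(pq.homozygote_fold_change(expr, dos))

    def test_invariant_to_constant_shift(self, rng):
        dos = rng.choice([0.0, 1.0, 2.0], size=40, p=[0.3, 0.4, 0.3])
        expr = dos + rng.normal(size=40)
        a = pq.homozygote_fold_change(expr, dos)
        b = pq.homozygote_fold_change(expr + 11.3, dos)
        assert a == pytest.approx(b, abs=1e-12)

    def test_additive_beta_one_gives_two(self, rng):
        # additive model: expected gap between homozygote medians is 2*beta
        vals = []
        for _ in range(50):
            dos = rng.binomial(2, 0.5, size=100).astype(float)
            expr = 1.0 * dos + rng.normal(0, 0.25, size=100)
            vals.append(pq.homozygote_fold_change(expr, dos))
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)


class TestEffectSizeVsSharing:
    def test_positive_correlation_when_shared_effects_larger(self, rng):
        k = rng.integers(1, 9, size=300)
        fc = 0.3 * k + rng.normal(0, 0.5, size=300)
        r, p = pq.effect_size_vs_sharing(pd.Series(fc), pd.Series(k))
        assert r > 0 and p < 0.05

    def test_constant_sharing_is_na(self, rng):
        fc = pd.Series(rng.uniform(1, 3, 50))
        r, p = pq.effect_size_vs_sharing(fc, pd.Series([3] * 50))
        assert math.isnan(r)

    def test_shuffled_sharing_near_zero(self, rng):
        k = rng.integers(1, 9, size=500)
        fc = 0.5 * k + rng.normal(0, 0.3, size=500)
        r0, _ = pq.effect_size_vs_sharing(pd.Series(fc),
                                          pd.Series(rng.permutation(k)))
        assert abs(r0) < 0.15

    def test_too_few_genes_is_na(self, rng):
        r, p = pq.effect_size_vs_sharing(pd.Series(rng.uniform(size=10)),
                                         pd.Series(rng.integers(1, 4, 10)))
        assert math.isnan(r)


class TestPi1:
    def test_all_tiny_p_gives_one(self):
        assert pq.pi1_estimate([1e-5] * 100) == 1.0

    def test_uniform_p_near_zero(self, rng):
        ps = rng.uniform(size=10_000)
        se = 3 * math.sqrt(0.5 * 0.5 / 10_000) / 0.5
        assert abs(pq.pi1_estimate(ps)) <= se + 1e-9

    def test_half_mixture_recovers_half(self, rng):
        ps = np.concatenate([rng.uniform(size=5000), np.full(5000, 1e-6)])
        assert pq.pi1_estimate(ps) == pytest.approx(0.5, abs=0.03)

    def test_bounds_and_lambda_validation(self, rng):
        assert 0.0 <= pq.pi1_estimate(rng.uniform(size=200), 0.8) <= 1.0
        with pytest.raises(ValueError):
            pq.pi1_estimate([0.5], lambda_=1.0)

    def test_empty_is_na(self):
        assert math.isnan(pq.pi1_estimate([]))


class TestTssDistanceBySharing:
    def test_all_distances_zero(self):
        best = pd.DataFrame({"gene_id": ["g1", "g2"], "distance": [0, 0]})
        table, rho = pq.tss_distance_by_sharing(best, pd.Series({"g1": 1, "g2": 2}))
        assert (table["median"] == 0).all()

    def test_single_level_trend_na(self):
        best = pd.DataFrame({"gene_id": ["g1", "g2"], "distance": [10, 20]})
        table, rho = pq.tss_distance_by_sharing(best, pd.Series({"g1": 1, "g2": 1}))
        assert math.isnan(rho)

    def test_decaying_distance_gives_negative_trend(self, rng):
        genes, rows = {}, []
        for i in range(400):
            k = int(rng.integers(1, 9))
            genes[f"g{i}"] = k
            d = rng.exponential(200_000 / k)  # higher sharing -> closer to TSS
            rows.append({"gene_id": f"g{i}", "distance": d * rng.choice([-1, 1])})
        table, rho = pq.tss_distance_by_sharing(pd.DataFrame(rows), pd.Series(genes))
        assert rho < 0


class TestClusters:
    def test_one_snp_two_genes_forms_cluster(self):
        best = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                             "snp_id": ["s1", "s1", "s2"],
                             "distance": [500_000, 480_000, 1_000]})
        res = pq.multi_gene_clusters({"P1": best})
        assert len(res.clusters) == 1
        assert res.clusters["n_genes"].iloc[0] == 2

    def test_no_shared_snp_no_clusters(self):
        best = pd.DataFrame({"gene_id": ["g1", "g2"], "snp_id": ["s1", "s2"],
                             "distance": [1, 2]})
        res = pq.multi_gene_clusters({"P1": best})
        assert res.clusters.empty and not res.replicated_snps

    def test_replicated_cluster_and_distance_excess(self, rng):
        # one distal SNP regulating 3 genes in two populations + background
        rows = [{"gene_id": f"g{i}", "snp_id": "hub", "distance": 500_000 + i}
                for i in range(3)]
        bg = [{"gene_id": f"h{i}", "snp_id": f"s{i}",
               "distance": rng.integers(0, 50_000)} for i in range(20)]
        best = pd.DataFrame(rows + bg)
        res = pq.multi_gene_clusters({"P1": best, "P2": best.copy()})
        assert "hub" in res.replicated_snps
        assert res.distance_ranksum_p < 0.01


class TestParsimonySharing:
    def _tree8(self):
        pops = ["CEU", "CHB", "GIH", "JPT", "LWK", "MEX", "MKK", "YRI"]
        d = np.full((8, 8), 0.15)
        np.fill_diagonal(d, 0.0)
        idx = {p: i for i, p in enumerate(pops)}
        def set_d(a, b, v):
            d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
        set_d("CHB", "JPT", 0.01)
        set_d("CEU", "GIH", 0.03)
        for a, b in [("LWK", "MKK"), ("LWK", "YRI"), ("MKK", "YRI")]:
            set_d(a, b, 0.04)
        return pq.build_population_tree(pd.DataFrame(d, index=pops, columns=pops))

    def test_tree_leaves_are_populations(self):
        t = self._tree8()
        assert sorted(x.name for x in t.tips()) == [
            "CEU", "CHB", "GIH", "JPT", "LWK", "MEX", "MKK", "YRI"]

    def test_single_population_eqtls_sit_at_leaves(self):
        t = self._tree8()
        sets = {f"g{i}": frozenset({"CEU"}) for i in range(10)}
        df = pq.parsimony_sharing(t, sets, n_random=20, seed=0)
        leaf = df[df["node"] == "CEU"]
        assert leaf["observed"].iloc[0] == 10
        internal = df[df["tip_set"].str.contains(",")]
        assert (internal["observed"] == 0).all()
        assert df["observed"].sum() == 10  # conservation

    def test_asian_clade_flagged_enriched(self):
        t = self._tree8()
        sets = {f"g{i}": frozenset({"CHB", "JPT"}) for i in range(30)}
        sets.update({f"h{i}": frozenset({pq.default_populations()[i % 8].name})
                     for i in range(10)})
        df = pq.parsimony_sharing(t, sets, n_random=100, seed=3)
        clade = df[df["tip_set"] == "CHB,JPT"]
        assert len(clade) == 1 and bool(clade["enriched"].iloc[0])

    def test_random_sets_rarely_flagged(self, rng):
        t = self._tree8()
        pops = [p.name for p in pq.default_populations()]
        sets = {f"g{i}": frozenset(rng.choice(pops, size=int(rng.integers(1, 4)),
                                              replace=False).tolist())
                for i in range(60)}
        df = pq.parsimony_sharing(t, sets, n_random=100, seed=4, mode="sets")
        assert df["enriched"].mean() <= 0.34  # no systematic flagging

    def test_gene_population_sets_respect_lenient_extension(self):
        disc = {"CEU": {"g1"}, "YRI": {"g1"}}
        lenient = {"CEU": {"g1"}, "YRI": {"g1"}, "CHB": {"g1"}}
        sets = pq.build_gene_population_sets(disc, lenient, seed=0)
        assert sets["g1"] >= {"CHB"}  # lenient population always included
        assert sets["g1"] & {"CEU", "YRI"}  # plus a random discovery pop
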