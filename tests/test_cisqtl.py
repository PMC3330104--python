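"""Spearman test, permutation thresholds, FDR estimators, stepwise mapping."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

import popeqtl as pq
from popeqtl.cisqtl import _perm_min_p
from popeqtl.containers import GenotypeMatrix


def _gm(dosages, positions=None, chrom="1", pop="P1"):
    n, m = dosages.shape
    pos = positions if positions is not None else np.arange(1, m + 1)
    snps = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"},
                        index=[f"s{j}" for j in range(m)])
    return GenotypeMatrix(pop, [f"i{k}" for k in range(n)], snps,
                          np.asarray(dosages, dtype=float))


class TestSpearman:
    def test_worked_example_matches_rank_pearson_oracle(self):
        # frozen from the exact mid-rank Pearson oracle (scipy agrees)
        rho, p, n = pq.spearman_assoc([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6], min_n=3)
        assert rho == pytest.approx(0.9561828874675149, abs=1e-12)
        o_rho, o_p = ss.spearmanr([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6])
        assert rho == pytest.approx(o_rho, abs=1e-12)
        assert p == pytest.approx(o_p, rel=1e-9)

    def test_strictly_decreasing_no_ties_gives_minus_one(self):
        rho, p, _ = pq.spearman_assoc([0, 1, 2, 3, 4, 5, 6, 7, 8, 9],
                                      [10, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        assert rho == -1.0
        assert 0 < p <= 1

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            d = rng.binomial(2, rng.uniform(0.1, 0.5), size=n).astype(float)
            e = rng.normal(size=n)
            if len(np.unique(d)) < 2:
                continue
            rho, p, _ = pq.spearman_assoc(d, e)
            o_rho, o_p = ss.spearmanr(d, e)
            assert rho == pytest.approx(o_rho, abs=1e-12)
            assert p == pytest.approx(o_p, rel=1e-8)

    def test_missing_dropped_pairwise(self, rng):
        d = rng.binomial(2, 0.4, size=30).astype(float)
        e = rng.normal(size=30)
        d2 = d.copy()
        d2[:5] = np.nan
        rho, p, n = pq.spearman_assoc(d2, e)
        o_rho, o_p, o_n = pq.spearman_assoc(d[5:], e[5:])
        assert n == 25 and rho == pytest.approx(o_rho, abs=1e-12)

    def test_zero_variance_skipped(self):
        rho, p, _ = pq.spearman_assoc([1.0] * 12, list(range(12)))
        assert math.isnan(rho) and math.isnan(p)

    def test_antisymmetric_under_expression_negation(self, rng):
        d = rng.binomial(2, 0.3, size=25).astype(float)
        e = rng.normal(size=25)
        r1, p1, _ = pq.spearman_assoc(d, e)
        r2, p2, _ = pq.spearman_assoc(d, -e)
        assert r1 == pytest.approx(-r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-14)

    def test_null_p_values_uniform(self, rng):
        # permutation-independent expression -> p ~ U(0,1) up to dosage ties
        n = 60
        d = rng.binomial(2, 0.5, size=n).astype(float)
        ps = []
        for _ in range(10_000):
            e = rng.normal(size=n)
            _, p, _ = pq.spearman_assoc(d, e)
            ps.append(p)
        stat, pval = ss.kstest(ps, "uniform")
        assert pval > 0.001


class TestCisPairs:
    def test_window_boundary_arithmetic(self):
        dos = np.random.default_rng(0).binomial(2, 0.5, size=(20, 3)).astype(float)
        gm = _gm(dos, positions=[1_000_000, 3_000_001, 500_000])
        gm.snps.sort_values("pos", inplace=True)  # genome order
        gm2 = gm.subset_snps(gm.snps.sort_values("pos").index)
        annot = pd.DataFrame(
            {"gene_id": ["G1"], "chrom": ["1"], "tss": [2_000_000], "strand": ["+"],
             "snp_in_probe": [False], "eligible": [True]},
            index=["p1"],
        )
        pairs = pq.enumerate_cis_pairs(annot, gm2, window=1_000_000, min_maf=0.0)
        assert set(pairs["snp_id"]) == {"s0"}  # exactly at -1 Mb boundary
        assert pairs["distance"].iloc[0] == -1_000_000

    def test_low_maf_snp_excluded(self):
        dos = np.zeros((50, 1))
        dos[:2, 0] = 1.0  # MAF 2%
        gm = _gm(dos, positions=[100])
        annot = pd.DataFrame(
            {"gene_id": ["G1"], "chrom": ["1"], "tss": [100], "strand": ["+"],
             "snp_in_probe": [False], "eligible": [True]}, index=["p1"])
        assert pq.enumerate_cis_pairs(annot, gm).empty

    def test_matches_exhaustive_double_loop(self, rng):
        m, genes = 200, 5
        pos = np.sort(rng.choice(5_000_000, size=m, replace=False)) + 1
        dos = rng.binomial(2, 0.4, size=(30, m)).astype(float)
        gm = _gm(dos, positions=pos)
        tss = rng.integers(1, 5_000_000, size=genes)
        annot = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(genes)], "chrom": "1", "tss": tss,
             "strand": "+", "snp_in_probe": False, "eligible": True},
            index=[f"p{i}" for i in range(genes)],
        )
        window = 500_000
        pairs = pq.enumerate_cis_pairs(annot, gm, window=window, min_maf=0.0)
        expected = {
            (f"p{i}", f"s{j}")
            for i in range(genes)
            for j in range(m)
            if abs(int(pos[j]) - int(tss[i])) <= window
        }
        assert set(zip(pairs["probe_id"], pairs["snp_id"])) == expected


class TestPermutationThreshold:
    def test_order_statistic_on_exact_grid(self):
        vals = np.array([0.0001 * k for k in range(1, 10_001)])
        assert pq.permutation_threshold(vals, 0.01, 10_000) == pytest.approx(0.01)

    def test_rejects_unresolvable_alpha(self):
        with pytest.raises(ValueError):
            pq.permutation_threshold(np.linspace(0, 1, 50), 0.01, 50)

    def test_monotone_in_alpha(self, rng):
        vals = rng.uniform(size=1000)
        t_small = pq.permutation_threshold(vals, 0.001, 1000)
        t_big = pq.permutation_threshold(vals, 0.01, 1000)
        assert t_small <= t_big

    def test_observed_equal_to_threshold_not_significant(self):
        # boundary rule: strict inequality
        assoc = pd.DataFrame(
            [["P1", "G1", "p1", "s1", "1", 100, 50, 0.5, 0.01, 20]],
            columns=["population", "gene_id", "probe_id", "snp_id", "chrom", "pos",
                     "distance", "rho", "p_nominal", "n_used"],
        )
        thr = pd.DataFrame(
            [["G1", "p1", 0.01, 0.01, 1000]],
            columns=["gene_id", "probe_id", "alpha", "threshold_p", "n_perms"],
        )
        best = pq.call_significant_genes(assoc, thr, alphas=(0.01,))
        assert not best["significant_0.01"].iloc[0]

    def test_min_p_exact_against_brute_force_with_missing_and_ties(self, rng):
        n, m, P = 30, 6, 200
        expr = np.round(rng.normal(size=n), 1)  # forces expression ties
        block = rng.binomial(2, 0.35, size=(n, m)).astype(float)
        block[rng.random((n, m)) < 0.2] = np.nan
        fast = _perm_min_p(block, expr, P, np.random.default_rng(42))
        idx = np.argsort(np.random.default_rng(42).random((P, n)), axis=1)
        slow = np.full(P, np.inf)
        for r in range(P):
            e = expr[idx[r]]
            for j in range(m):
                sub = ~np.isnan(block[:, j])
                if sub.sum() < 10:
                    continue
                rho, p = ss.spearmanr(block[sub, j], e[sub])
                if np.isfinite(p):
                    slow[r] = min(slow[r], p)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_joint_individual_permutation_invariance(self, rng):
        # permuting individuals jointly in genotype + expression changes nothing
        n, m = 40, 8
        block = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        expr = rng.normal(size=n)
        perm = rng.permutation(n)
        for j in range(m):
            r1 = pq.spearman_assoc(block[:, j], expr)
            r2 = pq.spearman_assoc(block[perm, j], expr[perm])
            assert r1[0] == pytest.approx(r2[0], abs=1e-12)


class TestFdr:
    @pytest.mark.parametrize(
        "n_genes,alpha,n_sig,expected",
        [
            (18_226, 0.01, 657, 0.28),  # reported CEU value
            (18_226, 0.001, 411, 0.04),  # reported MKK value
            (100, 0.05, 10, 0.5),
        ],
    )
    def test_expected_count_fdr(self, n_genes, alpha, n_sig, expected):
        assert round(pq.fdr_expected(n_genes, alpha, n_sig), 2) == expected

    def test_zero_significant_is_na(self):
        assert math.isnan(pq.fdr_expected(100, 0.01, 0))

    def test_capped_at_one_under_pure_null(self):
        assert pq.fdr_expected(1000, 0.05, 3) == 1.0

    def test_replication_fdr_arithmetic(self):
        disc = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(10)],
             "snp_id": [f"s{i}" for i in range(10)],
             "rho": [0.5] * 10}
        )
        other = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(10)],
             "snp_id": [f"s{i}" for i in range(10)],
             "rho": [0.4] * 6 + [-0.4] * 4,
             "p_nominal": [0.001] * 6 + [0.0001] * 4}
        )
        fdr, n_rep, n_tot, n_untested = pq.fdr_replication(disc, {"P2": other})
        assert (n_rep, n_tot) == (6, 10)  # 4 flipped-sign pairs don't replicate
        assert fdr == pytest.approx(0.4)

    def test_all_replicate_gives_zero(self):
        disc = pd.DataFrame({"probe_id": ["p0"], "snp_id": ["s0"], "rho": [0.5]})
        other = pd.DataFrame({"probe_id": ["p0"], "snp_id": ["s0"], "rho": [0.3],
                              "p_nominal": [1e-5]})
        fdr, *_ = pq.fdr_replication(disc, {"P2": other})
        assert fdr == 0.0

    def test_untested_best_snp_counts_as_nonreplicated(self):
        disc = pd.DataFrame({"probe_id": ["p0"], "snp_id": ["s0"], "rho": [0.5]})
        other = pd.DataFrame({"probe_id": ["p1"], "snp_id": ["s1"], "rho": [0.3],
                              "p_nominal": [1e-5]})
        fdr, n_rep, n_tot, n_untested = pq.fdr_replication(disc, {"P2": other})
        assert fdr == 1.0 and n_untested == 1


class TestStepwise:
    def _make_gene(self, rng, n=100, beta=1.0, sd=0.25, clone=False):
        dA = rng.binomial(2, 0.5, size=n).astype(float)
        dB = rng.binomial(2, 0.5, size=n).astype(float)
        if clone:
            dB = dA.copy()
        y = beta * dA + beta * dB + rng.normal(0, sd, size=n)
        gm = _gm(np.column_stack([dA, dB]), positions=[100, 200])
        snps = pd.DataFrame({"snp_id": ["s0", "s1"], "distance": [100, 200]})
        return gm, snps, y

    def test_two_independent_snps_recovered(self, rng):
        hits = 0
        for _ in range(50):
            gm, snps, y = self._make_gene(rng)
            res = pq.stepwise_independent("G1", snps, y, gm, threshold_p=1e-3)
            if len(res.independent_snps) == 2:
                hits += 1
        assert hits >= 45  # >= 90% of 50 simulations

    def test_perfect_clone_yields_exactly_one(self, rng):
        gm, snps, y = self._make_gene(rng, clone=True)
        res = pq.stepwise_independent("G1", snps, y, gm, threshold_p=1e-3)
        assert len(res.independent_snps) == 1

    def test_terminates_when_second_round_fails_threshold(self, rng):
        dA = rng.binomial(2, 0.5, size=60).astype(float)
        dB = rng.binomial(2, 0.5, size=60).astype(float)
        y = 1.5 * dA + rng.normal(0, 0.3, size=60)  # B carries no effect
        gm = _gm(np.column_stack([dA, dB]), positions=[100, 200])
        snps = pd.DataFrame({"snp_id": ["s0", "s1"], "distance": [100, 200]})
        res = pq.stepwise_independent("G1", snps, y, gm, threshold_p=1e-4)
        assert [s[1] for s in res.independent_snps] == [1]

    def test_steps_bounded_by_snp_count(self, rng):
        gm, snps, y = self._make_gene(rng)
        res = pq.stepwise_independent("G1", snps, y, gm, threshold_p=0.99)
        assert len(res.independent_snps) <= len(snps)
        assert [s[1] for s in res.independent_snps] == list(
            range(1, len(res.independent_snps) + 1)
        )


class TestMapCisIntegration:
    def test_planted_gene_found_and_determinism(self, small_study, normalized_study):
        st = small_study
        annot = pq.select_probes(st.annotation)
        res1 = pq.map_cis(normalized_study.subset_population("CEU"),
                          st.genotypes["CEU"], annot, alphas=(0.01,),
                          n_perms=300, seed=5)
        res2 = pq.map_cis(normalized_study.subset_population("CEU"),
                          st.genotypes["CEU"], annot, alphas=(0.01,),
                          n_perms=300, seed=5)
        pd.testing.assert_frame_equal(res1.associations, res2.associations)
        pd.testing.assert_frame_equal(res1.best, res2.best)
        # at least one planted gene shared in CEU should be recovered
        shared_genes = {e.gene_id for e in st.truth.planted_eqtls
                        if "CEU" in e.shared_in}
        sig = set(res1.best.loc[res1.best["significant_0.01"], "gene_id"])
        assert shared_genes & sig

    def test_thresholds_monotone_in_alpha(self, small_study, normalized_study):
        st = small_study
        annot = pq.select_probes(st.annotation)
        res = pq.map_cis(normalized_study.subset_population("YRI"),
                         st.genotypes["YRI"], annot, alphas=(0.01, 0.001),
                         n_perms=1000, seed=6)
        wide = res.thresholds.pivot_table(index=["gene_id", "probe_id"],
                                          columns="alpha", values="threshold_p")
        assert (wide[0.001] <= wide[0.01] + 1e-15).all()
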