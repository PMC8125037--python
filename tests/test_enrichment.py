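"""Synonymous-proxy enrichment test, weights, genomic control, FDR."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from conftest import bh_oracle
from germburden import datasets
from germburden.enrichment import (
    NO_SYNONYMOUS_PROXY,
    GeneBurdenCounts,
    aggregate_gene_counts,
    bh_qvalues,
    genomic_control,
    madsen_browning_weight,
    naive_functional_test,
    proxecat_lrt,
    proxecat_weighted,
    run_enrichment_scan,
)
from germburden.qc import FilterConfig
from germburden.simulate import SimulationConfig, simulate_cohort


def numerical_lrt(fc, sc, ft, st_):
    """Independent oracle: maximize the constrained log-likelihood
    numerically over (log r, log mu_case, log mu_ctrl)."""

    def nll(params):
        r, mc, mt = np.exp(params)
        ll = 0.0
        for x, mu in zip((fc, sc, ft, st_), (mc * r, mc, mt * r, mt)):
            if x > 0:
                ll += x * math.log(mu)
            ll -= mu
        return -ll

    best = None
    for x0 in ([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [-1.0, 2.0, 2.0]):
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 40000},
        )
        if best is None or res.fun < best:
            best = res.fun
    l1 = sum((x * math.log(x) if x > 0 else 0.0) - x for x in (fc, sc, ft, st_))
    return max(0.0, 2 * (l1 + best))


class TestProxecatLrt:
    def test_equal_ratios_give_zero_statistic(self):
        c = GeneBurdenCounts(gene="g", fun_case=2, syn_case=4, fun_ctrl=100, syn_ctrl=200)
        lam, p, reason = proxecat_lrt(c)
        assert lam == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert reason is None

    def test_matches_numerical_oracle(self):
        c = GeneBurdenCounts(gene="g", fun_case=4, syn_case=2, fun_ctrl=100, syn_ctrl=200)
        lam, p, _ = proxecat_lrt(c)
        assert lam == pytest.approx(numerical_lrt(4, 2, 100, 200), abs=1e-8)
        assert p == pytest.approx(stats.chi2.sf(lam, 1))

    def test_no_synonymous_proxy_reason(self):
        c = GeneBurdenCounts(gene="g", fun_case=5, syn_case=0, fun_ctrl=50, syn_ctrl=0)
        lam, p, reason = proxecat_lrt(c)
        assert lam is None and p is None
        assert reason == NO_SYNONYMOUS_PROXY

    def test_statistic_nonnegative_random(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            fc, sc, ft, st_ = rng.integers(0, 50, size=4)
            if sc + st_ == 0:
                continue
            c = GeneBurdenCounts(
                gene="g", fun_case=int(fc), syn_case=int(sc),
                fun_ctrl=int(ft), syn_ctrl=int(st_),
            )
            lam, p, reason = proxecat_lrt(c)
            assert reason is None
            assert lam >= 0
            equal_ratio = fc * st_ == ft * sc and (fc + ft) > 0
            if lam < 1e-12:
                # zero statistic only at exactly equal observed ratios
                # (or when one cohort has no observations at all)
                assert equal_ratio or fc + sc == 0 or ft + st_ == 0


class TestWeighted:
    def test_flat_weights_reduce_to_unweighted(self):
        c = GeneBurdenCounts(
            gene="g", fun_case=4, syn_case=2, fun_ctrl=100, syn_ctrl=200,
            fun_case_w=4.0, syn_case_w=2.0, fun_ctrl_w=100.0, syn_ctrl_w=200.0,
        )
        assert proxecat_weighted(c) == proxecat_lrt(c)

    def test_common_weight_scaling_cancels(self):
        # renormalization makes the statistic invariant to scaling every
        # weight by a common factor
        c1 = GeneBurdenCounts(
            gene="g", fun_case=4, syn_case=2, fun_ctrl=100, syn_ctrl=200,
            fun_case_w=8.0, syn_case_w=4.0, fun_ctrl_w=200.0, syn_ctrl_w=400.0,
        )
        lam1, _, _ = proxecat_weighted(c1)
        lam0, _, _ = proxecat_lrt(
            GeneBurdenCounts(gene="g", fun_case=8, syn_case=4, fun_ctrl=200, syn_ctrl=400)
        )
        assert lam1 == pytest.approx(lam0)

    def test_weight_formula(self):
        # pseudo-count stabilized inverse-frequency weight
        w = madsen_browning_weight(0, 39502)
        p = 1 / 39504
        assert w == pytest.approx(1 / math.sqrt(p * (1 - p)))
        assert madsen_browning_weight(100, 200) < madsen_browning_weight(1, 200)

    def test_weighted_matches_numerical_oracle(self):
        c = GeneBurdenCounts(
            gene="g", fun_case=3, syn_case=1, fun_ctrl=80, syn_ctrl=150,
            fun_case_w=3.7, syn_case_w=1.2, fun_ctrl_w=75.0, syn_ctrl_w=160.0,
        )
        lam, _, _ = proxecat_weighted(c)
        assert lam == pytest.approx(numerical_lrt(3.7, 1.2, 75.0, 160.0), abs=1e-8)


class TestGenomicControl:
    def test_null_calibrated_median_leaves_p_unchanged(self):
        stats_in = [0.45493642311957, 0.1, 2.0]
        lam_gc, p = genomic_control(stats_in)
        assert lam_gc == pytest.approx(1.0)
        np.testing.assert_allclose(p, stats.chi2.sf(stats_in, 1))

    def test_inflated_median_rescales(self):
        lam_gc, p = genomic_control([4.0, 0.8, 0.2])
        assert lam_gc == pytest.approx(0.8 / 0.454936423119572)
        np.testing.assert_allclose(p, stats.chi2.sf(np.array([4.0, 0.8, 0.2]) / lam_gc, 1))

    def test_deflated_median_clamped_to_one(self):
        lam_gc, _ = genomic_control([0.01, 0.02, 0.03])
        assert lam_gc == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            genomic_control([])


class TestBhQvalues:
    def test_single_p(self):
        assert bh_qvalues([0.03], m=1) == pytest.approx([0.03])

    def test_hand_worked_example(self):
        # step-up on p=(0.01,0.02,0.03,0.04): q_i = min_j>=i p_j*4/j = 0.04
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04], m=4), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_qvalues([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_qvalues([0.5], m=0)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_qvalues(p), q_sm, atol=1e-12)

    def test_matches_naive_definition_with_larger_m(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = list(rng.uniform(1e-6, 1, size=10))
            m = 25
            np.testing.assert_allclose(bh_qvalues(p, m=m), bh_oracle(p, m), atol=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1, size=15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_qvalues(p)[perm], bh_qvalues(p[perm]))


class TestAggregation:
    def test_candidate_gene_counts_match_published_table(self, cfg):
        # rare deleterious functional alleles: PIK3CD 2 in cases, 68 in controls
        candidates, _ = datasets.load_candidate_variants()
        acs = datasets.candidate_case_allele_counts()
        control = datasets.candidate_control_summary()
        counts = aggregate_gene_counts(candidates, acs, control, "PIK3CD", cfg, n_case=46)
        assert counts.fun_case == 2
        assert counts.fun_ctrl == 68

    def test_absent_gene_gives_zero_counts(self, cfg):
        candidates, _ = datasets.load_candidate_variants()
        control = datasets.candidate_control_summary()
        counts = aggregate_gene_counts(candidates, {}, control, "NOSUCH", cfg)
        assert (counts.fun_case, counts.syn_case, counts.fun_ctrl, counts.syn_ctrl) == (0, 0, 0, 0)

    def test_homozygote_counts_two_alleles(self, cfg):
        from germburden.variants import ControlSummary, VariantRecord

        v = VariantRecord(
            chrom="1", pos=10, ref="A", alt="G", gene="X",
            consequence="missense", cadd_phred=30.0,
        )
        counts = aggregate_gene_counts(
            [v], {v.key: 2}, ControlSummary(variants=[], n_controls=100), "X", cfg, n_case=1
        )
        assert counts.fun_case == 2


class TestScan:
    def test_enriched_genes_rank_top(self):
        cfg = SimulationConfig(
            seed=5, n_genes=120,
            enrichment_genes={f"G{i:05d}": 10.0 for i in range(5)},
        )
        cohort = simulate_cohort(cfg)
        scan = run_enrichment_scan(
            cohort.case_variants, cohort.genotypes, cohort.control
        )
        top = [r.gene for r in scan.results[:10]]
        assert sum(g in cfg.enrichment_genes for g in top) >= 3

    def test_no_case_variants_yields_no_tested_genes(self):
        from germburden.variants import ControlSummary

        with pytest.warns(UserWarning):
            scan = run_enrichment_scan(
                [], None, ControlSummary(variants=[], n_controls=10),
                case_allele_counts={}, n_case=5,
            )
        assert scan.n_tested == 0
        assert scan.results == []

    def test_naive_test_null_at_equal_rates(self):
        c = GeneBurdenCounts(gene="g", fun_case=2, fun_ctrl=20, n_case=10, n_ctrl=100)
        lam, p = naive_functional_test(c)
        assert lam == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
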