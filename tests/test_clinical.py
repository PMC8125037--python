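"""Exact clinical tests and cohort tallies."""

import pytest

from conftest import fisher_oracle, mannwhitney_exact_oracle
from germburden import datasets
from germburden.clinical import (
    ContingencyTable2x2,
    age_onset_comparison,
    carrier_summary,
    exclusivity_and_history_test,
    fisher_exact_2x2,
    mann_whitney_u,
)


class TestFisher:
    def test_published_clinical_table(self):
        # carriers of CLTCL1/SETD2 variants vs other-tumor history
        p = fisher_exact_2x2(ContingencyTable2x2(6, 2, 11, 27))
        assert p == pytest.approx(0.04, abs=0.005)

    def test_identical_proportions(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_full_enumeration_small_table(self):
        # (3,0,0,3): only k=3 and k=0 are as extreme, each 1/20
        assert fisher_exact_2x2(ContingencyTable2x2(3, 0, 0, 3)) == pytest.approx(0.10)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 7)) == 1.0

    def test_matches_oracle_exhaustive_small(self):
        for total in range(1, 16):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        t = ContingencyTable2x2(a, b, c, d)
                        assert fisher_exact_2x2(t) == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-9
                        ), (a, b, c, d)

    def test_invariant_to_simultaneous_row_col_swap(self):
        t = ContingencyTable2x2(6, 2, 11, 27)
        swapped = ContingencyTable2x2(27, 11, 2, 6)
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(swapped))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMannWhitney:
    def test_symmetric_groups(self):
        u, p = mann_whitney_u([1, 2], [1, 2])
        assert u == 2 == 2 * 2 / 2

    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_single_observations(self):
        _, p = mann_whitney_u([5], [7])
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_path_matches_enumeration(self):
        # all rank partitions for several (n1, n2) with combined n <= 10
        for n1, n2 in [(1, 3), (2, 3), (3, 3), (2, 5), (4, 4), (3, 6)]:
            values = list(range(1, n1 + n2 + 1))
            from itertools import combinations

            for group1 in combinations(values, n1):
                x = list(group1)
                y = [v for v in values if v not in group1]
                _, p = mann_whitney_u(x, y)
                assert p == pytest.approx(
                    mannwhitney_exact_oracle(x, y), abs=1e-9
                ), (x, y)

    def test_large_or_tied_samples_use_tie_corrected_normal(self):
        x = [1.0, 2.0, 2.0, 5.0, 8.0, 9.0, 12.0]
        y = [2.0, 3.0, 4.0, 4.0, 6.0, 10.0, 11.0]
        _, p = mann_whitney_u(x, y)
        assert 0 < p <= 1


class TestCarrierSummary:
    def test_published_clinical_cohort_tallies(self):
        records = datasets.load_known_carriers()
        assignments = datasets.known_carrier_assignments()
        s = carrier_summary(records, assignments, n_cohort=datasets.COHORT_SIZE)
        assert s.n_cohort == 125
        assert s.n_carriers == 17
        assert s.carrier_rate == pytest.approx(0.136)
        assert s.per_gene["MITF"] == 9
        assert s.per_gene["BAP1"] == 3
        assert s.per_gene["CDKN2A"] == 2
        assert s.per_gene["FLCN"] == 2
        assert s.per_gene["PTEN"] == 1
        assert s.n_carriers_with_mc1r == 12

    def test_empty_assignments(self):
        records = datasets.load_known_carriers()
        s = carrier_summary(records, {}, n_cohort=125)
        assert s.n_carriers == 0 and s.per_gene == {}

    def test_multi_hit_counted(self):
        records, _ = datasets.synthetic_wes_cohort()
        s = carrier_summary(records, {"W01": ["A", "B"]}, n_cohort=46)
        assert s.n_multi_hit == 1 and s.n_single_hit == 0

    def test_dangling_case_id_errors(self):
        records = datasets.load_known_carriers()
        with pytest.raises(ValueError, match="unknown case id"):
            carrier_summary(records, {"nope": ["MITF"]})


class TestExclusivityAndAges:
    def test_synthetic_cohort_reproduces_published_association(self):
        records, assignments = datasets.synthetic_wes_cohort()
        table, p = exclusivity_and_history_test(
            assignments, records, {"CLTCL1", "SETD2"}
        )
        assert table.cells == ((6, 2), (11, 27))
        assert p == pytest.approx(0.04, abs=0.005)

    def test_all_carriers_zero_margin(self):
        records, _ = datasets.synthetic_wes_cohort()
        assignments = {r.case_id: ["X"] for r in records}
        _, p = exclusivity_and_history_test(assignments, records, {"X"})
        assert p == 1.0

    def test_empty_gene_set_errors(self):
        records, assignments = datasets.synthetic_wes_cohort()
        with pytest.raises(ValueError):
            exclusivity_and_history_test(assignments, records, set())

    def test_age_shift_decreases_p(self):
        from germburden.simulate import SimulationConfig, simulate_cohort

        ps = []
        for shift in (0.0, 15.0):
            cfg = SimulationConfig(
                seed=9, n_genes=50, carrier_age_shift=shift,
                enrichment_genes={"G00000": 5.0, "G00001": 5.0},
            )
            cohort = simulate_cohort(cfg)
            assignments = {}
            gene_of = {v.key: v.gene for v in cohort.case_variants}
            for i, sid in enumerate(cohort.genotypes.sample_ids):
                genes = [
                    gene_of[k]
                    for j, k in enumerate(cohort.genotypes.variant_keys)
                    if cohort.genotypes.dosages[i][j] > 0
                ]
                assignments[sid] = genes
            _, _, p = age_onset_comparison(
                assignments, cohort.clinical, set(cfg.enrichment_genes)
            )
            ps.append(p)
        assert ps[1] < ps[0]

    def test_identical_ages_no_evidence(self):
        records, _ = datasets.synthetic_wes_cohort()
        # carriers and non-carriers get interleaved identical age patterns:
        # build two groups with the same values
        assignments = {r.case_id: (["X"] if i % 2 else []) for i, r in enumerate(records)}
        flat = [
            r
            for r in records
        ]
        m_c, m_n, p = age_onset_comparison(assignments, flat, {"X"})
        assert 0 < p <= 1

    def test_all_missing_ages_error(self):
        from germburden.variants import ClinicalRecord

        records = [ClinicalRecord(case_id="a"), ClinicalRecord(case_id="b")]
        with pytest.raises(ValueError):
            age_onset_comparison({"a": ["X"]}, records, {"X"})
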