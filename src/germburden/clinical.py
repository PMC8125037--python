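"""Exact clinical association tests and cohort summary tallies.

Small-cohort clinical comparisons use the Fisher exact test (two-sided by
probability ordering) for categorical variables and the Mann-Whitney U test
for continuous ones, alongside deterministic carrier tallies (carrier rates,
per-gene counts, MC1R co-carriage, single- versus multi-hit cases).
"""

from __future__ import annotations

import statistics as pystats
from dataclasses import dataclass, field

from scipy import stats

from .variants import ClinicalRecord


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows are exposure groups, columns the outcome: ((a, b), (c, d))."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    @property
    def cells(self):
        return ((self.a, self.b), (self.c, self.d))


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by probability ordering: the sum of
    hypergeometric probabilities, over tables with the observed margins, of
    every table no more probable than the observed one.  A zero margin
    yields p = 1 by convention."""
    if (
        t.a + t.b == 0
        or t.c + t.d == 0
        or t.a + t.c == 0
        or t.b + t.d == 0
    ):
        return 1.0
    return float(stats.fisher_exact(t.cells, alternative="two-sided")[1])


def fisher_exact_one_sided(t: ContingencyTable2x2) -> float:
    """One-sided (greater in the first row) Fisher exact p-value."""
    return float(stats.fisher_exact(t.cells, alternative="greater")[1])


def mann_whitney_u(
    x, y, *, exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact p-value by enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction (and continuity correction).
    Returns ``(U, two-sided p)`` with U taken for the first sample.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


@dataclass
class CarrierSummary:
    n_cohort: int
    n_carriers: int
    per_gene: dict[str, int] = field(default_factory=dict)
    n_carriers_with_mc1r: int = 0
    n_single_hit: int = 0
    n_multi_hit: int = 0

    def __post_init__(self):
        if self.n_carriers > self.n_cohort:
            raise ValueError("carriers cannot exceed cohort size")

    @property
    def carrier_rate(self) -> float:
        return self.n_carriers / self.n_cohort if self.n_cohort else 0.0


def carrier_summary(
    records: list[ClinicalRecord],
    assignments: dict[str, list[str]],
    n_cohort: int | None = None,
) -> CarrierSummary:
    """Tally carrier counts from per-case gene assignments.

    ``assignments`` maps case id -> list of genes in which the case carries
    a qualifying variant.  ``n_cohort`` defaults to the number of clinical
    records (pass it explicitly when the records cover carriers only).
    """
    known = {r.case_id for r in records}
    for cid in assignments:
        if cid not in known:
            raise ValueError(f"assignment references unknown case id {cid!r}")
    if n_cohort is None:
        n_cohort = len(records)
    by_id = {r.case_id: r for r in records}
    per_gene: dict[str, int] = {}
    n_carriers = n_mc1r = n_single = n_multi = 0
    for cid, genes in assignments.items():
        if not genes:
            continue
        n_carriers += 1
        for g in set(genes):
            per_gene[g] = per_gene.get(g, 0) + 1
        if len(set(genes)) > 1:
            n_multi += 1
        else:
            n_single += 1
        if by_id[cid].mc1r_variants:
            n_mc1r += 1
    return CarrierSummary(
        n_cohort=n_cohort,
        n_carriers=n_carriers,
        per_gene=dict(sorted(per_gene.items())),
        n_carriers_with_mc1r=n_mc1r,
        n_single_hit=n_single,
        n_multi_hit=n_multi,
    )


def exclusivity_and_history_test(
    assignments: dict[str, list[str]],
    records: list[ClinicalRecord],
    gene_set: set[str],
) -> tuple[ContingencyTable2x2, float]:
    """Fisher test of carriers-of-``gene_set`` against personal history of
    at least one *other* solid tumor (beyond the two index cancers)."""
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    a = b = c = d = 0
    for r in records:
        carrier = bool(gene_set & set(assignments.get(r.case_id, [])))
        if carrier:
            if r.other_solid_tumors:
                a += 1
            else:
                b += 1
        else:
            if r.other_solid_tumors:
                c += 1
            else:
                d += 1
    table = ContingencyTable2x2(a, b, c, d)
    return table, fisher_exact_2x2(table)


def age_onset_comparison(
    assignments: dict[str, list[str]],
    records: list[ClinicalRecord],
    gene_set: set[str],
    cancer: str = "melanoma",
) -> tuple[float, float, float]:
    """Median ages at first diagnosis for carriers of ``gene_set`` versus
    non-carriers, with a Mann-Whitney p-value.  ``cancer`` selects which
    diagnosis age is compared ("melanoma" or "rcc")."""
    attr = "age_first_melanoma" if cancer == "melanoma" else "age_first_rcc"
    carrier_ages, other_ages = [], []
    for r in records:
        age = getattr(r, attr)
        if age is None:
            continue
        if gene_set & set(assignments.get(r.case_id, [])):
            carrier_ages.append(age)
        else:
            other_ages.append(age)
    if not carrier_ages or not other_ages:
        raise ValueError("ages missing for one of the compared groups")
    _, p = mann_whitney_u(carrier_ages, other_ages)
    return pystats.median(carrier_ages), pystats.median(other_ages), p
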