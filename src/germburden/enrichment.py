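"""Gene-level burden aggregation and the synonymous-proxy enrichment test.

The discovery engine compares, per gene, the rare *functional* allele burden
in an internally sequenced case cohort against externally processed controls
(for example a gnomAD frequency release).  Because the two call sets go
through different capture, coverage and filtering, their absolute rare-allele
counts are not comparable; rare *synonymous* alleles, which are not under the
case-ascertainment pressure, serve as an internal proxy for those processing
differences.

Model: the four class totals are independent Poisson counts

    fun_case ~ Pois(mu_case * r_case)     syn_case ~ Pois(mu_case)
    fun_ctrl ~ Pois(mu_ctrl * r_ctrl)     syn_ctrl ~ Pois(mu_ctrl)

and the null hypothesis is an equal functional/synonymous rate ratio,
``r_case = r_ctrl``.  Any multiplicative processing artifact acting on both
classes of one cohort is absorbed into ``mu`` and cancels from the ratio.
The likelihood-ratio statistic has a closed-form constrained maximum:

    r_hat = (fun_case + fun_ctrl) / (syn_case + syn_ctrl)
    mu_hat_case = (fun_case + syn_case) / (1 + r_hat)
    mu_hat_ctrl = (fun_ctrl + syn_ctrl) / (1 + r_hat)

with Lambda = 2 * (l1 - l0) referred to chi-square with 1 df.  The weighted
variant multiplies each contributing allele count by an inverse
allele-frequency weight 1/sqrt(p(1-p)) with p estimated from controls under
a +1/+2 pseudo-count, up-weighting the rarest variants.

Scan-level corrections: a conservative genomic-control factor (median
statistic over the chi-square-1 median, clamped at 1) divides every
statistic before p-values, and Benjamini-Hochberg q-values control the FDR
across tested genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .qc import FilterConfig, classify_functional_class, is_deleterious, is_rare
from .variants import CohortGenotypes, ControlSummary, VariantRecord

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493642...

#: reason code for genes where the proxy test is undefined
NO_SYNONYMOUS_PROXY = "no synonymous proxy"
NO_OBSERVATIONS = "no observations"


@dataclass
class GeneBurdenCounts:
    """Per-gene rare-allele totals by functional class and cohort.

    Unweighted totals are integers; ``*_w`` totals are the weighted sums
    (equal to the unweighted totals when every weight is 1).
    """

    gene: str
    fun_case: float = 0.0
    syn_case: float = 0.0
    fun_ctrl: float = 0.0
    syn_ctrl: float = 0.0
    n_case: int = 0
    n_ctrl: int = 0
    fun_case_w: float | None = None
    syn_case_w: float | None = None
    fun_ctrl_w: float | None = None
    syn_ctrl_w: float | None = None

    def __post_init__(self):
        for name in ("fun_case", "syn_case", "fun_ctrl", "syn_ctrl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def weighted(self) -> tuple[float, float, float, float]:
        if self.fun_case_w is None:
            return (self.fun_case, self.syn_case, self.fun_ctrl, self.syn_ctrl)
        return (self.fun_case_w, self.syn_case_w, self.fun_ctrl_w, self.syn_ctrl_w)


@dataclass
class EnrichmentResult:
    gene: str
    counts: GeneBurdenCounts | None = None
    lrt_statistic: float | None = None
    p_raw: float | None = None
    p_gc: float | None = None
    q: float | None = None
    significant: bool = False
    reason: str | None = None  # set when the test is undefined for this gene


def _poisson_ll(counts, rates) -> float:
    """Poisson log-likelihood up to the constant -log(x!); 0*log(0) == 0."""
    ll = 0.0
    for x, mu in zip(counts, rates):
        if x > 0:
            if mu <= 0:
                return -math.inf
            ll += x * math.log(mu)
        ll -= mu
    return ll


def proxecat_lrt(
    c: GeneBurdenCounts, *, weighted: bool = False, one_sided: bool = False
) -> tuple[float | None, float | None, str | None]:
    """Likelihood-ratio test of equal functional/synonymous rate ratio.

    Returns ``(statistic, p, reason)``; statistic and p are ``None`` with a
    reason code when the test is undefined (no synonymous proxy alleles, or
    no alleles at all).  With ``one_sided=True`` the p-value is halved when
    the case ratio exceeds the control ratio (enrichment direction) and
    folded otherwise.
    """
    fc, sc, ft, st = c.weighted() if weighted else (
        c.fun_case,
        c.syn_case,
        c.fun_ctrl,
        c.syn_ctrl,
    )
    if fc + sc + ft + st <= 0:
        return None, None, NO_OBSERVATIONS
    if sc + st <= 0:
        return None, None, NO_SYNONYMOUS_PROXY

    # unconstrained MLE: each observed count is its own rate
    l1 = _poisson_ll((fc, sc, ft, st), (fc, sc, ft, st))
    # constrained MLE under equal ratio
    r = (fc + ft) / (sc + st)
    mu_case = (fc + sc) / (1.0 + r)
    mu_ctrl = (ft + st) / (1.0 + r)
    l0 = _poisson_ll((fc, sc, ft, st), (mu_case * r, mu_case, mu_ctrl * r, mu_ctrl))
    lam = max(0.0, 2.0 * (l1 - l0))
    p = float(stats.chi2.sf(lam, 1))
    if one_sided:
        case_ratio = fc / sc if sc > 0 else math.inf
        ctrl_ratio = ft / st if st > 0 else math.inf
        p = p / 2.0 if case_ratio >= ctrl_ratio else 1.0 - p / 2.0
    return lam, min(1.0, max(p, 0.0)) or np.nextafter(0, 1), None


def proxecat_weighted(c: GeneBurdenCounts, **kw) -> tuple[float | None, float | None, str | None]:
    """The same LRT applied to the weighted allele totals."""
    return proxecat_lrt(c, weighted=True, **kw)


def madsen_browning_weight(allele_count: int, allele_number: int) -> float:
    """Inverse allele-frequency weight 1/sqrt(p(1-p)) with the control
    frequency estimated under a +1/+2 pseudo-count,
    p = (AC + 1) / (AN + 2).  Variants unobserved in controls get the
    largest weight."""
    if allele_number < 0 or allele_count < 0:
        raise ValueError("allele counts must be >= 0")
    p = (allele_count + 1.0) / (allele_number + 2.0)
    return 1.0 / math.sqrt(p * (1.0 - p))


def genomic_control(statistics) -> tuple[float, np.ndarray]:
    """Conservative genomic-control correction.

    lambda = max(1, median(statistics) / chi-square-1 median); every
    statistic is divided by lambda and re-referred to chi-square-1.
    Returns ``(lambda, adjusted p-values)``.
    """
    arr = np.asarray([s for s in statistics if s is not None and np.isfinite(s)], dtype=float)
    if arr.size == 0:
        raise ValueError("no finite statistics for genomic control")
    lam_gc = max(1.0, float(np.median(arr)) / CHI2_1_MEDIAN)
    adjusted = stats.chi2.sf(arr / lam_gc, 1)
    return lam_gc, adjusted


def bh_qvalues(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m`` is the number of tests and may exceed ``len(p)`` when only a
    subset of tested hypotheses is supplied; q_i = min over p_j >= p_i of
    p_j * m / rank_j, capped at 1.  Ties share the largest rank.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(p.size, dtype=float)
    # ties share the largest rank among them (standard step-up behavior)
    sorted_p = p[order]
    i = 0
    while i < p.size:
        j = i
        while j + 1 < p.size and sorted_p[j + 1] == sorted_p[i]:
            j += 1
        ranks[i : j + 1] = j + 1
        i = j + 1
    q_sorted = sorted_p * m / ranks
    # enforce monotonicity from the largest p downward
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def aggregate_gene_counts(
    case_variants: list[VariantRecord],
    case_allele_counts: dict[tuple, int],
    control: ControlSummary,
    gene: str,
    cfg: FilterConfig | None = None,
    n_case: int = 0,
    weight_scheme: str = "madsen-browning",
) -> GeneBurdenCounts:
    """Aggregate one gene's rare-allele totals by class and cohort.

    ``case_allele_counts`` maps variant key -> alt allele count in cases.
    The deleteriousness filter applies to the *functional* stratum only;
    synonymous proxy alleles are rare synonymous alleles with no CADD
    requirement.  Inputs are assumed pre-filtered for rarity.
    """
    cfg = cfg or FilterConfig()
    counts = GeneBurdenCounts(gene=gene, n_case=n_case, n_ctrl=control.n_controls)
    an_ctrl = 2 * control.n_controls
    ctrl_ac = {v.key: v.allele_count for v in control.variants}

    def weight(key) -> float:
        if weight_scheme == "flat":
            return 1.0
        return madsen_browning_weight(ctrl_ac.get(key, 0), an_ctrl)

    # weighted totals are renormalized to unit mean weight per cohort so
    # they stay on the allele-count scale the Poisson likelihood assumes;
    # only the relative up-weighting of rarer variants is retained
    case_w: list[tuple[float, float, str]] = []  # (weight, ac, class)
    ctrl_w: list[tuple[float, float, str]] = []
    for v in case_variants:
        if v.gene != gene:
            continue
        ac = case_allele_counts.get(v.key, 0)
        if ac <= 0:
            continue
        cls = classify_functional_class(v.consequence, cfg)
        if cls == "functional" and is_deleterious(v, cfg):
            counts.fun_case += ac
            case_w.append((weight(v.key), ac, "functional"))
        elif cls == "synonymous":
            counts.syn_case += ac
            case_w.append((weight(v.key), ac, "synonymous"))
    for cv in control.variants:
        if cv.gene != gene or cv.allele_count <= 0:
            continue
        if cv.consequence_class in ("functional", "synonymous"):
            if cv.consequence_class == "functional":
                counts.fun_ctrl += cv.allele_count
            else:
                counts.syn_ctrl += cv.allele_count
            ctrl_w.append((weight(cv.key), cv.allele_count, cv.consequence_class))

    def normalized_totals(entries):
        total_ac = sum(ac for _, ac, _ in entries)
        if total_ac == 0:
            return 0.0, 0.0
        mean_w = sum(w * ac for w, ac, _ in entries) / total_ac
        fun = sum(w * ac for w, ac, c in entries if c == "functional") / mean_w
        syn = sum(w * ac for w, ac, c in entries if c == "synonymous") / mean_w
        return fun, syn

    counts.fun_case_w, counts.syn_case_w = normalized_totals(case_w)
    counts.fun_ctrl_w, counts.syn_ctrl_w = normalized_totals(ctrl_w)
    return counts


def naive_functional_test(c: GeneBurdenCounts) -> tuple[float, float]:
    """Functional-only two-sample Poisson rate LRT (no synonymous proxy).

    Compares per-genome functional rates between cohorts given exposures
    2*n_case and 2*n_ctrl; the comparator whose type-I error the proxy test
    is designed to repair when control processing inflates every count.
    """
    x1, x2 = c.fun_case, c.fun_ctrl
    e1, e2 = 2.0 * c.n_case, 2.0 * c.n_ctrl
    if e1 <= 0 or e2 <= 0:
        raise ValueError("cohort sizes required for the naive test")
    if x1 + x2 == 0:
        return 0.0, 1.0
    l1 = _poisson_ll((x1, x2), (x1, x2))
    pooled = (x1 + x2) / (e1 + e2)
    l0 = _poisson_ll((x1, x2), (pooled * e1, pooled * e2))
    lam = max(0.0, 2.0 * (l1 - l0))
    return lam, float(stats.chi2.sf(lam, 1))


@dataclass
class ScanResult:
    results: list[EnrichmentResult]
    lambda_gc: float
    n_tested: int
    config: FilterConfig = field(default_factory=FilterConfig)

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            c = r.counts
            rows.append(
                {
                    "gene": r.gene,
                    "fun_case": c.fun_case if c else 0,
                    "syn_case": c.syn_case if c else 0,
                    "fun_ctrl": c.fun_ctrl if c else 0,
                    "syn_ctrl": c.syn_ctrl if c else 0,
                    "lrt_statistic": r.lrt_statistic,
                    "p_raw": r.p_raw,
                    "p_gc": r.p_gc,
                    "q": r.q,
                    "significant": r.significant,
                    "reason": r.reason,
                }
            )
        return pd.DataFrame(rows)


def run_enrichment_scan(
    case_variants: list[VariantRecord],
    case_genotypes: CohortGenotypes | None,
    control: ControlSummary,
    cfg: FilterConfig | None = None,
    *,
    q_threshold: float = 0.2,
    weight_scheme: str = "madsen-browning",
    gene_universe: str = "case",
    case_allele_counts: dict[tuple, int] | None = None,
    n_case: int | None = None,
) -> ScanResult:
    """Full per-gene scan: rarity filter -> class/deleteriousness
    aggregation -> weighted proxy LRT -> genomic control -> BH FDR.

    Genes enter the test when they carry at least one qualifying rare
    deleterious variant in cases (``gene_universe="case"``, mirroring a
    case-ascertained scan) or in either cohort (``"both"``).  ``m`` for the
    BH correction is the number of genes actually tested.
    """
    cfg = cfg or FilterConfig()
    if case_allele_counts is None:
        if case_genotypes is None:
            raise ValueError("either genotypes or explicit case allele counts required")
        key_index = {k: j for j, k in enumerate(case_genotypes.variant_keys)}
        case_allele_counts = {
            k: case_genotypes.allele_count(j) for k, j in key_index.items()
        }
    if n_case is None:
        n_case = case_genotypes.n_samples if case_genotypes is not None else 0

    rare_case = [v for v in case_variants if is_rare(v, cfg)]
    case_del_genes = {
        v.gene
        for v in rare_case
        if classify_functional_class(v.consequence, cfg) == "functional"
        and is_deleterious(v, cfg)
        and case_allele_counts.get(v.key, 0) > 0
    }
    if gene_universe == "case":
        genes = sorted(case_del_genes)
    elif gene_universe == "both":
        ctrl_genes = {
            v.gene for v in control.variants if v.consequence_class == "functional"
        }
        genes = sorted(case_del_genes | ctrl_genes)
    else:
        raise ValueError(f"unknown gene_universe {gene_universe!r}")

    # pre-group by gene so the scan is linear in the input size
    case_by_gene: dict[str, list[VariantRecord]] = {}
    for v in rare_case:
        case_by_gene.setdefault(v.gene, []).append(v)
    ctrl_by_gene: dict[str, list] = {}
    for cv in control.variants:
        ctrl_by_gene.setdefault(cv.gene, []).append(cv)

    results: list[EnrichmentResult] = []
    tested: list[EnrichmentResult] = []
    for gene in genes:
        gene_control = ControlSummary(
            variants=ctrl_by_gene.get(gene, []),
            n_controls=control.n_controls,
            population=control.population,
        )
        counts = aggregate_gene_counts(
            case_by_gene.get(gene, []),
            case_allele_counts,
            gene_control,
            gene,
            cfg,
            n_case=n_case,
            weight_scheme=weight_scheme,
        )
        lam, p, reason = proxecat_weighted(counts)
        res = EnrichmentResult(
            gene=gene, counts=counts, lrt_statistic=lam, p_raw=p, reason=reason
        )
        results.append(res)
        if reason is None:
            tested.append(res)

    if not tested:
        import warnings

        warnings.warn("no testable gene in the scan", stacklevel=2)
        return ScanResult(results=results, lambda_gc=1.0, n_tested=0, config=cfg)

    lam_gc, p_gc = genomic_control([r.lrt_statistic for r in tested])
    for r, pg in zip(tested, p_gc):
        r.p_gc = float(max(pg, np.nextafter(0, 1)))
    qs = bh_qvalues([r.p_gc for r in tested], m=len(tested))
    for r, q in zip(tested, qs):
        r.q = float(q)
        r.significant = r.q <= q_threshold
    results.sort(key=lambda r: (r.q is None, r.q, r.p_gc if r.p_gc is not None else 2.0))
    return ScanResult(results=results, lambda_gc=lam_gc, n_tested=len(tested), config=cfg)
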