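"""Cohort-level report: the printed tallies recomputed from fixtures.

Everything here is derived at call time from the shipped tables — carrier
rates in the clinically screened cohort, novelty of the candidate variants,
panel and tumor-series overlaps, and the carriers-versus-tumor-history
association — so the report doubles as a reproducibility check.
"""

from __future__ import annotations

from . import datasets
from .clinical import carrier_summary, exclusivity_and_history_test
from .screening import (
    MELANOMA_SERIES,
    RCC_SERIES,
    is_novel_or_very_rare,
    screen_panel,
    tally_tcga_occurrences,
)


def cohort_report() -> dict:
    """Recompute the headline cohort numbers from the shipped fixtures."""
    carriers = datasets.load_known_carriers()
    assignments = datasets.known_carrier_assignments()
    summary = carrier_summary(carriers, assignments, n_cohort=datasets.COHORT_SIZE)

    candidates, _ = datasets.load_candidate_variants()
    n_novel = sum(is_novel_or_very_rare(v) for v in candidates)

    frex = screen_panel(candidates, datasets.frex_panel())
    tcga = tally_tcga_occurrences(candidates, datasets.tcga_panel())

    wes_records, wes_assignments = datasets.synthetic_wes_cohort()
    table, p_history = exclusivity_and_history_test(
        wes_assignments, wes_records, {"CLTCL1", "SETD2"}
    )
    wes_summary = carrier_summary(
        wes_records, wes_assignments, n_cohort=datasets.WES_COHORT_SIZE
    )

    return {
        "clinical_cohort": {
            "n_cohort": summary.n_cohort,
            "n_carriers": summary.n_carriers,
            "carrier_rate_pct": round(100 * summary.carrier_rate, 1),
            "per_gene": summary.per_gene,
            "mitf_e318k_carriers": summary.per_gene.get("MITF", 0),
            "mitf_e318k_rate_pct": round(
                100 * summary.per_gene.get("MITF", 0) / summary.n_cohort, 1
            ),
            "n_carriers_with_mc1r": summary.n_carriers_with_mc1r,
            "mc1r_cocarriage_pct": round(
                100 * summary.n_carriers_with_mc1r / summary.n_carriers, 1
            )
            if summary.n_carriers
            else 0.0,
        },
        "candidate_variants": {
            "n_candidates": len(candidates),
            "n_novel_or_very_rare": n_novel,
            "novel_or_very_rare_pct": round(100 * n_novel / len(candidates), 1),
        },
        "frex_screen": {
            "n_variants_matched": frex.n_variants_matched,
            "n_distinct_genes": frex.n_distinct_genes,
        },
        "tcga_screen": {
            "n_variants_matched": tcga.n_variants_matched,
            "total_occurrences": tcga.total_occurrences,
            "melanoma_occurrences": tcga.occurrences_in(MELANOMA_SERIES),
            "rcc_occurrences": tcga.occurrences_in(RCC_SERIES),
            "by_series": tcga.occurrences_by_series(),
        },
        "wes_cohort_synthetic": {
            "n_cohort": wes_summary.n_cohort,
            "n_candidate_carriers": wes_summary.n_carriers,
            "cltcl1_setd2_history_table": list(table.cells),
            "cltcl1_setd2_history_p": round(p_history, 4),
        },
    }


def format_report(report: dict) -> str:
    cc = report["clinical_cohort"]
    cv = report["candidate_variants"]
    fx = report["frex_screen"]
    tc = report["tcga_screen"]
    ws = report["wes_cohort_synthetic"]
    lines = [
        "Clinically screened cohort",
        f"  carriers of a pathogenic variant: {cc['n_carriers']}/{cc['n_cohort']}"
        f" ({cc['carrier_rate_pct']}%)",
        f"  MITF p.E318K carriers: {cc['mitf_e318k_carriers']}/{cc['n_cohort']}"
        f" ({cc['mitf_e318k_rate_pct']}%)",
        f"  carriers with >=1 MC1R variant: {cc['n_carriers_with_mc1r']}/{cc['n_carriers']}"
        f" ({cc['mc1r_cocarriage_pct']}%)",
        "Candidate variants",
        f"  novel or very rare (<0.01%): {cv['n_novel_or_very_rare']}/{cv['n_candidates']}"
        f" ({cv['novel_or_very_rare_pct']}%)",
        f"  FrEx panel overlap: {fx['n_variants_matched']} variants in"
        f" {fx['n_distinct_genes']} genes",
        f"  TCGA overlap: {tc['n_variants_matched']} variants,"
        f" {tc['total_occurrences']} occurrences"
        f" ({tc['melanoma_occurrences']} melanoma, {tc['rcc_occurrences']} RCC)",
        "WES cohort (synthetic stand-in)",
        f"  CLTCL1/SETD2 carriers vs other-tumor history: table"
        f" {ws['cltcl1_setd2_history_table']}, Fisher p = {ws['cltcl1_setd2_history_p']}",
    ]
    return "\n".join(lines)
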