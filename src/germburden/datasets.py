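"""Shipped fixture tables for the melanoma + RCC double-primary cohort.

The package bundles small plain-text encodings of the study's printed
summary tables: cohort characteristics, the 17 carriers of pathogenic
variants in known predisposing genes, the 13 candidate genes from the
enrichment scan with their case/control rare deleterious allele counts, and
the 41 candidate variants with population, FrEx and TCGA annotations.
Per-case data for the 46 exome-sequenced cases were never published, so
:func:`synthetic_wes_cohort` builds a synthetic stand-in cohort whose
marginal tallies match the published ones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .variants import (
    ClinicalRecord,
    ControlSummary,
    ControlVariant,
    PanelVariantTable,
    VariantRecord,
    read_clinical_table,
    read_panel_table,
)

#: full clinically screened cohort size
COHORT_SIZE = 125
#: exome-sequenced early-onset subset
WES_COHORT_SIZE = 46
#: external control cohort used by the enrichment scan
CONTROL_COHORT_SIZE = 19_751


def data_path(name: str):
    return resources.files("germburden.data") / name


def load_cohort_characteristics() -> dict[str, float]:
    df = pd.read_csv(data_path("table1_cohort.tsv"), sep="\t")
    return dict(zip(df["key"], df["value"]))


def load_known_carriers() -> list[ClinicalRecord]:
    """The 17 carriers of pathogenic variants in known melanoma/RCC
    predisposing genes, with their MC1R status."""
    return read_clinical_table(data_path("table2_known_carriers.csv"))


def known_carrier_assignments() -> dict[str, list[str]]:
    return {
        r.case_id: [r.predisposing_gene]
        for r in load_known_carriers()
        if r.predisposing_gene
    }


def load_candidate_genes() -> pd.DataFrame:
    """The 13 candidate genes with LOEUF, rare deleterious allele counts in
    cases (N=46) and external controls (N=19,751), and the published
    (non-recomputable) p/q-values."""
    return pd.read_csv(data_path("table3_candidate_genes.tsv"), sep="\t")


def load_candidate_variants() -> tuple[list[VariantRecord], pd.DataFrame]:
    """The 41 candidate rare deleterious variants.

    Returns the variants as records (pop_afs carry the non-cancer NW-European
    control AF under ``nc_nwe`` — excluded from popmax, which is a control
    subset rather than an outbred reference population — and the published
    popmax under ``popmax``) plus the raw dataframe with case AFs and
    external-series annotations.
    """
    df = pd.read_csv(
        data_path("table4_candidate_variants.tsv"),
        sep="\t",
        dtype={"chrom": str},
        na_values=["."],
        keep_default_na=True,
    )
    records = []
    for _, row in df.iterrows():
        pop_afs = {}
        if pd.notna(row["af_nc_nwe"]):
            pop_afs["nc_nwe"] = float(row["af_nc_nwe"])
        if pd.notna(row["af_popmax"]):
            pop_afs["popmax"] = float(row["af_popmax"])
        records.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                consequence=row["consequence"],
                cadd_phred=float(row["cadd"]),
                pop_afs=pop_afs,
            )
        )
    return records, df


def candidate_case_allele_counts() -> dict[tuple, int]:
    """Case alt-allele counts for the 41 candidates, derived from the
    published case AFs as AC = round(AF * 2 * 46)."""
    records, df = load_candidate_variants()
    return {
        rec.key: int(round(float(row["af_cases"]) * 2 * WES_COHORT_SIZE))
        for rec, (_, row) in zip(records, df.iterrows())
    }


def candidate_control_summary() -> ControlSummary:
    """Per-gene functional rare deleterious allele counts in the external
    controls, from the candidate-gene table (synonymous proxy counts were
    not published)."""
    df = load_candidate_genes()
    an = 2 * CONTROL_COHORT_SIZE
    variants = [
        ControlVariant(
            key=(str(row["gene"]), 1, "N", "A"),  # gene-level pseudo-key
            gene=str(row["gene"]),
            consequence_class="functional",
            allele_count=int(row["ac_controls"]),
            allele_number=an,
        )
        for _, row in df.iterrows()
    ]
    return ControlSummary(variants=variants, n_controls=CONTROL_COHORT_SIZE)


def frex_panel() -> PanelVariantTable:
    return read_panel_table(data_path("frex_panel.tsv"), label="FrEx")


def tcga_panel() -> PanelVariantTable:
    return read_panel_table(data_path("tcga_panel.tsv"), label="TCGA")


def synthetic_wes_cohort() -> tuple[list[ClinicalRecord], dict[str, list[str]]]:
    """Synthetic 46-case WES cohort (per-case data were never published).

    Deterministic records and per-case gene assignments whose marginals
    match the published tallies: 33 of 46 cases carry at least one of the
    41 candidate alleles (43 alleles in total), 8 cases carry a CLTCL1 or
    SETD2 variant of whom 6 have at least one other solid tumor, and 11 of
    the 38 non-carriers of those two genes have another solid tumor.
    """
    allele_budget = {
        "PIK3CD": 2, "MTOR": 4, "RAE1": 2, "ZBTB21": 3, "ESAM": 2,
        "TMEM192": 2, "NFRKB": 3, "EP300": 3, "MTSS2": 4, "SMC2": 4, "EBF4": 3,
    }
    assignments: dict[str, list[str]] = {}
    # 8 carriers of CLTCL1 (6 alleles) or SETD2 (5 alleles)
    assignments["W01"] = ["CLTCL1", "CLTCL1"]
    assignments["W02"] = ["CLTCL1", "CLTCL1"]
    assignments["W03"] = ["CLTCL1", "CLTCL1"]
    for i, cid in enumerate(("W04", "W05", "W06", "W07", "W08")):
        assignments[cid] = ["SETD2"]
    # remaining 32 alleles over 25 further carriers (7 carry two alleles)
    flat = [g for g, n in allele_budget.items() for _ in range(n)]
    carriers = [f"W{i:02d}" for i in range(9, 34)]  # W09..W33
    ci = 0
    for g in flat:
        cid = carriers[ci % len(carriers)]
        assignments.setdefault(cid, []).append(g)
        ci += 1
    # other-solid-tumor flags reproducing the published 2x2 margins
    tumor_ids = {"W01", "W02", "W03", "W04", "W05", "W06"}  # 6 of the 8
    tumor_ids |= {f"W{i:02d}" for i in range(9, 20)}  # 11 of the other 38
    ages_mm = [38 + (i * 7) % 25 for i in range(46)]
    ages_rcc = [40 + (i * 5) % 25 for i in range(46)]
    records = [
        ClinicalRecord(
            case_id=f"W{i:02d}",
            sex="M" if i % 3 else "F",
            age_first_melanoma=float(ages_mm[i - 1]),
            age_first_rcc=float(ages_rcc[i - 1]),
            other_solid_tumors=f"W{i:02d}" in tumor_ids,
        )
        for i in range(1, 47)
    ]
    return records, assignments
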