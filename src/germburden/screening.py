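"""Candidate-variant screening against external panels.

Candidates surviving the enrichment scan are looked up, by exact normalized
variant key, in reference panels: a population panel reporting allele
frequencies (FrEx-style) and a tumor-series panel reporting per-series
germline occurrence counts (TCGA-style, series SKCM / KIRC / KIRP plus
non-TCGA familial-cancer entries which are excluded from series tallies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clinical import ContingencyTable2x2, fisher_exact_one_sided
from .variants import PanelVariantTable, VariantRecord

TCGA_SERIES = frozenset({"SKCM", "KIRC", "KIRP", "LUAD", "LUSC"})
MELANOMA_SERIES = frozenset({"SKCM"})
RCC_SERIES = frozenset({"KIRC", "KIRP"})

#: reporting threshold: a candidate is "novel or very rare" when it has no
#: recorded popmax AF or a popmax AF strictly below 1e-4
VERY_RARE_AF = 1e-4


@dataclass
class PanelMatch:
    key: tuple[str, int, str, str]
    gene: str
    panel: str
    af: float | None = None
    occurrences: int | None = None
    series: str | None = None


@dataclass
class ScreeningReport:
    panel: str
    matches: list[PanelMatch] = field(default_factory=list)

    @property
    def n_variants_matched(self) -> int:
        return len({m.key for m in self.matches})

    @property
    def n_distinct_genes(self) -> int:
        return len({m.gene for m in self.matches})

    @property
    def total_occurrences(self) -> int:
        return sum(m.occurrences or 0 for m in self.matches)

    def occurrences_by_series(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.matches:
            if m.series is not None:
                out[m.series] = out.get(m.series, 0) + (m.occurrences or 0)
        return dict(sorted(out.items()))

    def occurrences_in(self, series: frozenset[str] | set[str]) -> int:
        return sum(
            m.occurrences or 0 for m in self.matches if m.series in series
        )


def screen_panel(
    candidates: list[VariantRecord], panel: PanelVariantTable
) -> ScreeningReport:
    """Exact-key lookup of candidate variants in a panel."""
    report = ScreeningReport(panel=panel.label)
    for v in candidates:
        for entry in panel.entries.get(v.key, []):
            report.matches.append(
                PanelMatch(
                    key=v.key,
                    gene=v.gene,
                    panel=panel.label,
                    af=entry.af,
                    occurrences=entry.occurrences,
                    series=entry.series,
                )
            )
    return report


def tally_tcga_occurrences(
    candidates: list[VariantRecord], panel: PanelVariantTable
) -> ScreeningReport:
    """Screen candidates against a tumor-series panel, keeping TCGA series
    entries only (familial-cancer entries such as fNTMC are excluded from
    the tally).  Raises on series labels outside the known vocabulary."""
    raw = screen_panel(candidates, panel)
    report = ScreeningReport(panel=panel.label)
    for m in raw.matches:
        if m.series is None:
            raise ValueError(f"series label required in TCGA-style panel for {m.key}")
        if m.series in TCGA_SERIES:
            report.matches.append(m)
        elif not m.series.startswith("f"):  # familial series are excluded, not errors
            raise ValueError(f"unknown series label {m.series!r}")
    return report


def is_novel_or_very_rare(v: VariantRecord, af_max: float = VERY_RARE_AF) -> bool:
    """True when no popmax AF is recorded or it is strictly below
    ``af_max`` (boundary values excluded)."""
    af = v.af_popmax
    return af is None or af < af_max


def series_enrichment_test(
    carriers_a: int, size_a: int, carriers_b: int, size_b: int
) -> float:
    """One-sided Fisher test for excess carriers in series group A versus
    group B (e.g., melanoma+RCC TCGA series versus lung series)."""
    if carriers_a > size_a or carriers_b > size_b:
        raise ValueError("carrier counts cannot exceed series sizes")
    table = ContingencyTable2x2(
        carriers_a, size_a - carriers_a, carriers_b, size_b - carriers_b
    )
    return fisher_exact_one_sided(table)
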