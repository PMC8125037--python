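"""Per-variant QC and the composite rarity/deleteriousness classification.

The tested variant set is defined by four successive rules applied to the
joint call set:

* positions with more than 10% missing genotypes are discarded;
* heterozygous calls with an alternative allelic fraction below 25% are set
  to missing (a low alt fraction at a het site indicates a miscalled or
  mosaic genotype);
* variants deviating from Hardy-Weinberg proportions (exact conditional
  test) are discarded;
* a variant is *rare* when its highest allele frequency across outbred
  reference populations is at most 0.25% — the frequency of the MITF p.E318K
  hotspot — or when it is absent from all of them; it is *deleterious* when
  its CADD phred score is >= 20, or it carries two or more non-conflicting
  Pathogenic/Likely-pathogenic ClinVar assertions, or it is a frameshift
  indel with mapping quality >= 50.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

from .variants import MISSING, CohortGenotypes, VariantRecord

logger = logging.getLogger(__name__)

PATHOGENIC_ASSERTIONS = frozenset({"Pathogenic", "Likely pathogenic"})

FUNCTIONAL_CONSEQUENCES = frozenset(
    {"missense", "stopgain", "frameshift", "inframe", "splice"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the QC and variant-classification rules."""

    missingness_max: float = 0.10
    het_aaf_min: float = 0.25
    hwe_alpha: float = 1e-6
    rarity_af_max: float = 0.0025
    cadd_min: float = 20.0
    frameshift_mq_min: float = 50.0
    clinvar_min_assertions: int = 2
    splice_is_functional: bool = True

    def __post_init__(self):
        for name in ("missingness_max", "het_aaf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 < self.rarity_af_max < 1.0):
            raise ValueError(f"rarity_af_max must be in (0,1), got {self.rarity_af_max}")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError(f"hwe_alpha must be in (0,1), got {self.hwe_alpha}")
        if self.cadd_min < 0 or self.frameshift_mq_min < 0:
            raise ValueError("score thresholds must be >= 0")
        if self.clinvar_min_assertions < 1:
            raise ValueError("clinvar_min_assertions must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_missingness(geno: CohortGenotypes, cfg: FilterConfig) -> list[tuple]:
    """Return the variant keys whose missing-genotype fraction is not
    strictly above ``missingness_max`` (drop iff fraction > threshold)."""
    if geno.n_samples == 0 or geno.n_variants == 0:
        raise ValueError("empty genotype matrix")
    return [
        key
        for j, key in enumerate(geno.variant_keys)
        if geno.missing_fraction(j) <= cfg.missingness_max
    ]


def filter_het_aaf(geno: CohortGenotypes, cfg: FilterConfig) -> CohortGenotypes:
    """Set heterozygous calls with alt/(ref+alt) strictly below
    ``het_aaf_min`` to missing.  Homozygous calls are untouched; a het call
    with zero total depth is set missing and logged.  Calls without allelic
    depths are left as-is."""
    if geno.allelic_depths is None:
        return geno
    new_rows = []
    for i, row in enumerate(geno.dosages):
        new_row = list(row)
        for j, d in enumerate(row):
            if d != 1:
                continue
            ad = geno.allelic_depths[i][j]
            if ad is None:
                continue
            total = ad[0] + ad[1]
            if total == 0:
                logger.warning(
                    "het call with zero depth at %s sample %s set missing",
                    geno.variant_keys[j],
                    geno.sample_ids[i],
                )
                new_row[j] = MISSING
            elif ad[1] / total < cfg.het_aaf_min:
                new_row[j] = MISSING
        new_rows.append(new_row)
    return CohortGenotypes(
        sample_ids=geno.sample_ids,
        variant_keys=geno.variant_keys,
        dosages=new_rows,
        allelic_depths=geno.allelic_depths,
    )


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditioning on the observed allele counts, sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed configuration.  Returns a p-value in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    lg = math.lgamma

    def log_prob(h: int) -> float:
        # P(het = h | n, allele counts) up to the common normalizer:
        # multinomial count of genotype configurations x 2^h
        a = (n_alt - h) // 2  # hom-alt
        r = n - h - a  # hom-ref
        return lg(n + 1) - lg(r + 1) - lg(h + 1) - lg(a + 1) + h * math.log(2)

    support = [h for h in range(n_alt % 2, n_minor + 1, 2) if (n - h - (n_alt - h) // 2) >= 0]
    logs = {h: log_prob(h) for h in support}
    lmax = max(logs.values())
    total = sum(math.exp(v - lmax) for v in logs.values())
    p_obs = math.exp(logs[n_het] - lmax)
    p = sum(math.exp(v - lmax) for v in logs.values() if math.exp(v - lmax) <= p_obs * (1 + 1e-12))
    return min(1.0, p / total)


def filter_hwe(geno: CohortGenotypes, cfg: FilterConfig) -> list[tuple]:
    """Return the variant keys whose HWE exact p-value is >= ``hwe_alpha``."""
    kept = []
    for j, key in enumerate(geno.variant_keys):
        counts = geno.genotype_counts(j)
        if sum(counts) == 0:
            continue
        if hwe_exact_test(*counts) >= cfg.hwe_alpha:
            kept.append(key)
    return kept


def is_rare(v: VariantRecord, cfg: FilterConfig) -> bool:
    """True iff the popmax AF is at most ``rarity_af_max`` (boundary
    inclusive) or no AF is recorded (a novel variant is rare)."""
    af = v.af_popmax
    return af is None or af <= cfg.rarity_af_max


def is_deleterious(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Composite deleteriousness rule: high CADD, OR congruent ClinVar
    pathogenicity, OR a high-mapping-quality frameshift."""
    if v.cadd_phred is not None and v.cadd_phred >= cfg.cadd_min:
        return True
    assertions = v.clinvar_assertions
    if (
        len(assertions) >= cfg.clinvar_min_assertions
        and all(a in PATHOGENIC_ASSERTIONS for a in assertions)
    ):
        return True
    if (
        v.consequence == "frameshift"
        and v.mapping_quality is not None
        and v.mapping_quality >= cfg.frameshift_mq_min
    ):
        return True
    return False


def classify_functional_class(consequence: str, cfg: FilterConfig | None = None) -> str:
    """Map a normalized consequence to the enrichment-test stratum:
    ``synonymous`` (the processing proxy), ``functional`` (the tested
    numerator) or ``other`` (excluded from both)."""
    if consequence == "synonymous":
        return "synonymous"
    functional = set(FUNCTIONAL_CONSEQUENCES)
    if cfg is not None and not cfg.splice_is_functional:
        functional.discard("splice")
    if consequence in functional:
        return "functional"
    return "other"
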