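"""Domain types and readers/writers for germline variant data.

The pipeline operates on four kinds of input: an annotated per-variant table
for the case cohort (or a VCF with per-sample genotypes), an external-control
summary of rare allele counts (gnomAD-style), screening panels keyed by
variant, and a per-case clinical table.  Everything downstream identifies a
variant by its normalized key ``(chrom, pos, ref, alt)`` — chromosome labels
without the ``chr`` prefix, alleles upper-cased, and shared suffix/prefix
bases trimmed so that differently written representations of the same indel
compare equal.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: Functional-consequence controlled vocabulary.
CONSEQUENCES = frozenset(
    {
        "missense",
        "synonymous",
        "stopgain",
        "frameshift",
        "inframe",
        "splice",
        "intronic",
        "other",
    }
)

#: Normalization of common annotator terms to the controlled vocabulary.
#: Unknown terms map to "other" with a logged warning.
CONSEQUENCE_MAP = {
    "missense": "missense",
    "missense_variant": "missense",
    "nonsynonymous snv": "missense",
    "nonsynonymous_snv": "missense",
    "synonymous": "synonymous",
    "synonymous snv": "synonymous",
    "synonymous_snv": "synonymous",
    "synonymous_variant": "synonymous",
    "stopgain": "stopgain",
    "stop_gained": "stopgain",
    "nonsense": "stopgain",
    "frameshift": "frameshift",
    "frameshift deletion": "frameshift",
    "frameshift insertion": "frameshift",
    "frameshift_variant": "frameshift",
    "inframe": "inframe",
    "nonframeshift deletion": "inframe",
    "nonframeshift insertion": "inframe",
    "inframe_deletion": "inframe",
    "inframe_insertion": "inframe",
    "splice": "splice",
    "splicing": "splice",
    "splice_region_variant": "splice",
    "splice_acceptor_variant": "splice",
    "splice_donor_variant": "splice",
    "intronic": "intronic",
    "intron_variant": "intronic",
    "other": "other",
}

#: Default "outbred population" labels over which af_popmax is taken
#: (gnomAD v2.1.1 outbred exome populations).
OUTBRED_POPULATIONS = ("afr", "amr", "eas", "nfe", "sas", "popmax")

MANDATORY_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "cadd_phred",
    "clinvar",
    "mq",
)


def normalize_consequence(term: str) -> str:
    key = term.strip().lower()
    if key in CONSEQUENCE_MAP:
        return CONSEQUENCE_MAP[key]
    logger.warning("unknown consequence term %r mapped to 'other'", term)
    return "other"


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Normalize a variant key: no-"chr" chromosome, upper-case alleles,
    common suffix then common prefix trimmed (position advanced past the
    trimmed prefix).  At least one base of each allele is retained."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    ref, alt = ref.strip().upper(), alt.strip().upper()
    if not ref or not alt:
        raise ValueError("ref and alt alleles must be non-empty")
    # trim shared trailing bases
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared leading bases, advancing pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, int(pos), ref, alt


@dataclass(frozen=True)
class VariantRecord:
    """One annotated germline variant.

    ``pop_afs`` maps population label -> allele frequency; an absent key
    means the variant was not observed in that population.  ``af_popmax``
    is derived as the maximum AF over the configured outbred populations,
    or ``None`` when none is recorded (a novel variant).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cadd_phred: float | None = None
    clinvar_assertions: tuple[str, ...] = ()
    mapping_quality: float | None = None
    pop_afs: dict[str, float] = field(default_factory=dict)
    outbred_populations: tuple[str, ...] = OUTBRED_POPULATIONS

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for pop, af in self.pop_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency out of [0,1] for {pop}: {af}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def af_popmax(self) -> float | None:
        afs = [
            af
            for pop, af in self.pop_afs.items()
            if pop in self.outbred_populations
        ]
        return max(afs) if afs else None


MISSING = -1  # dosage sentinel in the genotype matrix


@dataclass
class CohortGenotypes:
    """Sample x variant alt-allele dosage matrix with optional allelic depths.

    ``dosages[i][j]`` is the dosage (0/1/2) of variant ``j`` in sample ``i``
    or ``MISSING``.  ``allelic_depths[i][j]`` is ``(ref_reads, alt_reads)``
    or ``None`` when depths are unavailable.
    """

    sample_ids: list[str]
    variant_keys: list[tuple[str, int, str, str]]
    dosages: list[list[int]]
    allelic_depths: list[list[tuple[int, int] | None]] | None = None

    def __post_init__(self):
        n, m = len(self.sample_ids), len(self.variant_keys)
        if len(self.dosages) != n or any(len(row) != m for row in self.dosages):
            raise ValueError("dosage matrix dimensions inconsistent with ids")
        for row in self.dosages:
            for d in row:
                if d not in (0, 1, 2, MISSING):
                    raise ValueError(f"invalid dosage {d}")
        if self.allelic_depths is not None:
            if len(self.allelic_depths) != n or any(
                len(row) != m for row in self.allelic_depths
            ):
                raise ValueError("allelic-depth matrix dimensions inconsistent")
            for row in self.allelic_depths:
                for ad in row:
                    if ad is not None and (ad[0] < 0 or ad[1] < 0):
                        raise ValueError("read depths must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def missing_fraction(self, j: int) -> float:
        col = [row[j] for row in self.dosages]
        return sum(d == MISSING for d in col) / len(col)

    def allele_count(self, j: int) -> int:
        """Alt-allele count for variant j over non-missing calls."""
        return sum(row[j] for row in self.dosages if row[j] != MISSING)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) for variant j, ignoring missing."""
        col = [row[j] for row in self.dosages if row[j] != MISSING]
        return col.count(0), col.count(1), col.count(2)


@dataclass(frozen=True)
class ControlVariant:
    """One rare-variant entry of the external control summary."""

    key: tuple[str, int, str, str]
    gene: str
    consequence_class: str  # "functional" | "synonymous"
    allele_count: int
    allele_number: int

    def __post_init__(self):
        if not (0 <= self.allele_count <= self.allele_number):
            raise ValueError(
                f"allele count {self.allele_count} outside [0, AN={self.allele_number}]"
            )


@dataclass
class ControlSummary:
    """Per-variant (or per gene x class) rare allele counts in the external
    control cohort, plus the control cohort size."""

    variants: list[ControlVariant]
    n_controls: int
    population: str = "nfe"

    def gene_class_counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for v in self.variants:
            k = (v.gene, v.consequence_class)
            out[k] = out.get(k, 0) + v.allele_count
        return out


@dataclass(frozen=True)
class PanelEntry:
    af: float | None = None
    occurrences: int | None = None
    series: str | None = None

    def __post_init__(self):
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(f"panel AF out of [0,1]: {self.af}")
        if self.occurrences is not None and self.occurrences < 0:
            raise ValueError("panel occurrence count must be >= 0")


@dataclass
class PanelVariantTable:
    """Screening panel: normalized variant key -> one or more entries
    (multiple entries arise when a panel stratifies by series)."""

    label: str
    entries: dict[tuple[str, int, str, str], list[PanelEntry]]


@dataclass(frozen=True)
class MC1RVariant:
    name: str
    risk_class: str  # "R" (moderate risk), "r" (low risk), "other"

    def __post_init__(self):
        if self.risk_class not in ("R", "r", "other"):
            raise ValueError(f"MC1R class must be R/r/other, got {self.risk_class!r}")


@dataclass(frozen=True)
class ClinicalRecord:
    case_id: str
    sex: str | None = None
    age_first_melanoma: float | None = None
    age_first_rcc: float | None = None
    melanoma_histology: str | None = None
    rcc_histology: str | None = None
    other_solid_tumors: bool = False
    family_history: bool = False
    mc1r_variants: tuple[MC1RVariant, ...] = ()
    predisposing_gene: str | None = None

    def __post_init__(self):
        for age in (self.age_first_melanoma, self.age_first_rcc):
            if age is not None and age <= 0:
                raise ValueError(f"ages must be > 0, got {age}")


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_float(cell: str, what: str, line: int) -> float | None:
    cell = cell.strip()
    if cell in ("", ".", "NA", "nan"):
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"line {line}: unparseable {what} {cell!r}") from None


def read_variant_table(path) -> list[VariantRecord]:
    """Read the canonical tab-separated variant table.

    Columns: chrom, pos, ref, alt, gene, consequence, cadd_phred, clinvar
    (comma-joined assertions or "."), mq, then any number of ``af_<pop>``
    columns.  Missing values are "." or empty.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty variant table") from None
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise ValueError(f"{path}: missing mandatory column {col!r}")
        idx = {c: i for i, c in enumerate(header)}
        af_cols = [(c, c[3:]) for c in header if c.startswith("af_")]
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                pos = int(row[idx["pos"]])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: unparseable position {row[idx['pos']]!r}"
                ) from None
            pop_afs = {}
            for col, pop in af_cols:
                af = _parse_float(row[idx[col]], f"AF ({col})", lineno)
                if af is not None:
                    if not (0.0 <= af <= 1.0):
                        raise ValueError(f"line {lineno}: AF out of [0,1] in {col}: {af}")
                    pop_afs[pop] = af
            clinvar_cell = row[idx["clinvar"]].strip()
            assertions = (
                tuple(a.strip() for a in clinvar_cell.split(",") if a.strip())
                if clinvar_cell not in ("", ".")
                else ()
            )
            try:
                records.append(
                    VariantRecord(
                        chrom=row[idx["chrom"]].strip(),
                        pos=pos,
                        ref=row[idx["ref"]].strip(),
                        alt=row[idx["alt"]].strip(),
                        gene=row[idx["gene"]].strip(),
                        consequence=normalize_consequence(row[idx["consequence"]]),
                        cadd_phred=_parse_float(row[idx["cadd_phred"]], "CADD", lineno),
                        clinvar_assertions=assertions,
                        mapping_quality=_parse_float(row[idx["mq"]], "MQ", lineno),
                        pop_afs=pop_afs,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return records


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_variant_table(records: list[VariantRecord], path) -> None:
    """Write records in the canonical dialect read by :func:`read_variant_table`.

    The set of ``af_<pop>`` columns is the union of populations present.
    """
    pops = sorted({p for r in records for p in r.pop_afs})
    header = list(MANDATORY_COLUMNS) + [f"af_{p}" for p in pops]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in records:
            row = [
                r.chrom,
                r.pos,
                r.ref,
                r.alt,
                r.gene,
                r.consequence,
                _fmt(r.cadd_phred),
                ",".join(r.clinvar_assertions) if r.clinvar_assertions else ".",
                _fmt(r.mapping_quality),
            ]
            row += [_fmt(r.pop_afs.get(p)) for p in pops]
            writer.writerow(row)


def read_vcf_cohort(path) -> tuple[CohortGenotypes, list[VariantRecord]]:
    """Read a VCF 4.x call set into a dosage matrix plus minimal records.

    Multi-allelic sites are decomposed into one record per alt allele; the
    per-sample dosage of each record counts that allele only.  GT is
    mandatory; AD is honored when present.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no samples")
        if "GT" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF has no GT FORMAT field")
        keys: list[tuple[str, int, str, str]] = []
        records: list[VariantRecord] = []
        dosage_cols: list[list[int]] = []
        ad_cols: list[list[tuple[int, int] | None]] = []
        any_ad = False
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if alt is None or alt in ("*", "<NON_REF>"):
                    continue
                key = normalize_variant_key(rec.chrom, rec.pos, rec.ref, alt)
                dos_col: list[int] = []
                ad_col: list[tuple[int, int] | None] = []
                for s in samples:
                    call = rec.samples[s]
                    gt = call.get("GT")
                    if gt is None or any(a is None for a in gt):
                        dos_col.append(MISSING)
                    else:
                        dos_col.append(sum(1 for a in gt if a == ai))
                    ad = call.get("AD")
                    if ad is not None and len(ad) > ai and ad[0] is not None:
                        ad_col.append((int(ad[0]), int(ad[ai] or 0)))
                        any_ad = True
                    else:
                        ad_col.append(None)
                keys.append(key)
                records.append(
                    VariantRecord(
                        chrom=key[0],
                        pos=key[1],
                        ref=key[2],
                        alt=key[3],
                        gene=str(rec.info["GENE"]) if "GENE" in rec.info else "",
                        consequence="other",
                    )
                )
                dosage_cols.append(dos_col)
                ad_cols.append(ad_col)
    n = len(samples)
    dosages = [[dosage_cols[j][i] for j in range(len(keys))] for i in range(n)]
    depths = (
        [[ad_cols[j][i] for j in range(len(keys))] for i in range(n)] if any_ad else None
    )
    geno = CohortGenotypes(
        sample_ids=samples, variant_keys=keys, dosages=dosages, allelic_depths=depths
    )
    return geno, records


def read_control_summary(path, n_controls: int | None = None) -> ControlSummary:
    """Read an external-control summary TSV with columns chrom, pos, ref, alt,
    gene, class, ac, an (class in {functional, synonymous}).  ``n_controls``
    defaults to max(an)/2."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos", "ref", "alt", "gene", "class", "ac", "an"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing control-summary columns {sorted(missing)}")
    variants = []
    for _, row in df.iterrows():
        variants.append(
            ControlVariant(
                key=normalize_variant_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                gene=str(row["gene"]),
                consequence_class=str(row["class"]),
                allele_count=int(row["ac"]),
                allele_number=int(row["an"]),
            )
        )
    if n_controls is None:
        n_controls = int(df["an"].max()) // 2 if len(df) else 0
    return ControlSummary(variants=variants, n_controls=n_controls)


def read_panel_table(path, label: str = "panel") -> PanelVariantTable:
    """Read a screening panel TSV: chrom, pos, ref, alt plus optional
    ``af``, ``occurrences`` and ``series`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing panel column {col!r}")
    entries: dict[tuple[str, int, str, str], list[PanelEntry]] = {}
    for _, row in df.iterrows():
        key = normalize_variant_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        af = row.get("af")
        occ = row.get("occurrences")
        entry = PanelEntry(
            af=float(af) if pd.notna(af) else None,
            occurrences=int(occ) if pd.notna(occ) else None,
            series=str(row["series"]) if pd.notna(row.get("series")) else None,
        )
        entries.setdefault(key, []).append(entry)
    return PanelVariantTable(label=label, entries=entries)


def _parse_mc1r(cell: str) -> tuple[MC1RVariant, ...]:
    cell = (cell or "").strip()
    if cell in ("", ".", "WT"):
        return ()
    out = []
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        if "(" in part:
            name, cls = part.split("(", 1)
            out.append(MC1RVariant(name=name.strip(), risk_class=cls.strip(" )")))
        else:
            out.append(MC1RVariant(name=part, risk_class="other"))
    return tuple(out)


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read a per-case clinical CSV.

    Columns: case_id, sex, age_first_melanoma, age_first_rcc,
    melanoma_histology, rcc_histology, other_solid_tumors (0/1),
    family_history (0/1), mc1r_variants (";"-joined ``name (class)`` or WT),
    optional predisposing_gene.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if "case_id" not in df.columns:
        raise ValueError(f"{path}: missing column 'case_id'")
    records = []
    for _, row in df.iterrows():
        def _age(col):
            cell = row.get(col, "").strip()
            return float(cell) if cell not in ("", ".") else None

        records.append(
            ClinicalRecord(
                case_id=row["case_id"],
                sex=row.get("sex") or None,
                age_first_melanoma=_age("age_first_melanoma"),
                age_first_rcc=_age("age_first_rcc"),
                melanoma_histology=row.get("melanoma_histology") or None,
                rcc_histology=row.get("rcc_histology") or None,
                other_solid_tumors=row.get("other_solid_tumors", "").strip() in ("1", "true", "True"),
                family_history=row.get("family_history", "").strip() in ("1", "true", "True"),
                mc1r_variants=_parse_mc1r(row.get("mc1r_variants", "")),
                predisposing_gene=row.get("predisposing_gene") or None,
            )
        )
    return records
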