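# Methods

## Problem setting

`germburden` implements a gene-based discovery pipeline for rare germline
variants in a small, internally sequenced case cohort tested against large,
externally processed controls — the design used to search for co-susceptibility
genes in patients diagnosed with both malignant melanoma and renal cell
carcinoma. The central difficulty of that design is that the case exomes and
the external control call set (a gnomAD-style frequency release) are produced
by different capture kits, coverage profiles and filtering pipelines, so their
absolute rare-allele counts are not directly comparable. The pipeline's answer
is a *synonymous-proxy* test: rare synonymous alleles, which are not under the
case-ascertainment pressure, calibrate the processing differences internally.

## Variant filtering

A variant enters the analysis when it survives, in order:

1. **Missingness** — positions with strictly more than 10% missing genotypes
   are dropped.
2. **Het allelic fraction** — heterozygous calls with alt/(ref+alt) strictly
   below 25% are set to missing (likely miscalls); homozygous calls are
   untouched, and a het call with zero depth is set missing with a warning.
3. **Hardy–Weinberg** — the exact conditional test (probabilities of all
   heterozygote counts given the allele counts; p sums configurations no more
   probable than the observed one) at α = 1e-6, a standard call-set QC
   threshold, configurable. Applied to cases only by default.
4. **Rarity** — popmax allele frequency over the configured outbred reference
   populations at most 0.25% (boundary inclusive; the frequency of the MITF
   p.E318K hotspot), with an unobserved variant counting as rare.
5. **Deleteriousness** (functional stratum only) — CADD phred ≥ 20, OR at
   least two ClinVar assertions all of which are Pathogenic/Likely pathogenic
   (any other assertion voids the rule), OR a frameshift indel with mapping
   quality ≥ 50.

Consequences are normalized to a controlled vocabulary; missense, stop-gain,
frameshift, in-frame and splice variants count as *functional* (splice is
configurable), synonymous variants form the proxy stratum, everything else is
excluded from both numerators. The synonymous proxy deliberately carries **no**
deleteriousness filter: it must reflect data processing, not constraint.

Variant identity is `(chrom, pos, ref, alt)` after removing any `chr` prefix,
upper-casing alleles and trimming shared suffix then prefix bases. Full
left-alignment against the reference sequence is out of scope — annotated
inputs are expected to be normalized upstream — so only representation
trimming is applied.

## The enrichment test

Per gene, the four class totals are modeled as independent Poisson counts

    fun_case ~ Pois(μ_case·r_case)    syn_case ~ Pois(μ_case)
    fun_ctrl ~ Pois(μ_ctrl·r_ctrl)    syn_ctrl ~ Pois(μ_ctrl)

with H0: r_case = r_ctrl. A multiplicative processing artifact acting on both
classes of one cohort is absorbed into μ and cancels from the ratio — the
property that makes external controls usable. The constrained MLE is closed
form (r̂ = ΣF/ΣS, μ̂ = (F+S)/(1+r̂) per cohort); the LRT statistic
Λ = 2(ℓ₁−ℓ₀), with 0·log 0 ≡ 0, is referred to χ²₁. Genes without any
synonymous proxy allele get a missing result with a reason code rather than a
p-value. A numerical maximizer of the constrained likelihood serves as an
independent oracle in the tests and must agree with the closed form to 1e-8.

**Weights.** The weighted variant multiplies each contributing allele count by
w = 1/√(p̃(1−p̃)) with p̃ = (AC+1)/(AN+2) estimated from controls (a
pseudo-count-stabilized inverse-frequency weight, up-weighting the rarest
variants). Raw weighted sums are far off the count scale the Poisson
likelihood assumes (typical weights are 40–60), which destroys the χ²
calibration — measured null rejection rates approached 80% in early testing —
so weights are renormalized to unit mean within each cohort's contributing
alleles. Only the *relative* up-weighting of rarer variants survives
renormalization, which is all the weighting is for; the totals stay on the
allele-count scale and calibration matches the unweighted test when all
weights are equal. Flat weights are available as a configuration.

**Scan-level corrections.** A conservative genomic-control factor
λ = max(1, median(Λ)/0.4549) divides every statistic before p-values are
taken; Benjamini–Hochberg q-values (step-up, ties sharing the largest rank,
supporting m larger than the supplied subset) control the FDR across tested
genes, with q ≤ 0.2 flagged. By default the tested universe is
case-ascertained (genes with at least one qualifying rare deleterious case
variant); a "both" mode additionally tests genes carried only by controls.

## Synthetic cohorts

The generator draws per-gene class totals as independent Poisson counts with
an enrichment ratio ρ ≥ 1 on case functional counts and an artifact factor κ
multiplying both control classes. Defaults encode the study regime: 46 cases;
the functional rate λ_f = 0.0145 per haploid genome per gene matches the
observed density of roughly 130 rare deleterious variants per case over
~4446 tested genes (≈1.34 case functional alleles per gene); the synonymous
proxy, carrying no deleteriousness filter, is taken twice as dense
(λ_s = 0.029). The default control size of 2,000 keeps experiments at desk
scale while preserving the counts-per-gene regime; the full 19,751-control
size is available as a preset. Alleles are materialized as singleton variants
(each allele a distinct variant in one carrier), matching the observed
candidate-variant regime; a recurrent-site mode exists for exercising the HWE
filter. Clinical ages are normal draws centered at the cohort means
(57.3 / 58.8 years, SD 12) with an optional carrier age shift, chosen to
resemble, not reproduce, the cohort.

The generator does **not** simulate linkage, relatedness, ancestry structure,
per-site coverage or genotype errors; passing tests therefore demonstrate the
statistical behavior of the pipeline under its own model assumptions, not
robustness to those real-data complications (the genomic-control step is the
pipeline's blanket guard for residual miscalibration).

**Calibration experiments** assess the per-gene type-I error over *all*
simulated genes (gene universe "both"), since case-ascertained testing
conditions on a case hit and is not a calibration statement. At the default
densities the weighted proxy LRT runs at ≈0.055–0.065 per-gene rejection at
α = 0.05 — the known mild anti-conservativeness of the χ² reference at low
counts — while a naive functional-only Poisson comparison exceeds 25%
rejection once a κ = 2 processing artifact is present. Power experiments
report the fraction of designated enriched genes reaching q ≤ 0.2 per ρ and
are monotone over ρ ∈ {1, 2, 5, 10}.

Problem sizes used by the shipped experiments: 1,000 random count quadruples
for the MLE agreement check; 2 replicates of 1,000 genes (2,000 gene tests)
for null calibration; 2 replicates × 40 enriched genes among 200 per ρ for
power.

## Fixtures and published tallies

The printed summary tables ship as plain-text fixtures: cohort
characteristics, the 17 known-gene carriers with MC1R status, the 13
candidate genes with case/control allele counts, and the 41 candidate
variants with FrEx and TCGA annotations. From these the package recomputes
the carrier rate (17/125 = 13.6%), the MITF p.E318K rate (9/125 = 7.2%),
MC1R co-carriage among carriers (12/17 ≈ 70%), the novel-or-very-rare
fraction of candidates (25/41 = 61%, popmax absent or < 1e-4 with the
boundary excluded), the FrEx overlap (6 variants in 5 genes), and the TCGA
overlap (7 of 41 variants; 16 occurrences, 8 melanoma and 8 RCC, with the
familial thyroid-cancer entry excluded).

Case allele counts are derived from the printed case AFs as AC = round(AF·92)
(the table's 0.01/0.02 values are read as 1 and 2 alleles in 46 diploid
cases). Per-case clinical data for the 46 sequenced cases were never
published, so the carriers-versus-tumor-history association is demonstrated
on a synthetic stand-in cohort constructed to match the published marginals
(8 CLTCL1/SETD2 carriers, 6 of them with another solid tumor; 11 of 38
non-carriers with one), which reproduces the (6,2; 11,27) table and its
Fisher p ≈ 0.04. The published per-gene p/q-values of the discovery scan are
not recomputable from the printed information (the synonymous counts and
unrounded p-values were not released); the enrichment engine is therefore
validated by the property experiments above rather than against those
numbers.

## Numerical and design notes

* Exact tests: Fisher (two-sided by probability ordering — the convention
  that reproduces the published clinical p-value) and Mann–Whitney
  (exact enumeration when combined n ≤ 12 without ties, otherwise the
  tie-corrected normal approximation) are delegated to scipy behind the
  package's interfaces; the test suite checks both against exact-integer
  enumeration oracles. The HWE exact test and BH step-up are implemented
  here (no installed routine covers the conditional HWE test, and standard
  BH implementations do not accept m larger than the supplied p-vector).
* Zero margins in a 2×2 table give p = 1 by convention; monomorphic sites
  give HWE p = 1.
* "Personal history of solid tumors" excludes the two index cancers.
* Genomic control is clamped at λ ≥ 1 (it never inflates significance) and
  applied to the weighted statistic before FDR correction.
* All simulation randomness flows from one seeded `numpy` PCG64 generator,
  named in run manifests; identical seeds give identical outputs.

## Known limitations

* The Poisson model treats alleles as independent; recurrent variants and
  relatedness violate this and are not modeled.
* The χ²₁ reference is mildly anti-conservative at very low per-gene counts;
  the conservative genomic-control step partially compensates at scan level.
* The weighted test's renormalized inverse-frequency weights change power,
  not validity; their benefit depends on the true effect-frequency
  relationship, which the simulator does not attempt to model.
* Panel screening matches exact normalized keys only; no fuzzy or positional
  matching is attempted, by design (rare-variant identity must be
  allele-precise).
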