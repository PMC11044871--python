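# Methods

## Problem setting

famseg prioritizes rare, predicted-deleterious variants in a multi-family
exome study of a phenotype that is fully expressed in females and may be
sex-limited in males (the motivating application is lipedema, a chronic
adipose disorder diagnosed almost exclusively in women). The input is a
pedigree (PED), a jointly called multi-sample VCF annotated with gene
symbol, VEP impact class, Phred-scaled CADD, gnomAD global allele
frequency, and the per-gene LoFtool percentile, and a gene→GO-term
mapping. The output is, per family, the set of variants (or
compound-heterozygous pairs) consistent with at least one inheritance
model after annotation filtering; cross-family gene recurrence; and GO
overrepresentation statistics for the candidate gene set.

## Segregation model

Eleven declarative inheritance models are evaluated per family:

| model | scope | affected genotype | unaffected constraint | AF class |
|---|---|---|---|---|
| autosomal_dominant | autosomal | ≥1 alt | 0 alt | strict |
| autosomal_dominant_male_carriers | autosomal | ≥1 alt | 0 alt; males exempt | strict |
| autosomal_de_novo | autosomal | ≥1 alt; ≥1 affected with both sequenced parents hom-ref | 0 alt | strict |
| autosomal_recessive | autosomal | hom-alt | not hom-alt | lenient |
| autosomal_recessive_male_carriers | autosomal | hom-alt | not hom-alt; males exempt | lenient |
| compound_het | autosomal | het for both pair members, in trans | must not carry both | lenient |
| compound_het_male_carriers | autosomal | as above | males exempt | lenient |
| x_linked_dominant | X | ≥1 alt | 0 alt | strict |
| x_linked_dominant_male_carriers | X | ≥1 alt | 0 alt; males exempt | strict |
| x_linked_de_novo | X | as autosomal de novo | 0 alt | strict |
| x_linked_recessive | X | hom-alt / hemizygous alt | not hom-alt | lenient |

Key assumptions:

* **Full penetrance over observed individuals only.** Constraints apply
  to sequenced members with known affection status and a non-missing
  genotype; everyone else (unsequenced connectors, unknown-status
  relatives, missing calls) imposes no constraint. This encodes the
  study-design principle that no assumption is made about individuals who
  did not participate.
* **Male-carrier models** exempt unaffected males from all genotype
  constraints, modelling sex-limited expression. By construction each
  such model accepts a superset of the genotype configurations accepted
  by its fully penetrant counterpart (property-tested).
* **De novo** requires at least one affected carrier whose two parents
  are sequenced hom-ref, not all affecteds — so multi-generation families
  in which only the proband has sequenced parents remain evaluable.
* **X chromosome in males**: a diploid heterozygous call is biologically
  inconsistent and is demoted to missing (robustness to caller
  conventions) rather than treated as informative; a haploid/hemizygous
  alt call carries hom-alt dosage.

### Compound heterozygotes without phase

For every unordered pair of heterozygous candidate variants in one gene,
each sequenced affected with two informatively sequenced parents must be
het for both, with one variant traceable to the mother only (mother
carries it, father does not) and the other to the father only — or one
variant de novo (both parents hom-ref) and the other uniparentally
inherited. Affecteds without two sequenced parents contribute only the
both-het requirement. No constrained unaffected individual may carry both
members of a pair (unaffected males exempt under the male-carrier
variant). A configuration in which both parents carry the same variant is
uninformative for origin and conservatively rejected when it prevents
establishing trans phase.

## Annotation filters

| filter | rule | default | missing-value policy |
|---|---|---|---|
| rarity | gnomAD global AF < threshold (strict `<`) | 1e-4 strict / 1e-2 lenient | absent from gnomAD → AF 0.0 (absence from a population database is evidence of rarity) |
| LoF tolerance | LoFtool percentile < 0.9 | remove most-tolerant 10% of genes | missing score passes (no evidence of tolerance) |
| deleteriousness | CADD ≥ 15, HIGH impact retained regardless | 15 | missing CADD fails unless impact HIGH (no score is not evidence of damage) |
| quality | site FILTER must be PASS; genotypes with GQ < 20 or DP < 10 demoted to missing | GATK-convention defaults | — |

Each missing-value policy is configurable. Rarity is evaluated per model
class, so a variant at AF 0.005 is testable under recessive and
compound-het models while excluded from dominant ones; filtering is
therefore fused with model evaluation rather than applied once globally.
The three annotation predicates are pure and order-independent;
quality control runs first because it mutates genotypes.

Per-transcript annotations (VEP CSQ) are collapsed to a single record by
maximal impact severity (HIGH > MODERATE > LOW > MODIFIER), ties broken
by lexicographically smallest gene symbol then first occurrence — the
assignment of variants overlapping several genes is otherwise arbitrary
and this makes it deterministic. Multiallelic sites are split into
biallelic records with other alt alleles collapsed to ref, conserving
per-sample dosage across the split.

## Aggregation

Candidate hits roll up to genes keyed by annotation symbol (no alias
resolution — a documented limitation). Variant identity across families
is (chrom, pos, ref, alt), not rsID, since rsIDs may be absent. The
study-level summary reports the candidate-gene count as the cohort-wide
union, the number of variants shared by ≥2 families, the maximum number
of families sharing one variant, and whether any gene harbours candidates
in every family.

## Enrichment

Each GO term is tested with the exact upper-tail hypergeometric
probability P(X ≥ k) for drawing k of the term's K genes in a query of n
from a background of N. The tail is summed in log-space via log-gamma
binomial coefficients; the implementation agrees with exact rational
enumeration to < 1e-10 over all N ≤ 60 and with an independent survival
function to 1e-8 relative at N up to 2×10⁴. Benjamini–Hochberg step-up
adjustment is applied within each GO category separately by default
(matching per-category reporting conventions; a joint mode exists).
Defaults: background = all genes in the annotation file (the effective
background of web services is generally unpublished, so it is explicit
and overridable here); significance α = 0.05 on adjusted p; terms
overlapping the query in fewer than 2 genes are not tested (single-gene
overlaps are untestable noise). No ontology-graph propagation is
performed: the statistic is exactly the hypergeometric test on the
provided sets, and users wanting parent-term credit should pre-propagate
the mapping.

## Synthetic cohorts

The simulator emits the full input bundle plus a truth table. The default
configuration reproduces the cohort shape the analysis is designed for:
9 families, 31 sequenced individuals, 10 affected (all female, including
one monozygotic twin pair) — seven parent–parent–proband trios, one
quartet with an unaffected sister, and one six-person family with
affected MZ twin daughters, an unaffected sister, and an unaffected
brother. Phenotype and sex are configurable to exercise male-carrier
models.

* **Plants**: one per family, cycling through the model registry, with
  genotypes satisfying the model exactly and annotations passing every
  filter for the model's AF class (AF 5e-5 strict / 5e-3 lenient,
  CADD 25, LoFtool 0.2, MODERATE impact).
* **Decoys**: four per family, each a clone of the plant scenario
  breaking exactly one rule — AF at/above the class threshold, CADD 5
  without HIGH rescue, LoFtool 0.95, or segregation (affecteds hom-ref,
  which fails the carrier requirement of every model). Decoy genes each
  contain a single variant so a broken single-variant decoy cannot
  resurface as half of a compound-het pair.
* **Background**: 200 variants, one per background gene, genotyped by
  Mendelian gene-dropping from founder draws. The written gnomAD AF is
  the population frequency (a Beta(0.3, 3) spread, with a 20% point mass
  of novel alleles absent from gnomAD); the gene-dropping frequency is
  floored at 5% so that even novel alleles segregate in the pedigrees.
  CADD is uniform on (0, 40), LoFtool uniform on (0, 1), 2% of
  consequences are HIGH impact, 3% of sites fail FILTER, and 1% of
  genotypes are missing with a further 2% at low GQ. Background
  survivors are expected and provide candidate-list noise with
  multi-family recurrence.
* **GO annotation**: one planted term containing exactly the planted
  genes plus padding symbols that occur in no variant, and 30 background
  terms (5–25 genes each) sampled from the background gene pool across
  the three GO categories.

All randomness flows through a single seed; identical configurations
write byte-identical files. Problem sizes (200 background variants, 30
terms) are chosen so a full simulate→prioritize→enrich→verify cycle
completes in well under a second, which lets the recovery guarantee be
checked across 100 seeds routinely.

What the simulator does **not** emulate: linkage disequilibrium and
recombination (sites are independent), read-level error processes,
population stratification in allele frequencies, multi-variant genes in
the background (so compound-het noise arises only from plants), and
realistic exome scale (~2.8M called variants). Passing tests therefore
demonstrate correctness of the filtering and segregation logic under the
stated model, not robustness to annotation error or callers' artifacts in
real exomes.

## Numerical and degenerate-input choices

* Rarity uses strict `<`; CADD uses `≥`; LoFtool removal uses `≥` at the
  0.9 boundary ("highest 10%" removed). Boundary behaviour is pinned by
  tests (AF exactly 1e-4 fails strict; CADD exactly 15 passes; LoFtool
  exactly 0.9 is removed).
* The hypergeometric tail returns exactly 1.0 at k = 0; BH adjustment
  caps at 1 and is permutation-equivariant.
* Families with no sequenced affected member produce no hits; an empty
  variant stream produces an empty candidate list; an empty query or
  background is an error for enrichment.
* Candidate and gene tables are sorted deterministically ((chrom, pos,
  alt, family) and (descending recurrence, gene)).

## Known limitations

* The eleven-model registry is a reconstruction from the stated
  properties of the analysis (count, male-carrier variants, compound het,
  distinct AF classes for dominant/de novo vs recessive); it is data
  rather than code and can be replaced via a YAML file. Whether X-linked
  models belong to the strict or lenient AF class is not externally
  fixed; here dominant/de novo-like models are strict and recessive-like
  lenient, consistently on both scopes.
* Gene identity is the bare symbol; no HGNC alias resolution.
* Imprinting, mitochondrial, mosaic, and two-locus models are out of
  scope, as are kinship verification and statistical burden testing.
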