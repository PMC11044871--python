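"""Typed variant records read from annotated multi-sample VCFs.

VCF parsing is delegated to cyvcf2; this module turns each site into one
or more biallelic :class:`VariantRecord` objects carrying a single
:class:`VariantAnnotation` (gene symbol, VEP-style impact, Phred-scaled
CADD, gnomAD global allele frequency, LoFtool percentile) and per-sample
genotype calls.

Annotations may come either from flat INFO keys or from a VEP ``CSQ``
field; the key names and CSQ subfield layout are configured by
:class:`AnnotationSpec`. When a variant carries several transcript
consequences, the single most severe one is retained (HIGH > MODERATE >
LOW > MODIFIER; ties broken by lexicographically smallest gene symbol,
then first occurrence).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence, Union

from cyvcf2 import VCF


class VariantModelError(ValueError):
    pass


class Impact(enum.IntEnum):
    """VEP consequence impact classes, ordered by increasing severity."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one biallelic site.

    ``allele_count`` is the alt-allele dosage (0, 1, 2) or None for a
    missing call. Hemizygous alt calls (haploid GT on X in males) are
    recorded with dosage 2. Missing calls impose no segregation
    constraint downstream.
    """

    allele_count: Optional[int]
    quality: Optional[int] = None  # GQ
    depth: Optional[int] = None  # DP

    @property
    def missing(self) -> bool:
        return self.allele_count is None


MISSING_CALL = GenotypeCall(allele_count=None)


@dataclass(frozen=True)
class VariantAnnotation:
    gene_symbol: str
    impact: Impact
    cadd_phred: Optional[float] = None
    gnomad_af: Optional[float] = None
    loftool: Optional[float] = None

    def __post_init__(self):
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise VariantModelError(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if self.loftool is not None and not (0.0 <= self.loftool <= 1.0):
            raise VariantModelError(f"loftool out of [0,1]: {self.loftool}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise VariantModelError(f"negative cadd_phred: {self.cadd_phred}")


@dataclass
class VariantRecord:
    """One biallelic site (after decomposition) with per-sample calls."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    id: Optional[str]
    filter_pass: bool
    annotation: VariantAnnotation
    genotypes: dict[str, GenotypeCall]

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def call(self, sample_id: str) -> GenotypeCall:
        return self.genotypes.get(sample_id, MISSING_CALL)

    @property
    def is_x(self) -> bool:
        return self.chrom.removeprefix("chr").upper() == "X"


@dataclass
class AnnotationSpec:
    """Where to find annotations: flat INFO keys or a VEP CSQ field.

    In ``flat`` mode each field is its own INFO key. In ``csq`` mode the
    INFO key ``csq_key`` holds comma-separated transcript consequences,
    each pipe-delimited with subfields named in ``csq_format`` (normally
    parsed from the VCF header ``##INFO=<ID=CSQ,...Format: ...>`` line).
    """

    mode: str = "flat"  # "flat" | "csq"
    symbol_key: str = "SYMBOL"
    impact_key: str = "IMPACT"
    cadd_key: str = "CADD_PHRED"
    af_key: str = "gnomAD_AF"
    loftool_key: str = "LoFtool"
    csq_key: str = "CSQ"
    csq_format: Optional[list[str]] = None


def most_severe_annotation(entries: Sequence[VariantAnnotation]) -> VariantAnnotation:
    """Pick the single annotation with maximal impact severity.

    Ties are broken by lexicographically smallest gene symbol, then by
    first occurrence, so the choice is deterministic.
    """
    if not entries:
        raise VariantModelError("no annotation entries to choose from")
    return min(enumerate(entries),
               key=lambda t: (-int(t[1].impact), t[1].gene_symbol, t[0]))[1]


def _parse_float(value) -> Optional[float]:
    if value is None or value == "" or value == ".":
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def _parse_impact(value) -> Optional[Impact]:
    if value is None:
        return None
    try:
        return Impact[str(value).upper()]
    except KeyError:
        return None


def _csq_entries(raw: str, fmt: list[str], spec: AnnotationSpec) -> list[VariantAnnotation]:
    idx = {name: i for i, name in enumerate(fmt)}
    out = []
    for chunk in raw.split(","):
        parts = chunk.split("|")

        def get(key):
            i = idx.get(key)
            return parts[i] if i is not None and i < len(parts) else None

        symbol = get(spec.symbol_key) or "."
        impact = _parse_impact(get(spec.impact_key))
        if impact is None:
            impact = Impact.MODIFIER
        out.append(VariantAnnotation(
            gene_symbol=symbol,
            impact=impact,
            cadd_phred=_parse_float(get(spec.cadd_key)),
            gnomad_af=_parse_float(get(spec.af_key)),
            loftool=_parse_float(get(spec.loftool_key)),
        ))
    return out


def _csq_format_from_header(vcf: VCF, spec: AnnotationSpec) -> Optional[list[str]]:
    try:
        entry = vcf.get_header_type(spec.csq_key)
    except KeyError:
        return None
    desc = entry.get("Description", "")
    if "Format:" in desc:
        fmt = desc.split("Format:", 1)[1].strip().strip('"').strip()
        return fmt.split("|")
    return None


def _flat_annotation(variant, spec: AnnotationSpec, alt_index: int,
                     n_alts: int) -> VariantAnnotation:
    def info(key):
        v = variant.INFO.get(key)
        # per-alt (Number=A) values arrive as tuples for multiallelics
        if isinstance(v, tuple):
            v = v[alt_index] if alt_index < len(v) else None
        return v

    impact = _parse_impact(info(spec.impact_key))
    symbol = info(spec.symbol_key)
    return VariantAnnotation(
        gene_symbol=str(symbol) if symbol is not None else ".",
        impact=impact if impact is not None else Impact.MODIFIER,
        cadd_phred=_parse_float(info(spec.cadd_key)),
        gnomad_af=_parse_float(info(spec.af_key)),
        loftool=_parse_float(info(spec.loftool_key)),
    )


def _decompose_genotypes(variant, samples: list[str], alt_index: int) -> dict[str, GenotypeCall]:
    """Recode genotypes for one alt of a (possibly multiallelic) site.

    Alleles other than the current alt collapse to ref for this record,
    so summing alt dosages across the split records recovers the original
    multiallelic dosage for every sample. Haploid calls count the single
    allele with dosage 2 (hemizygous alt ~ hom-alt).
    """
    target = alt_index + 1
    gqs = variant.gt_quals
    dps = variant.gt_depths
    out: dict[str, GenotypeCall] = {}
    for i, sample in enumerate(samples):
        alleles = [a for a in variant.genotypes[i][:-1] if a is not None]
        known = [a for a in alleles if a >= 0]
        if not alleles or len(known) < len(alleles):
            out[sample] = MISSING_CALL
            continue
        n_target = sum(1 for a in known if a == target)
        if len(known) == 1:  # haploid call
            dosage = 2 if n_target == 1 else 0
        else:
            dosage = n_target
        gq = int(gqs[i]) if gqs is not None and gqs[i] >= 0 else None
        dp = int(dps[i]) if dps is not None and dps[i] >= 0 else None
        out[sample] = GenotypeCall(allele_count=dosage, quality=gq, depth=dp)
    return out


def read_vcf(path: Union[str, Path], annotation_spec: Optional[AnnotationSpec] = None
             ) -> Iterator[VariantRecord]:
    """Stream biallelic :class:`VariantRecord` objects from a VCF 4.x file.

    Multiallelic sites are split into one record per alt allele, with
    genotypes recoded so each record is biallelic. Records stream in file
    order. Missing annotation keys leave fields absent (handled by the
    downstream filters); a VCF without genotypes is fatal.
    """
    spec = annotation_spec or AnnotationSpec()
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise VariantModelError(f"{path}: no samples / GT FORMAT in VCF")
    csq_fmt = spec.csq_format
    if spec.mode == "csq" and csq_fmt is None:
        csq_fmt = _csq_format_from_header(vcf, spec)
        if csq_fmt is None:
            raise VariantModelError(
                f"CSQ subfield layout not given and not found in header of {path}"
            )
    for variant in vcf:
        alts = variant.ALT or []
        filter_pass = variant.FILTER is None  # cyvcf2: None == PASS
        for alt_index, alt in enumerate(alts):
            if spec.mode == "csq":
                raw = variant.INFO.get(spec.csq_key)
                if raw is None:
                    ann = VariantAnnotation(gene_symbol=".", impact=Impact.MODIFIER)
                else:
                    ann = most_severe_annotation(_csq_entries(str(raw), csq_fmt, spec))
            else:
                ann = _flat_annotation(variant, spec, alt_index, len(alts))
            yield VariantRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=alt,
                id=variant.ID,
                filter_pass=filter_pass,
                annotation=ann,
                genotypes=_decompose_genotypes(variant, samples, alt_index),
            )


CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "id", "gene", "family",
    "models", "cadd", "af", "loftool", "impact",
]


def write_candidates(hits, sink: IO[str]) -> None:
    """Write candidate hits as a deterministic TSV.

    One row per (variant, family); compound-het pairs contribute one row
    per member variant with the same model set. Sorted by
    (chrom, pos, alt, family). Absent values are written as ``.``.
    """
    rows = []
    for hit in hits:
        models = ",".join(sorted(hit.models_passed))
        for v in hit.variants:
            ann = v.annotation
            rows.append({
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "id": v.id if v.id else ".",
                "gene": hit.gene,
                "family": hit.family_id,
                "models": models,
                "cadd": "." if ann.cadd_phred is None else repr(ann.cadd_phred),
                "af": "." if ann.gnomad_af is None else repr(ann.gnomad_af),
                "loftool": "." if ann.loftool is None else repr(ann.loftool),
                "impact": ann.impact.name,
            })
    rows.sort(key=lambda r: (r["chrom"], r["pos"], r["alt"], r["family"], r["gene"]))
    writer = csv.DictWriter(sink, fieldnames=CANDIDATE_COLUMNS, delimiter="\t",
                            lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)


def read_candidates(source: Union[str, Path, IO[str]]):
    """Read a candidate TSV back into a DataFrame (round-trip checkable)."""
    import pandas as pd

    return pd.read_csv(source, sep="\t", dtype=str, na_filter=False)
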