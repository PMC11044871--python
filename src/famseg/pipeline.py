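"""End-to-end orchestration: PED + VCF -> candidate hits -> summary -> enrichment.

This is the library face of the command-line interface; tests and
analysis scripts call these functions directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from cyvcf2 import VCF

from famseg.aggregate import GeneRecurrence, SummaryReport, aggregate_by_gene, recurrence_summary
from famseg.enrichment import EnrichmentResult, enrich, read_gene2term
from famseg.filters import FilterConfig, quality_filter
from famseg.inheritance import CandidateHit, InheritanceModel, default_model_registry, evaluate_family
from famseg.pedigree import Family, parse_ped, validate_family
from famseg.variant_model import AnnotationSpec, read_vcf


@dataclass
class PrioritizeResult:
    families: list[Family]
    hits: list[CandidateHit]
    gene_recurrence: list[GeneRecurrence]
    summary: SummaryReport

    @property
    def candidate_genes(self) -> set[str]:
        return {h.gene for h in self.hits}


def vcf_sample_ids(vcf_path: Union[str, Path]) -> set[str]:
    return set(VCF(str(vcf_path)).samples)


def prioritize(ped_path: Union[str, Path], vcf_path: Union[str, Path],
               cfg: Optional[FilterConfig] = None,
               registry: Optional[Sequence[InheritanceModel]] = None,
               annotation_spec: Optional[AnnotationSpec] = None) -> PrioritizeResult:
    """Quality filtering, per-family model evaluation, and aggregation.

    Families with at least one affected member enter segregation
    analysis; members absent from the VCF are treated as unsequenced and
    impose no constraint.
    """
    cfg = cfg or FilterConfig()
    registry = default_model_registry() if registry is None else registry
    with open(ped_path) as fh:
        families = parse_ped(fh)
    samples = vcf_sample_ids(vcf_path)
    for fam in families:
        validate_family(fam, samples)
    variants = []
    for v in read_vcf(vcf_path, annotation_spec):
        v = quality_filter(v, cfg)
        if v is not None:
            variants.append(v)
    hits: list[CandidateHit] = []
    for fam in families:
        if not fam.affected:
            continue
        hits.extend(evaluate_family(variants, fam, registry, cfg))
    recs = aggregate_by_gene(hits)
    summary = recurrence_summary(recs, hits, n_families=len(families))
    return PrioritizeResult(families=families, hits=hits,
                            gene_recurrence=recs, summary=summary)


def enrich_candidates(candidate_genes: Sequence[str], gene2term_path: Union[str, Path],
                      alpha: float = 0.05, min_overlap: int = 2,
                      background_path: Optional[Union[str, Path]] = None,
                      fdr_scope: str = "per_category") -> list[EnrichmentResult]:
    """GO overrepresentation on a candidate gene list."""
    annotations = read_gene2term(gene2term_path)
    background = None
    if background_path is not None:
        with open(background_path) as fh:
            background = {line.strip() for line in fh if line.strip()}
    return enrich(set(candidate_genes), annotations, alpha=alpha,
                  min_overlap=min_overlap, background=background,
                  fdr_scope=fdr_scope)
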