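"""Gene-level roll-up of candidate hits and the study-level summary.

Variant identity for cross-family matching is (chrom, pos, ref, alt) —
rsIDs may be absent. Gene identity is the annotation symbol string, with
no alias resolution (a documented limitation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Sequence

from famseg.inheritance import CandidateHit


@dataclass
class GeneRecurrence:
    gene: str
    families: set[str] = field(default_factory=set)
    variant_keys: set[tuple] = field(default_factory=set)
    per_family_models: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SummaryReport:
    n_families: int
    total_candidate_genes: int
    n_multi_family_variants: int  # distinct variant keys seen in >=2 families
    max_families_per_variant: int
    universal_gene_exists: bool
    universal_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "n_families": self.n_families,
            "total_candidate_genes": self.total_candidate_genes,
            "n_multi_family_variants": self.n_multi_family_variants,
            "max_families_per_variant": self.max_families_per_variant,
            "universal_gene_exists": self.universal_gene_exists,
            "universal_genes": self.universal_genes,
        }


def aggregate_by_gene(hits: Sequence[CandidateHit]) -> list[GeneRecurrence]:
    """One entry per gene hit in >=1 family.

    Sorted deterministically by descending family count, then gene name,
    so recurrent genes surface first. Invariant to hit ordering.
    """
    by_gene: dict[str, GeneRecurrence] = {}
    for hit in hits:
        rec = by_gene.setdefault(hit.gene, GeneRecurrence(gene=hit.gene))
        rec.families.add(hit.family_id)
        rec.variant_keys.update(hit.variant_keys)
        rec.per_family_models.setdefault(hit.family_id, set()).update(hit.models_passed)
    return sorted(by_gene.values(), key=lambda r: (-len(r.families), r.gene))


def recurrence_summary(recs: Sequence[GeneRecurrence], variant_level: Sequence[CandidateHit],
                       n_families: int) -> SummaryReport:
    """Study-level report: gene count, variant sharing, universal genes.

    ``max_families_per_variant`` answers "was any single variant called
    in more than k families?"; ``universal_gene_exists`` answers whether
    some gene harbours surviving variants in every family.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    fams_per_variant: dict[tuple, set[str]] = {}
    for hit in variant_level:
        for key in hit.variant_keys:
            fams_per_variant.setdefault(key, set()).add(hit.family_id)
    multi = sum(1 for fams in fams_per_variant.values() if len(fams) >= 2)
    max_fams = max((len(f) for f in fams_per_variant.values()), default=0)
    universal = sorted(r.gene for r in recs if len(r.families) == n_families)
    return SummaryReport(
        n_families=n_families,
        total_candidate_genes=len(recs),
        n_multi_family_variants=multi,
        max_families_per_variant=max_fams,
        universal_gene_exists=bool(universal),
        universal_genes=universal,
    )


def write_gene_table(recs: Sequence[GeneRecurrence], sink: IO[str]) -> None:
    sink.write("gene\tn_families\tfamilies\tn_variants\tmodels\n")
    for r in recs:
        models = sorted({m for ms in r.per_family_models.values() for m in ms})
        sink.write("\t".join([
            r.gene,
            str(len(r.families)),
            ",".join(sorted(r.families)),
            str(len(r.variant_keys)),
            ",".join(models),
        ]) + "\n")


def write_summary(report: SummaryReport, sink: IO[str]) -> None:
    json.dump(report.to_dict(), sink, indent=2)
    sink.write("\n")
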