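"""Per-family segregation under a registry of eleven inheritance models.

Each :class:`InheritanceModel` is a declarative rule: chromosome scope
(autosomal or X-linked), the zygosity demanded of affected individuals,
the constraints placed on unaffected individuals, the allele-frequency
class used for rarity filtering (strict for dominant/de novo, lenient for
recessive/compound-het), and whether unaffected males are exempt from all
genotype constraints ("male carrier" models, modelling sex-limited
expression of a female-predominant phenotype).

The phenotype is assumed fully penetrant, but only over sequenced members
with known affection status: a missing genotype or unknown status imposes
no constraint, so unsequenced relatives never veto a candidate.

Male genotypes on X: a diploid heterozygous call in a male is biologically
inconsistent and is demoted to missing rather than treated as informative;
a hemizygous alt call carries hom-alt dosage.

Compound heterozygotes are detected without phasing, from parental
genotypes: the two variants of a pair must be traceable to opposite
parents (or one de novo with the other uniparentally inherited), and no
constrained unaffected individual may carry both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from famseg.filters import FilterConfig, annotation_filters
from famseg.pedigree import Family, Individual, Sex, Status
from famseg.variant_model import VariantRecord

SCOPES = ("autosomal", "x_linked")
KINDS = ("dominant", "de_novo", "recessive_hom", "compound_het")
STRICT_KINDS = frozenset({"dominant", "de_novo"})


class InheritanceError(ValueError):
    pass


@dataclass(frozen=True)
class InheritanceModel:
    name: str
    scope: str  # "autosomal" | "x_linked"
    kind: str  # "dominant" | "de_novo" | "recessive_hom" | "compound_het"
    male_carriers_allowed: bool = False

    def __post_init__(self):
        if self.scope not in SCOPES:
            raise InheritanceError(f"unknown scope {self.scope!r}")
        if self.kind not in KINDS:
            raise InheritanceError(f"unknown kind {self.kind!r}")

    @property
    def af_class(self) -> str:
        """Rarity class: strict (1e-4) for dominant/de novo, lenient (1e-2)
        for recessive and compound-het kinds."""
        return "strict" if self.kind in STRICT_KINDS else "lenient"


def default_model_registry() -> list[InheritanceModel]:
    """The default set of eleven inheritance models, in fixed order.

    Covers autosomal dominant, de novo, recessive-homozygous and
    compound-het (the latter three classes each with and without the
    male-carrier exemption where meaningful), plus X-linked dominant
    (with and without male carriers), X-linked de novo, and X-linked
    recessive. The registry is plain data and user-overridable via
    :func:`load_registry`.
    """
    return [
        InheritanceModel("autosomal_dominant", "autosomal", "dominant", False),
        InheritanceModel("autosomal_dominant_male_carriers", "autosomal", "dominant", True),
        InheritanceModel("autosomal_de_novo", "autosomal", "de_novo", False),
        InheritanceModel("autosomal_recessive", "autosomal", "recessive_hom", False),
        InheritanceModel("autosomal_recessive_male_carriers", "autosomal", "recessive_hom", True),
        InheritanceModel("compound_het", "autosomal", "compound_het", False),
        InheritanceModel("compound_het_male_carriers", "autosomal", "compound_het", True),
        InheritanceModel("x_linked_dominant", "x_linked", "dominant", False),
        InheritanceModel("x_linked_dominant_male_carriers", "x_linked", "dominant", True),
        InheritanceModel("x_linked_de_novo", "x_linked", "de_novo", False),
        InheritanceModel("x_linked_recessive", "x_linked", "recessive_hom", False),
    ]


def load_registry(path: Union[str, Path]) -> list[InheritanceModel]:
    """Load a model registry from a YAML list of mappings."""
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    models = [InheritanceModel(name=r["name"], scope=r["scope"], kind=r["kind"],
                               male_carriers_allowed=bool(r.get("male_carriers_allowed", False)))
              for r in rows]
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise InheritanceError("duplicate model names in registry")
    return models


def save_registry(models: Sequence[InheritanceModel], path: Union[str, Path]) -> None:
    rows = [{"name": m.name, "scope": m.scope, "kind": m.kind,
             "male_carriers_allowed": m.male_carriers_allowed} for m in models]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)


@dataclass
class CandidateHit:
    """A variant (or compound-het pair) surviving all filters in one family."""

    family_id: str
    gene: str
    variants: list[VariantRecord]
    models_passed: set[str] = field(default_factory=set)

    @property
    def variant_keys(self) -> tuple:
        return tuple(v.variant_key for v in self.variants)


def effective_dosage(v: VariantRecord, ind: Individual) -> Optional[int]:
    """Alt-allele dosage of one individual, or None if unconstraining.

    None for unsequenced individuals and missing calls. On X in males a
    diploid het call is inconsistent and demoted to missing; hemizygous
    alt counts as dosage 2.
    """
    if not ind.sequenced:
        return None
    call = v.call(ind.individual_id)
    if call.missing:
        return None
    if v.is_x and ind.sex is Sex.MALE and call.allele_count == 1:
        return None
    return call.allele_count


def _exempt(ind: Individual, model: InheritanceModel) -> bool:
    """Unaffected males are unconstrained under male-carrier models."""
    return model.male_carriers_allowed and ind.sex is Sex.MALE


def segregates(v: VariantRecord, fam: Family, model: InheritanceModel) -> bool:
    """Does a single variant segregate with affection status in a family?

    Constraints are evaluated only over sequenced members with known
    status and non-missing genotype; everyone else is unconstrained.
    Applies to single-variant kinds only (use :func:`compound_het_pairs`
    for compound-het models).
    """
    if model.kind == "compound_het":
        raise InheritanceError("segregates() does not handle compound_het models")
    if v.is_x != (model.scope == "x_linked"):
        raise InheritanceError(
            f"variant on {v.chrom} evaluated under {model.scope} model {model.name!r}"
        )
    for ind in fam.members.values():
        if ind.status is Status.UNKNOWN:
            continue
        d = effective_dosage(v, ind)
        if d is None:
            continue
        if ind.status is Status.AFFECTED:
            if model.kind in ("dominant", "de_novo"):
                if d < 1:
                    return False
            else:  # recessive_hom
                if d != 2:
                    return False
        else:  # unaffected
            if _exempt(ind, model):
                continue
            if model.kind in ("dominant", "de_novo"):
                if d != 0:
                    return False
            else:  # recessive_hom: het carriers allowed
                if d == 2:
                    return False
    if model.kind == "de_novo":
        return _has_de_novo_witness(v, fam)
    return True


def _has_de_novo_witness(v: VariantRecord, fam: Family) -> bool:
    """At least one affected carrier whose two sequenced parents are hom-ref.

    Demanding this of one affected (not all) keeps multi-generation
    families evaluable when only the proband has sequenced parents.
    """
    for ind in fam.members.values():
        if ind.status is not Status.AFFECTED:
            continue
        d = effective_dosage(v, ind)
        if d is None or d < 1:
            continue
        father, mother = fam.parents_of(ind.individual_id)
        if father is None or mother is None:
            continue
        df = effective_dosage(v, father)
        dm = effective_dosage(v, mother)
        if df == 0 and dm == 0:
            return True
    return False


def _parental_origin(d_father: int, d_mother: int) -> str:
    if d_mother >= 1 and d_father == 0:
        return "maternal"
    if d_father >= 1 and d_mother == 0:
        return "paternal"
    if d_father == 0 and d_mother == 0:
        return "de_novo"
    return "biparental"


def _pair_compatible(o1: str, o2: str) -> bool:
    if {o1, o2} == {"maternal", "paternal"}:
        return True
    uniparental = ("maternal", "paternal")
    return (o1 == "de_novo" and o2 in uniparental) or (o2 == "de_novo" and o1 in uniparental)


def compound_het_pairs(gene_variants: Sequence[VariantRecord], fam: Family,
                       model: InheritanceModel) -> list[tuple[VariantRecord, VariantRecord]]:
    """Phasing-free compound-heterozygote pairs within one gene.

    A pair (v1, v2) qualifies when, for every sequenced affected:

    * the affected is heterozygous for both variants (applied whenever the
      genotype is known);
    * if both parents are sequenced with known genotypes, one variant is
      traceable to the mother only and the other to the father only — or
      one variant is de novo (both parents hom-ref) and the other is
      uniparentally inherited. Affecteds without two informatively
      sequenced parents contribute only the both-het requirement;

    and no sequenced unaffected individual carries both variants
    (unaffected males exempt under male-carrier models).
    """
    if model.kind != "compound_het":
        raise InheritanceError(f"model {model.name!r} is not a compound_het model")
    genes = {v.annotation.gene_symbol for v in gene_variants}
    if len(genes) > 1:
        raise InheritanceError(f"variants span multiple genes: {sorted(genes)}")
    pairs = []
    for v1, v2 in combinations(sorted(gene_variants, key=lambda v: v.variant_key), 2):
        if _comphet_pair_ok(v1, v2, fam, model):
            pairs.append((v1, v2))
    return pairs


def _comphet_pair_ok(v1: VariantRecord, v2: VariantRecord, fam: Family,
                     model: InheritanceModel) -> bool:
    for ind in fam.members.values():
        if ind.status is Status.UNKNOWN:
            continue
        d1 = effective_dosage(v1, ind)
        d2 = effective_dosage(v2, ind)
        if ind.status is Status.AFFECTED:
            if d1 is not None and d1 != 1:
                return False
            if d2 is not None and d2 != 1:
                return False
            if d1 == 1 and d2 == 1:
                father, mother = fam.parents_of(ind.individual_id)
                if father is None or mother is None:
                    continue
                f1, m1 = effective_dosage(v1, father), effective_dosage(v1, mother)
                f2, m2 = effective_dosage(v2, father), effective_dosage(v2, mother)
                if None in (f1, m1, f2, m2):
                    continue  # uninformative parents: both-het only
                if not _pair_compatible(_parental_origin(f1, m1),
                                        _parental_origin(f2, m2)):
                    return False
        else:  # unaffected
            if _exempt(ind, model):
                continue
            if d1 is not None and d1 >= 1 and d2 is not None and d2 >= 1:
                return False
    return True


def evaluate_family(variants: Iterable[VariantRecord], fam: Family,
                    registry: Optional[Sequence[InheritanceModel]] = None,
                    cfg: Optional[FilterConfig] = None) -> list[CandidateHit]:
    """Run every model over a family's (quality-filtered) variants.

    For each model, variants are first screened with the rarity filter at
    the model's AF class plus the LoFtool and deleteriousness filters —
    so one variant can be testable under recessive models while excluded
    from dominant ones — then segregation (or compound-het pairing) is
    evaluated. One :class:`CandidateHit` is emitted per (gene,
    variant-or-pair) with the union of passing model names. Families with
    no sequenced affected member yield no hits.
    """
    registry = default_model_registry() if registry is None else registry
    cfg = FilterConfig() if cfg is None else cfg
    if not any(m.sequenced and m.status is Status.AFFECTED for m in fam.members.values()):
        return []
    variants = list(variants)
    hits: dict[tuple, CandidateHit] = {}

    def record(gene: str, vs: list[VariantRecord], model_name: str) -> None:
        key = (gene, tuple(v.variant_key for v in vs))
        hit = hits.get(key)
        if hit is None:
            hit = hits[key] = CandidateHit(family_id=fam.family_id, gene=gene, variants=vs)
        hit.models_passed.add(model_name)

    for model in registry:
        want_x = model.scope == "x_linked"
        scoped = [v for v in variants if v.is_x == want_x
                  and annotation_filters(v, model.af_class, cfg)]
        if model.kind == "compound_het":
            by_gene: dict[str, list[VariantRecord]] = {}
            for v in scoped:
                by_gene.setdefault(v.annotation.gene_symbol, []).append(v)
            for gene, gvs in by_gene.items():
                for v1, v2 in compound_het_pairs(gvs, fam, model):
                    record(gene, [v1, v2], model.name)
        else:
            for v in scoped:
                if segregates(v, fam, model):
                    record(v.annotation.gene_symbol, [v], model.name)
    return [hits[k] for k in sorted(hits)]
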