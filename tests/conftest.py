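"""Shared builders for pedigrees and variant records."""

from __future__ import annotations

import pytest

from famseg.pedigree import Family, Individual, Sex, Status
from famseg.variant_model import GenotypeCall, Impact, VariantAnnotation, VariantRecord

SEX = {"male": Sex.MALE, "female": Sex.FEMALE, "unknown": Sex.UNKNOWN}
STATUS = {"affected": Status.AFFECTED, "unaffected": Status.UNAFFECTED,
          "unknown": Status.UNKNOWN}


def build_family(members, family_id="F1"):
    """members: list of (id, father, mother, sex, status[, sequenced])."""
    fam = Family(family_id)
    for row in members:
        iid, father, mother, sex, status = row[:5]
        sequenced = row[5] if len(row) > 5 else True
        fam.add(Individual(
            individual_id=iid, family_id=family_id,
            father_id=father, mother_id=mother,
            sex=SEX[sex], status=STATUS[status], sequenced=sequenced,
        ))
    return fam


def build_variant(genotypes, chrom="1", pos=1000, ref="G", alt="A", vid=None,
                  gene="GENE1", impact=Impact.MODERATE, cadd=25.0, af=0.0,
                  loftool=0.2, filter_pass=True):
    """genotypes: dict sample -> dosage (0/1/2) or None for missing."""
    calls = {s: GenotypeCall(allele_count=d, quality=99, depth=30)
             for s, d in genotypes.items()}
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, id=vid, filter_pass=filter_pass,
        annotation=VariantAnnotation(gene_symbol=gene, impact=impact,
                                     cadd_phred=cadd, gnomad_af=af, loftool=loftool),
        genotypes=calls,
    )


@pytest.fixture
def trio():
    """Unaffected parents, affected daughter."""
    return build_family([
        ("FA", None, None, "male", "unaffected"),
        ("MO", None, None, "female", "unaffected"),
        ("P1", "FA", "MO", "female", "affected"),
    ])


@pytest.fixture
def quartet():
    """Trio plus an unaffected sister."""
    return build_family([
        ("FA", None, None, "male", "unaffected"),
        ("MO", None, None, "female", "unaffected"),
        ("P1", "FA", "MO", "female", "affected"),
        ("S1", "FA", "MO", "female", "unaffected"),
    ])


@pytest.fixture
def family_factory():
    return build_family


@pytest.fixture
def variant_factory():
    return build_variant
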