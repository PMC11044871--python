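from itertools import product

import pytest

from famseg.filters import FilterConfig
from famseg.inheritance import (
    InheritanceError,
    InheritanceModel,
    compound_het_pairs,
    default_model_registry,
    evaluate_family,
    load_registry,
    save_registry,
    segregates,
)
from famseg.pedigree import Status

from conftest import build_family, build_variant
from oracles import oracle_comphet_pairs, oracle_segregates

REGISTRY = default_model_registry()
SINGLE_MODELS = [m for m in REGISTRY if m.kind != "compound_het"]
COMPHET_MODELS = [m for m in REGISTRY if m.kind == "compound_het"]


class TestRegistry:
    def test_eleven_models(self):
        assert len(REGISTRY) == 11

    def test_names_unique(self):
        names = [m.name for m in REGISTRY]
        assert len(set(names)) == len(names)

    def test_af_class_follows_kind(self):
        for m in REGISTRY:
            if m.kind in ("dominant", "de_novo"):
                assert m.af_class == "strict"
            else:
                assert m.af_class == "lenient"

    def test_covers_both_scopes_and_male_carriers(self):
        assert {m.scope for m in REGISTRY} == {"autosomal", "x_linked"}
        assert any(m.male_carriers_allowed for m in REGISTRY)
        assert any(m.kind == "compound_het" for m in REGISTRY)

    def test_registry_round_trips_through_yaml(self, tmp_path):
        path = tmp_path / "models.yaml"
        save_registry(REGISTRY, path)
        assert load_registry(path) == REGISTRY


def variant_for(model, genotypes, **kw):
    chrom = "X" if model.scope == "x_linked" else "1"
    return build_variant(genotypes, chrom=chrom, **kw)


class TestSegregatesExamples:
    def test_de_novo_trio(self, trio):
        """Proband het, both parents hom-ref: de novo and dominant both fit."""
        geno = {"P1": 1, "FA": 0, "MO": 0}
        for name in ("autosomal_de_novo", "autosomal_dominant"):
            m = next(m for m in REGISTRY if m.name == name)
            assert segregates(variant_for(m, geno), trio, m)

    def test_affected_homref_fails_every_model(self, trio):
        geno = {"P1": 0, "FA": 0, "MO": 1}
        for m in SINGLE_MODELS:
            assert not segregates(variant_for(m, geno), trio, m)

    def test_unaffected_carrier_blocks_dominant_but_not_male_carrier_model(self):
        fam = build_family([
            ("FA", None, None, "male", "unaffected"),
            ("MO", None, None, "female", "unaffected"),
            ("P1", "FA", "MO", "female", "affected"),
        ])
        geno = {"P1": 1, "FA": 1, "MO": 0}
        ad = next(m for m in REGISTRY if m.name == "autosomal_dominant")
        ad_mc = next(m for m in REGISTRY if m.name == "autosomal_dominant_male_carriers")
        assert not segregates(variant_for(ad, geno), fam, ad)
        assert segregates(variant_for(ad_mc, geno), fam, ad_mc)

    def test_scope_mismatch_is_error(self, trio):
        ad = next(m for m in REGISTRY if m.name == "autosomal_dominant")
        v = build_variant({"P1": 1}, chrom="X")
        with pytest.raises(InheritanceError):
            segregates(v, trio, ad)

    def test_male_het_on_x_is_uninformative(self):
        """A diploid het call on X in a male neither confirms nor blocks."""
        fam = build_family([
            ("FA", None, None, "male", "unaffected"),
            ("MO", None, None, "female", "unaffected"),
            ("P1", "FA", "MO", "female", "affected"),
        ])
        xld = next(m for m in REGISTRY if m.name == "x_linked_dominant")
        geno = {"P1": 1, "FA": 1, "MO": 0}  # father het on X: inconsistent call
        assert segregates(variant_for(xld, geno), fam, xld)


def quartet_with_brother():
    return build_family([
        ("FA", None, None, "male", "unaffected"),
        ("MO", None, None, "female", "unaffected"),
        ("P1", "FA", "MO", "female", "affected"),
        ("B1", "FA", "MO", "male", "unaffected"),
    ])


class TestSegregationOracle:
    """Exhaustive genotype enumeration vs the independent truth-table oracle."""

    @pytest.mark.parametrize("model", SINGLE_MODELS, ids=lambda m: m.name)
    def test_trio_all_27_assignments(self, trio, model):
        members = list(trio.members)
        for combo in product((0, 1, 2), repeat=3):
            geno = dict(zip(members, combo))
            expected = oracle_segregates(geno, trio, model.kind,
                                         model.male_carriers_allowed,
                                         on_x=model.scope == "x_linked")
            assert segregates(variant_for(model, geno), trio, model) == expected, geno

    @pytest.mark.parametrize("model", SINGLE_MODELS, ids=lambda m: m.name)
    def test_quartet_all_81_assignments(self, model):
        fam = quartet_with_brother()
        members = list(fam.members)
        for combo in product((0, 1, 2), repeat=4):
            geno = dict(zip(members, combo))
            expected = oracle_segregates(geno, fam, model.kind,
                                         model.male_carriers_allowed,
                                         on_x=model.scope == "x_linked")
            assert segregates(variant_for(model, geno), fam, model) == expected, geno

    @pytest.mark.parametrize("model", SINGLE_MODELS, ids=lambda m: m.name)
    def test_missing_genotypes_match_oracle(self, trio, model):
        members = list(trio.members)
        for combo in product((0, 1, 2, None), repeat=3):
            geno = dict(zip(members, combo))
            expected = oracle_segregates(geno, trio, model.kind,
                                         model.male_carriers_allowed,
                                         on_x=model.scope == "x_linked")
            assert segregates(variant_for(model, geno), trio, model) == expected, geno


def test_male_carrier_models_accept_supersets(trio):
    """Relaxing penetrance for males can only enlarge the accepted set."""
    fam = quartet_with_brother()
    members = list(fam.members)
    pairs = [("autosomal_dominant", "autosomal_dominant_male_carriers"),
             ("autosomal_recessive", "autosomal_recessive_male_carriers"),
             ("x_linked_dominant", "x_linked_dominant_male_carriers")]
    by_name = {m.name: m for m in REGISTRY}
    for strict_name, relaxed_name in pairs:
        strict_m, relaxed_m = by_name[strict_name], by_name[relaxed_name]
        for combo in product((0, 1, 2), repeat=4):
            geno = dict(zip(members, combo))
            if segregates(variant_for(strict_m, geno), fam, strict_m):
                assert segregates(variant_for(relaxed_m, geno), fam, relaxed_m)


def test_unknown_status_and_unsequenced_never_change_verdict(trio):
    ad = next(m for m in REGISTRY if m.name == "autosomal_dominant")
    for combo in product((0, 1, 2), repeat=3):
        geno = dict(zip(trio.members, combo))
        base = segregates(variant_for(ad, geno), trio, ad)
        # add an unknown-status carrier and an unsequenced affected carrier
        extended = build_family([
            ("FA", None, None, "male", "unaffected"),
            ("MO", None, None, "female", "unaffected"),
            ("P1", "FA", "MO", "female", "affected"),
            ("U1", None, None, "female", "unknown"),
            ("U2", None, None, "female", "affected", False),
        ])
        geno2 = dict(geno, U1=2, U2=0)
        assert segregates(variant_for(ad, geno2), extended, ad) == base


class TestCompoundHet:
    def model(self, mc=False):
        return next(m for m in COMPHET_MODELS if m.male_carriers_allowed == mc)

    def test_quartet_trans_pair_returned(self, quartet):
        v1 = build_variant({"MO": 1, "FA": 0, "P1": 1, "S1": 1}, pos=100, gene="G")
        v2 = build_variant({"MO": 0, "FA": 1, "P1": 1, "S1": 0}, pos=200, gene="G")
        pairs = compound_het_pairs([v1, v2], quartet, self.model())
        assert pairs == [(v1, v2)]

    def test_single_variant_no_pairs(self, quartet):
        v1 = build_variant({"P1": 1}, gene="G")
        assert compound_het_pairs([v1], quartet, self.model()) == []

    def test_cis_configuration_excluded(self, quartet):
        """Both variants from the mother cannot hit both copies."""
        v1 = build_variant({"MO": 1, "FA": 0, "P1": 1, "S1": 0}, pos=100, gene="G")
        v2 = build_variant({"MO": 1, "FA": 0, "P1": 1, "S1": 0}, pos=200, gene="G")
        assert compound_het_pairs([v1, v2], quartet, self.model()) == []

    def test_de_novo_plus_uniparental_accepted(self, quartet):
        v1 = build_variant({"MO": 0, "FA": 0, "P1": 1, "S1": 0}, pos=100, gene="G")
        v2 = build_variant({"MO": 1, "FA": 0, "P1": 1, "S1": 0}, pos=200, gene="G")
        assert len(compound_het_pairs([v1, v2], quartet, self.model())) == 1

    def test_unaffected_sib_with_both_variants_excludes_pair(self, quartet):
        v1 = build_variant({"MO": 1, "FA": 0, "P1": 1, "S1": 1}, pos=100, gene="G")
        v2 = build_variant({"MO": 0, "FA": 1, "P1": 1, "S1": 1}, pos=200, gene="G")
        assert compound_het_pairs([v1, v2], quartet, self.model()) == []

    def test_unaffected_brother_exempt_under_male_carriers(self):
        fam = quartet_with_brother()
        v1 = build_variant({"MO": 1, "FA": 0, "P1": 1, "B1": 1}, pos=100, gene="G")
        v2 = build_variant({"MO": 0, "FA": 1, "P1": 1, "B1": 1}, pos=200, gene="G")
        assert compound_het_pairs([v1, v2], fam, self.model()) == []
        assert len(compound_het_pairs([v1, v2], fam, self.model(mc=True))) == 1

    def test_multi_gene_input_is_error(self, quartet):
        v1 = build_variant({"P1": 1}, gene="G1")
        v2 = build_variant({"P1": 1}, gene="G2")
        with pytest.raises(InheritanceError):
            compound_het_pairs([v1, v2], quartet, self.model())

    @pytest.mark.parametrize("mc", [False, True])
    def test_oracle_equivalence_six_variants(self, mc):
        """All pairs among 6 variants vs exhaustive enumeration, many genotype draws."""
        import random

        fam = quartet_with_brother()
        members = list(fam.members)
        model = self.model(mc)
        rng = random.Random(42)
        for rep in range(60):
            dosage_maps = [
                {m: rng.choice([0, 0, 1, 1, 2, None]) for m in members}
                for _ in range(6)
            ]
            variants = [build_variant({k: v for k, v in dm.items()},
                                      pos=100 + i, gene="G")
                        for i, dm in enumerate(dosage_maps)]
            got = compound_het_pairs(variants, fam, model)
            got_idx = sorted((variants.index(a), variants.index(b)) for a, b in got)
            expected = oracle_comphet_pairs(dosage_maps, fam,
                                            model.male_carriers_allowed)
            assert got_idx == sorted(expected), (rep, dosage_maps)


class TestEvaluateFamily:
    def test_af_class_gates_models(self, trio):
        """af=0.005 fits AD segregation but only lenient-class models may test it."""
        v = build_variant({"P1": 2, "FA": 1, "MO": 1}, af=0.005)
        hits = evaluate_family([v], trio)
        assert len(hits) == 1
        assert hits[0].models_passed == {"autosomal_recessive",
                                         "autosomal_recessive_male_carriers"}

    def test_dominant_pattern_above_strict_af_yields_nothing(self, trio):
        v = build_variant({"P1": 1, "FA": 0, "MO": 0}, af=0.005)
        assert evaluate_family([v], trio) == []

    def test_empty_stream(self, trio):
        assert evaluate_family([], trio) == []

    def test_family_without_sequenced_affected_yields_no_hits(self):
        fam = build_family([
            ("FA", None, None, "male", "unaffected"),
            ("MO", None, None, "female", "unaffected"),
            ("P1", "FA", "MO", "female", "affected", False),
        ])
        v = build_variant({"FA": 0, "MO": 0})
        assert evaluate_family([v], fam) == []

    def test_comphet_pair_is_single_gene_hit_with_both_variants(self, quartet):
        v1 = build_variant({"MO": 1, "FA": 0, "P1": 1, "S1": 0}, pos=100,
                           gene="G", af=0.005)
        v2 = build_variant({"MO": 0, "FA": 1, "P1": 1, "S1": 0}, pos=200,
                           gene="G", af=0.005)
        hits = evaluate_family([v1, v2], quartet)
        comphet_hits = [h for h in hits if len(h.variants) == 2]
        assert len(comphet_hits) == 1
        assert comphet_hits[0].models_passed >= {"compound_het"}
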