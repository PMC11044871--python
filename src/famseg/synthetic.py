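"""Truth-labelled synthetic cohorts for end-to-end pipeline testing.

The study's raw exomes are not publicly deposited, so this module
generates complete stand-in inputs with the same statistical structure:
a PED + multi-sample VCF + gene→GO-term mapping for a cohort of 9
families totalling 31 sequenced individuals with 10 affected (all
affected individuals female by default, including one monozygotic twin
pair), plus a machine-readable truth table.

Three classes of variant are emitted:

* **background** variants: per-family Mendelian gene-dropping from founder
  genotypes drawn at a population allele frequency sampled from a
  mixture (point mass near zero for novel alleles plus a Beta spread
  into the common range). Most violate the rarity, deleteriousness, or
  segregation filters; the few survivors form realistic candidate-list
  noise.
* **planted** variants: one per family, cycling through the inheritance-
  model registry, with genotypes constructed to satisfy the model
  exactly and annotations passing every filter for the model's AF class.
* **decoy** variants: clones of a plant scenario that break exactly one
  rule — allele frequency, CADD, LoFtool, or segregation — with the
  broken rule recorded in the truth table. Decoys are constructed so the
  broken rule fails them under *every* model (e.g. the segregation decoy
  leaves all affecteds hom-ref).

A planted GO term contains exactly the planted genes plus padding genes
that occur in no variant, so a correct pipeline ranks it first in the
enrichment output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from famseg.inheritance import CandidateHit, InheritanceModel, default_model_registry

CHROMS = [str(c) for c in range(1, 23)] + ["X"]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pedigree templates


@dataclass(frozen=True)
class _Member:
    suffix: str
    sex: str  # "1" male / "2" female
    status: str  # "2" affected / "1" unaffected
    father: Optional[str] = None
    mother: Optional[str] = None
    twin_of: Optional[str] = None  # MZ twin: genotype vector copied


# trio: two unaffected parents + affected daughter (proband)
_TRIO = [
    _Member("FA", "1", "1"),
    _Member("MO", "2", "1"),
    _Member("P1", "2", "2", "FA", "MO"),
]
# quartet: trio + unaffected sister
_QUARTET = _TRIO + [_Member("S1", "2", "1", "FA", "MO")]
# sextet with affected monozygotic twin daughters, an unaffected sister,
# and an unaffected brother (exercises male-carrier exemptions)
_TWIN_SEXTET = [
    _Member("FA", "1", "1"),
    _Member("MO", "2", "1"),
    _Member("P1", "2", "2", "FA", "MO"),
    _Member("P2", "2", "2", "FA", "MO", twin_of="P1"),
    _Member("S1", "2", "1", "FA", "MO"),
    _Member("B1", "1", "1", "FA", "MO"),
]

TEMPLATES: dict[str, list[_Member]] = {
    "trio": _TRIO,
    "quartet": _QUARTET,
    "twin_sextet": _TWIN_SEXTET,
}

# 7 trios + 1 quartet + 1 twin sextet = 31 sequenced individuals,
# 10 affected across 9 families (the cohort shape being emulated)
DEFAULT_TEMPLATES = ["trio"] * 7 + ["quartet"] + ["twin_sextet"]


@dataclass
class PlantSpec:
    family_id: str
    gene: str
    model: str
    expected_to_survive: bool = True
    kind: str = "plant"  # "plant" | "decoy"
    broken_rule: Optional[str] = None  # decoys: "af" | "cadd" | "loftool" | "segregation"


@dataclass
class SimulationConfig:
    n_families: int = 9
    family_templates: Optional[list[str]] = None  # default: DEFAULT_TEMPLATES
    n_background_variants: int = 200
    # background annotation distributions
    frac_novel: float = 0.2  # point mass at AF 0 (absent from gnomAD)
    af_beta_a: float = 0.3
    af_beta_b: float = 3.0
    cadd_max: float = 40.0
    p_high_impact: float = 0.02
    p_filter_fail: float = 0.03
    p_missing_genotype: float = 0.01
    # plants / decoys
    plant_models: Optional[list[str]] = None  # default: cycle the registry
    decoy_rules: tuple = ("af", "cadd", "loftool", "segregation")
    # GO annotation structure
    n_terms: int = 30
    planted_term_size: int = 15
    planted_term_id: str = "GO:9999999"
    term_size_range: tuple = (5, 25)
    annotation_mode: str = "flat"  # "flat" | "csq"
    seed: int = 0

    def templates(self) -> list[str]:
        if self.family_templates is not None:
            t = self.family_templates
        elif self.n_families == 9:
            t = DEFAULT_TEMPLATES
        else:
            t = [DEFAULT_TEMPLATES[i % len(DEFAULT_TEMPLATES)] for i in range(self.n_families)]
        if len(t) != self.n_families:
            raise SimulationError("family_templates length must equal n_families")
        unknown = set(t) - set(TEMPLATES)
        if unknown:
            raise SimulationError(f"unknown templates: {sorted(unknown)}")
        return list(t)


@dataclass
class _SimVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    vid: Optional[str]
    gene: str
    impact: str
    cadd: Optional[float]
    af: Optional[float]
    loftool: Optional[float]
    filter_pass: bool
    genotypes: dict[str, tuple]  # sample -> (dosage or None, gq, dp)


@dataclass
class SimulatedCohort:
    ped_path: Path
    vcf_path: Path
    gene2term_path: Path
    truth_path: Path
    truth: list[PlantSpec]
    sample_ids: list[str]


@dataclass
class RecoveryReport:
    n_expected: int
    n_recovered: int
    missed: list[str]
    n_decoys: int
    decoys_recovered: list[str]

    @property
    def sensitivity(self) -> float:
        return 1.0 if self.n_expected == 0 else self.n_recovered / self.n_expected


# ---------------------------------------------------------------------------
# genotype construction


def _family_samples(fam_id: str, template: list[_Member]) -> list[str]:
    return [f"{fam_id}-{m.suffix}" for m in template]


def _gene_drop(template: list[_Member], fam_id: str, af: float,
               rng: np.random.Generator) -> dict[str, int]:
    """Mendelian gene-dropping: founders from Binomial(2, af), children
    inherit one random allele from each parent; MZ twins copy."""
    dosages: dict[str, int] = {}
    alleles: dict[str, tuple[int, int]] = {}
    for m in template:
        sid = f"{fam_id}-{m.suffix}"
        if m.twin_of is not None:
            alleles[m.suffix] = alleles[m.twin_of]
        elif m.father is None:
            a = (int(rng.random() < af), int(rng.random() < af))
            alleles[m.suffix] = a
        else:
            fa = alleles[m.father]
            mo = alleles[m.mother]
            alleles[m.suffix] = (fa[rng.integers(2)], mo[rng.integers(2)])
        dosages[sid] = sum(alleles[m.suffix])
    return dosages


def _plant_genotypes(template: list[_Member], fam_id: str, model: InheritanceModel,
                     which: str = "single") -> dict[str, int]:
    """Genotypes satisfying `model` exactly in this family.

    ``which`` selects the member of a compound-het pair: "maternal" or
    "paternal" (for single-variant kinds use "single").
    """
    out: dict[str, int] = {}
    has_parents = any(m.father for m in template)
    if model.kind in ("de_novo", "compound_het") and not has_parents:
        raise SimulationError(
            f"model {model.name} infeasible in a template without parents"
        )
    for m in template:
        sid = f"{fam_id}-{m.suffix}"
        affected = m.status == "2"
        male = m.sex == "1"
        if model.kind in ("dominant", "de_novo"):
            if affected:
                out[sid] = 1
            elif model.male_carriers_allowed and male:
                out[sid] = 1  # exercises the male-carrier exemption
            else:
                out[sid] = 0
        elif model.kind == "recessive_hom":
            if affected:
                out[sid] = 2
            elif m.father is None:  # parent of an affected: obligate carrier
                out[sid] = 1
            elif model.male_carriers_allowed and male:
                out[sid] = 2
            else:
                out[sid] = 1 if m.suffix.startswith("S") else 0
        elif model.kind == "compound_het":
            if affected:
                out[sid] = 1
            elif m.father is None:
                carrier_parent = "MO" if which == "maternal" else "FA"
                out[sid] = 1 if m.suffix == carrier_parent else 0
            elif model.male_carriers_allowed and male:
                # carries this member of the pair; sims never give him both
                out[sid] = 1 if which == "maternal" else 0
            else:
                out[sid] = 0
        else:  # pragma: no cover
            raise SimulationError(f"unknown kind {model.kind}")
    return out


def _strict_af(model: InheritanceModel) -> float:
    return 0.00005 if model.af_class == "strict" else 0.005


def _decoy_af(model: InheritanceModel) -> float:
    # fails the model's own class; lenient-only survival is blocked by the
    # genotype pattern (het affecteds never satisfy recessive kinds)
    return 0.002 if model.af_class == "strict" else 0.05


# ---------------------------------------------------------------------------
# file emission


def _vcf_header(samples: list[str], mode: str) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for c in CHROMS:
        lines.append(f"##contig=<ID={c}>")
    if mode == "flat":
        lines += [
            '##INFO=<ID=SYMBOL,Number=1,Type=String,Description="Gene symbol">',
            '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Consequence impact">',
            '##INFO=<ID=CADD_PHRED,Number=1,Type=Float,Description="Phred-scaled CADD">',
            '##INFO=<ID=gnomAD_AF,Number=1,Type=Float,Description="gnomAD global AF">',
            '##INFO=<ID=LoFtool,Number=1,Type=Float,Description="LoFtool percentile">',
        ]
    else:
        lines.append(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
            'Format: Allele|SYMBOL|IMPACT|CADD_PHRED|gnomAD_AF|LoFtool">'
        )
    lines += [
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.6g}"


def _variant_line(v: _SimVariant, samples: list[str], mode: str) -> str:
    if mode == "flat":
        info = [f"SYMBOL={v.gene}", f"IMPACT={v.impact}"]
        if v.cadd is not None:
            info.append(f"CADD_PHRED={v.cadd:.6g}")
        if v.af is not None:
            info.append(f"gnomAD_AF={v.af:.6g}")
        if v.loftool is not None:
            info.append(f"LoFtool={v.loftool:.6g}")
        info_str = ";".join(info)
    else:
        info_str = (f"CSQ={v.alt}|{v.gene}|{v.impact}|"
                    f"{_fmt(v.cadd)}|{_fmt(v.af)}|{_fmt(v.loftool)}")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    cells = []
    for s in samples:
        d, gq, dp = v.genotypes.get(s, (0, 99, 30))
        cells.append(f"{gt_map[d]}:{gq}:{dp}")
    return "\t".join([
        v.chrom, str(v.pos), v.vid or ".", v.ref, v.alt, "100",
        "PASS" if v.filter_pass else "LowQual", info_str, "GT:GQ:DP",
    ] + cells) + "\n"


def _chrom_sort_key(v: _SimVariant):
    return (CHROMS.index(v.chrom), v.pos, v.alt)


# ---------------------------------------------------------------------------
# main entry points


def simulate_cohort(cfg: SimulationConfig, outdir: Union[str, Path]) -> SimulatedCohort:
    """Generate PED, VCF, gene→term mapping, and truth table in ``outdir``.

    All randomness flows through ``cfg.seed``; the same config writes
    byte-identical files on every run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    registry = {m.name: m for m in default_model_registry()}
    templates = cfg.templates()
    fam_ids = [f"F{i + 1}" for i in range(cfg.n_families)]

    # --- pedigree ----------------------------------------------------------
    ped_rows = []
    samples: list[str] = []
    for fid, tname in zip(fam_ids, templates):
        for m in TEMPLATES[tname]:
            sid = f"{fid}-{m.suffix}"
            samples.append(sid)
            father = f"{fid}-{m.father}" if m.father else "0"
            mother = f"{fid}-{m.mother}" if m.mother else "0"
            ped_rows.append([fid, sid, father, mother, m.sex, m.status])

    # --- plants and decoys -------------------------------------------------
    model_names = cfg.plant_models or [list(registry)[i % len(registry)]
                                       for i in range(cfg.n_families)]
    if len(model_names) != cfg.n_families:
        raise SimulationError("plant_models length must equal n_families")
    variants: list[_SimVariant] = []
    truth: list[PlantSpec] = []
    pos_counter = {c: 1_000_000 for c in CHROMS}

    def next_pos(chrom: str) -> int:
        pos_counter[chrom] += 1_000
        return pos_counter[chrom]

    def qual_geno(dosages: dict[str, int]) -> dict[str, tuple]:
        return {s: (d, 99, 30) for s, d in dosages.items()}

    for idx, (fid, tname, mname) in enumerate(zip(fam_ids, templates, model_names)):
        if mname not in registry:
            raise SimulationError(f"plant for {fid}: unknown model {mname!r}")
        model = registry[mname]
        template = TEMPLATES[tname]
        gene = f"PG{idx + 1:02d}"
        chrom = "X" if model.scope == "x_linked" else str((idx % 22) + 1)
        af = _strict_af(model)
        common = dict(gene=gene, impact="MODERATE", cadd=25.0, af=af,
                      loftool=0.2, filter_pass=True)
        try:
            if model.kind == "compound_het":
                for which in ("maternal", "paternal"):
                    geno = _plant_genotypes(template, fid, model, which)
                    variants.append(_SimVariant(
                        chrom=chrom, pos=next_pos(chrom), ref="G", alt="A",
                        vid=None, genotypes=qual_geno(geno), **common))
            else:
                geno = _plant_genotypes(template, fid, model)
                variants.append(_SimVariant(
                    chrom=chrom, pos=next_pos(chrom), ref="G", alt="A",
                    vid=None, genotypes=qual_geno(geno), **common))
        except SimulationError as e:
            raise SimulationError(f"infeasible plant {gene} ({mname}) in {fid}: {e}") from e
        truth.append(PlantSpec(family_id=fid, gene=gene, model=mname,
                               expected_to_survive=True))

        # decoys: one per rule, each breaking exactly that rule
        for rule in cfg.decoy_rules:
            dgene = f"DG{idx + 1:02d}{rule[0].upper()}"
            dparams = dict(gene=dgene, impact="MODERATE", cadd=25.0,
                           af=_strict_af(model), loftool=0.2, filter_pass=True)
            if rule == "af":
                dparams["af"] = _decoy_af(model)
            elif rule == "cadd":
                dparams["cadd"] = 5.0
            elif rule == "loftool":
                dparams["loftool"] = 0.95
            if rule == "segregation":
                # affecteds hom-ref: fails every model's carrier requirement
                dgeno = {f"{fid}-{m.suffix}": (1 if m.suffix == "MO" else 0)
                         for m in template}
            elif model.kind == "compound_het":
                dgeno = _plant_genotypes(template, fid, model, "maternal")
            else:
                dgeno = _plant_genotypes(template, fid, model)
            variants.append(_SimVariant(
                chrom=chrom, pos=next_pos(chrom), ref="C", alt="T",
                vid=None, genotypes=qual_geno(dgeno), **dparams))
            truth.append(PlantSpec(family_id=fid, gene=dgene, model=mname,
                                   expected_to_survive=False, kind="decoy",
                                   broken_rule=rule))

    # --- background variants ----------------------------------------------
    fam_templates = dict(zip(fam_ids, templates))
    for b in range(cfg.n_background_variants):
        gene = f"BG{b + 1:04d}"
        chrom = str((b % 22) + 1)
        novel = rng.random() < cfg.frac_novel
        pop_af = 0.0 if novel else float(rng.beta(cfg.af_beta_a, cfg.af_beta_b))
        # gene-dropping frequency: novel alleles still need carriers to
        # appear in the call set at all
        drop_af = max(pop_af, 0.05)
        impact = "HIGH" if rng.random() < cfg.p_high_impact else \
            str(rng.choice(["MODERATE", "LOW", "MODIFIER"], p=[0.5, 0.3, 0.2]))
        cadd = float(rng.uniform(0.0, cfg.cadd_max))
        loftool = float(rng.uniform(0.0, 1.0))
        filter_pass = rng.random() >= cfg.p_filter_fail
        genotypes: dict[str, tuple] = {}
        for fid in fam_ids:
            dosages = _gene_drop(TEMPLATES[fam_templates[fid]], fid, drop_af, rng)
            for sid, d in dosages.items():
                if rng.random() < cfg.p_missing_genotype:
                    genotypes[sid] = (None, 99, 30)
                elif rng.random() < 0.02:
                    genotypes[sid] = (d, int(rng.integers(0, 20)), 30)  # low GQ
                else:
                    genotypes[sid] = (d, 99, 30)
        variants.append(_SimVariant(
            chrom=chrom, pos=next_pos(chrom), ref="A", alt="G", vid=None,
            gene=gene, impact=impact, cadd=cadd,
            af=None if novel else pop_af, loftool=loftool,
            filter_pass=filter_pass, genotypes=genotypes))

    # --- write files -------------------------------------------------------
    ped_path = outdir / "cohort.ped"
    with open(ped_path, "w") as fh:
        for row in ped_rows:
            fh.write("\t".join(row) + "\n")

    vcf_path = outdir / "cohort.vcf"
    variants.sort(key=_chrom_sort_key)
    with open(vcf_path, "w") as fh:
        fh.write(_vcf_header(samples, cfg.annotation_mode))
        for v in variants:
            fh.write(_variant_line(v, samples, cfg.annotation_mode))

    gene2term_path = outdir / "gene2term.tsv"
    _write_gene2term(cfg, fam_ids, rng, gene2term_path)

    truth_path = outdir / "truth.tsv"
    write_truth(truth, truth_path)
    return SimulatedCohort(ped_path=ped_path, vcf_path=vcf_path,
                           gene2term_path=gene2term_path, truth_path=truth_path,
                           truth=truth, sample_ids=samples)


def _write_gene2term(cfg: SimulationConfig, fam_ids: list[str],
                     rng: np.random.Generator, path: Path) -> None:
    plant_genes = [f"PG{i + 1:02d}" for i in range(len(fam_ids))]
    bg_genes = [f"BG{b + 1:04d}" for b in range(cfg.n_background_variants)]
    n_pad = max(0, cfg.planted_term_size - len(plant_genes))
    pad_genes = [f"PAD{i + 1:03d}" for i in range(n_pad)]
    rows = []
    for g in plant_genes + pad_genes:
        rows.append((cfg.planted_term_id, "molecular_function", g, "planted term"))
    lo, hi = cfg.term_size_range
    cats = ["molecular_function", "biological_process", "cellular_component"]
    for t in range(cfg.n_terms):
        tid = f"GO:{t + 1:07d}"
        cat = cats[t % 3]
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(len(bg_genes), size=min(size, len(bg_genes)), replace=False)
        for gi in sorted(genes):
            rows.append((tid, cat, bg_genes[gi], f"background term {t + 1}"))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(r) + "\n")


def write_truth(truth: Sequence[PlantSpec], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["kind", "family_id", "gene", "model",
                    "expected_to_survive", "broken_rule"])
        for t in truth:
            w.writerow([t.kind, t.family_id, t.gene, t.model,
                        str(t.expected_to_survive), t.broken_rule or "."])


def read_truth(path: Union[str, Path]) -> list[PlantSpec]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(PlantSpec(
                family_id=row["family_id"], gene=row["gene"], model=row["model"],
                expected_to_survive=row["expected_to_survive"] == "True",
                kind=row["kind"],
                broken_rule=None if row["broken_rule"] == "." else row["broken_rule"],
            ))
    return out


def verify_truth(pipeline_output: Sequence[CandidateHit],
                 truth: Sequence[PlantSpec]) -> RecoveryReport:
    """Score pipeline output against the simulator's truth table.

    A plant is recovered when some hit in its family and gene lists the
    plant's model among its passing models; a decoy counts as recovered
    if *any* hit matches its family and gene. A noise-free configuration
    must score sensitivity 1.0 with zero decoys recovered.
    """
    by_fam_gene: dict[tuple[str, str], set[str]] = {}
    for hit in pipeline_output:
        by_fam_gene.setdefault((hit.family_id, hit.gene), set()).update(hit.models_passed)
    missed, decoys_hit = [], []
    n_expected = n_recovered = n_decoys = 0
    for t in truth:
        models = by_fam_gene.get((t.family_id, t.gene))
        if t.kind == "decoy":
            n_decoys += 1
            if models:
                decoys_hit.append(t.gene)
        elif t.expected_to_survive:
            n_expected += 1
            if models and t.model in models:
                n_recovered += 1
            else:
                missed.append(f"{t.family_id}:{t.gene}:{t.model}")
    return RecoveryReport(n_expected=n_expected, n_recovered=n_recovered,
                          missed=missed, n_decoys=n_decoys,
                          decoys_recovered=decoys_hit)
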