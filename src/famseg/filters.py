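"""Variant-quality, rarity, LoF-tolerance, and deleteriousness filters.

The annotation filters encode the study's tiered thresholds:

* gnomAD global allele frequency < 1e-4 for dominant / de novo model
  classes ("strict") and < 1e-2 for recessive / compound-heterozygous
  classes ("lenient"); comparisons are strict ``<``.
* LoFtool percentile < 0.9: variants in the 10% of genes most tolerant to
  loss of function are removed.
* Phred-scaled CADD >= 15, except that HIGH-impact variants are retained
  regardless of CADD score.

Missing-value policy (each piece configurable): a variant absent from
gnomAD is treated as frequency 0 (absence from a population database is
evidence of rarity); a missing CADD score fails the deleteriousness
filter unless the impact is HIGH (absence of a score is not evidence of
deleteriousness); a missing LoFtool percentile passes (no evidence of
LoF tolerance).

All filters are pure predicates; only :func:`quality_filter` touches the
record, demoting low-confidence genotypes (GQ/DP below threshold) to
missing, so it must run before segregation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from famseg.variant_model import GenotypeCall, Impact, VariantRecord

MODEL_CLASSES = ("strict", "lenient")


class FilterError(ValueError):
    pass


@dataclass
class FilterConfig:
    af_threshold_strict: float = 0.0001
    af_threshold_lenient: float = 0.01
    loftool_max: float = 0.9
    cadd_min: float = 15.0
    min_gq: int = 20
    min_dp: int = 10
    require_filter_pass: bool = True
    # missing-value policy toggles
    missing_af_is_rare: bool = True
    missing_cadd_fails: bool = True
    missing_loftool_passes: bool = True

    def __post_init__(self):
        if not (0.0 <= self.af_threshold_strict <= self.af_threshold_lenient <= 1.0):
            raise FilterError(
                "need 0 <= af_threshold_strict <= af_threshold_lenient <= 1, got "
                f"{self.af_threshold_strict} / {self.af_threshold_lenient}"
            )

    def af_threshold(self, model_class: str) -> float:
        if model_class == "strict":
            return self.af_threshold_strict
        if model_class == "lenient":
            return self.af_threshold_lenient
        raise FilterError(f"unknown model class {model_class!r}")


def quality_filter(v: VariantRecord, cfg: FilterConfig) -> Optional[VariantRecord]:
    """Site- and genotype-level quality control.

    Returns None (record dropped) if the record fails the VCF FILTER
    column and ``require_filter_pass`` is set. Otherwise returns the
    record with genotypes whose GQ or DP fall below threshold demoted to
    missing — the call is considered unreliable rather than wrong, so it
    imposes no segregation constraint.
    """
    if cfg.require_filter_pass and not v.filter_pass:
        return None
    demoted = {}
    changed = False
    for sample, call in v.genotypes.items():
        if call.missing:
            demoted[sample] = call
            continue
        bad_gq = call.quality is not None and call.quality < cfg.min_gq
        bad_dp = call.depth is not None and call.depth < cfg.min_dp
        if bad_gq or bad_dp:
            demoted[sample] = GenotypeCall(allele_count=None,
                                           quality=call.quality, depth=call.depth)
            changed = True
        else:
            demoted[sample] = call
    return replace(v, genotypes=demoted) if changed else v


def rarity_filter(af: Optional[float], model_class: str, cfg: FilterConfig) -> bool:
    """True iff the allele frequency is below the model class threshold.

    ``af`` may be None (variant absent from gnomAD): under the default
    policy that is mapped to frequency 0.0 before comparison; with
    ``missing_af_is_rare=False`` it fails outright.
    """
    if af is None:
        if not cfg.missing_af_is_rare:
            return False
        af = 0.0
    if not (0.0 <= af <= 1.0):
        raise FilterError(f"allele frequency out of [0,1]: {af}")
    return af < cfg.af_threshold(model_class)


def loftool_filter(score: Optional[float], cfg: FilterConfig) -> bool:
    """True (keep) iff the gene is not in the most LoF-tolerant tail.

    Higher LoFtool percentile = more tolerant of loss of function; scores
    at or above ``loftool_max`` (default 0.9, the most tolerant 10%) are
    removed. A missing score passes by default.
    """
    if score is None:
        return cfg.missing_loftool_passes
    if not (0.0 <= score <= 1.0):
        raise FilterError(f"LoFtool percentile out of [0,1]: {score}")
    return score < cfg.loftool_max


def deleteriousness_filter(cadd: Optional[float], impact: Impact, cfg: FilterConfig) -> bool:
    """True iff predicted deleterious: CADD >= threshold, or HIGH impact.

    HIGH-impact consequences are retained regardless of CADD score.
    """
    if impact is Impact.HIGH:
        return True
    if cadd is None:
        return not cfg.missing_cadd_fails
    return cadd >= cfg.cadd_min


def annotation_filters(v: VariantRecord, model_class: str, cfg: FilterConfig) -> bool:
    """Conjunction of rarity, LoFtool, and deleteriousness for one class.

    The three predicates are independent, so their order is immaterial.
    """
    ann = v.annotation
    return (rarity_filter(ann.gnomad_af, model_class, cfg)
            and loftool_filter(ann.loftool, cfg)
            and deleteriousness_filter(ann.cadd_phred, ann.impact, cfg))
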