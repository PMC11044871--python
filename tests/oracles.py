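"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each rule from its plain-language statement
in a different style from the package code (allowed-set membership and
exact rational arithmetic instead of predicate short-circuiting and
log-space sums), so agreement is meaningful.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

from famseg.pedigree import Family, Sex, Status


def effective(d, ind, on_x):
    """Oracle's view of a dosage: None = unconstraining."""
    if d is None or not ind.sequenced:
        return None
    if on_x and ind.sex is Sex.MALE and d == 1:
        return None  # inconsistent diploid het in a male on X
    return d


def oracle_segregates(dosages: dict, fam: Family, kind: str,
                      male_carriers: bool, on_x: bool) -> bool:
    """Truth-table check of a single-variant model via allowed-dosage sets."""
    for ind in fam.members.values():
        d = effective(dosages.get(ind.individual_id), ind, on_x)
        if d is None or ind.status is Status.UNKNOWN:
            continue
        if ind.status is Status.AFFECTED:
            allowed = {2} if kind == "recessive_hom" else {1, 2}
        else:
            if male_carriers and ind.sex is Sex.MALE:
                allowed = {0, 1, 2}
            elif kind == "recessive_hom":
                allowed = {0, 1}
            else:
                allowed = {0}
        if d not in allowed:
            return False
    if kind == "de_novo":
        for ind in fam.members.values():
            if ind.status is not Status.AFFECTED:
                continue
            d = effective(dosages.get(ind.individual_id), ind, on_x)
            if d not in (1, 2):
                continue
            fa = fam.members.get(ind.father_id) if ind.father_id else None
            mo = fam.members.get(ind.mother_id) if ind.mother_id else None
            if fa is None or mo is None:
                continue
            if effective(dosages.get(fa.individual_id), fa, on_x) == 0 and \
               effective(dosages.get(mo.individual_id), mo, on_x) == 0:
                return True
        return False
    return True


def oracle_comphet_pairs(variant_dosages: list, fam: Family,
                         male_carriers: bool) -> list:
    """Exhaustive pair enumeration under the stated compound-het rule.

    variant_dosages: list of dicts sample -> dosage. Returns index pairs.
    """
    ok = []
    for i, j in combinations(range(len(variant_dosages)), 2):
        if _pair_ok(variant_dosages[i], variant_dosages[j], fam, male_carriers):
            ok.append((i, j))
    return ok


def _origins(d_child, d_fa, d_mo):
    fa_has = d_fa is not None and d_fa > 0
    mo_has = d_mo is not None and d_mo > 0
    if mo_has and d_fa == 0:
        return "M"
    if fa_has and d_mo == 0:
        return "F"
    if d_fa == 0 and d_mo == 0:
        return "N"  # de novo
    return "?"


def _pair_ok(g1, g2, fam, male_carriers):
    for ind in fam.members.values():
        if not ind.sequenced or ind.status is Status.UNKNOWN:
            continue
        d1, d2 = g1.get(ind.individual_id), g2.get(ind.individual_id)
        if ind.status is Status.AFFECTED:
            for d in (d1, d2):
                if d is not None and d != 1:
                    return False
            if d1 == 1 and d2 == 1 and ind.father_id and ind.mother_id:
                fa = fam.members.get(ind.father_id)
                mo = fam.members.get(ind.mother_id)
                if fa is None or mo is None or not (fa.sequenced and mo.sequenced):
                    continue
                vals = (g1.get(fa.individual_id), g1.get(mo.individual_id),
                        g2.get(fa.individual_id), g2.get(mo.individual_id))
                if any(v is None for v in vals):
                    continue
                o1 = _origins(d1, vals[0], vals[1])
                o2 = _origins(d2, vals[2], vals[3])
                allowed = {("M", "F"), ("F", "M"), ("N", "M"), ("N", "F"),
                           ("M", "N"), ("F", "N")}
                if (o1, o2) not in allowed:
                    return False
        else:
            if male_carriers and ind.sex is Sex.MALE:
                continue
            if d1 is not None and d1 > 0 and d2 is not None and d2 > 0:
                return False
    return True


def oracle_hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Exact rational upper tail, summed with integer binomials."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def oracle_hypergeom_sf_table(N: int, K: int, n: int) -> list:
    """Exact P(X >= k) for k = 0..min(K,n), via a suffix sum of the pmf."""
    denom = comb(N, n)
    hi = min(K, n)
    pmf = [Fraction(comb(K, i) * comb(N - K, n - i), denom)
           if n - i <= N - K else Fraction(0) for i in range(hi + 1)]
    out = [Fraction(0)] * (hi + 1)
    acc = Fraction(0)
    for i in range(hi, -1, -1):
        acc += pmf[i]
        out[i] = acc
    return [float(x) for x in out]
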