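"""Gene Ontology overrepresentation by hypergeometric test with BH FDR.

Given a query set of candidate genes and a gene→term mapping, each term
is tested with the upper-tail hypergeometric probability

    P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the background size (by default all genes appearing in the
annotation), K the term size within the background, n the query size
within the background, and k the overlap. The tail sum is accumulated in
log-space via log-gamma binomial coefficients, so tiny p-values keep full
relative precision. Benjamini–Hochberg adjustment is applied within each
GO category separately by default (molecular function, biological
process, cellular component), mirroring per-category reporting; a joint
mode is available.

No ontology-graph propagation is performed: a gene annotated to a child
term is not automatically added to its ancestors, so the statistic is
exactly the hypergeometric test on the provided sets. Users wanting
propagated results should pre-propagate the mapping file.

The reported ``ratio`` is k / K: the fraction of a term's genes that
appear in the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np

CATEGORIES = ("molecular_function", "biological_process", "cellular_component")

# GAF column 9 aspect codes
_GAF_ASPECT = {"F": "molecular_function", "P": "biological_process",
               "C": "cellular_component"}


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetAnnotation:
    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise EnrichmentError(f"term {self.term_id} has no genes")
        if self.category not in CATEGORIES:
            raise EnrichmentError(f"unknown category {self.category!r}")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    term_size: int  # K
    background_size: int  # N
    query_size: int  # n
    overlap: int  # k
    ratio: float  # k / K
    p_raw: float
    p_adjusted: float
    significant: bool


def hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Direct log-space summation of C(K,i) C(N-K, n-i) / C(N, n) for
    i = k .. min(K, n). Exact at k = 0 (returns 1.0).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise EnrichmentError(
            f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}"
        )
    if k == 0:
        return 1.0
    lo = max(k, n - (N - K))
    hi = min(K, n)
    denom = _log_comb(N, n)
    log_terms = [_log_comb(K, i) + _log_comb(N - K, n - i) - denom
                 for i in range(lo, hi + 1)]
    m = max(log_terms)
    total = m + math.log(sum(math.exp(t - m) for t in log_terms))
    return min(1.0, math.exp(total))


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = list(p)
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise EnrichmentError("p-values must lie in [0,1]")
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted.tolist()


def read_gene2term(source: Union[str, Path, IO[str]]) -> list[GeneSetAnnotation]:
    """Read a gene→term mapping from TSV or GAF 2.x.

    The TSV dialect is 3+ columns: term_id, category, gene[, term_name];
    category may be a full name or a GAF aspect letter (F/P/C). GAF files
    are detected by the ``!gaf-version`` header and use columns 3 (gene
    symbol), 5 (GO ID), and 9 (aspect).
    """
    close = False
    if isinstance(source, (str, Path)):
        source = open(source)
        close = True
    try:
        lines = source.read().splitlines()
    finally:
        if close:
            source.close()
    is_gaf = bool(lines) and lines[0].startswith("!gaf-version")
    terms: dict[str, dict] = {}
    for line in lines:
        if not line.strip() or line.startswith(("!", "#")):
            continue
        fields = line.rstrip("\n").split("\t")
        if is_gaf:
            if len(fields) < 9:
                continue
            gene, term_id, aspect = fields[2], fields[4], fields[8]
            category = _GAF_ASPECT.get(aspect)
            if category is None:
                continue
            name = term_id
        else:
            if len(fields) < 3:
                raise EnrichmentError(f"bad gene2term row: {line!r}")
            term_id, category, gene = fields[0], fields[1], fields[2]
            category = _GAF_ASPECT.get(category, category)
            name = fields[3] if len(fields) > 3 else term_id
        entry = terms.setdefault(term_id, {"category": category, "name": name,
                                           "genes": set()})
        entry["genes"].add(gene)
    return [GeneSetAnnotation(term_id=tid, term_name=e["name"],
                              category=e["category"], genes=frozenset(e["genes"]))
            for tid, e in sorted(terms.items())]


def enrich(query_genes: Iterable[str], annotations: Sequence[GeneSetAnnotation],
           alpha: float = 0.05, min_overlap: int = 2,
           background: Optional[Iterable[str]] = None,
           fdr_scope: str = "per_category") -> list[EnrichmentResult]:
    """Test every annotated term for overrepresentation in the query.

    Background defaults to the union of all annotated genes; the query is
    intersected with it. Terms whose overlap with the query falls below
    ``min_overlap`` are not tested (single-gene overlaps are untestable
    noise). FDR is controlled within each category separately
    (``fdr_scope="per_category"``, the default) or jointly
    (``fdr_scope="joint"``). Results are sorted by adjusted p, then raw
    p, then term_id.
    """
    query = set(query_genes)
    if not query:
        raise EnrichmentError("empty query gene set")
    if fdr_scope not in ("per_category", "joint"):
        raise EnrichmentError(f"unknown fdr_scope {fdr_scope!r}")
    bg = set(background) if background is not None else \
        set().union(*(t.genes for t in annotations)) if annotations else set()
    if not bg:
        raise EnrichmentError("empty background gene set")
    q = query & bg
    n = len(q)
    N = len(bg)
    tested: list[EnrichmentResult] = []
    for term in annotations:
        term_genes = term.genes & bg
        K = len(term_genes)
        k = len(q & term_genes)
        if K == 0 or k < min_overlap:
            continue
        p = hypergeom_sf(N, K, n, k)
        tested.append(EnrichmentResult(
            term_id=term.term_id, term_name=term.term_name, category=term.category,
            term_size=K, background_size=N, query_size=n, overlap=k,
            ratio=k / K, p_raw=p, p_adjusted=float("nan"), significant=False,
        ))
    if fdr_scope == "per_category":
        for cat in CATEGORIES:
            group = [r for r in tested if r.category == cat]
            _apply_bh(group, alpha)
    else:
        _apply_bh(tested, alpha)
    tested.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    return tested


def _apply_bh(results: list[EnrichmentResult], alpha: float) -> None:
    if not results:
        return
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = q
        r.significant = q <= alpha


def write_enrichment(results: Sequence[EnrichmentResult], sink: IO[str]) -> None:
    sink.write("term_id\tterm_name\tcategory\tterm_size\tbackground_size\t"
               "query_size\toverlap\tratio\tp_raw\tp_adjusted\tsignificant\n")
    for r in results:
        sink.write("\t".join([
            r.term_id, r.term_name, r.category, str(r.term_size),
            str(r.background_size), str(r.query_size), str(r.overlap),
            f"{r.ratio:.6g}", f"{r.p_raw:.6g}", f"{r.p_adjusted:.6g}",
            str(r.significant),
        ]) + "\n")
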