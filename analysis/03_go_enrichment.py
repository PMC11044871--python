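"""Hypergeometric GO overrepresentation of the candidate gene set.

Tests every annotated term against the candidate genes (background = all
annotated genes), adjusts with Benjamini-Hochberg within each GO
category, and reports terms passing adjusted p <= 0.05.
"""

from pathlib import Path

from famseg.enrichment import write_enrichment
from famseg.pipeline import enrich_candidates

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genes = [g for g in (RESULTS / "candidate_genes.txt").read_text().split() if g]
    results = enrich_candidates(genes, RESULTS / "cohort" / "gene2term.tsv")
    with open(RESULTS / "enrichment.tsv", "w") as fh:
        write_enrichment(results, fh)
    sig = [r for r in results if r.significant]
    print(f"{len(results)} terms tested, {len(sig)} significant (adjusted p <= 0.05)")
    for r in sig:
        print(f"  {r.term_id} [{r.category}] ratio={r.overlap}/{r.term_size} "
              f"p_adj={r.p_adjusted:.3g}")


if __name__ == "__main__":
    main()
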