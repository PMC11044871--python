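"""Run segregation filtering and cross-family aggregation on the cohort.

Applies quality control, then for each family evaluates every variant
under the 11-model inheritance registry with the tiered rarity
(1e-4 dominant/de novo, 1e-2 recessive/compound-het), LoFtool (<0.9) and
CADD (>=15, HIGH-impact rescued) filters. Writes the candidate table,
per-gene recurrence, and the study-level summary.
"""

import json
from pathlib import Path

from famseg.aggregate import write_gene_table, write_summary
from famseg.pipeline import prioritize
from famseg.variant_model import write_candidates

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT = RESULTS / "cohort"


def main() -> None:
    res = prioritize(COHORT / "cohort.ped", COHORT / "cohort.vcf")
    with open(RESULTS / "candidates.tsv", "w") as fh:
        write_candidates(res.hits, fh)
    with open(RESULTS / "gene_recurrence.tsv", "w") as fh:
        write_gene_table(res.gene_recurrence, fh)
    with open(RESULTS / "summary.json", "w") as fh:
        write_summary(res.summary, fh)
    with open(RESULTS / "candidate_genes.txt", "w") as fh:
        fh.write("\n".join(sorted(res.candidate_genes)) + "\n")
    print(json.dumps(res.summary.to_dict(), indent=2))
    print(f"{len(res.hits)} hits -> {RESULTS/'candidates.tsv'}")


if __name__ == "__main__":
    main()
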