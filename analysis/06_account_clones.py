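"""Cohort set accounting: status matrix, recurrence, Venn regions, clustering.

Builds the ternary variant x sample status matrix (mutated / not mutated /
not covered), the PT recurrence histogram, the PT/CTC/CDX Venn partition
with integer percentages, and the VAF-based PCA + Ward/cosine clustering of
the samples.  Writes tables and a JSON partition report under results/.
"""

import argparse
import json
import sys
import warnings
from pathlib import Path

from ctclineage import pipeline as pl
from ctclineage import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()
    warnings.filterwarnings("ignore")

    cohort = read_cohort(args.cohort)
    variant_stage = pl.run_variant_stage(cohort)
    stage = pl.run_accounting_stage(cohort, variant_stage)

    matrix = stage.status_matrix.copy()
    matrix.index = [f"{c}:{p}:{r}:{a}" for c, p, r, a in matrix.index]
    matrix.to_csv(ROOT / "results" / "status_matrix.tsv", sep="\t")
    stage.pca.to_csv(ROOT / "results" / "sample_pca.tsv", sep="\t")

    v = stage.venn
    from ctclineage.accounting import percent_round_half_up
    report = {
        "universe": int(v.universe_size),
        "regions": {"+".join(sorted(r)): int(c)
                    for r, c in v.region_counts.items()},
        "pt_recurrence": {int(k): int(n) for k, n in stage.pt_recurrence.items()},
        "pt_total": int(stage.pt_total),
        "pt_single_specimen_pct": (
            percent_round_half_up(stage.pt_recurrence[1], stage.pt_total)
            if stage.pt_total else None),
    }
    (ROOT / "results" / "venn_partition.json").write_text(
        json.dumps(report, indent=1))

    print("status matrix -> results/status_matrix.tsv; "
          "partition -> results/venn_partition.json")
    print(f"  universe of {v.universe_size} variants; regions:")
    for r, c in sorted(v.region_counts.items(), key=lambda x: -x[1]):
        print(f"    {'+'.join(sorted(r)):<14} {c}")
    print(f"  PT recurrence: total {stage.pt_total}, "
          f"{stage.pt_recurrence[1]} private to one specimen")
    return 0


if __name__ == "__main__":
    sys.exit(main())
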