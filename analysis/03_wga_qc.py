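"""WGA artifact estimation: allele drop-out and false-positive rates.

ADO is measured by comparing germline het variants against the CD45-pool
WGA product (Fisher exact, VAF collapse); the per-pool FPR counts calls
absent from primary tumor and CDX per Mb covered >= 8x.  Writes
results/wga_qc.tsv.
"""

import argparse
import sys
import warnings
from pathlib import Path

import pandas as pd

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
    stage = pl.run_wga_stage(cohort, variant_stage)

    rows = [{"metric": "ado_rate", "sample_id": "cd45",
             "value": round(stage.ado_rate, 4),
             "n": len(stage.ado_assessments)}]
    for s, est in stage.fpr.items():
        rows.append({"metric": "fpr_per_mb", "sample_id": s,
                     "value": round(est.fpr_per_mb, 2),
                     "n": est.n_false_positive_events})
    out = ROOT / "results" / "wga_qc.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)

    print(f"WGA QC written to {out}")
    print(f"  ADO rate (CD45 vs germline): {stage.ado_rate:.3f} "
          f"over {len(stage.ado_assessments)} het sites "
          f"(simulated truth {cohort.config.ado_rate})")
    for s, est in stage.fpr.items():
        print(f"  {s}: {est.fpr_per_mb:.1f} false positives/Mb "
              f"({est.n_false_positive_events} events, "
              f"{est.covered_bases_ge8/1e6:.1f} Mb >= 8x)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
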