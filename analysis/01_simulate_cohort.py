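"""Simulate the study-scale cohort and write it as an on-disk fixture.

Generates, under results/cohort/, a cohort with known clonal ground truth:
germline + CD45 controls, 8 primary-tumor specimens (purity 0.6), 6
WGA-amplified pools of 5 CTCs (ADO 0.2, ~14 spurious calls/Mb, 10% locus
dropout), a tetraploid (WGD) CDX and its cell line — as a multi-sample VCF,
per-sample SNP count TSVs, coverage BEDs, a sample sheet and truth JSON.
"""

import argparse
import sys
from pathlib import Path

from ctclineage import SimulationConfig, simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()

    cohort = simulate_cohort(SimulationConfig(seed=args.seed))
    out = write_cohort(cohort, args.out)

    n_true = (cohort.variants["branch"] != "").sum()
    n_fp = (cohort.variants["branch"] == "").sum()
    print(f"cohort written to {out}")
    print(f"  samples: {len(cohort.samples)} "
          f"({cohort.samples['is_wga'].sum()} WGA)")
    print(f"  somatic variants: {n_true} true, {n_fp} injected artifacts")
    print(f"  het SNPs per sample: {len(cohort.snp_tables['germline'])}")
    print(f"  CNAs: " + ", ".join(
        f"{b}:{len(c)}" for b, c in cohort.truth.branch_cnas.items()))
    return 0


if __name__ == "__main__":
    sys.exit(main())
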