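"""Maximum-parsimony phylogeny of the tumor samples with branch assignment.

Encodes non-silent variants present in >= 2 samples as binary characters
(present = VAF > 0) plus an all-zero germline outgroup, searches tree space
with the parsimony ratchet, maps copy-number aberrations onto the tree post
hoc, and assigns every alteration to the branch whose downstream samples
equal its presence set.  Writes the Newick tree and the branch table.
"""

import argparse
import sys
import warnings
from pathlib import Path

from ctclineage import pipeline as pl
from ctclineage import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    warnings.filterwarnings("ignore")

    cohort = read_cohort(args.cohort)
    variant_stage = pl.run_variant_stage(cohort)
    cna_stage = pl.run_cna_stage(cohort)
    rescue = pl.run_rescue_stage(cohort, cna_stage)
    stage = pl.run_phylo_stage(cohort, variant_stage, rescue, cna_stage,
                               seed=args.seed)

    (ROOT / "results" / "tree.nwk").write_text(stage.tree.newick() + "\n")
    stage.branch_assignments.to_csv(ROOT / "results" / "branch_assignments.tsv",
                                    sep="\t", index=False)

    print(f"tree (score {stage.tree.score:.0f}) -> results/tree.nwk")
    print(f"  {stage.tree.newick()}")
    counts = (stage.branch_assignments
              .groupby(["branch", "kind"]).size().unstack(fill_value=0))
    print("branch alteration counts (SNVs and CNAs listed separately):")
    print(counts.to_string())
    n_homo = (stage.branch_assignments["branch"] == "homoplastic").sum()
    print(f"  {n_homo} alterations homoplastic (mostly ADO-affected cells)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
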