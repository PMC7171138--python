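"""On-disk cohort fixtures: multi-sample VCF, SNP count TSVs, truth JSON.

One simulated (or real) cohort round-trips losslessly through this module:
``write_cohort`` emits a VCFv4.2 file with per-sample DP/AD/FT/QS tags, one
SNP read-count TSV per sample, per-sample >=8x coverage masks as BED, a
sample sheet and the ground-truth JSON; ``read_cohort`` restores the same
in-memory :class:`~ctclineage.simulate.Cohort`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import Cohort, SimulationConfig, TruthRecord

VCF_NAME = "cohort.vcf"
SHEET_NAME = "samples.tsv"
TRUTH_NAME = "truth.json"
CONFIG_NAME = "config.json"


def _vcf_header(cohort: Cohort) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, size in cohort.chrom_sizes.items():
        header.contigs.add(chrom, length=size)
    header.add_meta("INFO", items=[("ID", "CSQCLASS"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "Consequence class")])
    header.add_meta("INFO", items=[("ID", "DRIVER"), ("Number", "0"),
                                   ("Type", "Flag"),
                                   ("Description", "Driver annotation")])
    header.add_meta("INFO", items=[("ID", "BRANCH"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "Simulated branch")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"),
                                     ("Type", "Integer"),
                                     ("Description", "Read depth")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"),
                                     ("Type", "Integer"),
                                     ("Description", "Allelic depths")])
    header.add_meta("FORMAT", items=[("ID", "FT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Per-sample caller filter")])
    header.add_meta("FORMAT", items=[("ID", "QS"), ("Number", "1"),
                                     ("Type", "Integer"),
                                     ("Description", "Base-quality sum score")])
    for s in cohort.samples["sample_id"]:
        header.add_sample(s)
    return header


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort fixture; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort.samples.to_csv(out / SHEET_NAME, sep="\t", index=False)

    obs = cohort.observations.set_index(["variant_id", "sample_id"])
    sample_ids = list(cohort.samples["sample_id"])
    variants = cohort.variants.sort_values(["chrom", "pos"], kind="stable")
    with pysam.VariantFile(str(out / VCF_NAME), "w",
                           header=_vcf_header(cohort)) as vcf:
        for v in variants.itertuples(index=False):
            rec = vcf.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            rec.info["CSQCLASS"] = v.consequence_class
            if v.is_driver:
                rec.info["DRIVER"] = True
            if v.branch:
                rec.info["BRANCH"] = v.branch
            rec.filter.add("PASS")
            for s in sample_ids:
                o = obs.loc[(v.variant_id, s)]
                rec.samples[s]["DP"] = int(o["depth"])
                rec.samples[s]["AD"] = (int(o["depth"]) - int(o["alt_count"]),
                                        int(o["alt_count"]))
                rec.samples[s]["FT"] = str(o["filter_flag"])
                rec.samples[s]["QS"] = int(o["qss"])
            vcf.write(rec)

    for s, table in cohort.snp_tables.items():
        table.to_csv(out / f"snp_counts_{s}.tsv", sep="\t", index=False)
    for s, mask in cohort.coverage_masks.items():
        mask.to_csv(out / f"coverage_{s}.bed", sep="\t", index=False,
                    header=False)

    truth = cohort.truth
    truth_json = {
        "clone_parent": truth.clone_parent,
        "branch_snvs": truth.branch_snvs,
        "branch_cnas": truth.branch_cnas,
        "sample_composition": truth.sample_composition,
        "wgd_clone": truth.wgd_clone,
        "per_variant_truth": truth.per_variant_truth.to_dict(orient="list"),
    }
    (out / TRUTH_NAME).write_text(json.dumps(truth_json, indent=1))
    cfg = dataclasses.asdict(cohort.config)
    cfg["fp_vaf_range"] = list(cfg["fp_vaf_range"])
    (out / CONFIG_NAME).write_text(json.dumps(cfg, indent=1))
    (out / "chrom_sizes.json").write_text(json.dumps(cohort.chrom_sizes))
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read back a cohort fixture written by :func:`write_cohort`."""
    d = Path(in_dir)
    samples = pd.read_csv(d / SHEET_NAME, sep="\t")
    samples["is_wga"] = samples["is_wga"].astype(bool)
    chrom_sizes = json.loads((d / "chrom_sizes.json").read_text())

    cfg_raw = json.loads((d / CONFIG_NAME).read_text())
    cfg_raw["fp_vaf_range"] = tuple(cfg_raw["fp_vaf_range"])
    config = SimulationConfig(**cfg_raw)

    var_rows, obs_rows = [], []
    sample_ids = list(samples["sample_id"])
    with pysam.VariantFile(str(d / VCF_NAME)) as vcf:
        for rec in vcf:
            ref, alt = rec.alleles
            vid = f"{rec.contig}:{rec.pos}:{ref}:{alt}"
            var_rows.append({
                "chrom": rec.contig, "pos": rec.pos, "ref": ref, "alt": alt,
                "branch": rec.info.get("BRANCH", ""),
                "consequence_class": rec.info["CSQCLASS"],
                "is_driver": "DRIVER" in rec.info,
                "variant_id": vid,
            })
            for s in sample_ids:
                fmt = rec.samples[s]
                flag = fmt["FT"]
                obs_rows.append({
                    "variant_id": vid, "sample_id": s,
                    "depth": int(fmt["DP"]), "alt_count": int(fmt["AD"][1]),
                    "filter_flag": flag, "qss": int(fmt["QS"]),
                    "called": flag != "NOCALL",
                })
    variants = pd.DataFrame(var_rows)
    observations = pd.DataFrame(obs_rows)

    snp_tables = {}
    coverage_masks = {}
    for s in sample_ids:
        snp_tables[s] = pd.read_csv(d / f"snp_counts_{s}.tsv", sep="\t")
        coverage_masks[s] = pd.read_csv(
            d / f"coverage_{s}.bed", sep="\t", header=None,
            names=["chrom", "start", "end"])

    t = json.loads((d / TRUTH_NAME).read_text())
    truth = TruthRecord(
        clone_parent={k: (v if v is not None else None)
                      for k, v in t["clone_parent"].items()},
        branch_snvs=t["branch_snvs"],
        branch_cnas=t["branch_cnas"],
        sample_composition=t["sample_composition"],
        per_variant_truth=pd.DataFrame(t["per_variant_truth"]),
        wgd_clone=t["wgd_clone"],
    )
    return Cohort(config=config, truth=truth, samples=samples,
                  variants=variants, observations=observations,
                  snp_tables=snp_tables, coverage_masks=coverage_masks,
                  chrom_sizes=chrom_sizes)
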