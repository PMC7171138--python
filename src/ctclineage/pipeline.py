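"""End-to-end orchestration of the comparative genomic analysis.

Runs, on a cohort (simulated or read from a fixture directory), the full
chain: somatic post-filtering with low-VAF rescue and the high-confidence
CTC rule; WGA quality control (ADO against the CD45 control, per-pool FPR);
allele-specific copy-number calling on the bulk samples; allelic-imbalance
rescue of known aberrations in the CTC pools; cohort set-accounting; and the
maximum-parsimony sample phylogeny with branch-assigned alterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import accounting, cna, filtering, imbalance, phylo, wga_qc
from .filtering import FilterPolicy
from .simulate import Cohort

GERMLINE = "germline"
CD45 = "cd45"
COVERED_DEPTH = 8


def _key_df(variants: pd.DataFrame) -> pd.DataFrame:
    return variants[["variant_id", "chrom", "pos", "ref", "alt",
                     "consequence_class"]]


def candidate_table(cohort: Cohort, sample: str) -> pd.DataFrame:
    """Caller-level candidates of one tumor sample, paired with the normal."""
    obs = cohort.observations
    tum = obs.loc[(obs["sample_id"] == sample) & obs["called"]]
    norm = obs.loc[obs["sample_id"] == GERMLINE,
                   ["variant_id", "depth", "alt_count"]]
    m = tum.merge(norm, on="variant_id", suffixes=("", "_normal"))
    m = m.merge(_key_df(cohort.variants), on="variant_id")
    return pd.DataFrame({
        "chrom": m["chrom"], "pos": m["pos"], "ref": m["ref"], "alt": m["alt"],
        "filter_flag": m["filter_flag"], "qss": m["qss"],
        "tumor_depth": m["depth"], "tumor_alt": m["alt_count"],
        "normal_depth": m["depth_normal"], "normal_alt": m["alt_count_normal"],
    })


@dataclass
class VariantStage:
    primary_calls: dict            # sample -> set of (chrom,pos,ref,alt)
    augmented_calls: dict          # after low-VAF rescue
    rescue_audit: pd.DataFrame
    pt_union: set
    cdx_set: set
    hc_ctc: dict                   # pool -> high-confidence set
    final_calls: dict              # per tumor sample, incl. rescue and HC rule
    vaf_matrix: pd.DataFrame       # variant_id x tumor sample, 0 if not called


def run_variant_stage(cohort: Cohort,
                      policy: FilterPolicy | None = None) -> VariantStage:
    policy = policy or FilterPolicy()
    tumor = cohort.tumor_samples
    roles = dict(zip(cohort.samples["sample_id"], cohort.samples["role"]))

    primary = {}
    for s in tumor:
        filt = filtering.apply_somatic_filters(candidate_table(cohort, s), policy)
        kept = filt.loc[filt["retained"]]
        primary[s] = set(zip(kept["chrom"], kept["pos"], kept["ref"], kept["alt"]))

    # read counts at adequately covered sites only; below 8x a site counts as
    # not covered and is never rescued
    obs = cohort.observations.merge(_key_df(cohort.variants), on="variant_id")
    rc = obs.loc[obs["depth"] >= COVERED_DEPTH,
                 ["chrom", "pos", "ref", "alt", "sample_id", "depth", "alt_count"]]
    augmented, audit = filtering.rescue_low_vaf(
        primary, rc, tumor, GERMLINE, policy)

    pt_samples = [s for s in tumor if roles[s] == "pt"]
    ctc_samples = [s for s in tumor if roles[s] == "ctc"]
    pt_union = set().union(*(augmented[s] for s in pt_samples)) if pt_samples else set()
    cdx_set = augmented.get("cdx", set()) | augmented.get("cell_line", set())

    # the "one other CTC pool" criterion is evaluated on raw per-pool calls
    hc_ctc, _ = filtering.high_confidence_ctc_set(
        {s: primary[s] for s in ctc_samples}, pt_union, cdx_set)

    final = {}
    for s in tumor:
        if roles[s] == "ctc":
            rescued_here = augmented[s] - primary[s]
            final[s] = hc_ctc[s] | rescued_here
        else:
            final[s] = augmented[s]

    keys = cohort.variants.set_index("variant_id")
    universe = sorted(set().union(*final.values()))
    vid_of = {(r.chrom, r.pos, r.ref, r.alt): r.Index
              for r in keys.itertuples()}
    vaf_obs = obs.set_index(["variant_id", "sample_id"])
    mat = {}
    for s in tumor:
        col = []
        for k in universe:
            vid = vid_of[k]
            if k in final[s]:
                o = vaf_obs.loc[(vid, s)]
                col.append(o["alt_count"] / o["depth"] if o["depth"] > 0 else 0.0)
            else:
                col.append(0.0)
        mat[s] = col
    vaf_matrix = pd.DataFrame(mat, index=[vid_of[k] for k in universe])
    return VariantStage(primary, augmented, audit, pt_union, cdx_set,
                        hc_ctc, final, vaf_matrix)


# ---------------------------------------------------------------------------
# WGA QC


def ado_counts_table(cohort: Cohort, wga_sample: str = CD45) -> pd.DataFrame:
    g = cohort.snp_tables[GERMLINE]
    w = cohort.snp_tables[wga_sample]
    m = g.merge(w, on=["chrom", "pos"], suffixes=("_g", "_w"))
    return pd.DataFrame({
        "chrom": m["chrom"], "pos": m["pos"],
        "germ_ref": m["ref_count_g"], "germ_alt": m["alt_count_g"],
        "wga_ref": m["ref_count_w"], "wga_alt": m["alt_count_w"],
        "gq": m["gq"],
    })


@dataclass
class WgaStage:
    ado_assessments: pd.DataFrame
    ado_rate: float
    fpr: dict  # sample -> FprEstimate


def run_wga_stage(cohort: Cohort, stage: VariantStage) -> WgaStage:
    eligible = wga_qc.select_reliable_germline_variants(ado_counts_table(cohort))
    assessments, ado_rate = wga_qc.estimate_ado(eligible)
    roles = dict(zip(cohort.samples["sample_id"], cohort.samples["role"]))
    fpr = {}
    for s in cohort.tumor_samples:
        if roles[s] != "ctc":
            continue
        fpr[s] = wga_qc.estimate_fpr(
            stage.primary_calls[s], stage.pt_union, stage.cdx_set,
            cohort.coverage_masks[s], sample_id=s)
    return WgaStage(assessments, ado_rate, fpr)


# ---------------------------------------------------------------------------
# Copy number


def germline_het_mask(cohort: Cohort, min_depth: int = COVERED_DEPTH,
                      vaf_band: tuple = (0.2, 0.8)) -> pd.DataFrame:
    """Germline-heterozygous SNPs (chrom, pos) usable for LRR/BAF."""
    g = cohort.snp_tables[GERMLINE]
    depth = g["ref_count"] + g["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, g["alt_count"] / depth, 0.0)
    keep = (depth >= min_depth) & (vaf >= vaf_band[0]) & (vaf <= vaf_band[1])
    return g.loc[keep, ["chrom", "pos"]].copy()


def snp_pair_table(cohort: Cohort, tumor_sample: str,
                   het: pd.DataFrame | None = None) -> pd.DataFrame:
    het = het if het is not None else germline_het_mask(cohort)
    t = cohort.snp_tables[tumor_sample]
    g = cohort.snp_tables[GERMLINE]
    m = het.merge(t, on=["chrom", "pos"]).merge(
        g, on=["chrom", "pos"], suffixes=("_t", "_g"))
    return pd.DataFrame({
        "chrom": m["chrom"], "pos": m["pos"],
        "tumor_ref": m["ref_count_t"], "tumor_alt": m["alt_count_t"],
        "normal_ref": m["ref_count_g"], "normal_alt": m["alt_count_g"],
    })


def sample_baf_track(cohort: Cohort, sample: str,
                     het: pd.DataFrame | None = None) -> pd.DataFrame:
    """``chrom, pos, baf, depth`` at germline-het SNPs for one sample."""
    het = het if het is not None else germline_het_mask(cohort)
    t = het.merge(cohort.snp_tables[sample], on=["chrom", "pos"])
    depth = (t["ref_count"] + t["alt_count"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(depth > 0, t["alt_count"] / depth, 0.5)
    return pd.DataFrame({"chrom": t["chrom"], "pos": t["pos"],
                         "baf": baf, "depth": depth})


@dataclass
class CnaStage:
    by_sample: dict = field(default_factory=dict)
    # sample -> {"track", "segments", "fit", "calls"}


def run_cna_stage(cohort: Cohort, samples: list[str] | None = None,
                  **segment_kwargs) -> CnaStage:
    roles = dict(zip(cohort.samples["sample_id"], cohort.samples["role"]))
    if samples is None:
        samples = [s for s in cohort.tumor_samples
                   if roles[s] in ("pt", "cdx", "cell_line")]
    het = germline_het_mask(cohort)
    out = CnaStage()
    for s in samples:
        track = cna.compute_lrr_baf(snp_pair_table(cohort, s, het))
        segments = cna.segment_genome(track, **segment_kwargs)
        fit, with_cn = cna.fit_ploidy_purity(segments)
        calls = cna.classify_segments(with_cn, fit)
        calls.insert(0, "sample_id", s)
        out.by_sample[s] = {"track": track, "segments": segments,
                            "fit": fit, "calls": calls}
    return out


# ---------------------------------------------------------------------------
# CTC aberration rescue


@dataclass
class RescueStage:
    catalog: pd.DataFrame
    presence: pd.DataFrame          # aberration x CTC sample
    assessments: list


def run_rescue_stage(cohort: Cohort, cna_stage: CnaStage,
                     reference_order: tuple = ("cell_line", "cdx"),
                     **score_kwargs) -> RescueStage:
    """Score every catalogued aberration in every CTC pool.

    The aberration catalog is the cross-sample-matched set of non-neutral or
    LOH segments of the bulk samples; for each aberration the BAF direction
    reference is the highest-priority carrier sample (cell line, then CDX,
    then the PT specimen that called it).
    """
    roles = dict(zip(cohort.samples["sample_id"], cohort.samples["role"]))
    all_calls = pd.concat(
        [d["calls"] for d in cna_stage.by_sample.values()], ignore_index=True)
    aberrant = all_calls.loc[(all_calls["klass"] != cna.NEUTRAL)
                             | all_calls["loh"]].reset_index(drop=True)
    if len(aberrant) == 0:
        raise ValueError("empty aberration catalog")
    matched = accounting.match_aberrations(aberrant)

    priority = {s: i for i, s in enumerate(reference_order)}
    cat_rows = []
    for ab_id, grp in matched.groupby("aberration_id"):
        grp = grp.sort_values(
            "sample_id", key=lambda c: c.map(lambda s: priority.get(s, 99)))
        rep = grp.iloc[0]
        cat_rows.append({"aberration_id": ab_id, "chrom": rep["chrom"],
                         "start": rep["start"], "end": rep["end"],
                         "klass": rep["klass"], "loh": rep["loh"],
                         "ref_sample": rep["sample_id"],
                         "n_samples": grp["sample_id"].nunique()})
    catalog = pd.DataFrame(cat_rows)

    het = germline_het_mask(cohort)
    ctc_samples = [s for s in cohort.tumor_samples if roles[s] == "ctc"]
    ctc_tracks = {s: sample_baf_track(cohort, s, het) for s in ctc_samples}

    parts = []
    assessments = []
    for ref_sample, grp in catalog.groupby("ref_sample"):
        ref_track = sample_baf_track(cohort, ref_sample, het)
        calls = cna_stage.by_sample[ref_sample]["calls"]
        neutral = calls.loc[(calls["klass"] == cna.NEUTRAL) & ~calls["loh"],
                            ["chrom", "start", "end"]]
        mat, ass = imbalance.rescue_all(grp, ref_track, ctc_tracks, neutral,
                                        **score_kwargs)
        parts.append(mat)
        assessments.extend(ass)
    presence = pd.concat(parts)
    presence = presence.reindex(index=catalog["aberration_id"])
    return RescueStage(catalog, presence, assessments)


# ---------------------------------------------------------------------------
# Accounting + phylogeny


@dataclass
class AccountingStage:
    status_matrix: pd.DataFrame
    venn: accounting.VennPartition
    pt_recurrence: pd.Series
    pt_total: int
    pca: pd.DataFrame
    linkage: np.ndarray


def run_accounting_stage(cohort: Cohort, stage: VariantStage) -> AccountingStage:
    roles = dict(zip(cohort.samples["sample_id"], cohort.samples["role"]))
    tumor = cohort.tumor_samples
    keys = cohort.variants.set_index("variant_id")
    vid_of = {(r.chrom, r.pos, r.ref, r.alt): r.Index for r in keys.itertuples()}

    universe = sorted(set().union(*stage.final_calls.values()))
    depth = cohort.observations.set_index(["variant_id", "sample_id"])["depth"]

    def depth_lookup(key, sample):
        return float(depth.loc[(vid_of[key], sample)])

    matrix = accounting.build_status_matrix(
        universe, {s: stage.final_calls[s] for s in tumor}, depth_lookup)

    groups = {
        "PT": [s for s in tumor if roles[s] == "pt"],
        "CTC": [s for s in tumor if roles[s] == "ctc"],
        "CDX": [s for s in tumor if roles[s] in ("cdx", "cell_line")],
    }
    venn = accounting.venn_partition(matrix, groups)
    hist, total = accounting.recurrence_histogram(matrix, groups["PT"])
    pca, link = accounting.cluster_samples_by_vaf(stage.vaf_matrix)
    return AccountingStage(matrix, venn, hist, total, pca, link)


@dataclass
class PhyloStage:
    character_matrix: pd.DataFrame
    cna_matrix: pd.DataFrame | None
    tree: phylo.PhyloTree
    branch_assignments: pd.DataFrame


def run_phylo_stage(cohort: Cohort, stage: VariantStage,
                    rescue: RescueStage | None = None,
                    cna_stage: CnaStage | None = None,
                    iterations: int = 60, seed: int = 0) -> PhyloStage:
    consequence = dict(zip(cohort.variants["variant_id"],
                           cohort.variants["consequence_class"]))
    vafs = stage.vaf_matrix.copy()
    vafs[GERMLINE] = 0.0
    chars = phylo.build_character_matrix(vafs, consequence)
    tree = phylo.parsimony_ratchet(chars, iterations=iterations, seed=seed)

    cna_matrix = None
    if rescue is not None and cna_stage is not None:
        bulk = {s: d["calls"] for s, d in cna_stage.by_sample.items()}
        rows = {}
        for ab in rescue.catalog.itertuples(index=False):
            iv = (ab.chrom, ab.start, ab.end)
            row = {}
            for s, calls in bulk.items():
                hit = any(
                    c.klass == ab.klass
                    and accounting.reciprocal_overlap(
                        iv, (c.chrom, c.start, c.end)) >= 0.5
                    for c in calls.itertuples(index=False))
                row[s] = int(hit)
            for s in rescue.presence.columns:
                row[s] = int(rescue.presence.loc[ab.aberration_id, s]
                             == imbalance.PRESENT)
            rows[ab.aberration_id] = row
        cna_matrix = pd.DataFrame(rows).T
        cna_matrix = cna_matrix.loc[cna_matrix.sum(axis=1) >= 2]

    assignments = phylo.assign_branch_alterations(
        tree, chars, cna_matrix, outgroup=GERMLINE)
    return PhyloStage(chars, cna_matrix, tree, assignments)


@dataclass
class PipelineResult:
    variant: VariantStage
    wga: WgaStage
    cna: CnaStage
    rescue: RescueStage
    accounting: AccountingStage
    phylogeny: PhyloStage


def run_pipeline(cohort: Cohort, policy: FilterPolicy | None = None,
                 ratchet_iterations: int = 60, seed: int = 0) -> PipelineResult:
    """Run every analysis stage on a cohort and bundle the results."""
    variant = run_variant_stage(cohort, policy)
    wga = run_wga_stage(cohort, variant)
    cna_stage = run_cna_stage(cohort)
    rescue = run_rescue_stage(cohort, cna_stage)
    acct = run_accounting_stage(cohort, variant)
    phy = run_phylo_stage(cohort, variant, rescue, cna_stage,
                          iterations=ratchet_iterations, seed=seed)
    return PipelineResult(variant, wga, cna_stage, rescue, acct, phy)
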