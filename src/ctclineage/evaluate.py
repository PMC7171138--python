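"""Truth-comparison utilities for simulated cohorts.

Given a cohort with ground truth and a pipeline result, these helpers
measure recovery: sensitivity of the allelic-imbalance rescue for truncal
aberrations, its false-call rate over truly neutral regions, and the set of
artifact-free variant rows on which pipeline output is expected to equal
the truth exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import imbalance
from . import pipeline as pl
from .accounting import reciprocal_overlap
from .pipeline import PipelineResult
from .simulate import Cohort


def match_catalog_entry(catalog: pd.DataFrame, truth_cna: dict) -> str | None:
    """Catalog aberration id matching a truth CNA at >= 50% reciprocal overlap."""
    best, best_ov = None, 0.0
    for ab in catalog.itertuples(index=False):
        ov = reciprocal_overlap(
            (ab.chrom, ab.start, ab.end),
            (truth_cna["chrom"], truth_cna["start"], truth_cna["end"]))
        if ov > best_ov:
            best, best_ov = ab.aberration_id, ov
    return best if best_ov >= 0.5 else None


def truncal_cna_rescue_sensitivity(cohort: Cohort,
                                   result: PipelineResult) -> tuple[float, int]:
    """Fraction of (truncal CNA, CTC pool) pairs scored present."""
    rs = result.rescue
    hits = total = 0
    for c in cohort.truth.branch_cnas.get("trunk", []):
        ab = match_catalog_entry(rs.catalog, c)
        if ab is None:
            continue
        row = rs.presence.loc[ab]
        hits += int((row == imbalance.PRESENT).sum())
        total += len(row)
    return (hits / total if total else float("nan")), total


def neutral_false_call_rate(cohort: Cohort, result: PipelineResult,
                            reference: str = "cell_line",
                            min_snps: int = 30) -> tuple[float, int]:
    """Present-rate of pseudo-aberrations scored over truly neutral regions.

    Neutral non-LOH segments of the reference sample are scored in every CTC
    pool as if they were aberrations, taking the raw sign of the reference
    BAF as the direction; under the null this should fire at most at the
    test's alpha.
    """
    het = pl.germline_het_mask(cohort)
    ref = pl.sample_baf_track(cohort, reference, het)
    calls = result.cna.by_sample[reference]["calls"]
    neutral = calls.loc[(calls["klass"] == "neutral") & ~calls["loh"]]
    ctc_tracks = {s: pl.sample_baf_track(cohort, s, het)
                  for s in cohort.tumor_samples if s.startswith("ctc")}
    false_calls = evaluable = 0
    for r in neutral.itertuples(index=False):
        if r.n_snps < min_snps:
            continue
        for s, track in ctc_tracks.items():
            paired = imbalance._paired(ref, track)
            seg = imbalance._snps_in(paired, r.chrom, r.start, r.end)
            bg_parts = [imbalance._snps_in(paired, q.chrom, q.start, q.end)
                        for q in neutral.itertuples(index=False)
                        if (q.chrom, q.start) != (r.chrom, r.start)]
            bg = pd.concat(bg_parts, ignore_index=True)
            seg = seg.assign(ref_baf=np.where(seg["ref_baf"] >= 0.5,
                                              0.75, 0.25))
            a = imbalance.score_aberration_in_ctc(seg, bg)
            if a.evaluable:
                evaluable += 1
                false_calls += int(a.present)
    return (false_calls / evaluable if evaluable else float("nan")), evaluable


def clean_variant_rows(cohort: Cohort, universe_ids) -> dict[str, set]:
    """Artifact-free variant ids mapped to their truth carrier samples.

    A row is artifact-free when it is untouched by ADO and injected false
    positives and every truth carrier shows unambiguous call evidence
    (depth >= 20, >= 5 alt reads, VAF >= 0.05).
    """
    truth = cohort.truth.per_variant_truth
    affected = set(truth.loc[truth["ado_dropped"] | truth["false_positive"],
                             "variant_id"])
    pvt = truth.set_index(["variant_id", "sample_id"])
    obs = cohort.observations.set_index(["variant_id", "sample_id"])
    tumor = cohort.tumor_samples
    clean = {}
    for vid in universe_ids:
        if vid in affected:
            continue
        carriers = {s for s in tumor if pvt.loc[(vid, s), "truly_present"]}
        ok = all(obs.loc[(vid, s), "depth"] >= 20
                 and obs.loc[(vid, s), "alt_count"] >= 5
                 and (obs.loc[(vid, s), "alt_count"]
                      / obs.loc[(vid, s), "depth"]) >= 0.05
                 for s in carriers)
        if ok:
            clean[vid] = carriers
    return clean
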