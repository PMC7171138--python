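"""Whole-genome-amplification quality control: ADO and false-positive rate.

WGA of few-cell inputs (CTC pools, CD45 control pools) loses one allele of a
heterozygous site at an appreciable rate (allele drop-out, ADO) and creates
spurious low-VAF calls (false positives).  Both artifact rates are estimated
per sample:

* **ADO** — germline heterozygous variants reliably genotyped in bulk
  germline DNA are compared with their read counts in the WGA product of
  known-normal cells (the CD45+ pool).  A site has dropped out when the
  allele ratio differs significantly (two-sided Fisher exact test, p < 0.05),
  the germline VAF lies in [0.2, 0.8] and the WGA VAF is < 0.1 or > 0.9.
* **FPR** — every call in a WGA sample absent from both the primary-tumor
  union and the CDX is conservatively counted as a false positive; the count
  is divided by the megabases of target covered >= 8x in that sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ADO_P_THRESHOLD = 0.05
ADO_GERMLINE_VAF = (0.2, 0.8)
ADO_WGA_VAF = (0.1, 0.9)


def select_reliable_germline_variants(
    counts: pd.DataFrame,
    min_depth: int = 8,
    min_alt_reads: int = 5,
    min_vaf: float = 0.05,
    min_gq: int = 30,
) -> pd.DataFrame:
    """Select germline variants eligible for ADO assessment.

    ``counts`` has one row per variant with paired read counts
    ``germ_ref, germ_alt, wga_ref, wga_alt`` and the germline genotype
    quality ``gq``.  A variant is eligible when coverage is >= ``min_depth``
    in both samples and the germline call shows >= ``min_alt_reads`` alt
    reads amounting to >= ``min_vaf`` of reads, with ``gq`` >= ``min_gq``.
    All boundaries are inclusive.
    """
    germ_depth = counts["germ_ref"] + counts["germ_alt"]
    wga_depth = counts["wga_ref"] + counts["wga_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        germ_vaf = np.where(germ_depth > 0, counts["germ_alt"] / germ_depth, 0.0)
    keep = (
        (germ_depth >= min_depth)
        & (wga_depth >= min_depth)
        & (counts["germ_alt"] >= min_alt_reads)
        & (germ_vaf >= min_vaf)
        & (counts["gq"] >= min_gq)
    )
    return counts.loc[keep].copy()


def estimate_ado(eligible: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Assess ADO per eligible germline variant and return the overall rate.

    For each variant the 2x2 table ``[[germ_ref, germ_alt], [wga_ref,
    wga_alt]]`` is tested with a two-sided Fisher exact test.  A variant is
    scored as dropped out when p < 0.05, the germline VAF is in [0.2, 0.8]
    and the WGA VAF is < 0.1 or > 0.9.  Sites with zero total reads in either
    sample are skipped with a warning.

    Returns
    -------
    ``(assessments, ado_rate)`` — per-variant table with ``fisher_p``,
    ``germline_vaf``, ``wga_vaf`` and ``is_ado``; the rate is
    ``is_ado.sum() / n_assessed``.
    """
    if len(eligible) == 0:
        raise ValueError("no eligible variants for ADO estimation")
    rows = []
    for row in eligible.itertuples(index=False):
        g_tot = row.germ_ref + row.germ_alt
        w_tot = row.wga_ref + row.wga_alt
        if g_tot == 0 or w_tot == 0:
            warnings.warn(
                f"skipping site with zero reads (germline {g_tot}, wga {w_tot})",
                stacklevel=2)
            continue
        table = [[row.germ_ref, row.germ_alt], [row.wga_ref, row.wga_alt]]
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        g_vaf = row.germ_alt / g_tot
        w_vaf = row.wga_alt / w_tot
        is_ado = (
            p < ADO_P_THRESHOLD
            and ADO_GERMLINE_VAF[0] <= g_vaf <= ADO_GERMLINE_VAF[1]
            and (w_vaf < ADO_WGA_VAF[0] or w_vaf > ADO_WGA_VAF[1])
        )
        rec = {"fisher_p": p, "germline_vaf": g_vaf, "wga_vaf": w_vaf,
               "is_ado": is_ado}
        for k in ("chrom", "pos", "ref", "alt"):
            if hasattr(row, k):
                rec[k] = getattr(row, k)
        rows.append(rec)
    assessments = pd.DataFrame(rows)
    if len(assessments) == 0:
        raise ValueError("all sites skipped: no assessable variants")
    ado_rate = float(assessments["is_ado"].mean())
    return assessments, ado_rate


@dataclass(frozen=True)
class FprEstimate:
    """Per-sample false-positive rate of a WGA sample."""

    sample_id: str
    n_false_positive_events: int
    covered_bases_ge8: int
    fpr_per_mb: float


def covered_bases(coverage_mask: pd.DataFrame) -> int:
    """Total bases in a BED-style mask (0-based half-open ``start``/``end``)."""
    if len(coverage_mask) == 0:
        return 0
    return int((coverage_mask["end"] - coverage_mask["start"]).sum())


def estimate_fpr(
    wga_sample_calls: set,
    pt_union: set,
    cdx_set: set,
    coverage_mask: pd.DataFrame,
    sample_id: str = "",
) -> FprEstimate:
    """Conservative per-Mb false-positive rate of one WGA sample.

    Every call absent from both the primary-tumor union and the CDX set is
    counted as a (potential) false positive; the count is divided by the
    megabases covered >= 8x, given as a BED-style mask.
    """
    bases = covered_bases(coverage_mask)
    if bases == 0:
        raise ValueError(
            f"sample {sample_id!r}: no bases covered >=8x; FPR undefined")
    n_fp = len(set(wga_sample_calls) - set(pt_union) - set(cdx_set))
    return FprEstimate(
        sample_id=sample_id,
        n_false_positive_events=n_fp,
        covered_bases_ge8=bases,
        fpr_per_mb=n_fp / (bases / 1e6),
    )
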