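"""Somatic variant post-filtering for tumor/normal pairs.

Candidate calls (e.g. from a MuTect2-style caller) are reduced to a reliable
somatic set by hard thresholds on caller flag, coverage, base-quality sum,
tumor VAF/alt-read support and normal contamination.  Two companion steps
recover sensitivity lost to those thresholds: a low-VAF rescue that re-admits
variants independently confirmed in at least two tumor samples, and a
high-confidence rule for WGA-amplified CTC pools that discards calls private
to a single pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: canonical key identifying a variant across samples
VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the somatic post-filter and the low-VAF rescue.

    Defaults are the operating point used throughout: coverage >= 8 in tumor
    and matched normal, QSS >= 30, tumor VAF >= 0.05 with >= 5 alt reads,
    zero alt reads in the normal, and caller flag PASS or t_lod_fstar.
    """

    min_depth: int = 8
    min_qss: float = 30.0
    min_vaft: float = 0.05
    min_alt_reads: int = 5
    max_vafn: float = 0.0
    accepted_flags: frozenset = field(
        default_factory=lambda: frozenset({"PASS", "t_lod_fstar"})
    )
    rescue_min_samples: int = 2
    rescue_min_alt_reads: int = 2
    rescue_min_vaf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_qss", "min_vaft", "min_alt_reads",
                     "max_vafn", "rescue_min_samples", "rescue_min_alt_reads",
                     "rescue_min_vaf"):
            if getattr(self, name) < 0:
                raise ValueError(f"FilterPolicy.{name} must be non-negative")


# rejection reasons, in the order the rules are applied
REASON_FLAG = "filter_flag"
REASON_BLACKLIST = "caller_blacklist"
REASON_COVERAGE = "insufficient coverage"
REASON_QSS = "low_qss"
REASON_VAFT = "low_vaft"
REASON_ALT_READS = "few_alt_reads"
REASON_VAFN = "normal_contamination"


def apply_somatic_filters(
    candidates: pd.DataFrame, policy: FilterPolicy | None = None
) -> pd.DataFrame:
    """Apply the somatic post-filter to a table of candidate calls.

    Parameters
    ----------
    candidates
        One row per candidate with columns ``chrom, pos, ref, alt,
        filter_flag, tumor_depth, tumor_alt, qss, normal_depth, normal_alt``
        and optionally ``caller_blacklist`` (bool).
    policy
        Thresholds; defaults to :class:`FilterPolicy`.

    Returns
    -------
    A copy of ``candidates`` with boolean ``retained`` and string ``reason``
    columns; ``reason`` is the first failing rule, or ``"PASS"``.
    """
    policy = policy or FilterPolicy()
    df = candidates.copy()
    if "caller_blacklist" not in df.columns:
        df["caller_blacklist"] = False

    tumor_depth = df["tumor_depth"].to_numpy(float)
    tumor_alt = df["tumor_alt"].to_numpy(float)
    normal_depth = df["normal_depth"].to_numpy(float)
    normal_alt = df["normal_alt"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaft = np.where(tumor_depth > 0, tumor_alt / tumor_depth, 0.0)
        vafn = np.where(normal_depth > 0, normal_alt / normal_depth, 0.0)

    conditions = [
        ~df["filter_flag"].isin(policy.accepted_flags).to_numpy(),
        df["caller_blacklist"].to_numpy(bool),
        (tumor_depth < policy.min_depth) | (normal_depth < policy.min_depth),
        df["qss"].to_numpy(float) < policy.min_qss,
        vaft < policy.min_vaft,
        tumor_alt < policy.min_alt_reads,
        vafn > policy.max_vafn,
    ]
    reasons = [REASON_FLAG, REASON_BLACKLIST, REASON_COVERAGE, REASON_QSS,
               REASON_VAFT, REASON_ALT_READS, REASON_VAFN]
    df["reason"] = np.select(conditions, reasons, default="PASS")
    df["reason"] = df["reason"].astype(str)
    df["retained"] = df["reason"] == "PASS"
    return df


def _as_key(row) -> tuple:
    return (row.chrom, row.pos, row.ref, row.alt)


def rescue_low_vaf(
    calls_by_sample: Mapping[str, set],
    readcounts: pd.DataFrame,
    tumor_samples: Iterable[str],
    normal_sample: str,
    policy: FilterPolicy | None = None,
) -> tuple[dict[str, set], pd.DataFrame]:
    """Re-admit low-VAF variants confirmed in at least two tumor samples.

    A variant passing the primary filter in >= ``rescue_min_samples`` tumor
    samples is added to every other tumor sample in which the read counts show
    supporting evidence (>= ``rescue_min_alt_reads`` alt reads at VAF >=
    ``rescue_min_vaf``) and the matched normal carries zero alt reads.
    A sample with no read-count entry at the site is recorded as
    ``not_covered`` and never rescued.

    Parameters
    ----------
    calls_by_sample
        Post-filter call sets, ``sample -> set of (chrom, pos, ref, alt)``.
    readcounts
        Long table ``chrom, pos, ref, alt, sample_id, depth, alt_count``
        covering every queried (variant, sample) pair that was sequenced.

    Returns
    -------
    ``(augmented_calls, audit)`` where ``augmented_calls`` maps each tumor
    sample to its calls including rescued ones and ``audit`` lists every
    evaluated (variant, sample) pair with its status
    (``rescued`` / ``no_support`` / ``not_covered`` / ``normal_contaminated``).
    """
    policy = policy or FilterPolicy()
    tumor_samples = list(tumor_samples)

    counts: dict[tuple, dict[str, tuple[int, int]]] = {}
    for row in readcounts.itertuples(index=False):
        counts.setdefault(_as_key(row), {})[row.sample_id] = (
            int(row.depth), int(row.alt_count))

    support: dict[tuple, int] = {}
    for sample in tumor_samples:
        for key in calls_by_sample.get(sample, set()):
            support[key] = support.get(key, 0) + 1
    shared = {k for k, n in support.items() if n >= policy.rescue_min_samples}

    augmented = {s: set(calls_by_sample.get(s, set())) for s in tumor_samples}
    records = []
    for key in sorted(shared):
        per_sample = counts.get(key, {})
        n_depth, n_alt = per_sample.get(normal_sample, (0, 0))
        for sample in tumor_samples:
            if key in augmented[sample]:
                continue
            if sample not in per_sample:
                status = "not_covered"
            elif n_alt > 0:
                status = "normal_contaminated"
            else:
                depth, alt = per_sample[sample]
                vaf = alt / depth if depth > 0 else 0.0
                if alt >= policy.rescue_min_alt_reads and vaf >= policy.rescue_min_vaf:
                    status = "rescued"
                    augmented[sample].add(key)
                else:
                    status = "no_support"
            records.append(
                {"chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                 "sample_id": sample, "status": status})
    audit = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "sample_id", "status"])
    return augmented, audit


def high_confidence_ctc_set(
    ctc_calls: Mapping[str, set],
    pt_union: set,
    cdx_set: set,
) -> tuple[dict[str, set], set]:
    """High-confidence variant filter for WGA-amplified CTC pools.

    A call in a CTC pool is high-confidence iff it is present in at least one
    primary-tumor specimen, or in the CDX, or in at least one *other* CTC
    pool.  Calls private to a single pool are discarded (they are dominated by
    WGA false positives).

    Returns the per-pool high-confidence sets and their union.
    """
    out: dict[str, set] = {}
    for pool, calls in ctc_calls.items():
        other = set()
        for p, c in ctc_calls.items():
            if p != pool:
                other |= c
        out[pool] = {v for v in calls
                     if v in pt_union or v in cdx_set or v in other}
    union = set().union(*out.values()) if out else set()
    return out, union
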