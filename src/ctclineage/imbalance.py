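"""Rescue of copy-number aberrations in noisy WGA samples via allelic imbalance.

Per-SNP LRR/BAF profiles of WGA-amplified CTC pools are too noisy for direct
segmentation, but an aberration already called in a cleaner sample (CDX, cell
line, primary tumor) leaves a recoverable fingerprint: inside the aberrant
segment the CTC BAFs should deviate from 0.5 *in the same direction* as the
reference sample's BAFs, SNP by SNP, because both samples lost/gained the
same parental haplotype.  WGA allele drop-out also pushes BAFs away from
0.5, but in a random direction per SNP.

For each (aberration, CTC sample) pair we therefore count consistent and
discordant SNPs inside the segment and compare them, by a one-sided Fisher
exact test, against the same counts over background SNPs drawn from regions
called copy-neutral without LOH in the reference — which measures that CTC
sample's own noise floor.  An aberration is present when p < 0.05 with
>= 80 % consistent SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PRESENT = "present"
ABSENT = "absent"
NOT_EVALUABLE = "not_evaluable"

P_THRESHOLD = 0.05
MIN_FRACTION_CONSISTENT = 0.8


@dataclass(frozen=True)
class ImbalanceAssessment:
    """Consistency of one CTC sample's BAFs with one known aberration."""

    aberration_id: str
    ctc_sample_id: str
    n_consistent: int
    n_discordant: int
    fisher_p: float
    fraction_consistent: float
    present: bool
    evaluable: bool
    lrr_only: bool = False

    @property
    def status(self) -> str:
        if not self.evaluable:
            return NOT_EVALUABLE
        return PRESENT if self.present else ABSENT


def _directions(baf: np.ndarray, depth: np.ndarray,
                min_dev: float, min_depth: int) -> np.ndarray:
    """Per-SNP imbalance direction: +1/-1 if informative, 0 otherwise."""
    dev = baf - 0.5
    informative = (np.abs(dev) > min_dev) & (depth >= min_depth)
    return np.where(informative, np.sign(dev), 0.0)


def _background_counts(
    background: pd.DataFrame, min_dev: float, min_depth: int
) -> tuple[int, int]:
    """Consistent/discordant counts over copy-neutral background SNPs.

    In the background the reference sample has no true imbalance, so its BAF
    sign at each SNP is pure noise; agreement of the CTC sign with it is a
    coin flip under the null.  The raw reference sign (no deviation
    threshold) is used, which keeps the counts invariant under mirroring
    all BAFs.
    """
    ctc_dir = _directions(background["ctc_baf"].to_numpy(float),
                          background["ctc_depth"].to_numpy(float),
                          min_dev, min_depth)
    ref_dir = np.sign(background["ref_baf"].to_numpy(float) - 0.5)
    usable = (ctc_dir != 0) & (ref_dir != 0)
    cons = int(np.sum(usable & (ctc_dir == ref_dir)))
    disc = int(np.sum(usable & (ctc_dir != ref_dir)))
    return cons, disc


def score_aberration_in_ctc(
    segment_snps: pd.DataFrame,
    background_snps: pd.DataFrame,
    aberration_id: str = "",
    ctc_sample_id: str = "",
    min_dev: float = 0.1,
    min_depth: int = 10,
    p_threshold: float = P_THRESHOLD,
    min_fraction: float = MIN_FRACTION_CONSISTENT,
) -> ImbalanceAssessment:
    """Test one known aberration for presence in one CTC sample.

    Parameters
    ----------
    segment_snps
        SNPs inside the aberrant segment with columns ``ref_baf`` (the
        reference sample's BAF), ``ctc_baf`` and ``ctc_depth``.
    background_snps
        Same columns for SNPs from segments called neutral without LOH in
        the reference sample.
    min_dev, min_depth
        A SNP is informative when ``|BAF - 0.5| > min_dev`` with depth >=
        ``min_depth``; the reference direction in the segment uses the same
        deviation threshold.

    Notes
    -----
    If no segment SNP has an informative reference direction the aberration
    is balanced in BAF (pure LRR event); it is flagged ``lrr_only`` and not
    evaluable by this test.
    """
    if len(segment_snps) == 0:
        return ImbalanceAssessment(aberration_id, ctc_sample_id, 0, 0,
                                   1.0, 0.0, present=False, evaluable=False)
    ref_dir = _directions(segment_snps["ref_baf"].to_numpy(float),
                          np.full(len(segment_snps), np.inf),
                          min_dev, 0)
    if not np.any(ref_dir != 0):
        return ImbalanceAssessment(aberration_id, ctc_sample_id, 0, 0,
                                   1.0, 0.0, present=False, evaluable=False,
                                   lrr_only=True)
    ctc_dir = _directions(segment_snps["ctc_baf"].to_numpy(float),
                          segment_snps["ctc_depth"].to_numpy(float),
                          min_dev, min_depth)
    usable = (ctc_dir != 0) & (ref_dir != 0)
    n_cons = int(np.sum(usable & (ctc_dir == ref_dir)))
    n_disc = int(np.sum(usable & (ctc_dir != ref_dir)))
    if n_cons + n_disc == 0:
        return ImbalanceAssessment(aberration_id, ctc_sample_id, 0, 0,
                                   1.0, 0.0, present=False, evaluable=False)
    bg_cons, bg_disc = _background_counts(background_snps, min_dev, min_depth)
    p = stats.fisher_exact([[n_cons, n_disc], [bg_cons, bg_disc]],
                           alternative="greater")[1]
    frac = n_cons / (n_cons + n_disc)
    present = bool(p < p_threshold and frac >= min_fraction)
    return ImbalanceAssessment(aberration_id, ctc_sample_id, n_cons, n_disc,
                               float(p), float(frac), present, evaluable=True)


def _snps_in(track: pd.DataFrame, chrom, start, end) -> pd.DataFrame:
    m = (track["chrom"] == chrom) & (track["pos"] >= start) & (track["pos"] <= end)
    return track.loc[m]


def _paired(ref_track: pd.DataFrame, ctc_track: pd.DataFrame) -> pd.DataFrame:
    merged = ref_track.merge(
        ctc_track, on=["chrom", "pos"], suffixes=("_ref", "_ctc"))
    return pd.DataFrame({
        "chrom": merged["chrom"], "pos": merged["pos"],
        "ref_baf": merged["baf_ref"],
        "ctc_baf": merged["baf_ctc"],
        "ctc_depth": merged["depth_ctc"],
    })


def rescue_all(
    catalog: pd.DataFrame,
    ref_track: pd.DataFrame,
    ctc_tracks: dict[str, pd.DataFrame],
    neutral_regions: pd.DataFrame,
    **score_kwargs,
) -> tuple[pd.DataFrame, list[ImbalanceAssessment]]:
    """Score a catalog of known aberrations in every CTC sample.

    Parameters
    ----------
    catalog
        One row per aberration: ``aberration_id, chrom, start, end`` (1-based
        inclusive), typically the aberrant segments of the CDX / cell line /
        primary tumor.
    ref_track
        Reference sample SNP track ``chrom, pos, baf, depth``.
    ctc_tracks
        ``sample -> track`` with the same columns.
    neutral_regions
        ``chrom, start, end`` regions called neutral without LOH in the
        reference sample; their SNPs form the per-CTC background.

    Returns
    -------
    ``(matrix, assessments)`` — ``matrix`` is aberrations x CTC samples with
    values ``present`` / ``absent`` / ``not_evaluable``.
    """
    results: dict[str, dict[str, str]] = {}
    assessments = []
    for sample, ctc_track in ctc_tracks.items():
        paired = _paired(ref_track, ctc_track)
        bg_parts = [_snps_in(paired, r.chrom, r.start, r.end)
                    for r in neutral_regions.itertuples(index=False)]
        background = (pd.concat(bg_parts, ignore_index=True) if bg_parts
                      else paired.iloc[0:0])
        for ab in catalog.itertuples(index=False):
            seg = _snps_in(paired, ab.chrom, ab.start, ab.end)
            a = score_aberration_in_ctc(
                seg, background, aberration_id=str(ab.aberration_id),
                ctc_sample_id=sample, **score_kwargs)
            assessments.append(a)
            results.setdefault(str(ab.aberration_id), {})[sample] = a.status
    matrix = pd.DataFrame(results).T
    matrix = matrix.reindex(index=[str(a) for a in catalog["aberration_id"]],
                            columns=list(ctc_tracks))
    return matrix, assessments
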