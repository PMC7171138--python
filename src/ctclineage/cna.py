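"""Allele-specific copy-number calling from per-SNP LRR and BAF.

The substrate is the set of germline-heterozygous SNPs of a tumor/normal
pair.  At each SNP the coverage log-ratio

    LRR = log2( (d_T / median d_T) / (d_N / median d_N) )

tracks total copy number and the B-allele frequency (alt-read fraction,
BAF) tracks the allelic ratio.  Both signals are segmented per chromosome
with circular binary segmentation (CBS); the union of the breakpoints
partitions the genome into homogeneous segments.  A grid search over tumor
purity and the copy number mapping to LRR = 0 then places every segment on
the lattice of integer (major, minor) allele copy numbers; ploidy is the
length-weighted median total copy number.  Segments are finally classified
relative to ploidy:

    gain                 total CN > ploidy + 0.5
    loss                 total CN < ploidy - 0.5
    high_amp             total CN > ploidy + 2
    homozygous_deletion  total CN < 0.5
    neutral              otherwise
    LOH                  minor CN == 0 (orthogonal flag)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GAIN = "gain"
LOSS = "loss"
HIGH_AMP = "high_amp"
HOMDEL = "homozygous_deletion"
NEUTRAL = "neutral"


# ---------------------------------------------------------------------------
# LRR / BAF track


def compute_lrr_baf(snp_counts: pd.DataFrame) -> pd.DataFrame:
    """Build the per-SNP LRR/BAF track of a tumor/normal pair.

    ``snp_counts`` has one row per germline-heterozygous SNP with columns
    ``chrom, pos, tumor_ref, tumor_alt, normal_ref, normal_alt``.  SNPs with
    zero normal depth are skipped; SNPs must already be restricted to
    germline hets (the caller supplies the genotypes).

    Returns a track ``chrom, pos, lrr, baf`` sorted by (chrom, pos), with
    ``baf = tumor_alt / tumor depth``.
    """
    df = snp_counts.copy()
    t_depth = (df["tumor_ref"] + df["tumor_alt"]).to_numpy(float)
    n_depth = (df["normal_ref"] + df["normal_alt"]).to_numpy(float)
    keep = n_depth > 0
    df, t_depth, n_depth = df.loc[keep], t_depth[keep], n_depth[keep]
    med_t = np.median(t_depth[t_depth > 0]) if (t_depth > 0).any() else 1.0
    med_n = np.median(n_depth)
    ratio = (t_depth / med_t) / (n_depth / med_n)
    # depth-0 tumor SNPs carry real signal (deletions); floor the ratio so
    # log2 stays finite
    lrr = np.log2(np.maximum(ratio, 2.0 ** -6))
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(t_depth > 0, df["tumor_alt"] / t_depth, 0.5)
    out = pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "pos": df["pos"].to_numpy(),
         "lrr": lrr, "baf": baf, "depth": t_depth})
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def mirrored_baf(baf: np.ndarray) -> np.ndarray:
    """Fold BAF about 0.5: ``|baf - 0.5| + 0.5`` (phase-free imbalance)."""
    return np.abs(np.asarray(baf, float) - 0.5) + 0.5


def segment_imbalance(baf: np.ndarray, depth: np.ndarray | None) -> float:
    """Noise-debiased mean mirrored BAF of one segment.

    Folding BAF about 0.5 inflates the mean of a *balanced* segment by the
    binomial read-sampling noise (~``sqrt(0.25/depth)``); the raw folded mean
    would be ~0.54 rather than 0.5 at depth 100.  The allelic imbalance is
    therefore estimated as ``sqrt(max(mean((baf-0.5)^2) - noise, 0))`` with
    the binomial noise floor subtracted, and reported as ``0.5 + imbalance``.
    Falls back to the raw folded mean when depths are unavailable.
    """
    baf = np.asarray(baf, float)
    if depth is None:
        return float(mirrored_baf(baf).mean())
    var_obs = float(np.mean((baf - 0.5) ** 2))
    noise = float(np.mean(0.25 / np.maximum(np.asarray(depth, float), 1.0)))
    return 0.5 + float(np.sqrt(max(var_obs - noise, 0.0)))


# ---------------------------------------------------------------------------
# Circular binary segmentation


def _max_arc_stat(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t|-like statistic over all circular arcs of ``x``.

    Returns ``(stat, i, j)`` where the arc is ``x[i:j]`` and the complement
    is the rest; widths below ``min_width`` on either side are excluded.
    """
    n = len(x)
    if n < 2 * min_width:
        return 0.0, 0, n
    sd = x.std()
    if sd == 0:
        return 0.0, 0, n
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    # arc sums S[j]-S[i] for all i<j via broadcasting
    diff = cs[None, 1:] - cs[:-1, None]          # [i, j-1] -> sum x[i:j]
    width = np.arange(1, n + 1)[None, :] - np.arange(n)[:, None]
    valid = (width >= min_width) & (width <= n - min_width)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_in = diff / width
        mean_out = (total - diff) / (n - width)
        t = (mean_in - mean_out) / (sd * np.sqrt(1.0 / width + 1.0 / (n - width)))
    t = np.where(valid, np.abs(t), 0.0)
    i, jm1 = np.unravel_index(int(np.argmax(t)), t.shape)
    return float(t[i, jm1]), int(i), int(jm1) + 1


def _arc_significant(
    x: np.ndarray, stat: float, rng: np.random.Generator,
    alpha: float, n_perm: int, min_width: int,
) -> bool:
    """Permutation test of the best arc, with early stopping."""
    exceed = 0
    stop = int(np.ceil(alpha * (n_perm + 1)))
    for _ in range(n_perm):
        perm = rng.permutation(x)
        s, _, _ = _max_arc_stat(perm, min_width)
        if s >= stat:
            exceed += 1
            if exceed >= stop:
                return False
    return (exceed + 1) / (n_perm + 1) < alpha


def cbs_breakpoints(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 200,
    min_width: int = 10,
    seed: int = 0,
) -> list[int]:
    """Breakpoint indices of one signal by circular binary segmentation.

    Recursively finds the most extreme arc, keeps its endpoints when a
    permutation test rejects homogeneity at ``alpha``, and recurses on the
    resulting pieces.  Returned indices ``b`` mean a boundary between
    ``x[b-1]`` and ``x[b]``; chromosome ends are not included.
    """
    x = np.asarray(x, float)
    rng = np.random.default_rng(seed)
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if len(seg) < 2 * min_width:
            return
        stat, i, j = _max_arc_stat(seg, min_width)
        if stat == 0.0:
            return
        if not _arc_significant(seg, stat, rng, alpha, n_perm, min_width):
            return
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        breaks.extend(cuts)
        edges = [lo, *cuts, hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(set(breaks))


def segment_genome(
    track: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 200,
    min_snps: int = 10,
    merge_lrr: float = 0.1,
    merge_baf: float = 0.05,
    use_baf: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Partition an LRR/BAF track into homogeneous segments.

    CBS is run per chromosome on LRR and (optionally) on mirrored BAF; the
    two breakpoint sets are unioned.  Adjacent segments whose mean LRR and
    mean mirrored BAF both differ by less than the merge thresholds are
    re-joined.  Chromosomes with fewer than ``min_snps`` SNPs form a single
    segment.

    Returns one row per segment: ``chrom, start, end, n_snps, mean_lrr,
    mean_mbaf`` with 1-based inclusive SNP-span coordinates.
    """
    track = track.sort_values(["chrom", "pos"], kind="stable")
    rows = []
    for chrom, sub in track.groupby("chrom", sort=True):
        lrr = sub["lrr"].to_numpy()
        baf = sub["baf"].to_numpy()
        mbaf = mirrored_baf(baf)
        depth = sub["depth"].to_numpy() if "depth" in sub.columns else None
        pos = sub["pos"].to_numpy()
        n = len(sub)
        breaks = set(cbs_breakpoints(lrr, alpha, n_perm, min_snps, seed))
        if use_baf:
            breaks |= set(cbs_breakpoints(mbaf, alpha, n_perm, min_snps, seed + 1))
        edges = [0, *sorted(b for b in breaks if 0 < b < n), n]
        segs = list(zip(edges[:-1], edges[1:]))
        # unioning LRR- and BAF-derived breakpoints can leave slivers below
        # the minimum width; fold each into the closer-mean neighbor
        while len(segs) > 1:
            widths = [b - a for a, b in segs]
            k = int(np.argmin(widths))
            if widths[k] >= min_snps:
                break
            a, b = segs[k]
            cand = []
            if k > 0:
                pa, pb = segs[k - 1]
                cand.append((abs(lrr[pa:pb].mean() - lrr[a:b].mean()), k - 1))
            if k < len(segs) - 1:
                na, nb = segs[k + 1]
                cand.append((abs(lrr[na:nb].mean() - lrr[a:b].mean()), k + 1))
            j = min(cand)[1]
            lo = min(segs[k][0], segs[j][0])
            hi = max(segs[k][1], segs[j][1])
            segs[min(k, j)] = (lo, hi)
            del segs[max(k, j)]
        # merge adjacent segments indistinguishable in both signals
        merged = [segs[0]]
        for a, b in segs[1:]:
            pa, pb = merged[-1]
            if (abs(lrr[pa:pb].mean() - lrr[a:b].mean()) < merge_lrr
                    and abs(mbaf[pa:pb].mean() - mbaf[a:b].mean()) < merge_baf):
                merged[-1] = (pa, b)
            else:
                merged.append((a, b))
        for a, b in merged:
            rows.append({
                "chrom": chrom,
                "start": int(pos[a]),
                "end": int(pos[b - 1]),
                "n_snps": b - a,
                "mean_lrr": float(lrr[a:b].mean()),
                "mean_mbaf": segment_imbalance(
                    baf[a:b], depth[a:b] if depth is not None else None),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ploidy / purity fit on the integer (major, minor) lattice


@dataclass(frozen=True)
class PloidyFit:
    """Genome-wide ploidy/purity solution of one sample."""

    ploidy: float
    purity: float
    wgd_flag: bool
    fit_residual: float
    baseline_cn: float  # copy number mapping to LRR = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


def _expected_lrr(total: np.ndarray, purity: float, baseline: float) -> np.ndarray:
    mix = purity * total + 2.0 * (1.0 - purity)
    ref = purity * baseline + 2.0 * (1.0 - purity)
    return np.log2(np.maximum(mix / ref, 2.0 ** -6))


def _expected_mbaf(major: np.ndarray, minor: np.ndarray, purity: float) -> np.ndarray:
    total = major + minor
    denom = purity * total + 2.0 * (1.0 - purity)
    num = purity * major + (1.0 - purity)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, 0.5)


def fit_ploidy_purity(
    segments: pd.DataFrame,
    max_cn: int = 8,
    purity_grid: np.ndarray | None = None,
    baseline_grid: np.ndarray | None = None,
    wgd_threshold: float = 3.0,
    baf_weight: float = 1.0,
    baseline_penalty: float = 0.001,
    purity_bonus: float = 1e-4,
) -> tuple[PloidyFit, pd.DataFrame]:
    """Fit purity and ploidy and assign integer allele-specific CN.

    Grid search over purity and the baseline copy number (the total CN whose
    LRR is 0) minimizing the ``n_snps``-weighted squared distance of each
    segment's ``(mean_lrr, mean_mbaf)`` to its nearest point on the lattice
    of integer (major, minor) expectations.  A small penalty on the baseline
    resolves the genome-doubling degeneracy toward the lower-ploidy solution
    and a tiny bonus prefers higher purity among exact ties.

    Returns the :class:`PloidyFit` and a copy of ``segments`` with
    ``total_cn, major_cn, minor_cn`` columns.  Ploidy is the
    ``n_snps``-weighted median total CN.
    """
    if len(segments) == 0:
        raise ValueError("no segments to fit")
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.10, 1.0001, 0.01), 4)
    if np.any(purity_grid <= 0) or np.any(purity_grid > 1):
        raise ValueError("purity grid must lie in (0, 1]")
    if baseline_grid is None:
        baseline_grid = np.round(np.arange(1.0, max_cn + 1e-9, 0.05), 4)

    major, minor = np.meshgrid(np.arange(max_cn + 1), np.arange(max_cn + 1))
    keep = (minor <= major) & (major + minor <= max_cn)
    major, minor = major[keep].astype(float), minor[keep].astype(float)
    total = major + minor

    lrr = segments["mean_lrr"].to_numpy()[:, None]
    mbaf = segments["mean_mbaf"].to_numpy()[:, None]
    w = segments["n_snps"].to_numpy(float)
    w = w / w.sum()

    best = (np.inf, None, None, None)
    for purity in purity_grid:
        e_baf = _expected_mbaf(major, minor, purity)[None, :]
        d_baf = (mbaf - e_baf) ** 2
        for baseline in baseline_grid:
            e_lrr = _expected_lrr(total, purity, baseline)[None, :]
            d = (lrr - e_lrr) ** 2 + baf_weight * d_baf
            idx = np.argmin(d, axis=1)
            obj = (w * d[np.arange(len(w)), idx]).sum()
            obj += baseline_penalty * baseline + purity_bonus * (1.0 - purity)
            if obj < best[0]:
                best = (obj, purity, baseline, idx)
    obj, purity, baseline, idx = best
    if idx is None:
        raise ValueError("degenerate fit: objective never evaluated")

    out = segments.copy()
    out["major_cn"] = major[idx].astype(int)
    out["minor_cn"] = minor[idx].astype(int)
    out["total_cn"] = out["major_cn"] + out["minor_cn"]

    order = np.argsort(out["total_cn"].to_numpy(), kind="stable")
    cum = np.cumsum(w[order])
    ploidy = float(out["total_cn"].to_numpy()[order][np.searchsorted(cum, 0.5)])
    fit = PloidyFit(
        ploidy=ploidy,
        purity=float(purity),
        wgd_flag=bool(ploidy >= wgd_threshold),
        fit_residual=float(obj),
        baseline_cn=float(baseline),
    )
    return fit, out


def classify_segments(segments: pd.DataFrame, fit: PloidyFit) -> pd.DataFrame:
    """Classify integer-CN segments relative to sample ploidy.

    Adds ``klass`` (gain / loss / high_amp / homozygous_deletion / neutral;
    ``high_amp`` and ``homozygous_deletion`` take precedence over plain
    gain / loss) and the orthogonal ``loh`` flag (minor CN == 0).
    """
    out = segments.copy()
    cn = out["total_cn"].to_numpy(float)
    klass = np.select(
        [cn < 0.5, cn > fit.ploidy + 2, cn > fit.ploidy + 0.5, cn < fit.ploidy - 0.5],
        [HOMDEL, HIGH_AMP, GAIN, LOSS],
        default=NEUTRAL,
    )
    out["klass"] = klass
    out["loh"] = out["minor_cn"].to_numpy() == 0
    return out
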