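"""Set-algebra accounting of alterations across tumor samples.

Bookkeeping over the cohort: ternary status matrices (mutated / not mutated /
not covered), recurrence histograms, Venn-style shared/private partitions
with the reported integer percentages, cross-sample matching of copy-number
calls, and VAF-based sample clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

MUTATED = "mutated"
NOT_MUTATED = "not_mutated"
NOT_COVERED = "not_covered"

COVERED_DEPTH = 8


def build_status_matrix(
    alterations: Sequence,
    calls_by_sample: Mapping[str, set],
    depth_lookup: Callable[[object, str], float],
    min_depth: int = COVERED_DEPTH,
) -> pd.DataFrame:
    """Ternary alteration x sample status matrix.

    A cell is ``mutated`` when the sample's (rescue-augmented) call set
    contains the alteration, ``not_covered`` when the site has depth below
    ``min_depth`` in that sample, else ``not_mutated``.
    """
    samples = list(calls_by_sample)
    data = {}
    for sample in samples:
        calls = calls_by_sample[sample]
        col = []
        for alt in alterations:
            if alt in calls:
                col.append(MUTATED)
            elif depth_lookup(alt, sample) < min_depth:
                col.append(NOT_COVERED)
            else:
                col.append(NOT_MUTATED)
        data[sample] = col
    return pd.DataFrame(data, index=list(alterations))


def recurrence_histogram(
    matrix: pd.DataFrame, sample_subset: Sequence[str] | None = None
) -> tuple[pd.Series, int]:
    """Histogram of alterations by the number of subset samples mutated.

    Returns ``(histogram, total)`` where the histogram index runs over
    ``k = 1 .. len(subset)`` and ``total`` is the number of alterations
    mutated in at least one subset sample.
    """
    subset = list(sample_subset) if sample_subset is not None else list(matrix.columns)
    if not subset:
        raise ValueError("sample subset must be non-empty")
    counts = (matrix[subset] == MUTATED).sum(axis=1)
    hist = pd.Series(
        {k: int((counts == k).sum()) for k in range(1, len(subset) + 1)})
    return hist, int((counts >= 1).sum())


def percent_round_half_up(numerator: float, denominator: float) -> int:
    """Integer percentage with half-up rounding (32/205 -> 16)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return int(np.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class VennPartition:
    """Disjoint-region partition of alterations by group presence."""

    groups: tuple[str, ...]
    region_counts: dict  # frozenset of group names -> count
    denominator: int
    universe_size: int

    def count(self, *groups: str) -> int:
        """Alterations present in exactly the named groups."""
        return self.region_counts.get(frozenset(groups), 0)

    def count_in(self, group: str) -> int:
        """Alterations present in ``group`` (any region containing it)."""
        return sum(c for r, c in self.region_counts.items() if group in r)

    def percent(self, *groups: str) -> int:
        return percent_round_half_up(self.count(*groups), self.denominator)

    def percent_in(self, group: str) -> int:
        return percent_round_half_up(self.count_in(group), self.denominator)


def venn_partition(
    matrix: pd.DataFrame,
    group_samples: Mapping[str, Sequence[str]],
    denominator: int | None = None,
) -> VennPartition:
    """Partition alterations into Venn regions by group-presence signature.

    An alteration is present in a group when it is ``mutated`` in at least
    one of the group's samples; ``not_covered`` cells never count as absent
    evidence.  Alterations present nowhere are dropped from the universe
    with a warning.  ``denominator`` (default: universe size) is the base of
    the reported integer percentages.
    """
    regions: dict[frozenset, int] = {}
    universe = 0
    n_empty = 0
    for _, row in matrix.iterrows():
        sig = frozenset(
            g for g, samples in group_samples.items()
            if any(row.get(s) == MUTATED for s in samples))
        if not sig:
            n_empty += 1
            continue
        universe += 1
        regions[sig] = regions.get(sig, 0) + 1
    if n_empty:
        warnings.warn(
            f"{n_empty} alteration(s) present in no group excluded from the universe",
            stacklevel=2)
    return VennPartition(
        groups=tuple(group_samples),
        region_counts=regions,
        denominator=denominator if denominator is not None else universe,
        universe_size=universe,
    )


# ---------------------------------------------------------------------------
# Cross-sample CNA identity


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """Reciprocal overlap of two (chrom, start, end) intervals, 1-based inclusive."""
    if a[0] != b[0]:
        return 0.0
    inter = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[2] - a[1] + 1), inter / (b[2] - b[1] + 1))


def match_aberrations(
    calls: pd.DataFrame, min_reciprocal_overlap: float = 0.5
) -> pd.DataFrame:
    """Group per-sample CNA calls into cross-sample aberrations.

    ``calls`` has columns ``sample_id, chrom, start, end, klass``.  Two calls
    are the same aberration when they have the same class and reciprocal
    overlap >= ``min_reciprocal_overlap``; identity is the transitive closure
    (single-linkage).  Adds an ``aberration_id`` column.
    """
    df = calls.reset_index(drop=True).copy()
    n = len(df)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ivs = list(zip(df["chrom"], df["start"], df["end"]))
    for i in range(n):
        for j in range(i + 1, n):
            if df["klass"][i] != df["klass"][j]:
                continue
            if reciprocal_overlap(ivs[i], ivs[j]) >= min_reciprocal_overlap:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    labels = {}
    ids = []
    for i, r in enumerate(roots):
        if r not in labels:
            labels[r] = (f"{df['klass'][i]}_{df['chrom'][i]}:"
                         f"{df['start'][i]}-{df['end'][i]}")
        ids.append(labels[r])
    df["aberration_id"] = ids
    return df


# ---------------------------------------------------------------------------
# VAF-based sample clustering


def cluster_samples_by_vaf(
    vaf_matrix: pd.DataFrame,
    min_samples_present: int = 2,
    method: str = "ward",
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA and hierarchical clustering of samples on their VAF profiles.

    Rows are alterations, columns samples; alterations present (VAF > 0) in
    fewer than ``min_samples_present`` samples are dropped.  Samples are
    clustered on cosine distances with Ward linkage as specified (an
    ``method="average"`` fallback is available, since Ward on a
    non-Euclidean metric is formally improper).

    Returns ``(pca_coordinates, linkage_matrix)``; both deterministic given
    the input.
    """
    keep = (vaf_matrix > 0).sum(axis=1) >= min_samples_present
    m = vaf_matrix.loc[keep]
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    x = m.T.to_numpy(float)  # samples x alterations
    if np.allclose(x, x[0]):
        raise ValueError("degenerate VAF matrix: all samples identical")
    if np.any(np.linalg.norm(x, axis=1) == 0):
        raise ValueError("sample with all-zero VAF vector: cosine undefined")
    n_comp = min(n_components, x.shape[0] - 1, x.shape[1])
    coords = PCA(n_components=n_comp, svd_solver="full").fit_transform(
        x - x.mean(axis=0))
    pca_df = pd.DataFrame(
        coords, index=m.columns, columns=[f"PC{i+1}" for i in range(n_comp)])
    z = linkage(pdist(x, metric="cosine"), method=method)
    return pca_df, z
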