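"""Status matrices, recurrence, Venn partitions and VAF clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from ctclineage import accounting as acc


def matrix_from_signatures(sig_counts, samples_by_group):
    """Build a status matrix realizing given group-presence signatures."""
    rows = []
    idx = []
    i = 0
    for sig, count in sig_counts:
        for _ in range(count):
            row = {}
            for g, samples in samples_by_group.items():
                for k, s in enumerate(samples):
                    row[s] = (acc.MUTATED if g in sig and k == 0
                              else acc.NOT_MUTATED)
            rows.append(row)
            idx.append(f"m{i}")
            i += 1
    return pd.DataFrame(rows, index=idx)


GROUPS = {"PT": [f"pt_{i}" for i in range(1, 9)],
          "CTC": [f"ctc_{i}" for i in range(1, 7)],
          "CDX": ["cdx", "cell_line"]}


class TestStatusMatrix:
    def test_three_states(self):
        depths = {("v1", "s1"): 100, ("v1", "s2"): 100,
                  ("v2", "s1"): 7, ("v2", "s2"): 100}
        m = acc.build_status_matrix(
            ["v1", "v2"], {"s1": {"v1"}, "s2": set()},
            lambda a, s: depths[(a, s)])
        assert m.loc["v1", "s1"] == acc.MUTATED
        assert m.loc["v1", "s2"] == acc.NOT_MUTATED
        assert m.loc["v2", "s1"] == acc.NOT_COVERED
        assert m.loc["v2", "s2"] == acc.NOT_MUTATED

    def test_cohort_matrix_matches_truth_outside_artifacts(self, cohort,
                                                           pipeline_result):
        """Away from ADO/FP/dropout cells, status equals truth presence."""
        m = pipeline_result.accounting.status_matrix
        keys = cohort.variants.set_index("variant_id")
        id_of = {(r.chrom, r.pos, r.ref, r.alt): r.Index
                 for r in keys.itertuples()}
        pvt = cohort.truth.per_variant_truth.set_index(
            ["variant_id", "sample_id"])
        agree = disagree = 0
        for key in m.index:
            vid = id_of[key]
            for s in m.columns:
                t = pvt.loc[(vid, s)]
                if t["ado_dropped"] or t["false_positive"]:
                    continue
                if m.loc[[key], s].iloc[0] == acc.NOT_COVERED:
                    continue
                expect_called = (t["truly_present"]
                                 and t["expected_vaf"] >= 0.05)
                got = m.loc[[key], s].iloc[0] == acc.MUTATED
                if got == expect_called:
                    agree += 1
                else:
                    disagree += 1
        # residual disagreement: read-sampling pushing alt support across
        # the caller/filter thresholds
        assert agree / (agree + disagree) > 0.97


class TestRecurrence:
    def test_printed_pt_histogram_accounting(self):
        """Recurrence histogram over 8 PT columns realizing the printed
        counts 153,27,9,8,5,2,1 for k=1..7 gives 205 total and a 75% k=1
        share."""
        counts = {1: 153, 2: 27, 3: 9, 4: 8, 5: 5, 6: 2, 7: 1}
        rows, idx = [], []
        i = 0
        pts = GROUPS["PT"]
        for k, n in counts.items():
            for _ in range(n):
                row = {s: (acc.MUTATED if j < k else acc.NOT_MUTATED)
                       for j, s in enumerate(pts)}
                rows.append(row)
                idx.append(f"m{i}")
                i += 1
        m = pd.DataFrame(rows, index=idx)
        hist, total = acc.recurrence_histogram(m, pts)
        assert total == 205
        assert {k: v for k, v in hist.items() if v} == counts
        assert acc.percent_round_half_up(hist[1], total) == 75

    def test_random_matrix_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(
            rng.choice([acc.MUTATED, acc.NOT_MUTATED, acc.NOT_COVERED],
                       size=(60, 5)),
            columns=list("abcde"))
        hist, total = acc.recurrence_histogram(m, list("abcde"))
        brute = [(m.loc[i] == acc.MUTATED).sum() for i in m.index]
        assert total == sum(1 for b in brute if b >= 1)
        for k in range(1, 6):
            assert hist[k] == sum(1 for b in brute if b == k)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            acc.recurrence_histogram(pd.DataFrame(), [])


class TestVenn:
    def test_printed_pt_overlap_accounting(self):
        """205 PT mutations: 172 PT-only, 32 shared with CDX + cell line,
        1 shared with CTCs only; 32/205 rounds to 16%."""
        m = matrix_from_signatures(
            [(("PT",), 172), (("PT", "CDX"), 32), (("PT", "CTC"), 1)], GROUPS)
        v = acc.venn_partition(m, GROUPS, denominator=205)
        assert v.universe_size == 205
        assert v.count("PT") == 172
        assert v.count("PT", "CDX") == 32
        assert v.count("PT", "CTC") == 1
        assert v.percent("PT", "CDX") == 16

    def test_printed_ctc_universe_percentages(self):
        """62 high-confidence CTC variants: 25 from PT (40%), 35 in the CDX
        (56%), 24 in both (39%), 37 CTC-private (60%)."""
        m = matrix_from_signatures(
            [(("CTC", "PT", "CDX"), 24), (("CTC", "PT"), 1),
             (("CTC", "CDX"), 11), (("CTC",), 26)], GROUPS)
        v = acc.venn_partition(m, GROUPS, denominator=62)
        assert v.universe_size == 62
        assert v.count_in("PT") == 25 and v.percent_in("PT") == 40
        assert v.count_in("CDX") == 35 and v.percent_in("CDX") == 56
        assert v.count("CTC", "PT", "CDX") == 24
        assert v.percent("CTC", "PT", "CDX") == 39
        private = v.count("CTC") + v.count("CTC", "CDX")
        assert private == 37
        assert acc.percent_round_half_up(private, 62) == 60

    def test_region_counts_sum_to_universe(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            m = pd.DataFrame(
                rng.choice([acc.MUTATED, acc.NOT_MUTATED], size=(40, 16),
                           p=[0.3, 0.7]),
                columns=[s for g in GROUPS.values() for s in g])
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v = acc.venn_partition(m, GROUPS)
            assert sum(v.region_counts.values()) == v.universe_size

    def test_not_covered_never_flips_partition(self):
        rng = np.random.default_rng(4)
        cols = [s for g in GROUPS.values() for s in g]
        m = pd.DataFrame(
            rng.choice([acc.MUTATED, acc.NOT_MUTATED, acc.NOT_COVERED],
                       size=(50, 16), p=[0.3, 0.4, 0.3]),
            columns=cols)
        keep = (m == acc.MUTATED).any(axis=1)
        m = m.loc[keep]
        v1 = acc.venn_partition(m, GROUPS)
        v2 = acc.venn_partition(m.replace(acc.NOT_COVERED, acc.NOT_MUTATED),
                                GROUPS)
        assert v1.region_counts == v2.region_counts

    def test_single_group(self):
        m = matrix_from_signatures([(("PT",), 7)], {"PT": GROUPS["PT"]})
        v = acc.venn_partition(m, {"PT": GROUPS["PT"]})
        assert v.region_counts == {frozenset({"PT"}): 7}

    def test_half_up_rounding(self):
        assert acc.percent_round_half_up(32, 205) == 16
        assert acc.percent_round_half_up(1, 8) == 13  # 12.5 rounds up
        assert acc.percent_round_half_up(153, 205) == 75


class TestAberrationMatching:
    def test_reciprocal_overlap(self):
        a = ("chr01", 1, 100)
        assert acc.reciprocal_overlap(a, ("chr01", 1, 100)) == 1.0
        assert acc.reciprocal_overlap(a, ("chr01", 51, 150)) == pytest.approx(0.5)
        assert acc.reciprocal_overlap(a, ("chr02", 1, 100)) == 0.0
        assert acc.reciprocal_overlap(a, ("chr01", 200, 300)) == 0.0

    def test_cross_sample_identity(self):
        calls = pd.DataFrame([
            ("s1", "chr01", 100, 200, "loss"),
            ("s2", "chr01", 110, 210, "loss"),   # same aberration
            ("s3", "chr01", 100, 200, "gain"),   # same span, other class
            ("s1", "chr02", 100, 200, "loss"),   # other chromosome
        ], columns=["sample_id", "chrom", "start", "end", "klass"])
        out = acc.match_aberrations(calls)
        ids = out["aberration_id"].tolist()
        assert ids[0] == ids[1]
        assert len(set(ids)) == 3


class TestClustering:
    def test_identical_samples_zero_distance(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(0.1, 0.6, 30)
        m = pd.DataFrame({"a": col, "b": col, "c": col[::-1] * 0.5 + 0.2})
        _, z = acc.cluster_samples_by_vaf(m)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_cohort_ctc_cdx_lineage_clusters_apart_from_pt(self,
                                                           pipeline_result):
        """The CTC/CDX/cell-line lineage and the PT specimens separate at
        the top of the dendrogram."""
        ac = pipeline_result.accounting
        samples = list(ac.pca.index)
        labels = fcluster(ac.linkage, 2, criterion="maxclust")
        by_cluster = {}
        for s, l in zip(samples, labels):
            by_cluster.setdefault(l, set()).add(s)
        parts = sorted(by_cluster.values(), key=len)
        lineage = {s for s in samples
                   if s.startswith("ctc") or s in ("cdx", "cell_line")}
        assert lineage in parts or (set(samples) - lineage) in parts

    def test_degenerate_inputs_rejected(self):
        flat = pd.DataFrame(np.ones((10, 4)) * 0.3, columns=list("abcd"))
        with pytest.raises(ValueError):
            acc.cluster_samples_by_vaf(flat)
        two = pd.DataFrame(np.random.default_rng(0).uniform(size=(10, 2)),
                           columns=list("ab"))
        with pytest.raises(ValueError):
            acc.cluster_samples_by_vaf(two)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.uniform(0, 0.8, (25, 6)), columns=list("abcdef"))
        p1, z1 = acc.cluster_samples_by_vaf(m)
        p2, z2 = acc.cluster_samples_by_vaf(m.copy())
        pd.testing.assert_frame_equal(p1, p2)
        assert np.array_equal(z1, z2)
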