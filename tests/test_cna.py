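"""Allele-specific copy-number calling: LRR/BAF, CBS, ploidy fit, classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctclineage import cna


def make_counts(n=300, tumor_depth=100, normal_depth=100, tumor_alt_p=0.5,
                chrom="chr01", rng=None):
    if rng is None:
        t_alt = (np.asarray(tumor_depth) * tumor_alt_p).astype(int)
        t_depth = np.full(n, tumor_depth) if np.isscalar(tumor_depth) else tumor_depth
    return pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, n + 1) * 1000,
        "tumor_ref": t_depth - t_alt, "tumor_alt": t_alt,
        "normal_ref": normal_depth // 2, "normal_alt": normal_depth // 2,
    })


class TestLrrBaf:
    def test_equal_depth_gives_zero_lrr_and_balanced_baf(self):
        track = cna.compute_lrr_baf(make_counts())
        assert np.allclose(track["lrr"], 0.0)
        assert np.allclose(track["baf"], 0.5)

    def test_zero_normal_depth_snp_skipped(self):
        counts = make_counts(n=10)
        counts.loc[3, ["normal_ref", "normal_alt"]] = 0
        track = cna.compute_lrr_baf(counts)
        assert len(track) == 9

    def test_one_copy_loss_closed_form(self):
        """A clonal (1,0) loss in a pure diploid: LRR -> log2(0.5) and the
        mirrored BAF -> 1.0 (closed-form expectation)."""
        n = 500
        t_depth = np.full(n, 100)
        t_alt = np.full(n, 50)
        lost = slice(0, 100)  # 20% of genome, median depth stays 100
        t_depth[lost] = 50
        t_alt[lost] = 0
        counts = pd.DataFrame({
            "chrom": "chr01", "pos": np.arange(1, n + 1) * 1000,
            "tumor_ref": t_depth - t_alt, "tumor_alt": t_alt,
            "normal_ref": 50, "normal_alt": 50})
        track = cna.compute_lrr_baf(counts)
        seg_lrr = track["lrr"].iloc[0:100].mean()
        seg_mbaf = cna.mirrored_baf(track["baf"].iloc[0:100].to_numpy()).mean()
        assert seg_lrr == pytest.approx(np.log2(0.5), abs=1e-9)
        assert seg_mbaf == pytest.approx(1.0, abs=1e-9)


def step_track(n=200, step_at=100, size=1.0, noise=0.1, seed=0,
               baf_dev=0.0):
    rng = np.random.default_rng(seed)
    lrr = np.where(np.arange(n) < step_at, 0.0, size) + rng.normal(0, noise, n)
    baf = 0.5 + np.where(np.arange(n) < step_at, 0.0, baf_dev)
    baf = np.clip(baf + rng.normal(0, 0.02, n), 0, 1)
    return pd.DataFrame({"chrom": "chr01", "pos": np.arange(1, n + 1) * 1000,
                         "lrr": lrr, "baf": baf,
                         "depth": np.full(n, 10_000)})


class TestSegmentation:
    def test_constant_signal_single_segment_per_chromosome(self):
        parts = [step_track(120, step_at=120, seed=s).assign(chrom=f"chr{s}")
                 for s in range(3)]
        segs = cna.segment_genome(pd.concat(parts, ignore_index=True), seed=0)
        assert len(segs) == 3
        assert (segs["n_snps"] == 120).all()

    def test_single_step_breakpoint_localized(self):
        """One LRR step of 1.0 in noise sigma=0.1: the breakpoint lands
        within +-2 SNPs of the truth in >= 95% of seeded runs."""
        hits = 0
        runs = 30
        for s in range(runs):
            segs = cna.segment_genome(step_track(200, 100, seed=s), seed=s,
                                      use_baf=False)
            bks = segs["end"].to_numpy() // 1000
            hits += any(abs(int(b) - 100) <= 2 for b in bks[:-1])
        assert hits >= 0.95 * runs

    def test_null_signal_rarely_split(self):
        clean = 0
        runs = 30
        for s in range(runs):
            track = step_track(200, step_at=200, seed=1000 + s)
            segs = cna.segment_genome(track, seed=s, use_baf=False)
            clean += int(len(segs) == 1)
        assert clean >= 0.95 * runs

    def test_few_snps_single_segment(self):
        segs = cna.segment_genome(step_track(8, 4, seed=2), seed=0)
        assert len(segs) == 1

    def test_segments_tile_each_chromosome(self, pipeline_result):
        for s, d in pipeline_result.cna.by_sample.items():
            track, segs = d["track"], d["calls"]
            for chrom, sub in segs.groupby("chrom"):
                n_track = (track["chrom"] == chrom).sum()
                assert sub["n_snps"].sum() == n_track
                sub = sub.sort_values("start")
                assert (sub["start"].to_numpy()[1:]
                        > sub["end"].to_numpy()[:-1]).all()


def lattice_segments(states, purity, baseline, n_snps=200, jitter=0.0, seed=0):
    """Exact (or jittered) expectations for a list of (major, minor) states."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (M, m) in enumerate(states):
        t = M + m
        lrr = np.log2((purity * t + 2 * (1 - purity))
                      / (purity * baseline + 2 * (1 - purity)))
        mbaf = ((purity * M + (1 - purity))
                / (purity * t + 2 * (1 - purity))) if t or purity < 1 else 0.5
        rows.append({"chrom": "chr01", "start": i * 10**6 + 1,
                     "end": (i + 1) * 10**6, "n_snps": n_snps,
                     "mean_lrr": lrr + rng.normal(0, jitter),
                     "mean_mbaf": mbaf + rng.normal(0, jitter)})
    return pd.DataFrame(rows)


class TestPloidyPurityFit:
    def test_diploid_with_loss_recovered(self):
        # 80% (1,1), 20% (1,0), pure tumor
        states = [(1, 1)] * 8 + [(1, 0)] * 2
        segs = lattice_segments(states, purity=1.0, baseline=2.0, jitter=0.01)
        fit, out = cna.fit_ploidy_purity(segs)
        assert fit.ploidy == 2.0
        assert fit.purity == pytest.approx(1.0, abs=0.05)
        assert not fit.wgd_flag
        lost = out.iloc[8:]
        assert (lost["major_cn"] == 1).all() and (lost["minor_cn"] == 0).all()

    def test_impure_diploid_recovered(self):
        states = [(1, 1)] * 7 + [(1, 0)] * 2 + [(2, 1)]
        segs = lattice_segments(states, purity=0.6, baseline=2.0, jitter=0.005)
        fit, _ = cna.fit_ploidy_purity(segs)
        assert fit.ploidy == 2.0
        assert fit.purity == pytest.approx(0.6, abs=0.05)

    def test_tetraploid_wgd_flagged(self):
        # doubled genome with odd-copy segments pinning the solution
        states = [(2, 2)] * 7 + [(2, 0)] * 2 + [(2, 1), (3, 2)]
        segs = lattice_segments(states, purity=0.9, baseline=4.0, jitter=0.005)
        fit, _ = cna.fit_ploidy_purity(segs)
        assert fit.ploidy == 4.0
        assert fit.purity == pytest.approx(0.9, abs=0.05)
        assert fit.wgd_flag

    def test_cohort_cdx_and_cell_line_wgd(self, cohort, pipeline_result):
        for s in ("cdx", "cell_line"):
            fit = pipeline_result.cna.by_sample[s]["fit"]
            assert fit.ploidy == pytest.approx(4.0, abs=0.5)
            assert fit.wgd_flag
        for s in [x for x in cohort.tumor_samples if x.startswith("pt_")]:
            fit = pipeline_result.cna.by_sample[s]["fit"]
            assert fit.ploidy == pytest.approx(2.0, abs=0.5)
            assert not fit.wgd_flag
            assert fit.purity == pytest.approx(0.6, abs=0.07)

    def test_invalid_purity_grid_rejected(self):
        segs = lattice_segments([(1, 1)], 1.0, 2.0)
        with pytest.raises(ValueError):
            cna.fit_ploidy_purity(segs, purity_grid=np.array([0.0, 0.5]))

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            cna.fit_ploidy_purity(lattice_segments([], 1.0, 2.0))


class TestClassification:
    def oracle(self, cn, ploidy, minor):
        if cn < 0.5:
            klass = "homozygous_deletion"
        elif cn > ploidy + 2:
            klass = "high_amp"
        elif cn > ploidy + 0.5:
            klass = "gain"
        elif cn < ploidy - 0.5:
            klass = "loss"
        else:
            klass = "neutral"
        return klass, minor == 0

    @pytest.mark.parametrize("ploidy", [1.5, 2.0, 3.0, 4.0])
    def test_exhaustive_against_threshold_oracle(self, ploidy):
        rows = []
        for total in range(0, 9):
            for minor in range(0, total // 2 + 1):
                rows.append({"chrom": "chr01", "start": 1, "end": 2,
                             "n_snps": 10, "mean_lrr": 0.0, "mean_mbaf": 0.5,
                             "total_cn": total, "minor_cn": minor,
                             "major_cn": total - minor})
        segs = pd.DataFrame(rows)
        fit = cna.PloidyFit(ploidy=ploidy, purity=1.0, wgd_flag=ploidy >= 3,
                            fit_residual=0.0, baseline_cn=ploidy)
        out = cna.classify_segments(segs, fit)
        for r in out.itertuples(index=False):
            klass, loh = self.oracle(r.total_cn, ploidy, r.minor_cn)
            assert r.klass == klass and r.loh == loh

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(total=st.integers(0, 12), minor_raw=st.integers(0, 12),
           ploidy=st.floats(0.5, 8.0, allow_nan=False))
    def test_pure_total_function_property(self, total, minor_raw, ploidy):
        """Every (CN, ploidy) pair maps to exactly one class; LOH tracks the
        minor allele only."""
        minor = min(minor_raw, total - minor_raw) if total else 0
        if minor < 0:
            minor = 0
        seg = pd.DataFrame([{"chrom": "c", "start": 1, "end": 2, "n_snps": 1,
                             "mean_lrr": 0.0, "mean_mbaf": 0.5,
                             "total_cn": total, "minor_cn": minor,
                             "major_cn": total - minor}])
        fit = cna.PloidyFit(ploidy=ploidy, purity=1.0,
                            wgd_flag=ploidy >= 3.0, fit_residual=0.0,
                            baseline_cn=ploidy)
        out = cna.classify_segments(seg, fit)
        klass, loh = self.oracle(total, ploidy, minor)
        assert out["klass"].iloc[0] == klass
        assert bool(out["loh"].iloc[0]) == loh
        assert out["klass"].iloc[0] in {cna.GAIN, cna.LOSS, cna.HIGH_AMP,
                                        cna.HOMDEL, cna.NEUTRAL}

    def test_named_examples(self):
        # ploidy 2, CN 3 -> gain; ploidy 4, CN 3 -> loss; (2,0) -> CN-LOH
        segs = pd.DataFrame([
            {"chrom": "c", "start": 1, "end": 2, "n_snps": 1, "mean_lrr": 0,
             "mean_mbaf": 0.5, "total_cn": 3, "minor_cn": 1, "major_cn": 2},
            {"chrom": "c", "start": 3, "end": 4, "n_snps": 1, "mean_lrr": 0,
             "mean_mbaf": 0.5, "total_cn": 2, "minor_cn": 0, "major_cn": 2},
        ])
        fit2 = cna.PloidyFit(2.0, 1.0, False, 0.0, 2.0)
        out2 = cna.classify_segments(segs, fit2)
        assert out2["klass"].iloc[0] == cna.GAIN
        assert out2["klass"].iloc[1] == cna.NEUTRAL and out2["loh"].iloc[1]
        fit4 = cna.PloidyFit(4.0, 1.0, True, 0.0, 4.0)
        assert cna.classify_segments(segs, fit4)["klass"].iloc[0] == cna.LOSS

    def test_cohort_cna_recovery(self, cohort, pipeline_result):
        """>= 90% of simulated CNAs >= 5 Mb are called with the right class
        in bulk samples of purity >= 0.6."""
        truth = cohort.truth
        checked = recovered = 0
        for branch, cnas in truth.branch_cnas.items():
            for c in cnas:
                if c["end"] - c["start"] + 1 < 5_000_000:
                    continue
                carriers = {
                    "trunk": ["pt_1", "cdx", "cell_line"],
                    "pt": ["pt_1"], "ctc": ["cdx", "cell_line"],
                    "cdx": ["cdx", "cell_line"]}[branch]
                for s in carriers:
                    calls = pipeline_result.cna.by_sample[s]["calls"]
                    wgd = pipeline_result.cna.by_sample[s]["fit"].wgd_flag
                    kind = c["kind"]
                    if wgd and branch in ("trunk", "pt", "ctc"):
                        # pre-WGD one-copy events double into ploidy-neutral
                        # LOH (losses) or stay gains
                        want = ("loh" if kind == "loss" else "gain")
                    else:
                        want = kind
                    seg = calls.loc[
                        (calls["chrom"] == c["chrom"])
                        & (calls["start"] <= (c["start"] + c["end"]) // 2)
                        & (calls["end"] >= (c["start"] + c["end"]) // 2)]
                    checked += 1
                    if len(seg) == 1:
                        r = seg.iloc[0]
                        ok = (r["loh"] if want == "loh"
                              else r["klass"] == want)
                        recovered += int(ok)
        assert checked > 0
        assert recovered / checked >= 0.9
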