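"""Synthetic cohort generator with known clonal ground truth.

The generator emulates the statistical structure of a CTC-derived-explant
study cohort: a rooted clone tree whose branches carry SNVs and copy-number
aberrations, samples composed as clone mixtures (germline, a WGA-amplified
CD45+ control pool, primary-tumor specimens, few-cell WGA CTC pools, a CDX
and a CDX-derived cell line), and per-site read counts with the artifacts
of whole-genome amplification — allele drop-out, spurious low-VAF calls and
regional locus dropout.  The clone tree has a fixed shape::

    normal -- trunk -+- pt -- pt_1 .. pt_k      (one private clone per PT)
                     +- ctc -+- ctc_private     (sampled by CTC pools only)
                             +- cdx             (optional WGD; CDX/cell line)

Every stochastic choice flows from a single seed, so a fixed configuration
is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ADO_RESIDUAL_VAF = 0.02   # allele fraction of the dropped allele's residue
DROPOUT_DEPTH_MEAN = 3.0  # Poisson mean depth inside locus-dropout blocks
DROPOUT_BLOCK_BP = 200_000
MIN_CALL_ALT_READS = 3    # caller emulation: a site is "called" at >= 3 alt reads

NORMAL = "normal"
TRUNK = "trunk"
PT = "pt"
CTC = "ctc"
CTC_PRIVATE = "ctc_private"
CDX = "cdx"


@dataclass
class SimulationConfig:
    """Study-scale cohort parameters.

    Defaults emulate the study conditions: 8 PT specimens, 6 pools of 5
    CTCs, WGA allele-dropout rate 0.2 and a false-positive rate of 14
    spurious calls per covered Mb (mid-range of the observed 7-21 per Mb),
    on a 54 Mb clinical-exome-sized target.
    """

    n_pt_specimens: int = 8
    n_ctc_pools: int = 6
    cells_per_pool: int = 5
    n_clones: int = 13            # trunk + pt + k pt-privates + ctc + ctc_private + cdx
    n_truncal_snvs: int = 18
    snvs_per_branch: int = 9
    private_snvs_per_pt: int = 6
    n_cnas: int = 13              # 3 truncal + 1 PT-branch + CTC/CDX-branch rest
    mean_depth_bulk: float = 100.0
    mean_depth_wga: float = 60.0
    # negative-binomial dispersion per sample, on top of a per-site capture
    # efficiency (lognormal, sd capture_log_sd) shared by all samples of the
    # cohort — shared capture bias cancels in tumor/normal coverage ratios
    depth_dispersion_bulk: float = 30.0
    depth_dispersion_wga: float = 2.0
    capture_log_sd: float = 0.3
    ado_rate: float = 0.2
    fpr_per_mb: float = 14.0
    target_size_mb: float = 54.0
    dropout_fraction: float = 0.1
    purity_by_sample: dict = field(default_factory=dict)
    ploidy_by_sample: dict = field(default_factory=dict)
    seed: int = 0
    # genome layout / nuisance parameters
    n_chromosomes: int = 9
    snp_spacing_bp: int = 25_000
    wga_baf_concentration: float = 25.0
    fp_vaf_range: tuple = (0.05, 0.3)
    silent_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in ("ado_rate", "dropout_fraction", "silent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("n_pt_specimens", "n_ctc_pools", "cells_per_pool",
                     "n_truncal_snvs", "snvs_per_branch", "n_cnas",
                     "n_chromosomes", "snp_spacing_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mean_depth_bulk", "mean_depth_wga",
                     "depth_dispersion_bulk", "depth_dispersion_wga",
                     "target_size_mb", "fpr_per_mb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_clones < 6:
            raise ValueError("n_clones must be >= 6 (fixed tree shape)")
        for v in self.purity_by_sample.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("purities must be in [0, 1]")
        n_true = (self.n_truncal_snvs + 3 * self.snvs_per_branch
                  + self.snvs_per_branch  # cdx branch
                  + self.n_pt_specimens * self.private_snvs_per_pt)
        expected_fp = self.fpr_per_mb * self.target_size_mb * (1 - self.dropout_fraction)
        if expected_fp > 10 * n_true:
            raise ValueError(
                "degenerate cohort: expected false positives per WGA sample "
                f"({expected_fp:.0f}) exceed true variants ({n_true}) 10-fold")

    def purity(self, sample: str, role: str) -> float:
        if sample in self.purity_by_sample:
            return self.purity_by_sample[sample]
        return {"pt": 0.6, "cdx": 0.9, "cell_line": 1.0, "ctc": 1.0,
                "germline": 0.0, "cd45": 0.0}[role]

    def wgd_on_cdx(self) -> bool:
        return self.ploidy_by_sample.get("cdx", 4.0) >= 3.0


@dataclass
class TruthRecord:
    """Simulated ground truth: clone tree, branch alterations, compositions."""

    clone_parent: dict               # clone -> parent clone (normal at root)
    branch_snvs: dict                # branch (clone) -> list of variant ids
    branch_cnas: dict                # branch (clone) -> list of CNA dicts
    sample_composition: dict         # sample -> {clone: fraction}
    per_variant_truth: pd.DataFrame  # variant_id, sample_id, truly_present,
                                     # expected_vaf, ado_dropped, false_positive
    wgd_clone: str | None

    def clades(self) -> dict:
        """clone -> set of clones in its subtree (inclusive)."""
        out = {c: {c} for c in self.clone_parent}
        for c in self.clone_parent:
            p = self.clone_parent[c]
            while p is not None:
                out[p].add(c)
                p = self.clone_parent[p]
        return out


@dataclass
class Cohort:
    """Simulated cohort: samples, variant observations, SNP tracks, truth."""

    config: SimulationConfig
    truth: TruthRecord
    samples: pd.DataFrame            # sample_id, role, is_wga
    variants: pd.DataFrame           # variant_id, chrom, pos, ref, alt,
                                     # consequence_class, is_driver, branch
    observations: pd.DataFrame       # variant_id x sample: depth, alt_count,
                                     # filter_flag, qss, called
    snp_tables: dict                 # sample -> chrom, pos, ref_count, alt_count
    coverage_masks: dict             # sample -> BED-like chrom, start, end
    chrom_sizes: dict

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.samples.loc[
            self.samples["role"].isin(["pt", "ctc", "cdx", "cell_line"]),
            "sample_id"])


# ---------------------------------------------------------------------------
# Primitive: one WGA-amplified site


def simulate_wga_site(
    true_genotype: str,
    depth_params: tuple[float, float],
    ado_rate: float,
    rng: np.random.Generator | int,
) -> dict:
    """Simulate the read counts of one site through whole-genome amplification.

    ``true_genotype`` is ``hom-ref``, ``het`` or ``hom-alt``; ``depth_params``
    is ``(mean, dispersion)`` of a negative-binomial depth model.  With
    probability ``ado_rate`` a het site loses one allele (chosen uniformly)
    and its VAF collapses toward 0 or 1.

    Returns ``{"depth", "ref_count", "alt_count", "vaf", "ado"}``.
    """
    if true_genotype not in ("hom-ref", "het", "hom-alt"):
        raise ValueError(f"unknown genotype {true_genotype!r}")
    mean, disp = depth_params
    if mean <= 0 or disp <= 0:
        raise ValueError("depth mean and dispersion must be positive")
    if not 0 <= ado_rate <= 1:
        raise ValueError("ado_rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    depth = int(rng.negative_binomial(disp, disp / (disp + mean)))
    p = {"hom-ref": 0.0, "het": 0.5, "hom-alt": 1.0}[true_genotype]
    ado = False
    if true_genotype == "het" and rng.random() < ado_rate:
        ado = True
        p = ADO_RESIDUAL_VAF if rng.random() < 0.5 else 1.0 - ADO_RESIDUAL_VAF
    alt = int(rng.binomial(depth, p)) if depth > 0 else 0
    return {"depth": depth, "ref_count": depth - alt, "alt_count": alt,
            "vaf": alt / depth if depth else float("nan"), "ado": ado}


# ---------------------------------------------------------------------------
# Cohort assembly helpers


def _negbin(rng, mean: np.ndarray, disp: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, float), 1e-9)
    return rng.negative_binomial(disp, disp / (disp + mean))


def _place_cnas(cfg: SimulationConfig, chrom_sizes: dict, rng) -> list[dict]:
    """Disjoint CNA intervals assigned to branches with a haplotype each."""
    n_extra = cfg.n_cnas - 4
    if n_extra < 0:
        raise ValueError("n_cnas must be >= 4 (3 truncal + 1 PT-branch)")
    n_ctc = int(np.ceil(n_extra * 0.55))
    plan = (
        [(TRUNK, "loss", 5.5), (TRUNK, "gain", 5.0), (TRUNK, "loss", 3.0),
         (PT, "loss", 5.0)]
        + [(CTC, ("loss", "loss", "gain")[i % 3], float(rng.uniform(1.5, 3.0)))
           for i in range(n_ctc)]
        + [(CDX, ("loss", "gain")[i % 2], float(rng.uniform(1.5, 2.5)))
           for i in range(n_extra - n_ctc)]
    )
    free = {c: 400_000 for c in chrom_sizes}  # next free offset per chromosome
    cnas: list = [None] * len(plan)
    # pack largest-first so big truncal events land on big chromosomes
    for i in sorted(range(len(plan)), key=lambda k: -plan[k][2]):
        branch, kind, size_mb = plan[i]
        size = int(size_mb * 1e6)
        chrom = max(chrom_sizes, key=lambda c: chrom_sizes[c] - free[c])
        if chrom_sizes[chrom] - free[chrom] < size + 200_000:
            raise ValueError("genome too small for the requested CNAs")
        start = free[chrom] + 1
        end = start + size - 1
        free[chrom] = end + 300_000
        cnas[i] = {
            "cna_id": f"cna_{i:02d}_{branch}_{kind}",
            "chrom": chrom, "start": start, "end": end,
            "branch": branch, "kind": kind,
            "hap": int(rng.integers(0, 2)),  # affected haplotype
        }
    return cnas


_PATHS = {
    TRUNK: (TRUNK,),
    PT: (TRUNK, PT),
    CTC: (TRUNK, CTC),
    CTC_PRIVATE: (TRUNK, CTC, CTC_PRIVATE),
    CDX: (TRUNK, CTC, CDX),
}


def _clone_path(clone: str) -> tuple:
    if clone == NORMAL:
        return ()
    if clone.startswith("pt_"):
        return (TRUNK, PT, clone)
    return _PATHS[clone]


def _clone_cn(clone: str, chrom: np.ndarray, pos: np.ndarray,
              cnas: list[dict], wgd_clone: str | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-position haplotype copy numbers (cnA, cnB) of one clone."""
    n = len(pos)
    cn = [np.ones(n), np.ones(n)]
    path = _clone_path(clone)
    delta = {"loss": -1, "gain": +1}
    for cna in cnas:
        if cna["branch"] not in path or cna["branch"] == CDX:
            continue
        m = (chrom == cna["chrom"]) & (pos >= cna["start"]) & (pos <= cna["end"])
        cn[cna["hap"]] = cn[cna["hap"]] + delta[cna["kind"]] * m
    if clone == wgd_clone:
        cn = [2 * cn[0], 2 * cn[1]]
    for cna in cnas:  # post-WGD events on the cdx branch
        if cna["branch"] == CDX and CDX in path:
            m = (chrom == cna["chrom"]) & (pos >= cna["start"]) & (pos <= cna["end"])
            cn[cna["hap"]] = cn[cna["hap"]] + delta[cna["kind"]] * m
    return np.maximum(cn[0], 0), np.maximum(cn[1], 0)


def _dropout_blocks(cfg: SimulationConfig, chrom_sizes: dict, rng) -> pd.DataFrame:
    """Random locus-dropout blocks (BED-like) totalling ``dropout_fraction``."""
    genome = sum(chrom_sizes.values())
    n_blocks = int(round(cfg.dropout_fraction * genome / DROPOUT_BLOCK_BP))
    chroms = list(chrom_sizes)
    rows = []
    taken: dict[str, list] = {c: [] for c in chroms}
    for _ in range(n_blocks):
        for _attempt in range(50):
            c = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, max(chrom_sizes[c] - DROPOUT_BLOCK_BP, 1)))
            end = start + DROPOUT_BLOCK_BP
            if all(end <= s or start >= e for s, e in taken[c]):
                taken[c].append((start, end))
                rows.append({"chrom": c, "start": start, "end": end})
                break
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def _complement(blocks: pd.DataFrame, chrom_sizes: dict) -> pd.DataFrame:
    rows = []
    for c, size in chrom_sizes.items():
        at = 0
        for b in blocks.loc[blocks["chrom"] == c].itertuples(index=False):
            if b.start > at:
                rows.append({"chrom": c, "start": at, "end": b.start})
            at = max(at, b.end)
        if at < size:
            rows.append({"chrom": c, "start": at, "end": size})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _in_blocks(blocks: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Membership of 1-based positions in BED-like (0-based half-open) blocks."""
    out = np.zeros(len(pos), bool)
    for b in blocks.itertuples(index=False):
        out |= (chrom == b.chrom) & (pos > b.start) & (pos <= b.end)
    return out


_BASES = np.array(list("ACGT"))


def _random_alleles(rng, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = _BASES[rng.integers(0, 4, n)]
    shift = rng.integers(1, 4, n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    return ref, alt


# ---------------------------------------------------------------------------
# Main entry


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Simulate a full cohort under ``config`` (see class docstring).

    Deterministic for a fixed configuration: the same seed reproduces the
    cohort exactly.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    # decreasing chromosome sizes (karyotype-like), summing to the target
    weights = np.arange(cfg.n_chromosomes, 0, -1) + 0.5
    sizes = (cfg.target_size_mb * 1e6 * weights / weights.sum()).astype(int)
    chrom_sizes = {f"chr{i + 1:02d}": int(sizes[i])
                   for i in range(cfg.n_chromosomes)}
    chrom_order = list(chrom_sizes)

    # --- samples ----------------------------------------------------------
    rows = [("germline", "germline", False), ("cd45", "cd45", True)]
    rows += [(f"pt_{i + 1}", "pt", False) for i in range(cfg.n_pt_specimens)]
    rows += [(f"ctc_{i + 1}", "ctc", True) for i in range(cfg.n_ctc_pools)]
    rows += [("cdx", "cdx", False), ("cell_line", "cell_line", False)]
    samples = pd.DataFrame(rows, columns=["sample_id", "role", "is_wga"])

    # --- clone tree -------------------------------------------------------
    n_pt_clones = cfg.n_clones - 5
    pt_clones = [f"pt_{i + 1}" for i in range(n_pt_clones)]
    clone_parent = {TRUNK: NORMAL, PT: TRUNK, CTC: TRUNK,
                    CTC_PRIVATE: CTC, CDX: CTC, NORMAL: None}
    for c in pt_clones:
        clone_parent[c] = PT
    wgd_clone = CDX if cfg.wgd_on_cdx() else None

    # --- CNAs and SNVs ----------------------------------------------------
    cnas = _place_cnas(cfg, chrom_sizes, rng)

    branch_snv_counts = {TRUNK: cfg.n_truncal_snvs, PT: cfg.snvs_per_branch,
                         CTC: cfg.snvs_per_branch,
                         CTC_PRIVATE: cfg.snvs_per_branch,
                         CDX: cfg.snvs_per_branch}
    for c in pt_clones:
        branch_snv_counts[c] = cfg.private_snvs_per_pt

    snv_rows = []
    used = set()
    for branch, count in branch_snv_counts.items():
        for _ in range(count):
            while True:
                chrom = chrom_order[int(rng.integers(cfg.n_chromosomes))]
                pos = int(rng.integers(1, chrom_sizes[chrom]))
                if pos % cfg.snp_spacing_bp == 0:
                    pos += 7
                if (chrom, pos) not in used:
                    used.add((chrom, pos))
                    break
            snv_rows.append({"chrom": chrom, "pos": pos, "branch": branch})
    variants = pd.DataFrame(snv_rows)
    ref, alt = _random_alleles(rng, len(variants))
    variants["ref"], variants["alt"] = ref, alt
    cons = np.where(rng.random(len(variants)) < cfg.silent_fraction,
                    "silent", "non-silent")
    cons[0] = "non-silent"  # the truncal driver
    variants["consequence_class"] = cons
    variants["is_driver"] = False
    variants.loc[0, "is_driver"] = True
    variants["false_positive"] = False

    # --- sample composition ----------------------------------------------
    comp: dict[str, dict[str, float]] = {
        "germline": {NORMAL: 1.0}, "cd45": {NORMAL: 1.0}}
    for i in range(cfg.n_pt_specimens):
        s = f"pt_{i + 1}"
        p = cfg.purity(s, "pt")
        sub = pt_clones[i % n_pt_clones]
        comp[s] = {NORMAL: 1.0 - p, PT: p / 2, sub: p / 2}
    for i in range(cfg.n_ctc_pools):
        s = f"ctc_{i + 1}"
        p = cfg.purity(s, "ctc")
        cells = rng.multinomial(cfg.cells_per_pool, [0.5, 0.5])
        comp[s] = {NORMAL: 1.0 - p}
        for clone, k in zip((CTC, CTC_PRIVATE), cells):
            if k:
                comp[s][clone] = p * k / cfg.cells_per_pool
    p = cfg.purity("cdx", "cdx")
    comp["cdx"] = {NORMAL: 1.0 - p, CDX: p}
    p = cfg.purity("cell_line", "cell_line")
    comp["cell_line"] = {NORMAL: 1.0 - p, CDX: p}
    comp = {s: {c: f for c, f in d.items() if f > 0} for s, d in comp.items()}

    # --- WGA dropout blocks / coverage masks ------------------------------
    wga_samples = list(samples.loc[samples["is_wga"], "sample_id"])
    dropout = {s: _dropout_blocks(cfg, chrom_sizes, rng) for s in wga_samples}
    coverage_masks = {s: _complement(dropout[s], chrom_sizes) for s in wga_samples}
    full = _complement(pd.DataFrame(columns=["chrom", "start", "end"]), chrom_sizes)
    for s in samples.loc[~samples["is_wga"], "sample_id"]:
        coverage_masks[s] = full.copy()

    # --- false-positive injection -----------------------------------------
    fp_rows = []
    fp_obs = {}  # (variant_index, sample) -> (depth, alt)
    for s in wga_samples:
        covered = coverage_masks[s]
        covered_bases = int((covered["end"] - covered["start"]).sum())
        n_fp = int(rng.poisson(cfg.fpr_per_mb * covered_bases / 1e6))
        lens = (covered["end"] - covered["start"]).to_numpy()
        picks = rng.integers(0, covered_bases, n_fp)
        cum = np.cumsum(lens)
        for off in picks:
            k = int(np.searchsorted(cum, off, side="right"))
            row = covered.iloc[k]
            pos = int(row["start"] + off - (cum[k] - lens[k]) + 1)
            if (row["chrom"], pos) in used:
                pos += 3
            used.add((row["chrom"], pos))
            idx = len(variants) + len(fp_rows)
            fp_rows.append({"chrom": row["chrom"], "pos": pos, "branch": "",
                            "consequence_class": "unknown", "is_driver": False,
                            "false_positive": True})
            # spurious calls mimic confidently-called artifacts: adequately
            # covered, low VAF but enough alt reads to be emitted as calls
            depth = max(int(_negbin(rng, cfg.mean_depth_wga,
                                    cfg.depth_dispersion_wga)), 8)
            vaf = rng.uniform(*cfg.fp_vaf_range)
            alt_count = int(np.clip(rng.binomial(depth, vaf), 5, depth))
            fp_obs[(idx, s)] = (depth, alt_count)
    if fp_rows:
        fp_df = pd.DataFrame(fp_rows)
        r, a = _random_alleles(rng, len(fp_df))
        fp_df["ref"], fp_df["alt"] = r, a
        variants = pd.concat([variants, fp_df], ignore_index=True)
    variants["variant_id"] = [
        f"{c}:{p}:{r}:{a}" for c, p, r, a in
        zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"])]

    # --- per-clone copy number & multiplicity at variant sites ------------
    v_chrom = variants["chrom"].to_numpy()
    v_pos = variants["pos"].to_numpy()
    clones = [NORMAL, TRUNK, PT, *pt_clones, CTC, CTC_PRIVATE, CDX]
    cn_tot = {}
    for c in clones:
        a, b = _clone_cn(c, v_chrom, v_pos, cnas, wgd_clone)
        cn_tot[c] = a + b
    v_branch = variants["branch"].to_numpy()
    mult = {}
    for c in clones:
        path = _clone_path(c)
        m = np.isin(v_branch, list(path)).astype(float)
        if c == wgd_clone:
            m = np.where(np.isin(v_branch, [b for b in path if b != CDX]),
                         2.0 * m, m)
        mult[c] = m

    # --- variant observations per sample ----------------------------------
    obs_frames = []
    truth_rows = []
    nv = len(variants)
    v_eff = rng.lognormal(-cfg.capture_log_sd ** 2 / 2, cfg.capture_log_sd, nv)
    for s, role, is_wga in samples.itertuples(index=False):
        frac = comp[s]
        num = np.zeros(nv)
        den = np.zeros(nv)
        mean_cn = 0.0
        for clone, f in frac.items():
            num += f * mult[clone]
            den += f * cn_tot[clone]
            mean_cn += f * (4.0 if clone == wgd_clone else 2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_vaf = np.where(den > 0, num / den, 0.0)
        mean_depth = (cfg.mean_depth_wga if is_wga else cfg.mean_depth_bulk)
        disp = (cfg.depth_dispersion_wga if is_wga else cfg.depth_dispersion_bulk)
        depth = _negbin(rng, mean_depth * v_eff * den / np.maximum(mean_cn, 1e-9),
                        disp)
        if is_wga:
            drop = _in_blocks(dropout[s], v_chrom, v_pos)
            depth = np.where(drop, rng.poisson(DROPOUT_DEPTH_MEAN, nv), depth)
        p_alt = exp_vaf.copy()
        ado_mask = np.zeros(nv, bool)
        if is_wga:
            ado_mask = (rng.random(nv) < cfg.ado_rate) & (exp_vaf >= 0.3)
            lost_alt = rng.random(nv) < 0.5
            p_alt = np.where(ado_mask,
                             np.where(lost_alt, ADO_RESIDUAL_VAF,
                                      1.0 - ADO_RESIDUAL_VAF),
                             p_alt)
            het = (exp_vaf > 0) & ~ado_mask
            conc = cfg.wga_baf_concentration
            noisy = rng.beta(np.maximum(p_alt * conc, 1e-6),
                             np.maximum((1 - p_alt) * conc, 1e-6))
            p_alt = np.where(het, noisy, p_alt)
            ado_mask &= lost_alt  # truth flag: the *alt* allele dropped
        alt_count = rng.binomial(depth.astype(int), np.clip(p_alt, 0, 1))
        # overlay this sample's injected false positives
        for (idx, fs), (d, a) in fp_obs.items():
            if fs == s:
                depth[idx], alt_count[idx] = d, a
        called = alt_count >= MIN_CALL_ALT_READS
        flag = np.where(called,
                        np.where(rng.random(nv) < 0.1, "t_lod_fstar", "PASS"),
                        "NOCALL")
        qss = alt_count * 31
        obs_frames.append(pd.DataFrame({
            "variant_id": variants["variant_id"], "sample_id": s,
            "depth": depth.astype(int), "alt_count": alt_count.astype(int),
            "filter_flag": flag, "qss": qss.astype(int), "called": called}))
        is_fp = np.array([(i, s) in fp_obs for i in range(nv)])
        truth_rows.append(pd.DataFrame({
            "variant_id": variants["variant_id"], "sample_id": s,
            "truly_present": exp_vaf > 0, "expected_vaf": exp_vaf,
            "ado_dropped": ado_mask, "false_positive": is_fp}))
    observations = pd.concat(obs_frames, ignore_index=True)
    per_variant_truth = pd.concat(truth_rows, ignore_index=True)

    # --- SNP tracks --------------------------------------------------------
    snp_rows = []
    for chrom in chrom_order:
        pos = np.arange(cfg.snp_spacing_bp, chrom_sizes[chrom] + 1,
                        cfg.snp_spacing_bp)
        snp_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    snps = pd.concat(snp_rows, ignore_index=True)
    n_snp = len(snps)
    phase_a = rng.random(n_snp) < 0.5  # alt allele on haplotype A?
    s_eff = rng.lognormal(-cfg.capture_log_sd ** 2 / 2, cfg.capture_log_sd, n_snp)
    s_chrom = snps["chrom"].to_numpy()
    s_pos = snps["pos"].to_numpy()
    cn_ab = {c: _clone_cn(c, s_chrom, s_pos, cnas, wgd_clone) for c in clones}

    snp_tables = {}
    for s, role, is_wga in samples.itertuples(index=False):
        frac = comp[s]
        num = np.zeros(n_snp)
        den = np.zeros(n_snp)
        mean_cn = 0.0
        for clone, f in frac.items():
            a, b = cn_ab[clone]
            num += f * np.where(phase_a, a, b)
            den += f * (a + b)
            mean_cn += f * (4.0 if clone == wgd_clone else 2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_baf = np.where(den > 0, num / den, 0.5)
        mean_depth = (cfg.mean_depth_wga if is_wga else cfg.mean_depth_bulk)
        disp = (cfg.depth_dispersion_wga if is_wga else cfg.depth_dispersion_bulk)
        depth = _negbin(rng, mean_depth * s_eff * den / np.maximum(mean_cn, 1e-9),
                        disp)
        p_alt = exp_baf.copy()
        if is_wga:
            drop = _in_blocks(dropout[s], s_chrom, s_pos)
            depth = np.where(drop, rng.poisson(DROPOUT_DEPTH_MEAN, n_snp), depth)
            ado = rng.random(n_snp) < cfg.ado_rate
            lost_a = rng.random(n_snp) < 0.5
            lost_alt = lost_a == phase_a
            p_ado = np.where(lost_alt, ADO_RESIDUAL_VAF, 1.0 - ADO_RESIDUAL_VAF)
            conc = cfg.wga_baf_concentration
            noisy = rng.beta(np.maximum(p_alt * conc, 1e-6),
                             np.maximum((1 - p_alt) * conc, 1e-6))
            p_alt = np.where(ado, p_ado, noisy)
        alt_count = rng.binomial(depth.astype(int), np.clip(p_alt, 0, 1))
        table = pd.DataFrame({
            "chrom": s_chrom, "pos": s_pos,
            "ref_count": depth.astype(int) - alt_count.astype(int),
            "alt_count": alt_count.astype(int)})
        if s == "germline":
            gq = np.where(rng.random(n_snp) < 0.96, 99,
                          rng.integers(5, 30, n_snp))
            table["gq"] = gq.astype(int)
        snp_tables[s] = table

    branch_snvs = {
        b: list(variants.loc[(variants["branch"] == b), "variant_id"])
        for b in branch_snv_counts}
    branch_cnas: dict[str, list] = {}
    for cna in cnas:
        carrier = cna["branch"]
        a, b = _clone_cn(carrier,
                         np.array([cna["chrom"]]),
                         np.array([(cna["start"] + cna["end"]) // 2]),
                         cnas, wgd_clone)
        entry = dict(cna)
        entry["total_cn"] = int(a[0] + b[0])
        entry["minor_cn"] = int(min(a[0], b[0]))
        branch_cnas.setdefault(carrier, []).append(entry)

    truth = TruthRecord(
        clone_parent=clone_parent,
        branch_snvs=branch_snvs,
        branch_cnas=branch_cnas,
        sample_composition=comp,
        per_variant_truth=per_variant_truth,
        wgd_clone=wgd_clone,
    )
    return Cohort(
        config=cfg, truth=truth, samples=samples,
        variants=variants.drop(columns=["false_positive"]),
        observations=observations, snp_tables=snp_tables,
        coverage_masks=coverage_masks, chrom_sizes=chrom_sizes,
    )


def config_to_dict(cfg: SimulationConfig) -> dict:
    return dataclasses.asdict(cfg)
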