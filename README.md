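# ctclineage

Clonal-lineage genomics of circulating tumor cells (CTCs): a tested
analysis pipeline relating whole-exome profiles of a primary tumor, pools
of whole-genome-amplified (WGA) CTCs, a CTC-derived explant (CDX) and its
cell line.

Few-cell WGA samples are the hard part of such cohorts: amplification
drops one allele of a heterozygous site at a high rate (allele drop-out,
ADO), creates spurious low-VAF calls at several events per megabase, and
leaves parts of the target uncovered.  This package implements the
inference chain that still extracts lineage information from them:

* **Somatic filtering** — hard tumor/normal thresholds (caller flag PASS /
  `t_lod_fstar`; coverage ≥ 8 in tumor and normal; QSS ≥ 30; VAF_T ≥ 0.05
  with ≥ 5 alt reads; VAF_N = 0), a read-count **rescue** of low-VAF
  variants confirmed in ≥ 2 tumor samples, and a **high-confidence CTC
  rule** (a pool's call must recur in ≥ 1 PT specimen, the CDX, or another
  pool) that removes nearly all WGA false positives.
* **WGA QC** — ADO estimated from germline het variants vs the CD45+
  control pool (two-sided Fisher exact, p < 0.05, germline VAF ∈ [0.2, 0.8],
  WGA VAF < 0.1 or > 0.9); FPR = calls absent from PT ∪ CDX per Mb covered
  ≥ 8×.
* **Allele-specific copy number** — per-SNP LRR/BAF, circular binary
  segmentation of both signals, a grid-search purity/ploidy fit on the
  integer (major, minor) lattice, and ploidy-relative classes
  (gain > ploidy+0.5, loss < ploidy−0.5, amplification > ploidy+2,
  homozygous deletion < 0.5, LOH iff minor CN = 0).
* **CTC aberration rescue** — known aberrations are detected in noisy CTC
  pools by per-SNP allelic-imbalance direction consistency with a cleaner
  reference sample, tested against the pool's own copy-neutral background
  (Fisher exact p < 0.05 with ≥ 80% consistent SNPs).
* **Set accounting** — ternary status matrices, recurrence histograms,
  Venn partitions with the reported integer percentages, Ward/cosine
  VAF clustering.
* **Phylogeny** — Fitch parsimony with a ratchet search over binary
  presence/absence characters (non-silent, ≥ 2 samples, present = VAF > 0),
  germline-rooted branch assignment of SNVs and CNAs.

Because the real data for such studies are controlled-access, the package
ships a first-class **synthetic cohort generator** (`ctclineage.simulate`)
with a known clone tree, branch-assigned alterations and explicit WGA
artifact processes; every stage is validated end-to-end against that
ground truth.  `docs/methods.md` details the models and defaults.

## Worked example

The numbered scripts under `analysis/` run the chain on a simulated
study-scale cohort (8 PT specimens, 6 pools of 5 CTCs, ADO 0.2, 14
spurious calls/Mb, tetraploid CDX):

```
$ python analysis/01_simulate_cohort.py --seed 0
cohort written to results/cohort
  samples: 18 (7 WGA)
  somatic variants: 102 true, 4807 injected artifacts
  het SNPs per sample: 2156
  CNAs: trunk:3, pt:1, ctc:5, cdx:4

$ python analysis/02_filter_variants.py
  ctc_1: 668 primary -> 24 final
  ...
  PT union 74, CDX set 36, 14 rescued site-sample pairs

$ python analysis/03_wga_qc.py
  ADO rate (CD45 vs germline): 0.200 over 1796 het sites (simulated truth 0.2)
  ctc_1: 13.4 false positives/Mb (650 events, 48.6 Mb >= 8x)
```

A raw CTC pool carries ~700 calls of which only ~25 survive the
high-confidence rule — the rest are the injected WGA artifacts; the ADO
and FPR estimators read the simulated rates (0.2 and 14/Mb) back off the
data.  Copy number (`04`), CTC rescue (`05`), accounting (`06`) and the
tree (`07`) continue:

```
$ python analysis/04_call_cnas.py
sample_id  ploidy  purity   wgd  n_segments  n_aberrant
     pt_1     2.0    0.58 False          18           7
     ...
      cdx     4.0    0.87  True          33          15
cell_line     4.0    0.98  True          35          19

$ python analysis/07_build_phylogeny.py
tree (score 67) -> results/tree.nwk
  (cdx,(((((((((((pt_2,pt_7),pt_6),pt_1),pt_5),pt_4),pt_8),pt_3),germline),ctc_1),((((ctc_5,ctc_6),ctc_3),ctc_2),ctc_4)),cell_line));
```

PT specimens fit as diploid at their simulated 0.6 purity, the CDX and
cell line as whole-genome-doubled tetraploids; the tree separates the PT
clade from the CTC+CDX+cell-line lineage, with the CDX/cell-line pair as a
clade inside it — the simulated clonal structure.

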