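# Methods

`ctclineage` re-implements, as a tested pipeline, the comparative genomic
inference used to relate circulating tumor cells (CTCs) to the primary tumor
they came from and to the xenograft (CDX) they can seed: somatic variant
filtering tuned for whole-genome-amplified (WGA) few-cell samples,
quantification of the WGA artifacts themselves, allele-specific copy-number
calling, a rescue procedure that detects known aberrations in CTC profiles
too noisy for de novo calling, cohort-level set accounting, and a
maximum-parsimony clonal phylogeny.  Because the sequencing data such
studies rest on are controlled-access, every stage is exercised on a
synthetic cohort with known clonal ground truth; this note records the
models, the defaults, and what the synthetic validation does and does not
establish.

## The synthetic cohort

### Clone tree and samples

The generator (`ctclineage.simulate`) builds a fixed-shape clone tree

```
normal — trunk —+— pt — pt_1 … pt_k        (one private subclone per PT specimen)
                +— ctc —+— ctc_private     (sampled only by CTC pools)
                        +— cdx             (whole-genome doubled; CDX + cell line)
```

and samples as clone mixtures: a bulk germline, a WGA-amplified CD45+
control pool (normal cells only), `n_pt_specimens` primary-tumor specimens
(`purity` 0.6, half of the tumor fraction in a specimen-private subclone),
`n_ctc_pools` pools of `cells_per_pool` cells drawn multinomially from the
two CTC-sampled clones, a CDX (purity 0.9) and a CDX-derived cell line
(purity 1.0).  Branches carry SNVs (18 truncal, 9 per major branch, 6
private per PT specimen by default) and copy-number aberrations (13 by
default: 3 truncal, 1 PT-branch, the rest split between the CTC and CDX
branches).  The CDX clone undergoes whole-genome doubling, so pre-WGD
one-copy losses become copy-neutral LOH (2+0) and its own post-WGD events
produce odd total copy numbers — which is what makes the tetraploid
solution identifiable for the ploidy fit.

The genome is a 54 Mb target (clinical-exome scale) split over nine
chromosomes of decreasing size, with germline-heterozygous SNPs every 25 kb
and phased haplotypes; each CNA deletes or duplicates one haplotype, so BAF
directions are consistent along a segment and across samples sharing the
event.  This phase structure is what the allelic-imbalance rescue exploits.

### Read-count model

Depths are negative binomial around a per-sample mean (bulk 100x, WGA 60x)
multiplied by a per-site capture efficiency (lognormal, log-sd 0.3) shared
by all samples.  The shared factor matters: capture bias cancels in
tumor/normal coverage ratios, as it does in real capture data; modelling
tumor and normal depths as independent overdispersed draws would roughly
double the LRR noise and is not what exome data look like.  On top of this,
WGA samples get heavier per-sample dispersion, a `dropout_fraction` (0.1)
of the target in contiguous 200 kb blocks forced to ~3x (locus dropout,
the "not covered" cells of the status matrices), per-site allele drop-out
(ADO) at rate `ado_rate` (0.2) that collapses a het site's allele fraction
to ~0.02 or ~0.98 with the lost haplotype chosen at random, beta-binomial
allele sampling (concentration 25) for surviving het sites, and spurious
private calls injected uniformly over the covered target at
`fpr_per_mb` (14, the mid-range of rates such samples show) with VAF
0.05–0.30.  ADO is an operational per-site model, not a polymerase model;
simulated sites are independent because no spatial-correlation scale for
amplification bias is established.

Spurious calls are injected with enough support (depth >= 8, >= 5 alt
reads) to survive the hard somatic filters, because they model artifacts
that *pass* a caller, not borderline noise; consequently the per-Mb FPR is
measured on post-filter calls, and what removes these artifacts is the
cross-sample high-confidence rule, not the per-sample thresholds.

What passing tests show: the estimators recover the rates and structure the
generator encodes, at study scale, through the full pipeline.  What they do
not show: robustness to mapping artifacts, indel-realignment noise,
position-correlated amplification bias, subclonal copy number, or
contamination structures the generator does not emulate.

## Variant filtering

Hard thresholds per tumor/normal pair, all boundaries inclusive: caller
flag PASS or `t_lod_fstar` (a generic `caller_blacklist` boolean stands in
for caller-internal exclusion flags), coverage >= 8 in both samples,
QSS >= 30, tumor VAF >= 0.05 with >= 5 alt reads, zero alt reads in the
normal.  Rejections carry the first failing rule, in that order.

The low-VAF rescue re-admits a variant into a sample when it passed the
primary filter in >= 2 tumor samples and the sample's read counts show
support; the support threshold (>= 2 alt reads at VAF >= 0.01, normal
clean) is a declared choice exposed in `FilterPolicy`, since "reliable"
is not otherwise quantified.  Sites without a usable read-count entry
(depth < 8) are `not_covered` and never rescued.

High-confidence CTC calls must be present in >= 1 PT specimen, the CDX
lineage, or >= 1 other CTC pool.  Two choices here: the "other pool"
criterion is evaluated on raw per-pool calls (the rescue-augmented mode is
available but off by default, since rescue itself already uses
cross-sample evidence), and "the CDX" means the union of CDX and cell-line
calls — the two samples are the same lineage and are tabulated together
throughout.

## WGA quality control

ADO: germline variants eligible when covered >= 8x in both samples with
>= 5 alt reads at >= 5% and genotype quality >= 30; each is tested with a
two-sided Fisher exact test on `[[ref,alt]_germline; [ref,alt]_WGA]` and
scored as dropout if p < 0.05, germline VAF in [0.2, 0.8] and WGA VAF
< 0.1 or > 0.9.  Two-sided is a declared choice: the VAF window already
encodes direction.  FPR: calls absent from PT-union and CDX divided by Mb
covered >= 8x (BED mask), a deliberately conservative definition that
counts true lineage-private variants as false positives; in the synthetic
cohort this bias is ~2% of the rate.

## Copy-number calling

Per germline-het SNP, `LRR = log2((d_T/median d_T)/(d_N/median d_N))` and
`BAF = alt/(alt+ref)`; the formulas are standard practice, chosen here
because no canonical definition exists for them.  Circular binary
segmentation runs per chromosome on LRR and on mirrored BAF
(`|BAF−0.5|+0.5`), with the maximal circular-arc t-statistic tested by
permutation (alpha 0.01, 200 permutations with early stopping, minimum 10
SNPs per segment).  The two breakpoint sets are unioned (intersection mode
available); slivers below the minimum width that the union can create are
folded into the closer-mean neighbor, and adjacent segments are re-merged
when both |Δmean LRR| < 0.1 and |Δmean mirrored BAF| < 0.05 — the BAF
conjunct is kept so that a copy-neutral LOH boundary with flat LRR
survives merging.

A segment's allelic imbalance is *not* the raw folded-BAF mean: folding
inflates a balanced segment's mean by the binomial sampling noise (~0.54
at 100x).  Instead `0.5 + sqrt(max(mean((BAF−0.5)^2) − mean(0.25/depth), 0))`
subtracts the noise floor; without this correction the ploidy fit
systematically prefers dense low-purity/high-ploidy lattices.

Ploidy/purity: a grid search (purity 0.10–1.00 step 0.01; baseline copy
number — the total CN mapping to LRR 0 — 1.0–8.0 step 0.05) minimizes the
SNP-count-weighted squared distance of segment (LRR, mirrored BAF) pairs to
the lattice of integer (major, minor) expectations

```
E[LRR | t]    = log2((p·t + 2(1−p)) / (p·b + 2(1−p)))
E[mBAF | M,m] = (p·M + (1−p)) / (p·(M+m) + 2(1−p))
```

with two regularizers: 0.001 per baseline copy (resolving the exact
genome-doubling degeneracy — doubling all CNs with p → p/(2−p) reproduces
both signals — toward the lower-ploidy solution unless odd-copy segments
pin it) and a 1e-4 bonus toward higher purity on exact ties.  This lattice
fit is a declared simplification with the same inputs and outputs as
pattern-based ploidy/purity callers.  Ploidy is the weighted median total
CN; WGD is flagged at ploidy >= 3.0 (no published criterion; exposed).
Classification relative to ploidy: gain > ploidy+0.5, loss < ploidy−0.5,
high-level amplification > ploidy+2, homozygous deletion < 0.5, LOH iff
minor CN = 0.

## Aberration rescue in CTC pools

For a catalogued aberration (aberrant or LOH segments of the bulk samples,
matched across samples at >= 50% reciprocal overlap, direction reference
taken from the highest-purity carrier: cell line, then CDX, then PT), each
in-segment SNP informative in the CTC (depth >= 10, |BAF−0.5| > 0.1 —
both exposed; the deviation threshold is a declared choice) is scored
consistent or discordant with the reference sample's BAF direction at that
SNP.  The counts are compared by a one-sided (enrichment) Fisher exact
test against the same counts over background SNPs from the reference's
copy-neutral non-LOH segments — the background controls for the pool's own
WGA noise.  In the background the reference has no true direction, so the
raw sign of its BAF is used; under the null agreement is a coin flip, and
this convention keeps the assessment exactly invariant under mirroring all
BAFs.  Present requires p < 0.05 *and* >= 80% consistent SNPs.  Aberrations
with no reference BAF direction (balanced gains) are flagged `lrr_only`
and reported not-evaluable rather than silently absent.

## Accounting and phylogeny

Status matrices are ternary (mutated / not mutated / not covered at depth
< 8); `not_covered` cells never count as absence in any sharing
computation.  Venn partitions assign each alteration to exactly one region
by its group-presence signature; percentages are integers, half-up, which
reproduces every printed worked example (e.g. 32/205 → 16%).  Sample
clustering uses PCA and hierarchical clustering with cosine distance and
Ward linkage as specified; Ward on a non-Euclidean metric is formally
improper, so an average-linkage fallback is exposed, but the default is
fidelity.  Cross-sample CNA identity uses >= 50% reciprocal overlap with
equal class (exposed; no published rule exists).

The character matrix holds non-silent alterations present in >= 2 samples,
binarized as VAF > 0, plus an all-zero germline outgroup column.  Trees
are scored by weighted Fitch parsimony (bitmask implementation, vectorized
over characters) and searched with a parsimony ratchet: per iteration, 25%
of characters are double-weighted, NNI hill-climbing runs under the
perturbed then the original weights, and the best tree is kept; ties are
broken by lexicographically smallest canonical Newick, with all co-optimal
trees retrievable.  Instances with <= 7 leaves are solved exactly by
enumerating all topologies (<= 945), which is cheaper than the heuristic
and guarantees the exhaustive-search optimum the validation demands; the
ratchet schedule (200 iterations by default, 60 in the pipeline driver,
where convergence is immediate at 17 leaves) applies above that size.
Sample columns are sorted by name before the search so the result cannot
depend on caller column order.  For branch assignment the tree is rooted
at the germline leaf and an alteration maps to the edge whose downstream
leaf set *equals* its presence set; anything else is flagged homoplastic.
Under WGA artifacts this is the honest outcome for, e.g., a truncal
variant dropped in one pool.  CNAs do not enter the search matrix; they
are mapped onto the SNV tree post hoc (the alternative is a config away).

## Problem sizes and determinism

The default cohort is 18 samples, ~100 true somatic variants plus ~4800
injected artifacts, 2156 het SNPs over 54 Mb — sizes chosen so the whole
pipeline runs in about 1.5 minutes on one core while keeping every rate
estimate within useful binomial error.  All randomness flows from explicit
seeds (`numpy.random.default_rng`); a fixed configuration is
byte-reproducible, and the test suite and acceptance script are seeded
throughout.

## Known limitations

* The ploidy fit assigns clonal integer states only; subclonal
  (fractional) copy number is out of scope, and a near-balanced tumor with
  no odd-copy segment is genuinely unidentifiable up to doubling (the
  baseline penalty then picks the lower ploidy).
* The generator ignores interactions between CNAs and SNV multiplicity
  beyond whole-genome doubling (a deletion never removes an acquired
  mutation from its haplotype).
* Indels are matched by exact (chrom, pos, ref, alt) identity; inputs are
  assumed left-normalized upstream.
* Sex chromosomes are not modelled; all simulated chromosomes are
  autosome-like.
* The parsimony search above 7 leaves is heuristic; optimality there is
  supported by the ratchet-vs-hill-climb property and the recovered truth
  clades, not by proof.
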