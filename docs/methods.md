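# Methods

`gametrace` implements an integrative analysis of gamete transcriptomes and
sperm promoter chromatin: it classifies transcripts by where they are
expressed (sperm, oocyte, both, or inconsistently between donors), clusters
sperm promoters into chromatin states from H3K4me3/H3K27me3 coverage,
follows both the chromatin states and the transcripts through
preimplantation development, germ layers and tissues, and scores
tumor-vs-normal deregulation per cancer type.  Because the real inputs are
large public RNA-seq/ChIP-seq compendia, the package ships a synthetic-data
generator that emulates their statistical structure with planted truth
labels, so every stage is testable end to end without downloads.

## Gamete transcript classes

The input is a transcripts × samples TPM matrix with ≥ 2 donor replicates
per gamete.  A transcript is *expressed* in a sample when TPM ≥ t (default
t = 1 TPM, configurable; the unit is already length- and depth-normalized,
so a single threshold is meaningful across samples).  Per gamete g it is
*consistent* when expressed in all replicates of g and *absent* when
expressed in none.  The classes are then

* **Sp** — consistent in sperm, absent in oocyte;
* **Oc** — the mirror image;
* **SpOc** — consistent in both;
* **NotExpressed** — absent in both;
* **Misc** — any remaining strict partial replicate pattern, i.e.
  inconsistent between donors; these are reported but excluded from
  downstream stages.

The all-replicates rule is the default; `min_fraction` relaxes consistency
to a majority rule when donor counts are larger.  "Specific" deliberately
requires absence (not mere inconsistency) in the other gamete, so the five
classes partition the transcript set.

## Promoter chromatin states

Promoters are ±10 kb windows around the TSS, binned at 100 bp (200 bins per
mark) in the direction of transcription; windows overhanging a chromosome
start keep their shape with missing bins zero-filled.  Bin signal is the
mean bedGraph coverage over the bin, scaled to counts-per-million by the
track's total signal integral, then log2(1+x) transformed.  The ChIP
normalization of the original datasets is not knowable from our inputs;
CPM+log2 is the package's explicit default.

Promoters are clustered with k-means (k-means++ initialization, n_init=10,
max_iter=300, fixed seed) on the concatenated per-bin-standardized
[K4 ‖ K27] vectors, separately within each (transcript class × biotype)
analysis group.  Two numerical choices matter here:

* **Variance floor.** Plain per-bin standardization amplifies the ~360
  far-flank bins — which contain only background noise — to unit variance,
  drowning the ~40 informative promoter-proximal bins.  Each bin's sd is
  floored at 25% of the largest bin sd before standardizing.
* **Model selection.** `k = "auto"` picks k ∈ {2..6} by mean silhouette,
  evaluated on the central-2 kb (K4, K27) summary plane — the scale on
  which the state vocabulary is defined — rather than on the 400-dim
  profile vectors, where the silhouette of any k > 2 is washed out by
  flank noise.  A config override pins k when the analysis requires it.

Clusters are labeled with quantile thresholds computed over the full
promoter universe (q50 and q75 of the per-promoter central-2 kb mean, per
mark): a cluster is **bivalent** when its mean central K4 ≥ q50(K4) and
K27 ≥ q75(K27); otherwise **high_K4** when K4 ≥ q75(K4); otherwise
**low_K4** when K4 ≥ q50(K4); otherwise **K4⁻K27⁻**.  The central 2 kb is
used because flank-wide means dilute narrow K4 peaks.  Labeling uses
cluster means, which keeps the rule stable even when individual promoters
sit near a quantile boundary.

`trace_states` re-derives each sperm cluster's label in another
compartment: thresholds are recomputed from that compartment's own
promoter-wide signal distribution, the cluster's mean central signal is
re-labeled, and the status is *maintained* (same label re-derives), *lost*
(K4⁻K27⁻ re-derives for a marked state) or *changed:<label>*.  Passing the
full promoter universe for the compartment keeps the quantiles meaningful
when one subgroup loses all signal.

## Expression dynamics

Stage-level expression is the mean TPM across replicates per stage,
ordered by the organism's grid.  Heatmap exports use row Z scores of
log2(TPM+1) with the sample (n−1) standard deviation; constant rows become
zeros rather than NaN.  The ZGA window is a property of the stage grid:
4-cell → 8-cell in human, 2-cell → 4-cell in mouse.

Trajectory calling is a total function into five patterns, applied in
order:

1. **zga_activated** — every pre-ZGA stage mean < t and the maximum from
   the ZGA start onward ≥ t·fold (fold = 2);
2. **early_then_degraded** — every stage up to and including the ZGA start
   ≥ t, final stage ≤ max(early)/fold, and non-increasing from the ZGA
   start (consecutive means may rise at most 10%, absorbing replicate
   noise);
3. **flat_on / flat_off** — always ≥ t (resp. < t) with max/min fold ratio
   < fold, computed on TPM+1 so the ratio stays defined at zero;
4. **other** — anything else.

Stage specificity (and the tissue/spermatogenesis `panel_specificity`)
flags rows whose peak Z ≥ 1.5 while every other stage stays below 0.5.
These cutoffs are package defaults standing in for a visual criterion; they
are exposed in the API.

## Enrichment

Term over-representation is the one-sided hypergeometric test
P(X ≥ k | N, K, n) via `scipy.stats.hypergeom`, with Benjamini–Hochberg
FDR across tested terms; terms with zero query overlap are dropped, and
the default report filter is p < 0.05 with FDR also emitted.  The default
background for a class-specific query is all classified transcripts.

Motif analysis extracts ±250 bp promoter sequences (reverse-complemented
for − strands), scans both strands with log2-odds PWMs against a uniform
(optionally empirical) nucleotide background, and calls a hit when the
score reaches 80% of the maximum attainable score; `N` bases contribute
zero log-odds, and a PWM no more informative than the background yields no
hits.  Enrichment counts promoters-with-≥1-hit (binary), keeping the
hypergeometric model exact; JASPAR-style count matrices get a 0.5
pseudocount per cell.  TF–target coupling across stages is a Spearman
correlation between the TF's stage means and the mean trajectory of its
motif-hit targets.

## Tumor-vs-normal deregulation

All effect sizes work on log2(TPM+1) (defined at zero TPM).  Per gene and
cancer code: the cohort Z score uses a Welch-style pooled standard error
(cohort sizes between tumor panels and fallback normals are highly
unequal), the log2 fold change is the difference of cohort means, and
significance comes from a tie-corrected rank-sum (Mann–Whitney) test with
BH-FDR across genes within the code.  A gene is called **up**/**down**
when FDR < 0.05 and |log2FC| ≥ 1 — an explicit, configurable stand-in for
an unstated decision rule.  Codes lacking ≥ 2 matched normals can attach a
fallback normal cohort (e.g. an external consortium); provenance is
recorded per code so users can stratify, and no batch correction is
attempted between normal sources.  The pan-cancer count is the number of
codes with a non-none call.  Note the calls are *not* invariant under
rescaling all TPMs, because log2(TPM+1) is not scale-free.

## Synthetic data generator

The generator's defaults define the study conditions used throughout the
tests: 1200 transcripts (35% lincRNA / 50% protein-coding / 15% other
ncRNA), 2 donor replicates per gamete, class fractions Sp 0.35 / Oc 0.12 /
SpOc 0.35 / Misc 0.09 / NotExpressed 0.09.  Expression noise is log-normal
on the log2(TPM+1) scale — the pipeline starts from TPM, so count-level
(negative-binomial) realism is unnecessary.  Expressed draws use sd 0.55
around class/state means; absent compartments draw |N(0, 0.15)|, keeping
both sides ≈ 4.5σ away from the 1 TPM threshold.  Misc transcripts are
expressed in a strict nonempty replicate subset of one gamete; an optional
dropout probability (default 0) zeroes their expressed cells.

Chromatin states are planted only for sperm-expressed transcripts, three
states at lincRNA promoters (high_K4 0.40 / low_K4 0.35 / none 0.25) and
four at protein-coding promoters (0.30 / 0.25 / bivalent 0.30 / none
0.15).  The class fractions above make marked promoters ≈ 55% of the
universe, which keeps the q50/q75 label thresholds inside signal bands
instead of on the background median.  Peaks are Gaussian: K4 sd 500 bp
(narrow active mark), K27 sd 2 kb (broad repressive domain), amplitudes
high_K4 30 / low_K4 8 / bivalent (10, 20) over background 1, with 5%
log-scale amplitude jitter and N(0, 0.5) bin noise clipped at zero.  Sperm
expression means are coupled to the planted state (6.5 > 5.0 > 4.2 > 3.5
on log2(TPM+1)), reproducing the expression–K4 correlation.

Trajectories follow the class: Sp → zga_activated, SpOc →
early_then_degraded, Oc → flat_on, Misc/NotExpressed → flat_off.  The
spermatogenesis panel peaks in round spermatid for K4-marked
sperm-expressed transcripts and in an earlier cell type otherwise.  In
germ layers and tissues, Sp high/low-K4 promoters (both biotypes) lose
their marks to background while Sp-PCG bivalent promoters retain both —
the retention map is configurable per (class, biotype, state) — and
post-implantation expression follows retention.  Tumor cohorts (26
TCGA-style codes, 12 tumor / 12 normal each by default, sd 0.5 around a
base mean of 3) plant a +2 log2FC for one designated Sp-lincRNA high-K4
gene in exactly 21 codes, random ±2 shifts for the remaining Sp-lincRNA
high-K4 genes, and no shift elsewhere; the last 5 codes carry no matched
normals and exercise the fallback-normal merge.

All draws flow from `numpy` Generators seeded as `default_rng([seed,
block])` in a fixed block order (layout, coordinates, expression, sperm
coverage, tumor, soma coverage, PWMs, terms, genome), so bundles are
byte-identical given a seed.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read-level sampling noise and mappability,
overlapping transcripts and ambiguous multi-mapping (the reason the
original analysis restricts to intergenic lincRNAs), inter-donor
biological variability beyond iid log-normal noise, input-subtracted ChIP
backgrounds, batch effects between normal sources, and tumor purity or
copy-number effects.

## Problem sizes and tolerances

The test and acceptance runs use the default 1200-transcript bundle, a
200/200 planted-motif sequence set, n = 50/50 cohorts for fold-change
recovery and 26 × 30/30 null cohorts for calibration — sizes at which every
recovery metric is stable across seeds.  Exactness checks compare the
binned signal against per-base enumeration (≤ 1e-9) and hypergeometric
p-values against exhaustive enumeration for all instances with N ≤ 25
(≤ 1e-12).  Calibration checks run 1000 permutations (null
over-representation level ≈ 0.04 at p < 0.05; the discrete test is
conservative) and 26-code null cohorts (false-call rate ≈ 0 thanks to the
|log2FC| ≥ 1 gate).

## Known limitations

* The labeling rule compares cluster means against promoter-universe
  quantiles; with < 50% marked promoters the q50 threshold degrades toward
  the background median and K4⁻K27⁻/low-K4 distinctions become unstable.
* Auto-k maximizes a 2-D silhouette and will merge states that differ only
  in profile *shape* at identical central signal.
* The rank-sum normal approximation is inaccurate below ~8 samples per
  cohort; cohorts of 2–7 samples pass validation but their p-values should
  be treated as indicative.
* Stage grids assume every stage has ≥ 1 sample; there is no imputation,
  smoothing, or pseudotime inference.
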