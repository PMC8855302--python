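# Methods

## Scope and model

`zdecay` implements the transcriptome-analysis layer of a mouse
maternal-to-zygotic transition (MZT) experiment in which a zygotically
expressed decay factor is depleted and the consequences for maternal mRNA
clearance are read out by spike-in-normalized RNA-seq, RT-qPCR,
immunofluorescence and 3′-ligation RACE. The pipeline starts from a gene ×
sample FPKM matrix (alignment and quantification are upstream and out of
scope) and covers:

1. **Spike-in normalization.** Exogenous spike-in species (identifier
   prefix `ERCC-`) are present at fixed amounts per sample, so after
   correct scaling their levels must be equal across samples. We compute
   per-sample factors by median-of-ratios against a geometric-mean
   reference: `ref_g = geomean_j(x_gj)` over samples for each spike-in
   `g`, then `s_j = median_g(ref_g / x_gj)`. The median makes the factor
   robust to individual spike-in dropout; zero readings are treated as
   missing (not as infinite ratios), and a sample with more than half its
   spike-ins missing triggers a warning. Endogenous totals after scaling
   are proportional to absolute transcript copy number, which is the
   property the analysis needs: global transcriptome output falls across
   the transition and fails to fall when decay is blocked, a signal that
   per-library normalization would erase.

2. **Flooring.** After scaling, endogenous genes with values < 1 FPKM in
   all samples are excluded, and remaining values < 1 are set to 1;
   spike-ins are exempt. Flooring guarantees finite ratios downstream
   without pseudocounts. Whether flooring precedes or follows scaling is
   a genuinely open choice; we scale first because flooring is a
   convention applied to final normalized values, and we state this as our
   own convention rather than an inference about anyone else's code.

3. **Dynamic-class calling.** Replicate values are averaged
   (arithmetically) per stage, and each gene's zygote/2-cell ratio `r`
   assigns it to one of three classes: maternal decay (`r > fold`),
   zygotic activation (`1/r > fold`), stable (otherwise), with `fold = 2`
   by default. A ratio exactly at the threshold goes to the stable class
   so the three classes always partition the universe (strict
   inequalities on both sides leave equality unassigned). Group
   trajectories are medians over member genes of replicate-averaged
   values; knockdown effects are ratios of group medians between
   conditions, reported as "increased by f-fold" above 1 and "decreased
   by 1/f-fold" below. Differential sets between conditions at one stage
   use the same strict-ratio rule. The degraded-in-WT reference set used
   in overlap analyses has its own threshold (> 3) and is passed
   explicitly, never conflated with the classification fold of 2.

4. **Overlap enrichment.** Overlap fractions are printed-style
   percentages (one decimal, round half-up). Enrichment is the one-sided
   upper-tail hypergeometric probability `P(X >= k)` for
   `X ~ Hypergeom(N, |A|, |B|)`, computed via `scipy.stats.hypergeom`
   with the log-survival form reported alongside so that overlaps whose
   p-values underflow doubles (log10 p well below −300) remain
   comparable. A t-test cannot produce a set-overlap p-value, so no other
   test is offered. The universe is always an explicit argument and is
   recorded in outputs.

5. **RACE tail calling.** Reads are modeled as
   `prefix + anchor + A^a + U^u + linker` in cDNA space (U sequenced as
   T). The anchor is located by its rightmost exact match (upstream
   content is irrelevant), the linker by its leftmost match after the
   anchor; the terminal T run and the A run immediately 5′ of it are the
   oligo(U) and poly(A) calls. Any other residue between them is a parse
   failure — mixed tails are flagged, not guessed. Exact matching is the
   default because the intended inputs are Sanger reads of TA clones; a
   Hamming-distance tolerance and a reverse-complement pre-pass are
   available as flags. "Uridylated" means oligo(U) length ≥ 1 by default
   (configurable), and the summary bins reads at poly(A) < 20 nt versus
   ≥ 20 nt, the bin edge at which uridylation enrichment on short tails
   is conventionally reported.

6. **Assay formulas.** qPCR uses the ddCT scheme with Gapdh as default
   reference: `dCT = CT(gene) − CT(ref)` per replicate,
   `ddCT = mean dCT(test) − mean dCT(control)`, `fold = 2^(−ddCT)`. The
   population formula is silent on replicate aggregation; we aggregate
   from replicate means of dCT and retain per-replicate folds
   `2^(−ddCT_i)` for a fold-scale SEM (a dCT-scale SEM is emitted too —
   fold-scale is the default report). Significance is a Welch
   (unequal-variance) two-sided t-test on replicate dCT values; Welch is
   chosen because equal variances across conditions is an assumption we
   have no grounds to make. Immunofluorescence signal is
   `S = A_d(S_a − S_ba) / (A_a(S_d − S_bd))`, i.e. background-subtracted
   antibody intensity normalized to the DNA channel with area weighting;
   compartment proportions divide each compartment's S by their sum.

## Synthetic data: what it emulates and what it does not

The simulator encodes the study design as its defaults: two stages
(zygote, 2-cell) × two conditions (WT, knockdown) × 2 replicates; 624
decaying, 140 activated and 495 stable genes (the observed three-class
proportions at one-tenth scale, keeping runtimes in seconds); a 92-species
spike-in mix spanning ~3.5 decades, constant across samples by
construction; per-class fold changes of 4 (no per-class effect-size
distribution is published, so these are fixtures, not estimates);
knockdown multipliers of 2.32 on decaying genes and 1/4.37 on activated
genes at the 2-cell stage only (siRNA is injected at the zygote stage and
acts later, so zygote expectations are identical across conditions — and
the multipliers are the magnitudes of the published group-median effects);
multiplicative log-normal noise with σ = 0.2 natural-log units, the
standard noise model for strictly positive FPKM-scale data, at a level
giving replicate Spearman correlations ≈ 0.97, matching well-correlated
duplicates. Activated genes peak at the 2-cell stage (they are
near-absent before genome activation); the other classes peak in the
zygote. Gene peak abundances are drawn log-uniform over ~6–300 FPKM so
that divided levels stay above the flooring threshold.

The simulator does **not** model read-level sampling, library-size or GC
effects, transcript isoforms, batch structure, or biological covariance
between genes; noise is independent per gene × sample. Passing
label-recovery tests therefore demonstrates correctness of the decision
rules under the stated noise model, not classifier performance on real
embryo data. RACE simulation draws poly(A) lengths uniformly on [0, 60]
with uridylation probability 0.8 below 20 nt and 0.1 above (uniform
oligo(U) length 1–8 nt); qPCR simulation adds independent Gaussian noise
per CT channel. All generators require an explicit seed and are
bit-reproducible.

## Numerical choices and edge cases

- Spike-in factors: zeros are missing data for the median; an all-zero
  spike-in column is an error, not a silent fallback.
- The absolute scale of normalized values is anchored to the
  geometric-mean spike-in reference. Consequently, multiplying one sample
  column by `c` changes all normalized values by the single global factor
  `c^(1/n)` while every ratio-based downstream quantity (classification,
  relative totals, fold changes, QC) is exactly invariant; an anchor
  that made absolute values strictly invariant would stop the
  no-op case (identical spike-in columns → factors of 1) from holding.
- Spearman QC uses average ranks for ties; groups with one replicate are
  skipped with a notice rather than failing the run.
- Boundary ratios exactly at a fold threshold are non-significant
  (stable / neither set), everywhere, by the strict-inequality rule.
- Hypergeometric p-values: the natural-scale value may underflow to 0;
  the log10 value is the durable quantity.
- ddCT with a single replicate reports the fold but no SEM/p (warning);
  zero-variance replicate sets (noise-free simulations) bypass the t-test
  and report p = 1 or 0 by mean equality.
- Tail parsing of an empty tail yields the `no-tail` class with lengths
  (0, 0); summaries exclude reads whose anchor or linker was not found.

## Problem sizes

Tests and the acceptance script run the simulator at its default scale
(1259 genes, 8 samples) or smaller, 100–500 RACE reads, and exhaustive
enumeration oracles on universes of ≤ 30 elements; the full suite
completes in a few seconds.

## Known limitations

- The three-class rule is a pure fold-threshold classifier; no dispersion
  modeling or FDR control is intended (or appropriate, given duplicate
  libraries), and none is provided.
- Set enrichment assumes a fixed, explicit universe; results are only as
  meaningful as that choice.
- The tail parser is grammar-exact by design and will reject genuinely
  mixed tails (e.g. A-U-A), which some single-molecule datasets contain;
  it targets clone-level Sanger data.
- Compartment proportions operate on already-quantified signals; image
  segmentation is out of scope.
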