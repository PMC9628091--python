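# Methods

## The problem and the estimand

Plasma cell-free DNA (cfDNA) carries CpG methylation marks from its tissues
of origin. Given low-input enzymatic methyl-seq of a two-group patient
cohort — here, good versus poor coronary collateral circulation (CCC),
graded angiographically — the pipeline asks which small genomic regions are
differentially methylated between the groups, and whether a handful of them
suffice to predict group membership in held-out samples.

Because cfDNA sequencing depth per CpG is low, single-CpG methylation calls
are noisy. The working statistic is therefore the **average methylation
fraction (AMF)** of a 100-bp bin: for a sample and bin,

    AMF = (methylated read observations at reference CpGs in the bin)
        / (all read observations at reference CpGs in the bin),

a depth-weighted ratio over read observations, not an average over distinct
CpGs. Only CpG-dense bins (>= 5 reference CpGs) are used, which stabilizes
the ratio at low depth. A bin with no covered CpG in a sample is missing,
never zero.

## Pipeline stages and their assumptions

1. **QC and matrix assembly.** A sample passes QC when its enzymatic
   conversion rate (1 − residual CHH methylation fraction; CHH cytosines
   are essentially unmethylated in human DNA) strictly exceeds 0.99 and the
   median over bins of per-bin average CpG depth is >= 3. After stacking
   per-sample AMF vectors, a bin is retained only when its missing-cell
   fraction is strictly below 10%. Blacklist/repeat masking is applied at
   the CpG-call level: the pipeline's entry point is per-cytosine call
   files, so read-level masking upstream is out of its hands; for CpGs
   fully inside masked intervals the two are equivalent.

2. **Unsupervised structure.** Bins are screened by across-sample SD
   (z-score of the SD vector > 2, SD computed on observed cells only),
   missing cells are imputed with group means, and a centered PCA (top 30
   components, deterministic sign convention) is run. Component
   significance uses a permutation null: each bin's values are shuffled
   independently across samples — preserving every bin's marginal while
   destroying inter-bin correlation — and the cutoff is the maximum
   top-component variance proportion over the permutations. A whole-column
   shuffle would leave the covariance spectrum untouched and provide no
   null, which is why the per-bin scheme is the only meaningful reading.
   Retained components are correlated with clinical covariates (Pearson;
   point-biserial via 0/1 coding for binaries; Spearman in parallel).

3. **DMR screen.** The cohort is split 85:15 into training and test,
   stratified by group with per-group round-half-up (so 109/34 gives
   93/29 train and 16/5 test). Three full-size bootstrap subsets are drawn
   with replacement from the training set, stratified within group so the
   small group is never lost. Within each subset every bin with > 90%
   non-missing bootstrap observations gets Welch's unequal-variances
   t-test (methylation variance is heteroscedastic along the genome);
   p-values become Benjamini–Hochberg q-values; good-minus-poor mean
   differences are z-standardized across all tested bins. A subset's DMRs
   satisfy q < 0.05 and |z| > 2 (hypomethylated when z < −2). The final
   candidates are the bins selected in **all** subsets that also rank in
   the top 500 of **every** subset's q-ordering (ties: larger |z|, then
   coordinate).

   Bootstrap duplicates count as independent observations — plain
   bootstrap semantics. A consequence worth stating: a single subset's
   p-values are mildly anti-conservative (the effective sample size is
   smaller than the nominal one), so on a null cohort an individual subset
   flags on the order of 0.5–1.5% of tested bins. Selectivity is restored
   by the three-way intersection and rank filter, which on null data
   retain well under 1%. This is exactly the role the resampling cascade
   plays: reproducibility screening, not single-test calibration.

4. **Marker selection.** A random-forest classifier is trained on the
   candidate AMF profiles of the training samples (missing cells imputed
   with training-group means; test cells with overall training means — no
   label leakage). `mtry` (max_features) is tuned on a three-point grid
   {⌊√p/2⌋, ⌊√p⌋, 2⌊√p⌋} by 10×10 repeated stratified cross-validation
   with CV AUC as the criterion; 500 trees. The training ROC is built from
   out-of-fold CV predictions — forest resubstitution predictions are
   near-perfect by construction and carry no information. Importance is
   mean decrease in Gini impurity (scikit-learn's normalized variant;
   rankings match R's MeanDecreaseGini, scales differ). The top 20 markers
   are annotated exon > intron > intergenic against an exon table, with
   nearest gene and signed distance.

5. **External validation.** Marker-interval AMF is recomputed from
   external healthy-cfDNA per-CpG bed files with the identical
   depth-weighted definition; external samples with a covered CpG in fewer
   than half the marker regions are excluded. Per region the healthy
   distribution is compared with the study groups (two-sided Mann–Whitney
   vs the good group) and summarized by a *stringency* indicator: healthy
   IQR <= poor IQR + 0.05 and healthy median >= poor median − 0.05. This is
   an explicit reporting heuristic for "similar to or tighter than the
   high-methylation group", not an inferential test; the tolerance also
   absorbs read-count quantization (a saturated near-1 group can have an
   exactly-zero sample IQR that no continuous cohort can undercut).

## The synthetic cohort

The generator emulates the data regime the analysis assumes, at the
per-CpG call level:

- two unbalanced groups, defaults 109 "good" vs 34 "poor";
- 5,000 bins of 100 bp on two synthetic chromosomes; 20% of bins are
  CpG-sparse (< 5 CpGs) to exercise the density filter, dense bins carry
  5–12 CpGs placed uniformly without collision;
- each bin's background methylation mean is Beta(50, 3)-distributed
  (mean ≈ 0.94) — the near-1, narrow cfDNA background; a sample's bin
  methylation is Beta with that mean and across-sample SD 0.03
  (`within_spread`);
- 100 bins are hypomethylated DMRs: the good group's mean drops by 0.3
  (`dmr_effect`) and its SD widens by 0.10 (`dmr_spread`), reproducing the
  wide-good / narrow-poor AMF pattern the screen is meant to find;
- per-CpG read depth is i.i.d. Poisson(8); zero-depth CpGs are absent from
  the call file, so missingness arises mechanically;
  P(bin uncovered) = E[exp(−k·depth)] over the bin's CpG count k, and
  `missing_target` inverts this formula for the depth;
- CHH calls carry a 0.005 per-read false-methylation probability
  (conversion rate ≈ 99.5%, comfortably above the 99% gate);
- clinical covariates (age, sex, hypertension, diabetes, smoking) are
  drawn independently of group with realistic marginals, so
  characteristics-table association tests are null by construction;
- the healthy validation cohort (12 samples, depth 30) follows each marker
  region's poor-group mean with a tighter spread (0.02), reflecting the
  narrower AMF distributions reported for healthy reference cfDNA.

What the generator does **not** model: fragment-level correlation between
adjacent CpGs within a read (CpGs are conditionally independent given the
bin's methylation level), batch effects, GC-coverage bias, tissue
deconvolution structure, or alignment artifacts beyond a bin-aligned
blacklist. Passing tests therefore demonstrate that the pipeline recovers
the structure it is designed for under its own stated noise model — not
that it would behave identically on real cfDNA, where inter-CpG
correlation effectively reduces the number of independent observations per
bin.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; bin identifiers are
  `chrom:start-end`.
- The 10% null filter and the 99% conversion gate are strict inequalities
  (`< 0.10`, `> 0.99`).
- "Median of average depth" is the median over covered bins of
  (total observations / covered CpGs) per bin.
- Welch's test guards the zero-variance degenerate case: equal means give
  p = 1, unequal means give ±inf t and a p floored at the smallest
  positive float (never a division error). q-values default to
  Benjamini–Hochberg with enforced monotonicity; an `empirical-null`
  option rescales by an estimated null proportion (twice the fraction of
  p > 0.5, capped at 1) in the spirit of empirical-null FDR tools, whose
  density-estimation internals are not reproduced exactly.
- PCA sign convention: each component's largest-|loading| entry is
  positive. The permutation cutoff is a maximum, so it is non-decreasing
  in the number of permutations.
- All randomness flows from one global seed through
  `numpy.random.SeedSequence` spawning into per-stage seeds; reports are
  JSON with sorted keys, and a repeated run is byte-identical.
- Test problem sizes: the study-scale configuration (143 samples, 5,000
  bins, 100 DMRs) is used for recovery, null-calibration and determinism
  checks; recovery and classifier checks aggregate 20 seeds; the
  permutation-PCA null check uses 4 cohorts × 25 permutation seeds at 200
  permutations each (the cutoff is a max, so fewer permutations make the
  zero-significant-components check harder, not easier). Classifier
  sanity checks use a reduced CV protocol (5-fold × 1, 150 trees, fixed
  mtry) since they measure held-out AUC rather than tuning behavior; the
  pipeline default remains 10×10 CV.

## Known limitations

- Counts reported by the published study (e.g. 606,483 retained bins,
  42,092 variance-screened bins, 1430 intersection DMRs, 256 candidates)
  depend on the non-public patient cohort and are not reproduction
  targets; the pipeline reproduces the *procedure* and its arithmetic
  (split sizes, gates, thresholds), with recovery measured against the
  generator's ground truth instead.
- The empirical-null q-value option is an approximation, not a
  re-implementation of density-based estimators.
- Region annotation uses a minimal exon-table gene model; UTRs, promoters
  and strand-aware distance conventions are out of scope.
- The healthy-cohort comparison is descriptive; its stringency indicator
  is a labeled heuristic with a fixed 0.05 tolerance.
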