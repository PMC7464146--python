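# Methods

This note defines every statistical procedure implemented in `nedmr`,
in the order the pipeline runs them. All genomic intervals are 0-based,
half-open `[start, end)`. All stages are deterministic given a seed.

## 1. Synthetic data generation (`nedmr.simulate`)

A two-chromosome genome (10 Mb each) carries gene models with TSS
coordinates, CpG-island annotations, and array probes. The generator plants:

- **DMRs**: clusters of 3 probes (40 bp spacing) whose NE-tumor beta values
  are shifted by a configurable Δβ (default 0.35, half hypo-, half
  hyper-methylated) relative to both non-NE tumors and normal lung.
  Background probes draw from a bimodal baseline (Beta(2,10) or Beta(10,2)
  per probe); per-sample values come from a Beta distribution with
  concentration 60 around the (possibly shifted) baseline mean. Planted
  probes use the baseline mode compatible with the effect sign so the shift
  never saturates at 0 or 1. Entries go missing completely at random at
  rate 0.005.
- **Methylation–expression links**: one gene with TSS within ±400 kb of each
  planted DMR; tumor expression is `5 + slope·(DMR summary beta) + noise`
  with configurable sign and noise SD.
- **Tissue modules**: six gene modules with tissue-specific elevation across
  an 18-tissue panel; one module is brain-high, and its genes are also
  shifted +1 SD in NE tumors. Module genes are drawn disjoint from the
  link-partner genes so the other modules are genuinely null for NE status.
- **ATAC peaks**: negative-binomial counts (dispersion 0.05) for 2000 peaks
  over 3 NE and 5 non-NE cell lines with 2 replicates each; library-size
  factors in [0.7, 1.4]. 100 peaks get a planted NE log2 fold-change of 4;
  40% of those sit inside planted-DMR 500 bp consensus windows. For each
  planted peak placed in a DMR window, the DMR's linked gene's cell-line
  expression tracks the peak's per-line log2 accessibility (z-scored),
  creating recoverable peak–gene couplings.

Everything planted is recorded in a truth manifest (JSON-serializable).

## 2. NE-DMR calling (`nedmr.dmr`, `DMRCaller`)

**Probe filter.** A probe is removed if, within any of the three groups, more
than 5% of its values are missing, or its within-group standard deviation is
zero. Removal counts are reported; `n_remaining = n_input − n_removed`.

**Testing.** Each surviving probe is tested NE vs normal and NE vs non-NE
with the two-sided Mann–Whitney U test. When the pooled sample size is ≤ 12
the p-value is computed by exact enumeration of all label assignments on
midranks (tie-aware); otherwise the normal approximation with tie correction
is used (SciPy). Missing values are dropped pairwise.

**Selection.** With m tests per comparison, a probe passes iff, in *both*
comparisons, the Bonferroni-adjusted p-value (`min(1, m·p)`) is < 0.01 and
the absolute difference of group medians exceeds 0.1.

**Merging.** Each passing probe becomes a 101 bp window
`[pos − 50, pos + 51)`. Windows sharing at least one base are merged
transitively (book-ended windows are not merged). The merge report records
the count identity: probes not in any multi-probe region each form a
singleton DMR, plus one DMR per multi-probe region. The per-sample DMR
summary is the NaN-aware median beta over member probes.

**Annotation.** DMRs are annotated with promoter overlap (strand-aware
[TSS−2000, TSS+500)), CpG class (island / shore = 2 kb flank / open sea) and
all genes with a TSS within ±500 kb of the DMR midpoint.

## 3. DMR–expression linking (`nedmr.linking`, `DMRGeneLinker`)

Candidate pairs are (DMR, gene) with `|TSS − DMR midpoint| ≤ 500 kb`
(inclusive; midpoint = floor((start+end)/2)). For each pair, Pearson r is
computed on pairwise-complete tumor samples (minimum 3; pairs below the
minimum are flagged and excluded from the cutoff). The significance
threshold is the empirical 98th percentile of |r| over all candidate pairs
(linear-interpolation quantile); a link is significant iff |r| strictly
exceeds it. As an analytic reference, the minimal |r| that stays significant
under Bonferroni correction is solved from the t-transform
`t = r√(n−2)/√(1−r²)` via root finding; for n = 151 samples and 135,250
tests at α = 0.05 it is 0.3997, i.e. ≈ 0.4.

## 4. Tissue modules (`nedmr.modules`, `TissueModuleClusterer`)

The tissue panel is log10(x+1)-transformed; duplicate gene rows keep the
highest-SD entry; zero-variance rows are dropped; rows are mean-centered.
Classical (Torgerson) MDS embeds genes in 3 dimensions: the squared
Euclidean distance matrix is double-centered, eigendecomposed, and the top-3
eigenvector coordinates scaled by √eigenvalue are kept, with a deterministic
sign convention. k-means (K = 6, 50 restarts, fixed seed) partitions the
embedding; modules are renumbered by descending size (ties by smallest gene
id). Ward hierarchical clustering on the standardized matrix, cut at K,
provides a consistency check via the adjusted Rand index.

## 5. Module scoring (`nedmr.scoring`, `ModuleScorer`)

Tumor expression rows are z-scored across samples (ddof = 1; FPKM-like
inputs are log2(x+0.5)-transformed first); a sample's module score is the
mean z over the module's matched genes (zero-variance genes excluded). AUC
against the binary NE label uses the rank (Mann–Whitney) formulation with
ties counted one half; the ROC curve comes from a threshold sweep.

## 6. Differential accessibility (`nedmr.atac`, `NBDifferentialTest`)

Size factors are median-of-ratios: per-peak geometric-mean reference over
peaks with all-positive counts (nonzero-entry fallback available), per-sample
median ratio, rescaled to geometric mean 1. Per-peak dispersion is estimated
by the method of moments on normalized counts, `(s² − m)/m²` within each
group, keeping the larger of the two estimates, clipped to [1e-8, 10]; the
maximum compensates the downward bias introduced by flooring negative
estimates and keeps the Wald test's type-I rate near nominal. Each peak is
fit with a negative-binomial log-link GLM (intercept + NE indicator,
log-size-factor offsets) by iteratively reweighted least squares; the group
coefficient's Wald z against the normal distribution gives the p-value
(floored at the smallest positive double), Benjamini–Hochberg adjusted;
peaks with q < 0.05 are called differential.

## 7. Peak–gene links (`nedmr.peaks`, `PeakGeneLinker`)

Differential peaks are classified: **TSS** iff the peak overlaps any
[TSS−1000, TSS+1001) window; **distal** iff the peak midpoint is more than
10,000 bp from every TSS; otherwise **intermediate** (excluded). Replicate
counts are averaged per cell line on the normalized log2(x+1) scale
(≥ 4 lines required). TSS peaks link to genes whose TSS window overlaps the
peak and pass at |r| > 0.7; distal peaks link to genes with
|TSS − midpoint| ≤ window (200 kb / 500 kb / 1 Mb) and pass at r > 0.7
(positive only, since distal accessibility is expected to activate; an
option admits |r|). Unique genes of passing TSS links form the TSS gene
signature.

## 8. Integration (`nedmr.integrate`)

DMRs are standardized to 500 bp consensus windows centered on the midpoint,
clamped to chromosome bounds (clamping shortens, never re-centers). Overlap
between window sets uses an interval tree; sharing one base counts,
book-ended intervals do not; fractions are reported in both directions.
Module correlation profiles represent each gene by its maximal-|r| link per
data layer (accessibility links from cell lines, methylation links from
tumors) and tabulate per-module fractions over bins partitioning [−1, 1],
plus an unlinked fraction; fractions sum to 1 per module and layer.
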