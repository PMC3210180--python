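# Methods

## The prediction model

The pipeline treats enhancer prediction as template matching of chromatin
profiles. The template is a 5 × 100 matrix of tag counts: for each of the five
enhancer-characteristic histone modifications (H3K4me1, H3K4me2, H3K4me3,
H3K9ac, H3K27ac), a 10-kb window centered on each training anchor is divided
into 100 bins of 100 bp, a tag contributes to the bin holding its midpoint
`⌊(start+end)/2⌋`, and the binned vectors are summed element-wise over
anchors. Summation (not averaging) preserves integer counts; correlation-based
scoring is scale-free, so the distinction does not affect downstream scores.

Anchors enter the template only if significantly tag-enriched for all five
positive marks and for none of the negative controls (default set H3K27me3,
H3K36me3, H4K20me1; configurable, since mark panels vary between assays).
Enrichment of a window of length L is `P(X ≥ k)` for `X ~ Poisson(λ₀·L)`,
where λ₀ is the genome-wide tag rate (total tags / total genome length) of
that assay. The threshold is Bonferroni-corrected by the number of candidate
sites times the number of marks tested — the most conservative reading of
"corrected for multiple tests". "Not enriched" for a negative mark means its
p-value exceeds the same corrected threshold.

Scanning slides the 10-kb window across each DHS site in 100-bp steps, with
candidate centers from the site start to the site end inclusive. Each window
is binned per mark and compared to the template by Spearman's rank
correlation; the five per-mark coefficients are averaged and the maximum over
steps is the site's score. A site is called an enhancer when its best score is
at least the cutoff (default ρ = 0.5; for n = 100 bins this corresponds to
p ≈ 1e-7 on the t transformation of ρ, and n is kept an explicit parameter
because the effective number of independent bins is assay-dependent). The
recorded anchor is the 100-bp bin centered on the best window center,
matching the scan resolution.

### Numerical conventions

- Spearman's ρ is the Pearson correlation of mid-ranks. Binned tag counts are
  extremely tie-heavy (mostly zeros), so the tie-free shortcut formula would
  be wrong; mid-ranks handle ties exactly.
- A window in which some mark's counts are constant (typically all zero) has
  no defined rank correlation for that mark; such marks contribute 0 to the
  average. This guarantees that tag deserts can never reach the cutoff.
- Score ties between window centers resolve to the smallest (leftmost)
  center; windows that would overhang a chromosome end are skipped, and a DHS
  site none of whose windows fit yields a no-call sentinel.
- All coordinates are 0-based half-open throughout; RepeatMasker `.out`
  (1-based inclusive) is converted at the parsing boundary.
- Anchors whose training window would overhang a chromosome edge are dropped
  rather than truncated, preserving the 100-bin geometry of the sum.

## Promoter filtering

Promoters share much of the enhancer signature and sit in open chromatin, so
provisional calls are screened against CAGE: a genome-wide 100-bp bin is
CAGE-enriched when its tag count passes the Poisson test against the CAGE
background rate at a Bonferroni threshold of α divided by the number of
genome-wide bins. Calls anchored within 1 kb (configurable) of an enriched
bin are flagged as promoters and removed; the retained/removed sets partition
the provisional calls exactly.

## Cross-validation and ROC

The anchor set is shuffled into 10 folds whose sizes differ by at most one
(137 anchors give seven folds of 14 and three of 13). For each fold the
template is rebuilt from the other nine folds and scores (a) each held-out
anchor window and (b) an equal number of random windows drawn uniformly with
probability proportional to chromosome length, excluding anchor windows
(collisions are resampled). Anchor selection is not re-run per fold — the
anchor list is fixed before validation. Pooled score lists are converted to
an ROC curve by counting scores ≥ c at thresholds c = 1.00, 0.98, …, −1.00
(interval 0.02, read as cumulative normalized frequencies — the only reading
that produces a monotone curve), closed at (0,0) and (1,1); AUC is the
trapezoidal area. At this interval the AUC is within 0.01 of the exact
pairwise statistic P(true > false) + ½P(tie).

## TE attribution

A call is TE-derived when its 100-bp anchor overlaps ≥ 1 bp of a repeat
interval (judging overlap on the anchor, not the 10-kb window, since the
anchor is the recorded locus; the DHS interval can be used instead). Ties go
to the repeat with maximal overlap, then the longer, then the leftmost.
Family classification follows Repbase: SINE/Alu → Alu, SINE/MIR → MIR,
LINE/L1 → L1, LINE/L2 → L2, class LTR → LTR, class DNA → DNA, all else
Other. Expected counts allocate the observed TE-derived total across the six
major families proportionally to annotated bp, so expectations conserve the
observed total by construction; the χ² goodness-of-fit test then has df = 5.
The family age proxy defaults to mean percent divergence from consensus; an
explicit age table may be substituted. Sharing between cell types is greedy
one-to-one anchor-overlap matching (each call joins at most one pair), with
the shared fraction over the union |A| + |B| − |shared|; the hypergeometric
under-sharing test exposes its full parameterization (population, shared
successes, TE-derived draws, shared TE-derived observed) rather than
hard-coding one reading.

## Expression linkage

Transcriptional units merge same-strand transcripts that overlap, taken
transitively; boundaries are the outermost transcript ends, and the TSS is
the strand-appropriate end. Probe-level matrices are averaged over probes
fully contained in the unit span. Enhancers are counted in the window
TSS ± 50 kb (the "100-kb window surrounding the TSS"; half-open on the
right). Genes are differential when one-way ANOVA across the two cell-type
groups gives p ≤ 1e-7 — a threshold treated as already multiplicity-adjusted,
with no second correction — and direction follows the sign of the group-mean
difference. Count asymmetry at differential genes is a Wilcoxon signed-rank
test on per-gene (same-cell, other-cell) count pairs: zeros dropped, tied
absolute differences mid-ranked, W the positive-rank sum, with an exact
two-tailed p by convolution of the null rank-sum distribution for ≤ 15
nonzero pairs and a tie-corrected normal approximation beyond. Divergence
deciles sort genes by mean(A) − mean(B) on the normalized-intensity scale (no
log transform, matching a plain subtraction), split them into 10 equal bins
(remainder spread over leading bins), and average the per-gene normalized
count difference n_A/total_A − n_B/total_B per bin; normalization by
per-cell-type call totals is a config choice (`per-total` or `none`). Genes
with zero enhancers in both cell types are included.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, not
sequencing mechanics (no read sequences, fragment-size models or mappability).

**Placement.** Signal features (enhancers and promoters) sit on an evenly
spaced lattice across the chromosomes with ±1 kb jitter, guaranteeing the
≥ 10 kb separation invariant; background DHS sites occupy the interleaving
lattice positions. A configuration whose genome cannot satisfy the guarantee
is rejected up front. Each feature owns a 500-bp DHS interval in the cell
types where it is active; enhancer activity splits 40/40/20 between cell A
only, cell B only, and both. Promoters are active in both cell types.

**Tag landscapes.** Each assay has a uniform Poisson background (default
1e-3 tags/bp for histone marks and DHS, 5e-5 for CAGE) plus, at active
features, per-bin Poisson counts with mean A·shape(offset), where the shape
is one or two Gaussian bumps. Defaults: H3K4me1/H3K4me2 bimodal with bumps at
±1 kb and 500-bp width; H3K4me3/H3K9ac/H3K27ac unimodal with 700-bp width;
promoters unimodal in all five marks with H3K4me3 dominant; CAGE a sharp
50-bp-wide spike at promoters only; negative marks pure background. All
shapes and amplitudes are configuration, since the signature is known from
figures rather than formulas.

Amplitudes (8 expected extra tags per 100-bp bin at each component peak for
enhancer marks) were fixed from the enrichment arithmetic, not by trial
against outcomes: because λ₀ is measured from total tag counts, the planted
signal itself inflates the Poisson mean at this feature density (about 80
signal-bearing features per Mb, versus single digits in a mammalian genome),
and the chosen amplitude/background pair keeps the per-window planted signal
7–16 standard deviations above that inflated mean while background windows
stay at the true background. This compression of genome scale is the main
respect in which the synthetic data are easier than real data: real
enhancers vary in strength and shape, and marks are noisier, so passing
recovery tests here demonstrates correctness of the machinery, not expected
field performance.

**TEs.** A Bernoulli fraction (default 0.4) of enhancer anchors is wrapped in
a TE whose family is drawn from donation weights deliberately skewed toward
older families (MIR 0.25, L2 0.20, LTR 0.20, DNA 0.15, L1 0.10, Alu 0.10),
while background TEs (default 2,000, kept clear of planted anchors so the
anchor fraction stays exact) follow genomic weights dominated by Alu and L1.
Family mean lengths and divergences follow the field's rough ordering (Alu
short and young through MIR short and old), so the planted age/contribution
correlation and the Alu/L1 under-representation emerge from the configuration
rather than being asserted downstream.

**Expression.** Unit means are μ₀ + β·(planted enhancers active in the cell
within TSS ± 50 kb) with μ₀ = 100, β = 50 and Gaussian replicate noise
σ = 20, floored at zero, over 20 (cell A) and 21 (cell B) replicates —
an unbalanced design of the kind real expression panels have. β = 50 with these replicate
counts puts a one-enhancer difference at roughly 8 within-gene standard
errors, so the ANOVA threshold of 1e-7 retains genuinely coupled genes.
Exon-array (MAS5-scale) noise structure is not modeled.

Everything is reproducible from (config, seed): child generators are derived
from a seed sequence keyed by stage, cell type and mark, so changing the seed
changes tags but not the schema, and identical inputs reproduce every output
byte-identically.

## Problem sizes

The default study conditions — 5 Mb over two chromosomes, 200 enhancers, 200
promoters, 400 background DHS sites, ~2,100 TEs, ~370 transcripts, 41
expression samples — were chosen so that every stage has enough events for
its statistics (≈ 120 active enhancers per cell type for training and ROC,
≈ 90 differential genes for the asymmetry test) while a full end-to-end run
completes in seconds. The exhaustive oracle checks in the test suite
(hypergeometric enumeration to N = 60, Wilcoxon sign enumeration to n = 12)
are the slowest components.

## Known limitations

- Background tag rates are uniform; real ChIP-Seq backgrounds have
  mappability and copy-number structure that would widen the null score
  distribution.
- The sliding scan evaluates centers only inside the DHS interval, so an
  enhancer whose signature is centered well outside its DHS would be missed;
  windows overhanging chromosome ends are skipped, never truncated.
- Sharing between cell types is anchor-overlap; because each cell type's
  best window center jitters independently, the measured shared fraction
  understates the planted overlap of active loci.
- The hypergeometric sharing test's parameterization is one of several
  defensible readings; the parameters are explicit so alternatives can be
  tested without code changes.
- λ₀ estimation from total counts biases enrichment p-values conservatively
  upward wherever signal is dense; on the compressed synthetic genome this
  inflation is material (2–9× per mark) and the amplitude defaults account
  for it.
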