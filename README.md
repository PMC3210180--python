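# chromenh

Chromatin-profile enhancer prediction at open-chromatin sites, attribution of
calls to transposable-element (TE) families, and linkage of enhancer counts to
cell-type-specific and differential gene expression — exercised end-to-end on
synthetic genomes with planted signal.

## The problem

Active enhancers carry a recognizable chromatin signature: local enrichment of
five histone modifications (H3K4me1, H3K4me2, H3K4me3, H3K9ac, H3K27ac) with
characteristic spatial profiles around the enhancer core, while marks such as
H3K27me3, H3K36me3 and H4K20me1 show no such pattern. This package implements
a profile-matching pipeline that exploits that signature:

1. **Training.** Anchor sites (p300-like binding sites) are kept when a
   Poisson test against the genomic background tag rate — `P(X ≥ k)` with
   `X ~ Poisson(λ₀·L)`, Bonferroni-corrected — finds them enriched for all
   five positive marks and none of the negative controls. Each anchor's 10-kb
   window is divided into 100 bins of 100 bp; per-mark binned tag counts are
   summed over anchors into a 5 × 100 training profile.
2. **Scanning.** Each DNaseI-hypersensitive site (DHS) is scanned with a 10-kb
   window stepped every 100 bp. At each step the five test count vectors are
   compared to the training profile by Spearman's rank correlation (mid-ranks
   for ties) and the five ρ values are averaged; the best-scoring window per
   DHS is kept when its score is ≥ 0.5 (significance of the cutoff from
   `t = ρ·√((n−2)/(1−ρ²))` on Student's t with n−2 df).
3. **Promoter filtering.** Genome-wide 100-bp bins significantly enriched for
   CAGE tags (Poisson test, Bonferroni over all bins) mark transcription start
   sites; calls anchored within 1 kb of such a bin are promoters and removed.
4. **Validation.** Ten-fold cross-validation scores held-out anchors and
   random genomic windows against profiles trained on the remaining folds;
   the ROC curve is built from score frequencies at 0.02 threshold intervals.
5. **TE attribution.** Calls whose anchor overlaps a RepeatMasker interval are
   TE-derived; the six major Repbase families (Alu, MIR, L1, L2, LTR, DNA) are
   tallied against their genomic-abundance expectation (χ², df = 5), and the
   normalized contribution is correlated with family age (percent divergence).
6. **Expression linkage.** Overlapping co-directional transcripts merge into
   transcriptional units; TE-derived calls are counted within 100 kb of each
   TSS and related to expression (count-binned means, Wilcoxon signed-rank
   count asymmetry at ANOVA-differential genes, divergence deciles).

Real inputs at genome scale (ENCODE tagAlign tracks, UCSC rmsk tables, exon
array matrices) are out of desk-scale reach, so the package ships a
synthetic-genome generator that emulates their statistical structure — planted
enhancers and CAGE-marked promoters with mark-specific Gaussian profile
shapes over Poisson backgrounds, TE annotations with family-specific lengths
and divergences, and replicated two-cell-type expression whose gene means
increase by β per nearby active enhancer — together with a truth table for
end-to-end evaluation.

## Worked example

```sh
python analysis/01_simulate.py --seed 1      # writes raw inputs + summary
python analysis/02_train_profile.py --seed 1
python analysis/03_scan_enhancers.py --seed 1
python analysis/04_validate_roc.py --seed 1
python analysis/05_te_attribution.py --seed 1
python analysis/06_expression_link.py --seed 1
```

On the default study conditions (5-Mb genome, 200 planted enhancers, 200
promoters, 400 background DHS sites, two cell types) the drivers print:

```
125 of 170 candidate sites enriched in all five positive marks and no negative mark

 cell  provisional_calls  enhancer_calls  promoters_removed  sensitivity  precision
cellA                304             120                184          1.0        1.0
cellB                306             120                186          1.0        1.0

           run  n_anchors    auc
planted_signal        125 0.9772
null_amplitude        120 0.5101

cellA: 47/120 calls TE-derived; chi2=106.4 (df=5) p=2.31e-21; age correlation rho=0.89
cellA: expression vs TE-enhancer count, Spearman over bins = 1.00
  up in cellA: 3.15 enhancers/gene there vs 1.36 in cellB (Wilcoxon p = 1.22e-09)
divergence deciles: Spearman(expression divergence, normalized count difference) = 0.96
```

Reading: every planted enhancer DHS is recovered at the ρ ≥ 0.5 cutoff with no
false positives; all provisionally-called promoters are removed by the CAGE
filter; cross-validation separates anchors from random windows (AUC 0.98,
collapsing to 0.51 when no signal is planted); family contributions deviate
from genomic abundance in the planted direction and older families donate
more; and all three expression associations recover the planted positive
coupling between enhancer counts and expression.

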