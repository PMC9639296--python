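# polyeqtl

eQTL mapping and regulatory-network analysis for allopolyploid crop
populations, built around the downstream analyses typical of a two-stage
seed-development eQTL study in *Brassica napus*: genome-wide
expression-QTL scans with LD clumping and local/distant classification,
distant-eQTL hotspot detection by permutation, expression piggybacking of
adjacent genes, homoeolog regulation and feedback between the An and Cn
subgenomes, open-chromatin enrichment of lead SNPs, transcriptome-wide
association (TWAS), and boosted-tree ranking of candidate upstream
transcription factors.

Real population-scale data for these analyses is large and access-restricted,
so the package ships a first-class synthetic-study generator
(`polyeqtl.simulate`) that emulates a two-subgenome genome with LD-block
genotypes, planted local/distant eQTLs, a planted hotspot regulator,
homoeolog pairs with negative-feedback coupling, co-expressed adjacent gene
pairs, open-chromatin regions enriched over causal variants, and a
quantitative trait — with exhaustive ground truth, so every stage of the
pipeline is testable end to end.

## The statistics at the core

* **Association scan.** For gene *g* and SNP *s*, OLS of
  log2(TPM+1) on additive dosage (0/1/2); explained variance
  r² = squared Pearson correlation, p-value from the t-test on the slope,
  significance at P ≤ 1e-6. Optional genotype-PC covariates for structured
  populations.
* **LD clumping.** Greedy: the smallest-P significant SNP becomes the lead
  and absorbs every remaining significant SNP with r²(lead, SNP) > 0.2.
  An eQTL is *local* if its lead lies within ±500 kb of the gene body
  (boundary inclusive), else *distant*.
* **Hotspots.** Distant-eQTL leads counted in 1-Mb windows stepped by
  100 kb; the null distribution of the genome-wide maximum count comes from
  1000 uniform re-placements of the leads; windows with empirical P < 0.01
  are merged into hotspots.
* **Piggybacking.** Census of local-eGene pairs by number of intervening
  genes against a 1000-permutation null; adjacent pairs classed I (both
  local), II (one), III (neither), IV (non-adjacent both-local sample);
  class correlation CDFs compared by KS tests; class-I pairs stratified by
  the open-chromatin state of their lead SNPs (Welch t-tests).
* **Subgenome regulation.** Homoeolog pairs by reciprocal best hit on
  similarity scores; gene X regulates its homoeolog Y if X's TSS is within
  ±150 kb of a distant-eQTL lead of Y; expression propensity
  log2fc = mean[log2(TPM_An+1) − log2(TPM_Cn+1)] with a paired t-test and
  BH adjustment (imbalanced at padj < 0.05); feedback probed by comparing
  cross-homoeolog correlations of aHGPs with vs without a local eQTL on
  the regulating gene.
* **OCR enrichment.** Lead SNPs in merged ATAC peaks vs a
  per-chromosome-preserving positional shuffle (1000 permutations, 95% CI);
  KS comparison of lead r² inside vs outside open chromatin.
* **TWAS.** Per-gene OLS of the trait on log2(TPM+1), BH FDR ≤ 0.05.
* **TF ranking.** Per target gene, an XGBoost regressor
  (n_estimators=1000, max_depth=3, learning_rate=1e-4, reg_alpha=0,
  reg_lambda=1) of target expression on TF expression; the top-3 TFs by
  total gain per target are tallied across targets and TFs ranked by count.

## Worked example

```python
from polyeqtl import SimConfig, run_simulated

metrics = run_simulated(SimConfig(seed=1), "demo_run")
print(metrics["n_eqtl_20DAF"], metrics["n_local_20DAF"], metrics["n_distant_20DAF"])
# 231 131 100
print(metrics["planted_hotspot_called"], metrics["planted_hotspot_empirical_p"])
# True 0.0
print(round(metrics["feedback_pcc_local"], 3), round(metrics["feedback_pcc_nolocal"], 3))
# -0.617 0.013
print(metrics["grn_top_tf"], metrics["planted_regulator_rank"])
# BnaA01g0085 1
```

The demo study plants 20 plain local eQTLs (effect 1.0 on the log2 scale),
one distant-eQTL hotspot whose TF regulator drives 40 target genes
(effect 0.8), 40 asymmetrically regulated homoeolog pairs (half with
negative feedback, strength −0.8), 25 An-biased pairs, 45 co-expressed
adjacent pairs and a 5-gene quantitative trait. In the run above the scan
recovers 231 eQTLs (131 local, 100 distant); the planted hotspot window is
called with empirical P = 0 and the regulator TF ranks first in the
boosted-tree aggregation; feedback pairs show the planted negative
cross-homoeolog correlation (−0.62) against ≈0 for pairs without a local
eQTL on the regulating gene.

The same pipeline runs from files:

```bash
polyeqtl simulate --seed 1 --out study/
polyeqtl run --inputs study/ --out results/
```

Inputs are plain standard formats (GFF3 genes, VCF genotypes, TSV
expression/trait/similarity, BED peaks), so user data drops in the same
way; without a `truth.json` the recovery metrics are simply omitted.

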