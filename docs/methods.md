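# Methods

This note documents the models and procedures implemented in `polyeqtl`,
the assumptions behind the synthetic-study generator, and the numerical
choices made where the design was genuinely open.

## Coordinate contract

All in-memory coordinates are 0-based, half-open. VCF and GFF3 (1-based
inclusive) are converted at the I/O boundary; BED passes through unchanged.
A point at 0-based position p is inside interval [s, e) iff s ≤ p < e.
All window rules are strand-agnostic bp distances; strand enters only
through the TSS (start of a + gene, end of a − gene).

## Association model

Expression is transformed to log2(TPM+1). For each gene–SNP pair the model
is single-marker OLS on additive dosage; explained variance r² is the
squared Pearson correlation of dosage with (covariate-residualized)
expression and the p-value comes from the slope t-test, floored at 1e-300.
This replaces the mixed-model (kinship) machinery of population-scale
tools: the synthetic population has no relatedness structure, so a kinship
term would estimate noise. For structured user data, the top-k genotype
principal components can be included as fixed covariates
(`AnalysisParams.n_pcs`). Heterozygotes are coded 1 (additive model).
Missing genotypes are dropped per SNP; a mean-imputation path exists for
callers that prefer complete matrices.

Default thresholds (all surfaced in `AnalysisParams`): significance
P ≤ 1e-6; LD clump absorption at r² > 0.2 with ties on P broken by larger
r², then lower coordinate (determinism); local/distant boundary at ±500 kb
around the gene body, inclusive — "within 500 kb" is read inclusively and
the same reading is applied to the ±150-kb homoeolog window. Two eQTLs of
one gene match across developmental stages if their leads are within
100 kb or in LD (r² > 0.2).

## Hotspot detection

Distant-eQTL leads (one per eQTL record, i.e. per gene × locus pair) are
counted in 1-Mb windows stepped every 100 kb, last partial window included.
The null is the genome-wide maximum count under uniform re-placement of
the same number of leads over the concatenated genome (1000 permutations
by default; a per-chromosome-count-preserving mode is available). The call
threshold is the smallest integer c with fraction(null maxima ≥ c) < α
(α = 0.01); a window's empirical P is the fraction of null maxima at or
above its count. Called windows that overlap or abut merge into one
hotspot (the stepping scheme makes neighbours overlap anyway; `merge_gap`
is configurable). Because the test statistic is a discrete maximum and the
threshold rule uses a strict inequality, the realized type-I level is
slightly below α at low lead densities; measured over 1000 independent
null placements at 900 leads on the demo genome it is ≈0.013, i.e.
calibrated. Stage comparison labels hotspots overlap (reciprocal coverage
≥ 0.9), partial (any lesser overlap) or special (none). Hotspot→TWAS-gene
enrichment uses a one-sided hypergeometric test over the eGene universe
with BH correction across hotspots (the enrichment test family was an open
choice; hypergeometric is the standard 2×2 enrichment test and a
permutation cross-check exists in the test suite).

## Piggybacking

"Adjacent" means consecutive gene ordinals on one chromosome, strand
ignored. The adjacency census counts local-eGene pairs at each number of
intervening genes; the permutation null samples equal-sized gene sets
uniformly without replacement (empirical P with the +1 correction).
Classes: I both genes local, II exactly one, III neither, IV a random
sample of non-adjacent both-local pairs sized to the class-I count so the
correlation CDFs are comparable. A gene with several local eQTLs uses its
minimum-P lead for the chromatin-state lookup; strata are both_open /
one_open / both_closed by OCR membership of the two leads, compared with
Welch t-tests (the unequal-variance form, since stratum variances differ).

## Subgenome analysis

Homoeolog pairs come from reciprocal best hit on a long-format similarity
table; a tie at either best hit breaks reciprocity and drops the pair
(strict "best hit"; deterministic). X regulates Y iff X's TSS lies within
±150 kb (inclusive) of a distant-eQTL lead of Y, with leads pooled over
both stages by default. Exactly one direction → aHGP; none or both →
sHGP. Expression propensity is the mean paired difference
log2(TPM_An+1) − log2(TPM_Cn+1) (positive = An-biased), tested with a
paired two-sided t-test and BH adjustment across pairs (the adjustment
procedure was unnamed in the source analyses; BH is assumed and
documented). The feedback comparison conditions on the *regulating* gene's
local eQTL ("Local" vs "NoLocal" aHGPs; a flag allows conditioning on the
regulated gene instead) and compares cross-homoeolog Pearson correlations
with KS tests. TF enrichment among feedback pairs is a permutation test
drawing equal-sized gene sets uniformly.

## OCR enrichment

Peak sets are merged with gap 0 (book-ended intervals join). The
enrichment null shuffles lead positions uniformly *within* chromosomes,
preserving per-chromosome counts, with peaks fixed: shuffling peaks would
distort their length structure, and per-chromosome preservation guards
against chromosome-size confounding. An optional mode also shuffles peak
starts (length-preserving). Reported: observed count, null mean, 2.5/97.5
percentile CI of null counts (the CI is on null counts, matching how such
nulls are drawn), empirical P = (1 + #{null ≥ obs})/(n_perm + 1).

## TF ranking

Per target gene, an XGBoost regressor of target log2(TPM+1) on TF
log2(TPM+1) features (target excluded from its own features), headline
hyperparameters n_estimators=1000, max_depth=3, learning_rate=1e-4,
reg_alpha=0, reg_lambda=1, exact tree method, single-threaded with a fixed
seed for reproducibility. Importance is total gain — the conventional
regulatory-strength proxy in boosted-tree GRN methods. The tiny learning
rate yields near-zero fitted functions but split selection (hence gain) is
unaffected; the test suite confirms ranking agreement with a conventional
learning rate of 0.05 on strong-signal data. Per target the top-3 nonzero
TFs are extracted (ties lexicographic); TFs are ranked by top-3 count,
then rank-1 count, then id — both counts are reported because either can
serve as the headline tally. There is no train/test split: the procedure
is feature selection, not prediction benchmarking.

## The synthetic study

The generator emulates the structures the pipeline is meant to recover,
not the full biology. What it models:

- **Genome.** 2 chromosomes per subgenome (An/Cn) of 12 Mb, 120 genes per
  chromosome in positionally matched slots, so each (A, C) slot is a true
  homoeolog pair; ~10% of slots are TFs (shared within a slot). Similarity
  scores are high on true slots with low-scoring decoys, exercising RBH.
- **Genotypes.** 240 SNPs per chromosome in 100-kb LD blocks: each block
  has a founder dosage vector (Binomial(2, p), p ∈ [0.12, 0.43]) and every
  SNP copies it with a 3% per-entry resampling rate, giving intra-block
  r² ≈ 0.9 and inter-block r² ≈ 0. Empirical MAF is constrained to
  (0.10, 0.45) by rejection. This block-copy scheme replaces coalescent
  simulation deliberately: downstream analyses depend on LD only through
  the 0.2 clumping rule.
- **Expression.** Built on the log2 scale (baseline ~ Normal(3, 1) per
  slot, shared between homoeologs; noise SD 0.5 per stage) and
  exponentiated, so log2(TPM+1) downstream approximately recovers the
  linear model. Planted, in demo defaults: 20 plain local eQTLs
  (|β| = 1.0; 30% of them stage-1-specific), one hotspot whose TF
  regulator is cis-driven (β = 1.0) and propagates (±0.8 × its expression
  deviation) into 40 non-TF targets on other chromosomes, 20 feedback
  aHGPs (regulating gene cis-driven; partner receives +0.8 × a driver SNP
  near the regulator's TSS and −0.8 × the regulator's expression
  deviation, producing both a distant eQTL at the regulator locus and a
  negative cross-correlation), 20 no-local aHGPs (driver SNP only), 25
  An-biased pairs (+1.0 shift), and 45 adjacent pairs with local eQTLs and
  a shared factor (SD 0.8) plus an extra same-chromatin-state factor
  (SD 0.7, scaled by the in-OCR effect boost for both_open pairs; 0.7
  rather than the smaller value one might first try comes from a power
  analysis — with 15 pairs per stratum and MAF-dependent genetic variance,
  a smaller coupling cannot separate the strata reliably).
- **Open chromatin.** Peaks (0.8–2.2 kb) cover ~10% of the genome. Causal
  SNPs fall in peaks with odds 5 (in-OCR probability 0.357); the open
  state is a property of the causal LD block (block-mates of a flagged
  SNP are covered too), so whichever block-mate wins the lead carries the
  planted state. Flagged-open variants get a 1.5× effect boost, driving
  the r²-in-vs-out comparison.
- **Trait.** A weighted (±1) sum of 5 local-eQTL genes' log expression
  plus Normal(0, 1) noise; causal genes occupy distinct LD blocks so TWAS
  false discoveries are not manufactured by construction.

What it does **not** model — hence what passing tests do not show about
real data: population structure and relatedness, realistic recombination
or allele-frequency spectra, read-level noise, peak-calling artefacts,
polygenic trait architecture, or expression networks beyond the planted
couplings. Recovery rates here certify the pipeline's logic, not expected
power on a real population.

Determinism: one `numpy` Generator seeded by `SimConfig.seed` drives
generation in a fixed call order; identical configs give byte-identical
output files. The analysis side takes an independent seed
(`AnalysisParams.seed`) for its permutation tests and the boosted-tree
models (single-threaded xgboost).

## Problem sizes used in the tests

Unit and acceptance tests run the demo configuration (300 accessions, 480
genes, 960 SNPs), 200-run calibration batches with 200–1000 permutations
per run, 10 seeds for the TF-ranking recovery (8 targets per seed), and
20 permuted-trait TWAS runs. These sizes were chosen so the full suite
completes on a single CPU in minutes while keeping every statistical check
adequately powered; the methods themselves have no dependence on them.

## Known limitations

- The scan is marginal OLS; conditional/stepwise association and
  effective-test-count corrections are out of scope, so the 1e-6 default
  is a convention, not a computed genome-wide threshold.
- The low-expression gene filter of population pipelines (cutoff on the
  95th percentile of log2 expression) is not applied: synthetic genes are
  all expressed, and the zero-variance guard covers the degenerate case.
- Hotspot empirical P values are bounded below by the permutation count;
  merged hotspots inherit the minimum window P.
- TF enrichment of feedback pairs is underpowered at the demo scale
  (20 pairs, 2× planted bias); the operation is validated on constructed
  sets instead.
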