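# Methods

This note documents the statistical model behind `gcaxis`, the defaults
that matter, and the design decisions taken where the procedure was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The subtyping model

Each tumor sample *s* receives two scores. For a module *M* of co-expressed
genes, the raw score is the median of log₂(TPM+1) expression over *M*;
the axis score is the z-standardization of the raw score across the tumor
cohort (sample sd, ddof = 1; normal samples are excluded from the
standardization population). The subtype is the quadrant of the score pair
(GLYCOLYSIS, CHOLESTEROL): both ≤ 0 → Quiescent; glycolysis > 0 only →
Glycolysis; cholesterol > 0 only → Cholesterol; both > 0 → Mixed.

*Boundary decision.* A literal reading of the quadrant definitions assigns
score pairs exactly at zero to two subtypes at once. We use strict
inequalities for the "high" side, so ties at 0 fall to the ≤ 0 quadrant and
the classifier is a function; the origin is Quiescent. The boundary has
zero probability for continuous scores, so this cannot change results in
practice.

*Scale decision.* Medians are taken on log₂(TPM+1) by default
(`log_scale=True`): on raw TPM the median over a module is dominated by its
highest-abundance members. Raw-TPM scoring is available as a flag.

## Signature modules by consensus clustering

The curated glycolysis/cholesterol signature sets only partially co-express
in tumors; the analysis first finds the co-expressed core of each set.
Items are the signature **genes**; evidence is the **samples**.

For each of `n_reps = 100` draws, ⌈0.8·n⌉ samples are subsampled without
replacement (`p_item = 0.8` applied to samples; all genes retained,
pFeature = 1), genes (row-standardized once on the full cohort) are
clustered with PAM (k-medoids; deterministic greedy BUILD + SWAP) on
1 − Pearson correlation computed over the drawn samples, and the consensus
matrix accumulates co-clustering indicators. Because every gene is present
in every draw, the consensus denominator is exactly `n_reps` — the
co-evaluated-pairs bookkeeping of item-subsampling variants is not needed.
Final assignments cut an average-linkage dendrogram of 1 − consensus into
k clusters. With a fixed seed the whole procedure is bit-reproducible
(per-rep RNG substreams are spawned from one root seed).

**Choosing k.** For each k the area A(k) under the empirical CDF of the
upper-triangular consensus entries is computed; A(k) is non-decreasing in k.
The relative gain r(k) = (A(k) − A(k−1))/A(k−1) is large while genuine
modules are still being separated and flattens afterwards. We select the k
with the sharpest subsequent flattening — the largest r(k)/r(k+1) among
candidates with r(k) ≥ 0.05 (the floor; smallest k if none qualifies). A
fixed absolute threshold alone proved non-discriminating in simulation:
cleanly splitting a *stable* cluster always removes consensus mass, so
post-true-k gains plateau near 0.05–0.10 rather than dropping to zero. The
full area curve and gain sequence are reported (`k_selection.json`), never
hidden. Area-based elbows remain insensitive to very small modules (a
3-gene module moves < 4 % of the pair mass); when the module structure is
known a priori — as for the synthetic cohort below — k is stated as a study
condition instead.

**Labeling.** Each source signature claims the cluster holding the
plurality of its genes; its module is that cluster ∩ that signature.
Plurality ties or both signatures claiming one cluster abort with an error
(no axis separation). Modules are disjoint by construction.

*Open choices resolved.* The procedure's published description is
internally inconsistent about the inner distance/algorithm and the
resampling depth; we follow the most precise parameter statement
(reps = 100, pItem = 0.8, pFeature = 1, Pearson) with PAM as the inner
clusterer, and expose all four as configuration.

## Survival analysis

Kaplan–Meier estimation, the k-group log-rank test, and Cox proportional
hazards (partial likelihood, **Efron** tie handling, Wald 95 % CIs
exp(β ± 1.96·se)) are delegated to lifelines. The module fixes the cohort
conventions: pairwise subtype log-rank p-values are reported unadjusted
(as such contrasts are conventionally printed) with a BH column alongside;
clinical covariates enter as binary contrasts (T3+T4 vs T1+T2,
Stage III+IV vs I+II, G3+G4 vs G1+G2, age > 65, male, recurrence); subtypes
enter one-vs-rest ("Other" as reference); the multivariate model is fitted
once per subtype indicator jointly with all clinical contrasts. A covariate
is flagged an independent risk factor when p < 0.05 **and** the entire 95 %
CI of the HR lies above 1.

## Differential expression

Per gene on log₂(TPM+1): log₂FC = mean(A) − mean(B), pooled variance s²_g
with d_g = n_A + n_B − 2 df, shrunk toward a prior s₀² with d₀ prior df:
s̃²_g = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g);
t = log₂FC / (s̃_g·√(1/n_A + 1/n_B)) on d₀ + d_g df. (d₀, s₀²) are
estimated by method of moments on log s²_g via the digamma/trigamma
identities for log scaled-F variates; d₀ = ∞ (all genes share s₀²) when the
observed log-variance spread does not exceed chi-square sampling noise, and
`prior_df = 0` recovers the ordinary pooled t exactly. This moderated-t
core is implemented here rather than wrapped from an external package;
matching any particular package's d₀ estimator is a non-goal. DEGs:
|log₂FC| > 1 and BH FDR < 0.05.

## Enrichment

* **ORA**: upper-tail hypergeometric p = P(X ≥ k) for the overlap of a DEG
  list with each set, restricted to the analysis background; BH across sets.
* **GSEA**: genes ranked by signal-to-noise (sd floored at 0.2·|mean|, 0.2
  if the mean is 0); weighted KS running sum (hit steps ∝ |score|^p,
  p = 1 by default; miss steps 1/(N−|S|)); ES = signed extreme. The null
  permutes phenotype labels: p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1), NES
  divides ES by the mean |ES*| of the same sign. Significance: p < 0.05 and
  FDR < 0.25. Phenotype permutation preserves inter-gene correlation, so a
  tightly co-expressed set needs signal beyond its own coherence to reach
  significance — visible on synthetic cohorts, where a diluted module can
  show a large ES with an unremarkable permutation p.
* **ssGSEA / microenvironment scores**: per sample, genes are ranked
  (average ties), and the score sums the difference between the
  rank^α-weighted ECDF of in-set genes (α = 0.25) and the unweighted ECDF
  of out-of-set genes, walking from the top of the ranking. Stromal and
  immune signatures are **user inputs** (any GMT); the combined
  infiltration score is exactly their sum. The nonlinear tumor-purity
  transform of the original microenvironment method is out of scope.

## Genomic contrasts

All contingency analyses share one test: Pearson chi-square without
continuity correction; any 2×2 table with an expected count < 5 falls back
to Fisher's exact two-sided test (flagged in the output). Degenerate 2×2
proportion contrasts (a zero-margin column, e.g. a gene mutated in every
sample of both groups) carry no information and report p = 1. Mutation
frequencies are contrasted pairwise between subtypes per gene with BH
across genes; CNV Gain/Loss proportions likewise (5-level integer calls are
collapsed on read: {−2,−1} → Loss, {0} → Neutral, {1,2} → Gain). Mutual
exclusivity of a gene pair uses the 2×2 co-mutation table over the profiled
samples (by default all samples in the mutation table; pass `samples=` to
override), Fisher two-sided, odds ratio with Haldane 0.5 correction when a
cell is empty. The correlate screen computes Spearman ρ (Pearson
selectable) of every gene against a target, p from the t approximation, BH
across genes. Kruskal–Wallis (tie-corrected) serves all k-group
distributional comparisons, including signature-gene expression across the
four subtypes plus normals.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes and
carries ground truth for every stage. Defaults (one choice, stated here):

* **Cohort**: 400 tumors, 50 normals — a TCGA-scale liver cohort.
* **Activities**: per axis, a two-component Gaussian mixture: low mean 0,
  high mean 1 (p = 0.5 each), sd 0.2. The planted subtype is the quadrant
  of the activity pair at the midpoint threshold 0.5; with independent
  axes the four subtypes are balanced in expectation. The bimodal design
  makes quadrant membership crisp at high separation and degrades smoothly.
* **Expression**: gene baselines Uniform(3, 8) on log₂; an on-program gene
  adds `program_effect = 2.0` × activity; residual noise N(0, 0.5²).
  Signature structure: 13 glycolysis and 17 cholesterol on-program genes,
  plus 11 and 3 off-program genes driven by per-axis nuisance factors
  (so each curated set only partially co-clusters and consensus must
  separate **four** modules), plus 5 and 4 low-abundance genes
  (log₂ ≈ −4) planted to fail the TPM filter — set sizes 29 and 24, with
  44 genes surviving the filter. 300 background noise genes. log₂ values
  are back-transformed (2^x − 1, clipped at 0) and columns renormalized to
  10⁶ so the TPM invariant holds exactly.
* **Survival**: exponential event times with hazard = (1/1500 days) ×
  subtype multiplier {Quiescent 0.6, Glycolysis 1.5, Cholesterol 0.65,
  Mixed 2.7} — the ordering Mixed ≫ Glycolysis > Cholesterol ≈ Quiescent
  of one-vs-rest hazard ratios reported for this axis. Administrative
  censoring at τ = −ln(0.3)/h₀ targets ~30 % censoring at the baseline
  hazard (the realized rate shifts slightly with the multipliers).
* **Mutations**: per-gene, per-subtype Bernoulli frequencies (TP53 0.40 in
  Mixed vs 0.05 in Quiescent; CTNNB1 0.25, TTN 0.20, MUC16 0.15 flat). The
  TP53/CTNNB1 pair is drawn jointly with the co-mutation probability
  multiplied by 0.1, planting mutual exclusivity.
* **CNV**: 3-state calls with planted contrasts (TP53 Loss 0.45 Mixed vs
  0.10 Quiescent; MYC Gain 0.50 vs 0.15; CTNNB1 Gain 0.40 vs 0.10).
* **Normals**: both activities at −0.75 (below the low tumor component),
  so signature expression in normals sits under every tumor subtype.

What the generator does **not** emulate: library-size and GC biases,
count-level noise (expression is lognormal around the program mean, not
negative binomial), realistic mutation spectra or CNV segment structure,
correlated clinical covariates, and informative censoring. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed generative structure, not robustness to the full messiness of real
cohorts.

## Problem sizes and numerical conventions

The test suite and acceptance script run the full pipeline on the default
400-tumor cohort, consensus with 100 resamples, GSEA with 200 permutations
in the pipeline (1 000 in the focused statistic test), Cox recovery at
n = 500, and null-CI coverage over 200 replicates of n = 120 — sizes chosen
so every planted effect is comfortably detectable. Other conventions:
axis z-scores use the sample sd (ddof = 1); zero-variance axis scores,
constant Cox covariates, constant consensus gene rows, and all-identical
Kruskal–Wallis inputs are errors, not NaNs; subsample correlation NaNs
(a gene constant within one draw) are treated as zero correlation; BH has a
single implementation shared by every stage; pipeline outputs carry no
timestamps, and every random draw descends from the single configured seed,
so re-runs are byte-identical. Stage results are additionally cached under
the output directory keyed by a content hash of parameters + upstream
state, so a partial re-run resumes from the last unchanged stage.

## Known limitations

* Area-based k selection is blind to very small modules (see above).
* ORA/GSEA run only against user-supplied GMT collections; no annotation
  databases are bundled or fetched.
* The moderated-t prior estimator is a method-of-moments fit; exact
  agreement with any specific published empirical-Bayes implementation is
  not claimed.
* Cox models assume proportional hazards; no time-varying covariates, no
  penalized (lasso) variant.
* CIBERSORT-style deconvolution and external immune-subtype derivation are
  out of scope.
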