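# gcaxis

Metabolic subtyping of tumor expression cohorts on the **glycolysis /
cholesterol-synthesis axis**.

Tumors reprogram their metabolism, and two of the dominant programs —
aerobic glycolysis and de-novo cholesterol biosynthesis — vary largely
independently across patients. Scoring each tumor on both programs and
splitting on the signs of the standardized scores yields four metabolic
subtypes with distinct prognosis and genomics:

| GLYCOLYSIS z | CHOLESTEROL z | subtype     |
|--------------|---------------|-------------|
| ≤ 0          | ≤ 0           | Quiescent   |
| > 0          | ≤ 0           | Glycolysis  |
| ≤ 0          | > 0           | Cholesterol |
| > 0          | > 0           | Mixed       |

`gcaxis` implements the full analysis as a tested, reusable library and
CLI, for computational biologists working with bulk RNA-seq cohorts (e.g.
TCGA-style liver cancer data):

1. **Preprocessing** — FPKM→TPM conversion (`TPM_gs = FPKM_gs / Σ_g FPKM_gs · 10⁶`),
   duplicate-symbol collapse by per-sample median, removal of samples
   without follow-up, and a signature-gene filter (TPM ≥ 1 in ≥ 50 % of
   samples).
2. **Consensus co-expression modules** — Monti-style resampling consensus
   clustering of the signature *genes* (PAM on 1 − Pearson distance over
   subsampled samples; reps = 100, pItem = 0.8), consensus-CDF-area elbow
   for choosing k, and mapping of clusters back to the glycolysis /
   cholesterol source sets.
3. **Quadrant subtyping** — per-sample median log₂(TPM+1) expression of
   each module, z-scored over the tumor cohort; the sign pair gives the call.
4. **Downstream contrasts** — Kaplan–Meier curves, overall + pairwise
   log-rank tests, univariate/multivariate Cox PH (Efron ties, one-vs-rest
   subtype contrasts, risk-factor flag: p < 0.05 and 95 % CI of HR above 1);
   moderated-t differential expression (|log₂FC| > 1, BH FDR < 0.05);
   hypergeometric ORA and phenotype-permutation GSEA (p < 0.05, FDR < 0.25);
   ssGSEA-based stromal/immune (ESTIMATE-style) scores; mutation and CNV
   frequency contrasts, TP53/CTNNB1-style mutual-exclusivity tests, and a
   Spearman correlate screen.
5. **Synthetic cohorts** — a generator that plants two latent program
   activities, four gene modules, proportional-hazards survival, and
   mutation/CNV structure with known ground truth, so every stage is
   testable end to end.

## Worked example

```python
from gcaxis import (SimulationConfig, simulate_cohort, filter_low_expression,
                    extract_signature_matrix, consensus_cluster, label_modules,
                    compute_axis_scores, assign_subtype, subtype_counts,
                    logrank_test, evaluate_recovery)

cohort = simulate_cohort(SimulationConfig(seed=7))          # 400 tumors, 50 normals
filtered, dropped = filter_low_expression(cohort.expression)
sig = extract_signature_matrix(filtered, cohort.gene_sets,
                               ["GLYCOLYSIS_SIGNATURE", "CHOLESTEROL_SIGNATURE"])
res = consensus_cluster(sig.subset_samples(cohort.tumor_samples), [4],
                        n_reps=100, p_item=0.8, seed=11)[0]
modules = label_modules(res.assignments, cohort.gene_sets,
                        "GLYCOLYSIS_SIGNATURE", "CHOLESTEROL_SIGNATURE")
calls = assign_subtype(compute_axis_scores(cohort.expression, modules,
                                           cohort.tumor_samples))
print(len(dropped), len(modules.glycolysis_module), len(modules.cholesterol_module))
print(subtype_counts(calls).to_dict())
clin = cohort.clinical.data
print(round(evaluate_recovery(calls, cohort.truth_subtypes())[0], 3),
      logrank_test(clin["os_time_days"], clin["os_event"],
                   calls["subtype"].astype(str)).p)
```

prints

```
9 13 17
{'Quiescent': 98, 'Glycolysis': 96, 'Cholesterol': 114, 'Mixed': 92}
0.935 2.0125361743804964e-19
```

i.e. 9 low-abundance signature genes removed by the filter; the consensus
step isolates the 13-gene glycolysis and 17-gene cholesterol modules out of
the 44 retained signature genes; the quadrant calls recover the planted
subtype of 93.5 % of tumors; and the four subtypes separate strongly in
survival (log-rank p ≈ 2·10⁻¹⁹, Mixed worst, Quiescent best).

The same analysis runs from the shell:

```bash
gcaxis simulate --seed 7 --out cohort/
gcaxis run-all config.yaml --out results/     # YAML with inputs or a simulate block
```

Every run writes per-stage TSV/JSON outputs, a markdown report, and a
`provenance.json` with the parameters and seed of each stage; seeded re-runs
are byte-identical, and stage results are cached by content hash.

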