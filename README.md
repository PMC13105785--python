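# toxbiome

Analysis pipeline for studying how gut-microbiome composition and metabolism
relate to the hematologic toxicity of pelvic chemoradiotherapy — and how that
toxicity differs between the sexes. It covers the full chain from weekly
blood counts to causal inference:

* **Toxicity.** Weekly blood counts (WBC, ANC, ALC, hemoglobin, platelets)
  are graded 0–4 per CTCAE v5.0 laboratory bands, and each patient's per-AE
  maximum grades X₁ ≥ X₂ ≥ … (sorted descending) are collapsed into the
  hematologic toxicity index

  HTI = X₁ + X₂/(1+X₁) + X₃/((1+X₁)(1+X₂)) + … + Xₙ/∏_{j<n}(1+Xⱼ),

  a severity-dominated score with max-grade g ≤ HTI < g+1. Cohort tables
  compare AE rates across strata by Pearson chi-square (or Fisher's exact).
* **Diversity.** Shannon and inverse-Simpson alpha diversity, Bray–Curtis
  distances, classical PCoA, multi-term PERMANOVA with sequential (type-I)
  R² partitioning, and the Scheirer–Ray–Hare two-factor rank test for
  diversity trajectories over treatment time points.
* **Associations.** MaAsLin-style multivariable linear models of TSS +
  log2-transformed feature abundances (taxa, pathways, metabolites) on AE
  grades, sex and clinical covariates, with Benjamini–Hochberg FDR (q <
  0.25), plus a LEfSe-style Kruskal–Wallis + LDA-effect-size screen.
* **Networks.** Group-specific Spearman co-occurrence networks over
  prevalent taxa and a NetShift-inspired driver score combining neighborhood
  turnover (Jaccard distance) with rising betweenness.
* **Mendelian randomization.** Two-sample MR from GWAS summary statistics:
  p < 1e-5 instrument selection with greedy LD clumping (r² > 0.01, 1000 kb),
  allele harmonization (swaps, strand flips, palindromic-SNP frequency
  checks, r² ≥ 0.8 proxies), IVW / MR-Egger / weighted-median estimators,
  Cochran's Q, Egger-intercept and leave-one-out sensitivity analyses.
* **Synthetic data.** Seeded generators for every input — a cohort with a
  planted sex effect on myelosuppression, 4-time-point compositional
  microbiome and metabolite tables with planted sex/toxicity effects, and
  exposure/outcome GWAS pairs with known causal effect and optional
  pleiotropy — so every stage is testable against recorded ground truth.

## Worked example

```python
import pandas as pd
import toxbiome as tb

# a patient with five concurrent grade-2 hematologic AEs
tb.compute_hti([2, 2, 2, 2, 2])        # -> 2.9876543209876543  (~2.9877)

# sex vs grade 3-4 lymphopenia contingency table: chi-square (1 df)
stat, p = tb.chisq_2x2([[140, 98], [39, 52]])
print(round(p, 3))                     # -> 0.009

# end-to-end on synthetic data
meta, labs = tb.simulate_cohort(tb.CohortParams(seed=1))
th = tb.GradeThresholds.from_yaml()
profiles = [tb.grade_series(s, th) for _, s in labs.groupby("patient_id")]
hti = pd.Series({p.patient_id: tb.compute_hti(p) for p in profiles})
m = meta.set_index("patient_id")
print(hti[m.sex == "female"].median(), hti[m.sex == "male"].median())
# -> 3.625 2.8519  (the planted extra weekly decline in females raises their HTI)
```

The same pipeline is available from the shell:

```bash
toxbiome simulate cohort --seed 1 --out sim
toxbiome grade --labs sim/labs.tsv --out profiles.tsv
toxbiome hti --profiles profiles.tsv --out hti.tsv
toxbiome table1 --profiles profiles.tsv --hti hti.tsv --metadata sim/metadata.tsv
toxbiome simulate gwas --seed 1 --out sim
toxbiome mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv --ld sim/ld.tsv --seed 1 --out mr
```

The MR run above prints (true planted causal effect 0.3, 50 instruments):

```
         method  estimate       se   ci_low  ci_high            p  n_snp       or
            ivw  0.295909 0.017523 0.261565 0.330253 5.572825e-64     50 1.344348
          egger  0.269785 0.059158 0.153836 0.385734 3.537164e-05     50 1.309683
weighted_median  0.269836 0.025367 0.220116 0.319555 1.999093e-26     50 1.309749
```

All three estimators recover the planted effect; the odds-ratio columns are
the exponentiated estimates with their 95% confidence bounds.

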