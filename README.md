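# psopd

Pharmacodynamic (PD) biomarker analysis for two-arm biologic trials in
moderate-to-severe plaque psoriasis — the workflow used to compare an
IL-23-pathway blocker against an IL-17A blocker on serum cytokines and
lesional skin transcriptomes. It is written for translational scientists
and biostatisticians who need the complete chain from raw tables to ranked
enrichment results, plus a synthetic cohort generator with known ground
truth for validating every stage.

## What it computes

**Serum analytes** (log2 pg/ml, or Olink NPX used as-is):

* Group summaries per (arm, week, analyte) and Welch *t* comparisons
  against a healthy-control reference, reporting
  `log2ratio = x̄_grp − x̄_HC` with Satterthwaite degrees of freedom.
* Longitudinal PD effects: for each analyte, the subject-level log2 ratio
  to baseline `y_iw = x_iw − x_i0` is modelled as

  `y_iw = μ_{w,arm(i)} + β (x_i0 − x̄_0) + b_i + ε_iw`,  `b_i ~ N(0, σ_b²)`

  (REML mixed model; week × arm cell means, centred baseline covariate,
  subject random intercept), with per-week within-arm effects, between-arm
  contrasts, and Benjamini–Hochberg adjustment across analytes. Proteins
  with an estimated reduction exceeding 1.25-fold at FDR < 0.05 are
  flagged per arm, including the both/A-only/B-only partition.
* Responder contrasts (absolute PASI < 3 at every visit in weeks 20–48)
  and Pearson correlation of analytes with PASI.

**Skin transcriptomes** (gene-level counts):

* log2 CPM with pseudocount; paired lesional/nonlesional differential
  expression at baseline using an empirical-Bayes **moderated paired t**:
  per-gene variances of the paired log2 differences are shrunk toward a
  lowess mean–variance trend, with prior degrees of freedom estimated by
  method of moments. The **disease transcriptome** is the gene set with
  |log2 GM fold change| > log2 2 and FDR < 0.05.
* **Percent improvement** toward nonlesional expression per transcript:

  `improvement = 100 · (L̄₀ − L̄_t) / (L̄₀ − N̄L₀)`

  on group-mean log2 expression, the fraction of transcripts with
  improvement > 75% ("normalized"), and differential-normalization sets
  (> 50% improvement and > 25% margin between arms).
* Single-sample **gene-set variation scores** (Gaussian-kernel CDF,
  symmetric rank weights, weighted KS random walk, `max_diff` scoring)
  with Kruskal–Wallis group comparisons.
* Hypergeometric **over-representation analysis** against GMT collections
  with BH adjustment and term–gene networks.

**Synthetic cohorts**: negative-binomial paired counts with a planted
disease-gene set whose lesional offset decays by configurable per-arm,
per-week improvement fractions; log-normal serum trajectories with
configurable decline kinetics; PASI linearly coupled to designated
analytes. Planted truth is returned so recovery can be scored.

## Worked example

```python
from psopd import (SimulationConfig, normalize_counts, filter_expressed,
                   paired_de, percent_improvement, fraction_normalized,
                   pd_effect_model)
from psopd.simulate import generate_skin_cohort, generate_serum_cohort

cfg = SimulationConfig(seed=42, n_per_arm=17, n_genes=2000, n_disease_genes=300)
counts, meta, truth = generate_skin_cohort(cfg)
expr = normalize_counts(counts.loc[filter_expressed(counts)])
res = paired_de(expr, meta)
print(res.summary())
tr = res.disease_transcriptome(2.0, 0.05)
for arm in ("A", "B"):
    for wk in (4, 24):
        s = fraction_normalized(percent_improvement(expr, meta, tr, arm, wk), 75.0)
        print(f"arm {arm} week {wk:>2}: {s['pct_normalized']:.1f}% normalized")
```

prints

```
Paired moderated DE: 2000 genes, 34 pairs, prior df 128, residual df 33; 1732 genes at FDR < 0.05
arm A week  4: 78.6% normalized
arm A week 24: 93.8% normalized
arm B week  4: 0.0% normalized
arm B week 24: 90.7% normalized
```

The recovered disease transcriptome (290 of the 300 planted genes; 146 up,
144 down) tracks the planted improvement kinetics: arm A (fraction 0.80 at
week 4) has most transcripts past the 75% threshold early, arm B (0.45)
almost none, and both arms converge by week 24 (planted 0.85) — the
early/late crossover this analysis is designed to expose. The serum side
works the same way:

```python
serum, hc, pasi, _ = generate_serum_cohort(SimulationConfig(seed=42, n_per_arm=30))
pd_res = pd_effect_model(serum)
pd_res.flag_proteins(1.25, 0.05, week=48)
# {'A': ['BD-2', 'IL-17A', 'IL-17F', 'IL-22', 'IL-23'],
#  'B': ['BD-2', 'IL-17A', 'IL-17F', 'IL-22'],
#  'both': ['BD-2', 'IL-17A', 'IL-17F', 'IL-22'],
#  'A_only': ['IL-23'], 'B_only': []}
```

where e.g. the IL-17F week-48 effect in arm B is estimated at −2.50 log2
(planted: full removal of a 2.38 log2 disease offset).

## Command line

```bash
psopd simulate --seed 7 --out-dir cohort/
psopd run-all --counts cohort/counts.tsv --meta cohort/meta.csv \
              --serum cohort/serum.csv --hc cohort/hc.csv \
              --gmt cohort/gene_sets.gmt --seed 7 --out-dir run/
```

Single stages: `psopd serum-pd`, `psopd de`, `psopd normalize-score`,
`psopd gsva`, `psopd ora`. Every run directory contains the serialized
config and a SHA-256 provenance record; reruns are byte-identical.

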