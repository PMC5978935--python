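# ddrmeth

Analysis toolkit for studying epigenetic silencing of DNA-damage-response
(DDR) genes in IDH-mutant low-grade glioma from Illumina HM-450K-style
methylation data, and for asking whether promoter methylation predicts
differential benefit from radiotherapy (RT) versus temozolomide (TMZ).

It is aimed at statistical genomicists who work with beta-value matrices,
matched expression and clinical follow-up across several cohorts, and who
need the full chain from probe filtering to treatment-interaction survival
models as reusable, tested Python functions. Because patient-level trial
and TCGA data are access-controlled, the package ships a first-class
synthetic-study generator that reproduces the statistical structure of such
a study (with ground truth), so every method can be exercised and validated
end to end.

## What it computes

Methylation is handled on two scales: the beta value `β = Meth/(Meth+Unmeth+offset)`
(a methylation fraction) and the variance-stabilised M value
`M = log2(β/(1−β))`, with tests on M and effect sizes on β.

* **Probe selection** — a three-component Gaussian mixture on normal-brain
  M values (EM, k-means-seeded restarts) classifies probes as
  unmethylated/hemi/methylated; analysis is restricted to
  normally-unmethylated promoter CpGs (|TSS distance| ≤ 1500 nt). A CpG is
  *functionally methylated* when Pearson r(methylation, expression) ≤ −0.3
  with BH-FDR ≤ 0.1 in two independent datasets.
* **Preprocessing** — detection-p / sex-chromosome / SNP probe filters and
  parametric empirical-Bayes ComBat (location/scale) batch adjustment on M
  values (validated against `sva::ComBat`).
* **Subtyping and 1p/19q** — Ward/Euclidean clustering for the CpG island
  methylator phenotype (CIMP), and codeletion calling from combined-channel
  intensity log ratios via circular binary segmentation with a permutation
  acceptance rule.
* **MGMT score & purity** — the two-probe logistic MGMT-STP27-style score
  (score = logit probability, classification cutoff 0.358) and the HMP
  tumor-purity index: sparse PLS (NIPALS with lasso soft-thresholding) of
  arcsin-√purity on unmethylated (median β < 0.2) intergenic probes, plus
  robust-Wald score–purity association and purity adjustment.
* **Differential analysis** — limma-style moderated t (empirical-Bayes
  variance shrinkage, method-of-moments hyperparameters) with DMP gates
  |Δβ| ≥ 0.1, FDR ≤ 0.1, four-dataset sign-consistent intersection, and
  differential expression at |log2FC| ≥ log2 1.2.
* **STATIS** — multi-table concordance on probe-configuration operators
  W = XᵀX/‖XᵀX‖: RV-coefficient interstructure, permutation test of the
  first eigenvalue, compromise eigensystem and per-table projections.
* **Survival** — Cox proportional-hazards models (lifelines, Efron ties)
  of the form `time ~ score + arm + score:arm (+ codel)` with LRT against
  the no-interaction null, per-CpG interaction screening with BH-FDR,
  Kaplan–Meier summaries at score quartile cutoffs, and the
  expected-survival surface S(t | score, arm).

## Worked example

```python
import ddrmeth as dm

bundle = dm.simulate_study(dm.SimConfig(seed=1))          # 4 datasets + truth
manifest = dm.run_pipeline(dm.PipelineConfig(seed=1), "out")
print(manifest["stages"]["select"])
print(manifest["stages"]["survival"])
```

prints (abridged):

```
{'mixture_means': [-4.0391, -0.093, 3.8575], 'n_promoter_ddr': 130,
 'n_unmethylated_ntb': 301, 'n_candidates': 65,
 'n_functional_cpgs': 35, 'n_functional_genes': 19}
{'n_screened': 35, 'n_flagged': 0,
 'score_interaction_coef': -0.3173, 'score_interaction_hr': 0.7281,
 'score_interaction_lrt_p': 0.0916, ...}
```

The mixture means sit at the three planted probe states; 35 of 65 candidate
DDR promoter CpGs pass the dual-dataset functional criterion; and the Cox
fit on the desk-scale trial cohort recovers a treatment-by-score
interaction hazard ratio below 1 — higher methylation scores are associated
with longer progression-free survival specifically in the TMZ arm, which is
the predictive-marker signature the package is built to detect.

The scripts in `examples/` walk through each capability (simulation,
functional selection, scoring and purity, STATIS, differential analysis,
survival interaction, full pipeline) with printed, annotated output. A thin
CLI covers the shell-worthy entry points:

```bash
ddrmeth simulate --outdir sim --seed 1
ddrmeth run-all --outdir out --seed 1
ddrmeth mgmt-score --model model.yaml --m-values m.tsv --out scores.tsv
```

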