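# tmaprog

Prognostic protein-expression profiling for tissue-microarray (TMA)
immunohistochemistry. The package is aimed at computational pathology and
translational-oncology analysts who want a tested, fully scriptable version
of the classic TMA workflow: quantify stained spot images as continuous
H-scores, build a patients × location-specific-protein matrix, normalize
it, split patients into survival-linked groups, select differential
biomarkers under FDR control, and validate the marker panel with
supervised classifiers and on an independent gene-expression matrix.

At its core is the H-score, a continuous per-spot summary of
immunohistochemical staining:

    H = Σᵢ Pᵢ · i,   i = 0, 1, 2, 3,   H ∈ [0, 300]

where `Pᵢ` is the percentage of cells at staining-intensity grade `i`
(0 negative … 3 strong). Positive (DAB-brown) staining is detected by the
red > blue pixel rule; grades come either from object-level
red-minus-blue intensity or from percent-positive binning (grade 1 ⇔
10–25% positive cells). Downstream, the pipeline uses Euclidean
complete-linkage clustering, Kaplan–Meier/log-rank and Cox survival
analysis, pooled-variance t-tests with Benjamini–Hochberg adjustment,
SVM/random-forest/logistic classification with ROC/AUC, and classical MDS
+ k-means for the gene-expression validation stage.

A synthetic-data module generates every input — spot images, H-score
cohorts with planted prognostic structure and survival times, and a
gene-expression analog — with full ground truth, so each stage can be
checked against what was planted.

## Worked example

Run the full pipeline on the default synthetic study (56 patients × 108
location-specific features, latent groups of 19/37, ten planted markers at
effect size 2):

```python
from tmaprog import run_pipeline, PipelineConfig

summary = run_pipeline(PipelineConfig(seed=1))
```

or from the shell: `tmaprog run --seed 1`. Selected output for seed 1:

```
spot_scoring:        mean_abs_h_error 0.0        (6 rendered spots, nucleus mode)
clustering:          cluster_sizes {1: 37, 2: 19}, poor_prognosis_label 2
                     ari_vs_truth 0.859
                     median_survival_months {1: 16.2, 2: 10.1}
                     logrank_p 0.090
                     tumor_normal_fisher_p 0.0
selection (q<0.05):  n_selected 10, n_planted_recovered 10, n_false_positive 0
svm:                 accuracy 0.889, sensitivity 1.0, specificity 0.667, auc 0.944
expression_validation: n_marker_genes 9, ari_vs_truth 1.0
```

Reading this: the automated H-scores reproduce the generator's true spot
scores exactly at default noise; hierarchical clustering recovers the two
planted prognostic groups almost perfectly (adjusted Rand index 0.859) and
the poor-prognosis cluster (label 2, median survival 10.1 months vs 16.2)
is identified from the Kaplan–Meier medians; the t-test/BH stage finds
exactly the ten planted markers and nothing else at q < 0.05; a
linear-kernel SVM trained on two-thirds of each group classifies the
held-out third with 88.9% accuracy; and the nine marker genes (the two p16
compartment features collapse to one gene) recover the groups perfectly on
the gene-expression analog. The log-rank p of 0.090 reflects the default
survival gap (medians 11.7 vs 13.2 months), which is deliberately modest —
group separation in survival at this scale is only powered at larger
hazard ratios.

Other entry points: `tmaprog simulate` writes a synthetic cohort to disk,
`tmaprog score --image spot.png --mode nucleus` quantifies one spot image,
and `tmaprog validate` trains/evaluates a classifier from files on disk.
Each CLI command is a thin wrapper over an importable function.

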