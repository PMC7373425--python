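# acini3d

Spatial cluster analysis of oncogene-expressing cells in 3D mammary acini,
and information-theoretic model selection of the features that predict
cluster-level tumor initiation.

## The scientific problem

Mammary acini grown in 3D culture are hollow spheres of epithelial cells —
a single cell layer around a lumen. When an oncogenic program is activated
in a sparse, random subset of cells (marked, *transduced* cells inside an
otherwise normal epithelium), only some acini develop tumor-like
multilayered outgrowths. The recurring observation is a **proximity
effect**: outgrowths arise where several transduced cells sit close
together, while isolated transduced cells stay quiescent.

`acini3d` turns that observation into a quantitative, reusable pipeline.
Given the 3D centroids of all cells of each acinus at the start of imaging
(x, y, z in µm, plus a transduced flag), it:

1. **identifies clusters** of transduced cells per acinus — pairwise
   Euclidean distances → complete-linkage dendrogram → adaptive (dynamic)
   branch cut, singletons allowed;
2. **computes nine per-cluster features** — acinus size and surface
   density (the acinus treated as a sphere of diameter Dmax, area π·Dmax²),
   transduced counts, the cluster-sphere population, mean pairwise
   distances, transduced fraction in the cluster volume, and transduced
   cell–cell contacts (centres closer than mean cell diameter + 2 SD);
3. **selects predictive models**: every subset of the nine features
   (2⁹ = 512 logistic models) is fitted by maximum likelihood and ranked
   by AICc = −2 logL + 2k + 2k(k+1)/(n−k−1); models are compared via
   Akaike weights wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2), a Δ ≤ 3 confidence set,
   and per-feature importance (sum of weights of models containing the
   feature), with odds ratios and Wald 95% CIs from the best model;
4. **controls for acinus of origin** with a random-intercept mixed
   logistic model (Laplace approximation), taking the three most
   important features plus interactions with the starting number of
   normal cells;
5. **validates itself** end-to-end with a synthetic-acinus generator:
   monolayer shells with controllable transduced-cell aggregation and
   cluster-level outcomes drawn from P(tumor) = logistic(β0 + β1·m),
   m = transduced cells in the cluster, β1 = ln 9 by default.

It is written for quantitative biologists analysing segmented-nucleus
centroid tables (e.g. exported from Imaris or any 3D segmentation tool) in
organoid / acinus tumor-initiation experiments.

## Worked example

Simulate a study-scale cohort and run the analysis (the numbered scripts
under `analysis/` are thin drivers over the library; `acini3d run` does
the same in one step):

```bash
python analysis/01_simulate_cohort.py --seed 4
python analysis/02_identify_clusters.py
python analysis/03_extract_features.py --seed 4
python analysis/04_select_models.py
```

which prints:

```
simulated 20 acini, 690 cells, 142 transduced (7.1 per acinus)
39 clusters over 20 acini; sizes min/median/max = 1/3/10; 4 singletons
39 feature rows; tumor outcome in 26 clusters (67%)
best model: n_transduced_in_cluster
confidence set (delta <= 3): 20 models
importance ranking (top 3):
                feature  importance     aicc_sum
n_transduced_in_cluster    0.980936 10652.121750
         density_acinus    0.405768 11912.104996
  n_contacts_transduced    0.373393 11675.054205
odds ratios, achieved vs published reference:
                            quantity  achieved  reference
 best_model_or_transduced_in_cluster  6.473801       8.96
mixed_model_or_transduced_in_cluster  3.258390       6.73
```

Reading this: of 512 candidate models the single-feature model on the
number of transduced cells in the cluster wins on AICc, that feature
carries essentially all the Akaike-weight importance (0.98 of 1), and each
additional transduced cell in a cluster multiplies the tumor odds by ~6.5
in this cohort (the generative truth is 9; the reference column shows the
published estimates from the original cohort for side-by-side comparison).
`analysis/05_parameter_recovery.py` repeats generate→analyze over many
cohorts and shows the estimator is centred on the truth (bias of the
single-feature log-odds ≈ 0 on non-separated fits, 95% CI coverage ≈ 95%).

Real data enter through `acini3d run --mode canonical_csv` (a flat CSV of
cell records) or `--mode supplementary_xlsx` (one-sheet-per-acinus
workbooks of centroids plus a label workbook of transduced cell ids, with
an explicit `--column-map` because sheet layouts vary).

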