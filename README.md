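# microsig

Discriminative analysis of two-group (case-control) gut-microbiome
cohorts — for example, metastatic versus non-metastatic cancer patients
profiled by 16S sequencing. Given per-rank relative-abundance tables
(samples × taxa, percent scale) and a binary group label, `microsig` runs
two independent analysis branches over logit Z-scored abundances:

1. **PELORA supervised clustering** — greedy growth of taxon clusters
   whose centroid (per-sample mean Z-score of the members) minimizes the
   L2-penalized negative Bernoulli log-likelihood
   J(β) = −Σ [y ln π + (1−y) ln(1−π)] + λ Σ βⱼ², π = logistic(Xβ),
   with penalty λ tuned by bootstrap out-of-bag misclassification.
2. **Iterative Random Forest (iRF)** — forests refit K times with
   split-candidate sampling weighted by the previous iteration's Gini
   importances, out-of-bag AUC with a stratified-bootstrap 95% CI,
   relative variable importance (max = 100%), and taxon–taxon interaction
   discovery by generalized Random Intersection Trees with per-interaction
   bootstrap **stability scores** in [0, 1]. Interpretation via
   Accumulated Local Effects curves and 2-D partial dependence surfaces.

A third, optional step maps discriminating taxa to metabolite features by
pairwise Spearman correlation. A synthetic-cohort generator with planted
ground truth (cluster shifts, label-driving interactions, taxon–metabolite
correlations) makes every claim testable end to end.

Both `PeloraClassifier` and `IterativeRandomForestClassifier` follow the
scikit-learn estimator API (`fit`, `predict_proba`, `get_params`,
`clone`-compatible), and `LogitZTransformer` is a standard transformer;
module-level functions (`fit_pelora`, `iterate_irf`, `logit_zscore`, ...)
are thin wrappers over them.

## Worked example

```python
import numpy as np
from microsig.synthetic_data import cluster_scenario
from microsig.transforms import logit_zscore, centroid
from microsig.pelora import fit_pelora
from microsig.irf import iterate_irf

cohort = cluster_scenario(seed=0)      # n=60, 45 genera, planted 5-taxon cluster
table = cohort.table("genus")
z = logit_zscore(table)                # zero-replace -> logit -> pooled Z-score
y = table.group.to_numpy()

fit = fit_pelora(z, y, lam=1/32, max_clusters=2)
print("cluster 1:", fit.clusters[0])
print("planted:  ", cohort.truth["planted_cluster"]["taxa"])
res = centroid(z, fit.clusters[0], group=y)
print(f"centroid group means: PC {res.group_means[0]:.3f}, "
      f"PC met {res.group_means[1]:.3f} (p = {res.p_value:.2g}, {res.test_used}-test)")

irf = iterate_irf(z.values, y, K=3, n_trees=300, seed=0)
print(f"OOB AUC = {irf.auc:.3f} (95% CI {irf.auc_ci[0]:.3f}-{irf.auc_ci[1]:.3f})")
```

prints

```
cluster 1: ['genus_003', 'genus_001', 'genus_000', 'genus_004', 'genus_002']
planted:   ['genus_000', 'genus_001', 'genus_002', 'genus_003', 'genus_004']
centroid group means: PC -0.462, PC met 0.462 (p = 4.6e-15, t-test)
OOB AUC = 0.953 (95% CI 0.897-0.994)
```

The supervised clustering recovered exactly the five planted taxa as its
first cluster; their centroid separates the groups symmetrically around 0
(a consequence of pooled standardization), and the forest branch
independently confirms the cohort is discriminable (OOB AUC 0.95).

## Command line

Every stage is also a `microsig` subcommand over the same TSV formats
(samples in rows, taxa in columns, metadata with `sample_id`/`group`):

```sh
microsig simulate  --spec spec.yaml --out cohort/
microsig transform --input cohort/abundance_genus.tsv --metadata cohort/metadata.tsv --rank genus --out z
microsig pelora    --abundance cohort/abundance_genus.tsv --metadata cohort/metadata.tsv --out pelora_out
microsig irf       --abundance cohort/abundance_genus.tsv --metadata cohort/metadata.tsv --out irf_out
microsig associate --taxa cohort/abundance_genus.tsv --metabolites cohort/metabolites.tsv --out assoc
microsig run       --config pipeline.yaml      # both branches + manifest
```

`microsig run` writes every intermediate object plus a manifest with
per-stage seeds and SHA-256 checksums; identical config and seed
reproduce every output byte for byte.

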