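# lncluster

Unsupervised stratification of tumor cohorts from long non-coding RNA
(lncRNA) expression, with downstream molecular and clinical
characterization of the discovered clusters.

Bulk RNA-seq cohorts (e.g. TCGA head-and-neck squamous cell carcinoma,
where lncRNA expression separates an HPV-driven subgroup from
smoking-associated subgroups) can be partitioned into molecular subtypes
using only the lncRNA transcriptome.  `lncluster` implements that analysis
as a reusable, fully tested pipeline:

1. **Feature selection** — keep detectable lncRNAs (mean RPKM ≥ 0.3
   across samples) and the top-k (default 500) most variable genes on the
   log2(RPKM + 1) scale.
2. **Consensus clustering** — repeatedly subsample 80% of the samples,
   partition each subsample with PAM k-medoids on Euclidean distance, and
   record for every sample pair the *consensus value*
   M(i,j) = C(i,j)/N(i,j): the proportion of runs clustering i and j
   together among runs sampling both.  For each k in 2..6 the consensus
   matrix is summarized by the **proportion of ambiguous clustering**
   (PAC): the fraction of pairwise consensus values inside an intermediate
   window (0.1, 0.9).  The selected k is the smallest k whose PAC is
   within 0.01 of the minimum — a clean clustering has consensus values
   piled near 0 and 1, so PAC is minimized at the best-supported k.
   Final labels come from complete-linkage agglomeration of 1 − M.
3. **Cluster association** — Fisher's exact test (2×2, two-sided
   probability-mass rule, odds ratios) and uncorrected Pearson chi-square
   (r×c) for categorical covariates (HPV status, mutations, smoking,
   grade, anatomic site); Welch's t for continuous ones (age).
4. **Guilt-by-association (GBA)** — per cluster, a binary template vector
   marks its samples; surrogate lncRNAs satisfy Pearson r > 0.3 with
   p < 10⁻⁶ against the template, mean cluster RPKM ≥ 0.1, and
   overexpression versus normal tissue (Welch t on log2 scale,
   BH-corrected p < 0.05).  Protein-coding genes correlating with the
   cluster's mean surrogate profile at |r| > 0.3, p < 10⁻⁹ become the
   directly/inversely co-expressed partner lists.
5. **Enrichment** — one-sided hypergeometric over-representation of those
   PCG lists in user-supplied GMT gene sets (p < 0.05), universe = all
   measured PCGs.
6. **Survival** — Kaplan–Meier curves per cluster and the global k-sample
   log-rank test for two endpoints (overall survival, recurrence), with
   administrative censoring at a 60-month horizon.

Because public tumor matrices need a download, the package ships a
first-class synthetic cohort generator (`lncluster.synthetic_data`) that
plants the structure the analysis assumes — sample clusters, per-cluster
marker lncRNAs, directly/inversely co-expressed PCGs, a normal-tissue
block, cluster-linked covariates and exponential survival — so every stage
is testable end to end.  Real expression/clinical TSVs are a drop-in
replacement.

## Worked example

```python
from lncluster import (SimulationConfig, simulate_cohort, ConsensusParams,
                       consensus_cluster, compare_partitions, run_gba)
from lncluster.feature_selection import FeatureSelectionParams, select_features

cohort = simulate_cohort(SimulationConfig(seed=1))     # 200 tumors, 5 planted clusters
lnc = cohort.expression.select_class("lncRNA").select_role("tumor")
selected = select_features(lnc, FeatureSelectionParams(top_k=300))
result = consensus_cluster(selected.log2(),
                           ConsensusParams(n_resamples=250, seed=1))
print("PAC by k:", {k: round(v, 3) for k, v in result.pac.items()})
print("selected k:", result.selected_k)
print("ARI vs truth:", compare_partitions(result.final_labels,
                                          cohort.truth_labels))
```

prints

```
PAC by k: {2: 0.559, 3: 0.332, 4: 0.107, 5: 0.0, 6: 0.1}
selected k: 5
ARI vs truth: 1.0
```

PAC falls to its minimum at the planted k = 5 (every pairwise consensus
value is 0 or 1 there) and rises again at k = 6, where one true cluster
must be split arbitrarily; the recovered labels match the planted ones
exactly.  Continuing with GBA and survival on the same cohort:

```python
surr = run_gba(cohort.expression, result.final_labels)
for cs in surr:
    print(cs.cluster, len(cs.surrogates), len(cs.up_pcgs), len(cs.down_pcgs))
```

recovers the 40 planted marker lncRNAs and (29–30)/(19–20) up/down PCGs
per cluster, and the log-rank test on the simulated overall-survival
endpoint (4-fold hazard spread across clusters, 60-month horizon) gives
chi² = 31.55 on 4 df, p = 2.4 × 10⁻⁶.

The same stages are available from the shell:

```sh
lncluster simulate --out cohort/ --seed 1
lncluster run --out results/ --seed 1      # full pipeline + manifest.json
```

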