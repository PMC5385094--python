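# Methods

## Scope and model

`lncluster` stratifies a tumor cohort from its lncRNA expression matrix
(non-negative RPKM-like values) and characterizes the resulting clusters
molecularly and clinically.  All distance, correlation and t-test
computations run on log2(RPKM + 1); threshold filters stated in RPKM
(detectability, within-cluster expression) are applied to the raw scale.
The log transform is a deliberate choice: Euclidean distances and Pearson
correlations on raw RPKM are dominated by a handful of highly expressed
genes, whereas the log scale weights fold changes.

## Consensus clustering and PAC

For each candidate k (default 2..6), `n_resamples` (default 1000; the
bundled presets use 100–250) runs each draw ⌈0.8·n⌉ samples and all genes
(both proportions configurable), and partition the subsample with PAM
k-medoids on Euclidean distance.  PAM is implemented deterministically:
greedy BUILD initialization (first medoid minimizes total distance, each
subsequent medoid maximizes the cost reduction) followed by
steepest-descent SWAP, at most 100 sweeps.  Determinism matters because
every run must be reproducible from the single pipeline seed; sub-streams
are derived per k so results for one k do not depend on the range tested.

The consensus value of a sample pair is C(i,j)/N(i,j), co-clustering runs
over co-sampling runs; a pair never co-sampled is an error (the fix is
more resamples, not a silent placeholder).  PAC is the fraction of
strict-lower-triangle consensus values strictly inside (0.1, 0.9) — the
standard window; a well-supported k drives consensus values to 0 or 1.
`select_k` returns the smallest k with PAC within `k_tolerance` (default
0.01) of the minimum, encoding a preference for the smaller k when the
difference between two candidate k values is minor.  Final labels cut a
complete-linkage tree on 1 − M and are renumbered 1..k by decreasing
cluster size (ties: smallest contained sample id).  An `inner_linkage`
parameter is accepted for configuration parity with the conventional
consensus-clustering parameter set but is unused with a k-medoids base
clusterer.  A 1 − Pearson distance and per-gene median centering are
available as options; both default off.

## Association tests

Categorical covariates: global uncorrected Pearson chi-square on the
k × L contingency table (Fisher's exact when 2 × 2), and per-(cluster,
level) two-sided Fisher 2 × 2 tests of in-cluster vs out-of-cluster
against level vs rest.  The two-sided Fisher rule is the probability-mass
convention (sum of all margin-fixed tables no more probable than the
observed one); the odds ratio is the cross-product ad/bc, reported as
+inf when bc = 0 and ad > 0 and as undefined when both products vanish.
Enrichment/depletion is called from the odds ratio at alpha = 0.05.
Continuous covariates use Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom.  Multiple-testing correction is
Benjamini–Hochberg step-up by default, Bonferroni by flag.  Missing
feature values are dropped pairwise per test and counted.

## Guilt-by-association

Templates are binary cluster indicators — the minimal realization of an
idealized "maximally expressed in one cluster" profile (a z-scored
variant would only rescale Pearson r, which is affine-invariant).
Surrogate selection applies, per cluster: (i) r > 0.3 and p < 10⁻⁶
against the template, with the Pearson p from the exact t transform
t = r√(n−2)/√(1−r²); (ii) mean raw RPKM within the cluster ≥ 0.1;
(iii) overexpression of cluster tumors versus normal tissue, Welch t on
log2 with BH-corrected p < 0.05 and cluster mean above normal mean.  The
BH family is the per-cluster set of genes passing (i)–(ii): the
correction is meant to control the discoveries actually taken forward,
not the full transcriptome.  The normals comparison is cluster-vs-normal
(not all-tumors-vs-normal); a gene constant across samples has undefined
correlation and is counted and excluded.  PCG partners correlate the
cluster's mean surrogate profile (per-sample mean of log2 values over
surrogates) at |r| > 0.3, p < 10⁻⁹, split by sign into direct (up) and
inverse (down) lists sorted by |r|.

## Enrichment

Over-representation is the plain upper-tail hypergeometric
P(X ≥ overlap) of each GMT set against a query list within a universe,
by design the PCGs measured in the matrix — testing against genes that
could never have been selected would inflate every p.  Sets are
intersected with the universe first; significance is raw p < 0.05 with a
BH column reported alongside for reference.  No modified
(EASE-style) score is used: the plain test is exactly testable against
explicit summation.

## Survival

Kaplan–Meier product-limit curves per cluster and a global k-sample
log-rank test (observed minus expected events with the hypergeometric
variance at each event time, chi-square on k − 1 df).  Follow-up is
administratively censored at a horizon (default 60 months) before
testing; an event exactly at the horizon is kept as an event.  Tied
events at one time are processed simultaneously.  Pairwise post-hoc
comparisons are out of scope; the global test is what the pipeline
reports.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, on the
log2(RPKM + 1) scale: per-gene baselines mu_g ~ N(1, 1); i.i.d. N(0,
noise_sd²) noise; marker lncRNAs and up-PCGs shifted +marker_shift inside
their cluster; down-PCGs shifted −marker_shift inside their cluster *on a
baseline elevated by +marker_shift* — an inversely co-expressed gene must
be expressed outside the cluster for its repression to be observable,
otherwise the floor at RPKM = 0 erases the planted signal.  Values map
back through max(0, 2^x − 1).  Normal samples receive no shifts.  Marker
blocks are disjoint across clusters, so cluster centroids form an
approximately equidistant simplex; this makes low-k partitions unstable
under subsampling (high PAC) while the planted k is perfectly stable —
the regime in which PAC-based selection is informative.

Default preset: 200 tumors in clusters of (55, 50, 35, 35, 25), 20
normals, 500 lncRNAs with 40 markers per cluster, 600 PCGs with 30 up /
20 down per cluster, marker_shift 2.0 vs noise_sd 0.5 (a 4-sd
separation), clustering on the top 300 variable lncRNAs with 250
resamples.  These sizes keep a full consensus run at a few seconds while
preserving the qualitative regime of a 426-sample cohort; a
`full_scale()` preset (426 tumors, clusters (134, 126, 71, 66, 29)) and
a `tiny()` 3-cluster smoke preset are provided.  Covariates are drawn
per cluster from categorical probability tables patterned on HPV-driven
head-and-neck cohorts (one HPV-positive, TP53-wild-type cluster with the
best survival; smoking/larynx-heavy clusters with TP53/NSD1/KMT2D
mutations); ages are N(mean_c, sd_c); survival times are exponential
with per-cluster hazards per month spanning a 4-fold range, and each
endpoint is censored by an independent exponential time whose rate is
chosen so the marginal censoring probability equals `censor_rate`
(default 0.3) exactly — independent censoring with an interpretable
marginal rate.

What the generator does not emulate: read-count noise (RPKM values are
log-normal, not count-based), isoforms, batch effects, library-size
artefacts, gene–gene correlation beyond the planted blocks, viral
transcripts, or the heavy-tailed marginal distribution of real TCGA
RPKM.  Passing tests therefore demonstrate correctness of the algorithms
under the stated generative model, not robustness to every artefact of
real cohorts; with real data the feature-selection and clustering
choices (top-k, distance, PAC window) deserve sensitivity checks.

## Numerical conventions and degenerate inputs

- Pearson r clipped to [−1, 1]; |r| = 1 reports p = 0; constant vectors
  are an error scalar-wise and "non-correlated, counted" in vectorized
  screening.
- Fisher p compared to the observed table probability with a 1e−12
  relative guard (the probability-mass rule is discontinuous in exact
  ties).
- PAC window is open on both sides; the CDF grid is 0..1 in steps of
  0.01 with P(X ≤ t) convention.
- Tie-breaks are deterministic everywhere: gene-id lexicographic order in
  top-variability selection, lowest medoid index in PAM assignment,
  smallest sample id in cluster renumbering.
- Zero contingency margins, empty templates (a cluster covering all or
  no samples), empty surrogate lists, missing normals, and k exceeding
  the item count raise typed errors rather than returning sentinels.

## Known limitations

- PAM uses one deterministic BUILD start; on pathological geometries a
  restarted or randomized PAM could find lower-cost medoids.  Within the
  consensus loop this is immaterial (subsampling provides the variation)
  but the single-shot clustering of one subsample is not guaranteed
  globally optimal.
- PAC-based selection shares the known weakness of consensus methods on
  strongly nested structure: when a true cluster contains well-separated
  sub-clusters, PAC can continue to fall past the "natural" k.
- The log-rank chi-square is asymptotic; for very small groups a
  permutation version would be preferable and is not implemented.
- Enrichment treats gene sets as flat lists; no ontology-graph
  redundancy handling.
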