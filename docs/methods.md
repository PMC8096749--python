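# Methods

## Network construction

Each subject contributes, per atlas region, a bag of positive grey-matter
voxel values. The pipeline starts from these bags (or extracts them from a
GM value map plus an integer atlas on the same voxel grid); any upstream
segmentation, registration, or smoothing is out of scope.

**Density estimation.** Each region's value distribution is estimated by a
Gaussian kernel density estimate with Silverman's rule-of-thumb bandwidth
(0.9 · min(SD, IQR/1.349) · n^(−1/5)), evaluated on a single grid per
subject of 2⁷ = 128 points. The grid spans the subject's pooled regional
range, extended by three times the largest regional bandwidth so every
region's kernel mass lies on the shared support. The evaluated density is
renormalised to a discrete probability mass vector (summing to 1), matching
the discrete summation form of the divergence below. A region with fewer
than two distinct values has no bandwidth and raises a degenerate-sample
error naming the region.

**Similarity.** For mass vectors P, Q on the shared grid the symmetric
divergence is D(P,Q) = Σᵢ [P(i) ln(P(i)/Q(i)) + Q(i) ln(Q(i)/P(i))] and the
edge weight is KLS(P,Q) = exp(−D(P,Q)) ∈ (0, 1], equal to 1 exactly when
the two distributions coincide. Logs are natural; masses are floored at
1e-10 and renormalised before the logarithms, which keeps divergences finite
for near-disjoint supports while preserving the KLS → 0 limit. The result is
a symmetric 90 × 90 weighted matrix per subject with a zero diagonal by
convention. The kernel, bandwidth rule, and grid placement are not forced by
the KLS definition itself; the defaults here follow common KDE practice.

## Thresholding and graph metrics

At sparsity S the K = round(S · 4005) strongest off-diagonal edges are
retained (round-half-even; weight ties broken by ascending node-index pair
for bit-reproducibility). The analysis window is S ∈ [0.10, 0.34] in steps
of 0.01, and each metric curve is summarised by its trapezoidal AUC over the
window.

Metrics default to **weighted** mode: clustering uses Onnela's
geometric-mean-of-triangle-weights generalisation with weights scaled by the
maximum weight; path-based metrics use Dijkstra distances on lengths
1/weight. The classical binary clustering formula
C_p = (1/n) Σᵢ 2tᵢ/(kᵢ(kᵢ−1)) — with tᵢ the triangle count and kᵢ the
degree of node i, nodes with kᵢ < 2 contributing 0 — is available as
`mode="binary"` and is the form checked exhaustively against brute-force
enumeration on all ≤ 6-node graphs. Characteristic path length averages over
connected ordered pairs only; global and nodal efficiency average 1/distance
with disconnected pairs contributing 0; local efficiency of a node is the
global efficiency of its neighbourhood subgraph (node removed). Betweenness
is Brandes' algorithm (networkx), unnormalised. Nodal degree is binary count
or strength (weight sum).

**Null networks.** Small-world indices compare each thresholded graph to 100
Maslov–Sneppen rewired references (10·|E| attempted double-edge swaps,
weights carried with the swapped edges), which preserve node count, edge
count, degree sequence, and the weight multiset exactly. γ = C_p/C_p^rand,
λ = L_p/L_p^rand, σ = γ/λ. The swap loop is numba-compiled because the
ensemble (subjects × sparsities × 100 nulls) dominates runtime.

**Sparsity-window selection.** A sparsity is admissible when (a) the mean
binary degree 2K/90 exceeds 2·ln(90) ≈ 9.0 and (b) σ > 1.1 for every
subject. Under criterion (a) taken literally with natural log, S = 0.10
gives mean degree 2·400/90 ≈ 8.9 < 9.0, so the smallest admissible grid
point is 0.11; `select_sparsity_range` implements the strict rule, while the
package's default analysis window keeps the conventional 0.10 lower bound.
Both are exposed.

**Hubs.** Per nodal metric the top 10 % of regions (9 of 90) by group-mean
AUC are flagged (rank-9 ties broken by node index); a region's hub score is
the number of metrics (0–3) in which it is flagged, and `is_hub` defaults to
score ≥ 2.

## Group inference

Group differences in AUC metrics use two-tailed permutation tests on the
difference of group means with an add-one correction,
p = (1 + #{|diff*| ≥ |diff|}) / (n_perm + 1), 5000 label permutations by
default, so p ∈ (0, 1] and the test is exact under exchangeability. Effect
sizes are Cohen's d with pooled SD. Nodal tests are FDR-corrected
(Benjamini–Hochberg, q = 0.05) per metric across the 90 regions (pooling all
270 tests is available as an option); a region is reported altered when
significant in at least one of the three nodal metrics.

Partial correlations between nodal AUCs and clinical scores (computed within
patients, adjusting for age, gender coded 0/1, and education) residualise
both variables by least squares with intercept and test the residual Pearson
r against a t distribution with n − k − 2 degrees of freedom. A variable
fully explained by the covariates returns r = 0, p = 1.

**NBS.** Edgewise pooled-variance t tests on the raw KLS weights (not
thresholded networks — an assumption, since nothing forces either choice),
one direction at a time; suprathreshold edges at the one-tailed primary-p
critical value; connected components sized by their number of connections;
corrected component p = proportion of permutations whose maximal component
size is ≥ the observed size (the ≥ convention is the conservative reading).
Note that with a liberal primary threshold (p = 0.05) on 90 nodes, chance
alone yields ~200 suprathreshold edges that usually form one giant
component, so small planted subnetworks are only recoverable with stricter
primary thresholds (the planted-recovery test uses 0.005); family-wise error
control holds at any primary threshold.

## Classification

Linear SVM (scikit-learn SVC) on either the 4005 upper-triangle edge weights
or the 7 + 270 graph-metric AUCs. Outer evaluation: stratified 5-fold CV;
within each outer training fold, features are z-scored and C is selected
from {10⁻³ … 10⁴} by an inner stratified 5-fold grid search — no statistic
of the held-out fold ever enters training (verified by a canary test in
which a feature equals the labels on training folds only). Reported
sensitivity (recall of the patient class), specificity, and balanced
accuracy = (sensitivity + specificity)/2 are fold means. Significance
repeats the whole nested procedure on permuted labels (1000 by default);
p = #{permuted balanced accuracy > observed}/n_perm, with an add-one variant
available since the plain estimator can return 0. Region importance is the
fold-mean absolute weight, mapped directly for metric features and summed
over incident edges for edge features (an aggregation choice, not forced);
the default report lists the top 20 regions and flags an all-zero weight
vector as degenerate.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
brain geometry. Each region's values are drawn from a two-component Gaussian
mixture truncated at zero (component gap 0.25, SD 0.08, mixture weight 0.6,
in GM-volume-like units on [0, 1]); 90 regions are organised into 9
modules that share mixture means, with per-region jitter (SD 0.03) and
per-subject noise (SD 0.012), so within-module pairs have similar
distribution shapes and hence high KLS edges — producing the modular,
small-world-like topology (γ ≫ 1) the metrics expect. Defaults are 20
subjects per group and 300 voxels per region: large enough for stable KDEs,
small enough for desk-scale runs.

Planted group effects: `mean_shift` displaces affected regions' mixture
means in patients by magnitude × severity (severity ~ U(0.5, 1.5) per
patient), altering those regions' edges; `module_tighten` pulls affected
regions toward their module's base parameters, strengthening within-module
similarity and hence segregation (C_p, E_loc). Patients' UPDRS-III scores
are generated as 5 + slope·severity + noise (slope 20, noise SD 3), so
clinical correlations with severity-driven network changes have known sign;
age, gender, and education are drawn independently of the effect so
covariate adjustment is testable against plain correlation. With magnitude
0 the two groups are exchangeable, which the calibration tests rely on.

What the generator does **not** model: spatial smoothness and registration
artifacts, realistic parcel shapes and sizes, long-range anatomical
covariance unrelated to distribution shape, site/scanner effects, and
realistic clinical-score distributions. Passing tests therefore demonstrate
correctness and calibration of the machinery under the assumed statistical
structure, not performance on real MRI data.

NIfTI export packs each region's voxels into contiguous blocks of an
integer-labelled volume so extraction recovers the bags exactly (as
multisets); the default 30³ volume (27 000 voxels) exactly accommodates the
90 parcels of 300 voxels.

## Reproducibility and problem sizes

One global seed deterministically derives all stage seeds (SHA-256 of
seed:stage, reduced below 2³¹); identical configurations yield bit-identical
outputs, and constructed networks are cached per subject keyed by a digest
of the input voxel values. Test problem sizes are chosen for desk scale: the
exhaustive metric oracle covers all 207 graphs on 2–6 nodes; permutation
calibration uses 2000 replicate 20-vs-20 tests with 499 permutations each;
NBS recovery uses 20/group with 1000 permutations; the demo pipeline run
uses 20 + 20 subjects, 300 voxels/region, 1000 group permutations, 20 null
networks per threshold, and 25 SVM label permutations per feature kind
(library defaults remain 100 nulls, 5000 and 1000 permutations).

## Known limitations

* The KDE kernel/bandwidth/grid conventions affect absolute KLS values;
  comparisons across software require matching those choices.
* Weighted clustering and local-efficiency variants differ between
  toolboxes; both implemented modes (binary formula, Onnela weighted) are
  documented and oracle-tested, but other generalisations exist.
* NBS on raw weighted matrices (rather than thresholded graphs) and t-based
  edge statistics are assumptions; both are isolated behind the `nbs`
  interface.
* The permutation estimator for SVM significance can return p = 0; the
  add-one variant is provided.
* Partial-correlation p-values assume approximately Gaussian residuals.
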