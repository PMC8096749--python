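# morphkls

Single-subject grey-matter (GM) morphological brain network analysis based on
Kullback–Leibler divergence similarity (KLS), with graph-theoretic
characterisation, permutation-based group inference, clinical correlation,
and linear-SVM single-subject classification. Developed for studies of
early-stage Parkinson's disease, where group-level structural covariance
networks cannot be related to individual clinical scores — the KLS approach
yields one normalised 90-node network *per subject*.

## Who this is for

Neuroimaging researchers who have voxel-wise GM value maps (e.g. from VBM)
plus an integer-labelled atlas (90 regions by default), or pre-extracted
regional voxel-value tables, and want individual morphological networks and
the full downstream statistical battery. A synthetic-cohort generator makes
every stage testable without MRI data.

## The model

For each subject and each atlas region *i*, the distribution of GM voxel
values is estimated by Gaussian kernel density estimation, evaluated on a
subject-common grid of n = 2⁷ sample points and renormalised to a discrete
probability mass function P<sub>i</sub>. Edges are the KL-divergence-based
similarity

```
D_KL(P, Q) = Σᵢ [ P(i) ln(P(i)/Q(i)) + Q(i) ln(Q(i)/P(i)) ]     (symmetric KL)
KLS(P, Q)  = exp(−D_KL(P, Q))  ∈ (0, 1],  = 1 iff P = Q
```

giving a 90 × 90 weighted undirected matrix per subject. Networks are
thresholded over a sparsity window S ∈ [0.10, 0.34] (step 0.01), and each
metric's curve is summarised by its area under the curve (AUC):

* **global**: clustering coefficient C_p, characteristic path length L_p,
  global/local efficiency E_glob/E_loc, and the small-world indices
  γ = C_p/C_p^rand, λ = L_p/L_p^rand, σ = γ/λ against 100 degree-preserving
  (Maslov–Sneppen) rewired null networks;
* **nodal**: betweenness, degree (strength), nodal efficiency; hub scores
  (0–3) count the metrics in which a region ranks in the top 10 %.

Inference: two-tailed permutation tests (5000 label permutations) on AUCs,
Benjamini–Hochberg FDR across regions for nodal metrics, Cohen's d,
partial correlations with clinical scores (age/gender/education adjusted),
and a network-based statistic (NBS) whose family-wise-corrected component
p-values come from the permutation null of the maximal suprathreshold
component size (size = number of connections). Classification: linear SVM,
nested stratified 5-fold cross-validation with an inner grid search over
C ∈ {10⁻³ … 10⁴}, label-permutation significance, and region rankings from
fold-mean absolute weights.

## Worked example

Simulate a 20 + 20 cohort in which the patient group's within-module
similarity is strengthened in 30 planted regions, build the per-subject KLS
networks, and test whether patients show higher network segregation:

```python
import numpy as np
import morphkls as mk

affected = tuple(r for r in range(90) if r % 9 < 3)        # 3 of 9 modules
design = mk.SimulationDesign(
    n_per_group=20, voxels_per_region=300,
    planted_effect=mk.PlantedEffect(affected, 0.9, "module_tighten"),
    seed=42)
cohort, metas = mk.simulate_cohort(design)
nets = [mk.build_network(s) for s in cohort]

cp_auc = np.array([
    mk.auc(np.array([mk.clustering_coefficient(
        mk.threshold_by_sparsity(net, float(s)).adjacency)[1]
        for s in mk.DEFAULT_SPARSITIES]))
    for net in nets])
diff, p = mk.permutation_test(cp_auc[20:], cp_auc[:20], n_perm=1000, seed=3)
print(f"C_p AUC patients - controls: {diff:.5f}, permutation p = {p:.4f}")
```

```
C_p AUC patients - controls: 0.00327, permutation p = 0.0020
```

The planted segregation increase is detected (patients' clustering AUC is
significantly higher; the matching local-efficiency test gives p = 0.0040).
On the same cohort, a linear SVM on the 4005 edge weights reaches a
fold-mean balanced accuracy of 0.975, and 16 of its top-20 weight-ranked
regions are planted ones.

The same analysis from the shell, end to end:

```bash
morphkls run --out demo_run --seed 123
```

writes metadata, per-subject network TSVs, metric AUC tables, comparison /
NBS / correlation reports, and classification summaries under `demo_run/`.

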