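# scnkit

Structural covariance network (SCN) analysis of regional grey-matter
volume, for neuroimaging groups comparing the network topology of a
patient cohort against matched controls when each group yields only **one**
network.

Inter-individual differences in the grey-matter volume (GMV) of one brain
region co-vary with other regions; the cross-subject Pearson correlation of
confound-adjusted regional volumes defines a group-level network over the
90 cerebral regions of an AAL-style atlas. `scnkit` implements the full
workflow:

- demographic group statistics (pooled t-test, uncorrected Pearson χ² for
  sex tables);
- age/gender confound regression of regional volumes (one pooled GLM);
- per-group 90×90 covariance networks and proportional thresholding over
  sparsity S = 0.05…0.50 (step 0.01, 46 nested binary graphs; at sparsity S
  the round(S·4005) strongest-|r| edges are kept);
- global metrics — clustering Cp, characteristic path length Lp, global and
  local efficiency, small-world index σ = (Cp/Cp_rand)/(Lp/Lp_rand) against
  degree-preserving nulls — and nodal metrics — degree, nodal efficiency,
  betweenness centrality;
- group inference on the **area under each metric's sparsity curve** by
  label permutation (default R = 5000), two-tailed add-one p-values,
  Benjamini–Hochberg FDR across the 90-node family per nodal metric;
- covariate-adjusted (partial) correlation between regional volume and
  clinical scores;
- a synthetic cohort generator with modular factor-model covariance and
  planted, exactly-known group effects, so every stage is testable against
  ground truth.

A small real clinical table (24 complete thoracic spinal-cord-injury
patients and the sex composition of their 26-subject control arm) ships
with the package for the demographic statistics and worked examples.

## Worked example

```python
import numpy as np
from scnkit import (
    SyntheticConfig, generate_cohort, regress_confounds,
    build_covariance_network, build_graph_series,
    metric_curve_extractor, permutation_test, chi_square_2x2,
)
from scnkit.datasets import gender_contingency
from scnkit.scn import default_sparsities

# demographic statistic on the bundled cohort
chi2, p, _ = chi_square_2x2(gender_contingency())
print(f"sex chi2 = {chi2:.3f}, p = {p:.3f}")

# synthetic two-group cohort (24 patients / 26 controls, 90 ROIs)
volumes, cohort, truth = generate_cohort(SyntheticConfig(seed=1))
model = regress_confounds(volumes, cohort)
res_p = model.residuals_for_group(cohort, "patient")
res_c = model.residuals_for_group(cohort, "control")

series = build_graph_series(build_covariance_network(res_p, group="patient"))
print(f"{len(series)} sparsity levels, {series.edge_counts[0]} edges at 5%")

s = default_sparsities()
test = permutation_test(
    res_p, res_c, metric_curve_extractor("clustering", s), s,
    n_perm=200, rng=np.random.default_rng(0),
)
print(f"clustering AUC diff = {test.observed_diff:+.4f}, p = {test.p:.3f}")
```

prints

```
sex chi2 = 0.007, p = 0.933
46 sparsity levels, 200 edges at 5%
clustering AUC diff = -0.0094, p = 0.697
```

The χ² of 0.007 says the two arms are sex-balanced; the 46-level series
starts with the 200 strongest of 4005 candidate edges; and on this draw
the clustering-AUC permutation test finds no group difference
(p ≈ 0.70), as it should — the planted group effect in the default
generator is a covariance perturbation on 10 regions, not a global
topology shift.

The same pipeline runs from the shell:

```sh
scnkit simulate --seed 1 --out scratch/sim          # write synthetic tables
scnkit run --config analysis.yaml --out scratch/out # full seeded analysis
scnkit report scratch/out                           # summarize a report
```

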