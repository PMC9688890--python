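# thalnet

Structural covariance network analysis of thalamic nuclei volumes.

In multiple sclerosis, thalamic atrophy appears early and has been linked to
fatigue and cognitive symptoms. One way to study intra-thalamic organization
with conventional T1 imaging is the *structural covariance network*: treat
the 50 FreeSurfer thalamic nuclei (25 per hemisphere) as nodes and connect
nuclei whose volumes correlate across the subjects of a group. `thalnet`
implements that analysis end to end, starting from a per-subject table of
absolute nucleus volumes and covariates:

1. **Volumetry** — volumes are expressed as a percentage of estimated total
   intracranial volume, `vol% = absolute / eTIV x 100`, and compared across
   groups (fatigued MS, non-fatigued MS, healthy controls) with one-way
   ANOVA plus Bonferroni post hoc tests at `alpha = 0.05/50 = 0.001`;
   Spearman/Pearson correlations against lesion volume, disease duration
   and age.
2. **Network construction** — within each group, every nucleus volume is
   residualized on age, sex and lesion load (OLS); the 50 x 50 inter-regional
   correlation matrix `C_ij` of the residuals is thresholded by connection
   density: at sparsity `d` the `round(d x 1225)` pairs with largest `|C_ij|`
   become edges of a binary undirected graph. The density grid is
   0.05-0.40 in steps of 0.01 (36 graphs per group), and edge sets are
   nested across the grid.
3. **Graph metrics** — clustering coefficient `Cp`, characteristic path
   length `Lp` (finite pairs, with the unreachable fraction reported),
   global and local efficiency, nodal degree / efficiency / betweenness,
   and the small-world indices `gamma = Cp/Cp_rand`, `lambda = Lp/Lp_rand`,
   `sigma = gamma/lambda`, normalized against degree-preserving
   double-edge-swap null networks (200 by default).
4. **Curve statistics** — each metric's curve over the grid is summarized by
   its average and its trapezoid area under the curve (AUC). Between-group
   AUC differences are tested with permutation tests (5000 by default) that
   re-run the whole pipeline (residualization included) on every
   relabeling; nodal families share one permutation stream across the 50
   nuclei and are corrected with Benjamini-Hochberg FDR at 0.05.
5. **Synthetic cohorts** — clinical cohorts of this kind cannot be shared,
   so `thalnet.simulate` generates tables with the assumed structure
   (block-correlated multivariate-Gaussian percent volumes at published
   healthy-control scales, group atrophy, covariate effects, eTIV
   conversion) and can plant a known network difference for power and
   calibration studies.

## Worked example

```python
import thalnet as tn

spec = tn.plant_network_difference(
    tn.SyntheticCohortSpec(seed=1), "F-MS", "strong")
cohort = tn.generate_cohort(spec)          # 25 F-MS / 25 NF-MS / 40 HC
cfg = tn.RunConfig(rng_seed=1, n_permutations=1000)

curve = tn.metric_curve(cohort, "F-MS", "Lp", cfg)
print(f"F-MS Lp: average {curve.average:.4f}, AUC {curve.auc:.4f}")

res = tn.permutation_group_difference(cohort, ("F-MS", "NF-MS"), "Lp", cfg)
print(f"Lp AUC {res.auc_a:.4f} vs {res.auc_b:.4f}, p = {res.p_value:.4f}")
```

prints

```
F-MS Lp: average 2.8478, AUC 0.9962
Lp AUC 0.9962 vs 0.7517, p = 0.0010
```

The planted group's characteristic path length is longer at every density
(its covariance was rewritten into a lattice-like ring decay), and the
permutation test on the AUC detects it at the resolution limit of 1000
permutations. The same run's nodal-efficiency family localizes the planted
low-connectivity nucleus (Right-MDm) after FDR correction in most
replicates.

The same pipeline runs from the shell:

```bash
thalnet simulate --preset strong --seed 1 --out cohort.csv
thalnet volumetry --cohort cohort.csv --out results/
thalnet permtest --cohort cohort.csv --groups F-MS,NF-MS \
    --metric Lp,nodal_efficiency --seed 1 --out results/
```

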