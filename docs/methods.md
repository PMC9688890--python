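# Methods

## The analysis model

`thalnet` analyses group-level *structural covariance networks* of the
thalamus. The objects of study are not individual connectomes: a network is
a property of a group. Its nodes are the 50 thalamic nuclei of the
FreeSurfer `segmentThalamicNuclei` parcellation (25 per hemisphere) and its
edges reflect how strongly two nuclei's volumes co-vary across the subjects
of that group. The underlying assumption is that regions which develop,
degenerate or are wired together covary in size; a disease process that
disconnects a nucleus shows up as a loss of covariance.

The pipeline, per group:

1. **Covariate removal.** Each nucleus volume is regressed (OLS, intercept
   included) on age, sex (0 = female, 1 = male) and lesion volume; the
   residuals replace the raw values. Covariates constant within a group —
   lesion volume in healthy controls — are dropped automatically and
   logged. Residualization is per group by default; a pooled variant is
   available (`RunConfig.pooled_residualization`).
2. **Association matrix.** The default mode (`residual_pearson`) is the
   product-moment correlation of each pair of residual columns, i.e. the
   correlation of the two nuclei with the regressed covariates partialled
   out. A `full_partial` mode computes pairwise partial correlations from a
   Ledoit-Wolf shrinkage precision matrix of the residuals, controlling all
   other 48 nuclei; with ~25 subjects per group this estimate only exists
   under regularization, which is why it is offered as a sensitivity
   analysis rather than the default.
3. **Density thresholding.** The matrix is binarized over a sparsity grid,
   0.05 to 0.40 in steps of 0.01 (36 values). At density `d` exactly
   `round(d x N(N-1)/2)` edges are kept — the pairs with the largest
   absolute correlation (negative covariance counts as association). Ties
   at the cutoff are broken by lexicographic node-pair order, so
   thresholding is deterministic, and rounding is half-away-from-zero
   (d = 0.05 on 50 nodes gives 61 edges, d = 0.40 gives 490). Ranking by
   density rather than by a fixed correlation cutoff guarantees every group
   the same edge count at each grid point, which the AUC comparison between
   groups requires; it also makes edge sets nested along the grid and
   invariant to any monotone transform of |C_ij|.

## Graph metrics

All graphs are binary, undirected, 50 nodes. Distances are hop counts from
breadth-first search.

* `Cp` — mean clustering coefficient: per node, 2 x triangles / k(k-1);
  degree < 2 contributes 0.
* `Lp` — characteristic path length: mean distance over *reachable*
  ordered pairs. At the sparse end of the grid (61 edges on 50 nodes) the
  graph is usually disconnected; averaging finite distances keeps `Lp`
  defined, and the unreachable-pair fraction is reported alongside so the
  convention is never silent. Efficiencies use 1/inf = 0 instead.
* `Eglob` — mean inverse distance over ordered pairs; `Eloc` — per node,
  the global efficiency of the subgraph induced by its neighbors.
* Nodal degree, nodal efficiency (mean inverse distance to all others), and
  betweenness centrality (Brandes, fractional credit across tied shortest
  paths, unnormalized, unordered-pair scale).
* `gamma`, `lambda`, `sigma` — `Cp` and `Lp` divided by their means over
  degree-preserving null networks (double-edge swaps rejecting self-loops
  and multi-edges; default 10 x edge-count successful swaps per null, 200
  nulls). `sigma = gamma/lambda > 1` indicates small-world organization.
  Nulls whose `Lp` is undefined are excluded from the mean and counted.

## Curve summaries and inference

Every metric is evaluated at all 36 densities; the curve is summarized by
its unweighted average and its composite-trapezoid AUC. Undefined points
(possible for `Lp`) are dropped from the AUC with a log message.

Between-group differences in AUC use two-sided nonparametric permutation
tests with the add-one rule, `p = (1 + #{|null| >= |obs|}) / (B + 1)`,
default `B = 5000`. The pooled subjects of the two groups are relabeled at
the original group sizes and the *entire* pipeline — residualization
onwards — is recomputed per relabeling, so group structure cannot leak
through the residuals. The relabeling stream is keyed on the sorted group
pair: swapping the group order replays the same permutations, negating the
observed difference and leaving p unchanged. For the 50-node nodal
families, all nodes share one set of relabelings (preserving inter-node
dependence) and raw p-values are adjusted with Benjamini-Hochberg FDR at
0.05. For `gamma`/`lambda`/`sigma` tests the per-permutation null-network
count is reduced (`n_null_networks_perm`, default 50) to bound cost; the
observed statistic always uses the full count.

Permutation tests are the pipeline's hot loop (B relabelings x 2 groups x
36 densities x 50-source BFS), so the distance/curve extraction and the
double-edge-swap loop run as numba kernels; the test suite pins them to
Floyd-Warshall and exhaustive-enumeration oracles on small graphs.

## Volumetry

Absolute volumes are normalized to percent of eTIV. Per nucleus, the three
groups are compared with one-way ANOVA; post hoc pairwise comparisons use
the pooled within-group variance t statistic (df = N - 3) with Bonferroni
x3, and the significance threshold defaults to 0.05/50 = 0.001. The exact
post hoc recipe behind published SPSS tables of this kind is typically
unstated; this definition is fixed here and not claimed to reproduce any
specific published p-value. Degenerate inputs with zero between-group
variance report F = 0, p = 1. Clinical correlations default to Spearman
(rank transform, then product-moment), with Pearson by flag; lesion volume
and disease duration are evaluated in patients only.

## Synthetic cohorts

The generator emulates the cohort the analysis is designed for, with
defaults fixed once:

* group sizes 25 (F-MS) / 25 (NF-MS) / 40 (HC);
* percent-scale nucleus volumes drawn from a multivariate Gaussian whose
  marginal means and SDs are published healthy-control volumetry values for
  the 50 nuclei; volumes are converted to absolute mL through group-specific
  Gaussian eTIV draws (HC 1396 +/- 282 mL; patients ~1330 +/- 260 mL), so
  eTIV normalization is exercised nontrivially;
* correlation structure: within-block r = 0.45, between-block r = 0.12 over
  the six anatomical nucleus groups (anterior, lateral, ventral,
  intralaminar, medial, posterior) spanning both hemispheres. The block
  model is a plausible test harness, not a biological claim; typical
  structural-covariance correlations motivate the values;
* atrophy: fractional mean deficits in the nuclei reported atrophied in
  each patient group (e.g. ~37% in the right laterodorsal nucleus), taken
  from the published group-mean ratios;
* covariates: age uniform on 18-45 years, ~65% female, lesion volume
  Gamma(4, 1.6) mL (mean ~6.4) in patients, disease duration Gamma(2, 1.2)
  years; linear effects per region of -0.2% of the regional mean per year
  of age, -3% for male sex, -1% per mL lesion volume. These give the
  residualization step real work without dominating the covariance.

A per-group correlation rewrite (`plant_network_difference`) supplies
known-positive cohorts. Weakening within-block correlations alone would
drive the thresholded graphs toward random graphs, which *shortens* path
length under the finite-pair convention, so the planted "disintegrated"
group instead uses a ring-distance correlation decay `r^d` over a fixed
ring of the 50 nuclei: its thresholded graphs are lattice-like, connected
but with systematically long `Lp` at every density. The designated nucleus
(Right-MDm) has its correlations attenuated *and* its idiosyncratic SD
inflated by the inverse factor; the inflation matters because the shared
eTIV draw induces a baseline correlation (~0.5) between all absolute-volume
pairs that correlation attenuation on the percent scale cannot remove.
Preset constants — moderate (decay 0.80, attenuation 0.40), strong (0.90,
0.10) — were fixed by a one-time calibration run (20 replicate cohorts per
candidate at B = 1000): under "strong" the planted group's Lp AUC exceeded
the control group's in 20/20 replicates, the designated node's efficiency
AUC was lower in 20/20, and the node survived FDR in 15/20.

## What the tests do and do not show

The synthetic generator reproduces the *statistical skeleton* the method
assumes: Gaussian block covariance, linear covariate effects, multiplicative
eTIV scaling, group mean shifts. It does not model segmentation error,
spatially structured atrophy, non-Gaussian volume distributions,
hemispheric asymmetry of covariance, or lesion-volume/atrophy coupling.
Passing calibration and recovery tests therefore demonstrates that the
implementation is correct and the inference valid under its assumptions —
not that the method is robust to real MRI artifacts.

Problem sizes used by the test suite were chosen to make the Monte-Carlo
bands tight while keeping the suite practical: 500 replicate cohorts at
B = 200 for the type-I calibration of the Lp-AUC test (99% binomial band
around 0.05), 100 replicates at B = 1000 for planted-effect recovery
(B = 1000 is the smallest round count whose add-one p resolution, 1/1001,
can pass the rank-one BH threshold 0.05/50 = 0.001), and 10,000 independent
null regions for the volumetry flag rate at 0.001.

## Numerical and design choices

* Seeds: one root seed spawns named per-stage streams
  (`thalnet.rng.stage_rng`), so stage order cannot change results; null
  networks get per-(group, density) streams, permutations a per-pair
  stream.
* Residual degeneracy: a zero-variance residual column raises an error
  naming the region rather than propagating NaNs.
* `n_null_networks` must only be >= 1, but the default (200) follows the
  ">150 nulls" convention for stable `gamma`/`lambda` means.
* Correlations are clipped to [-1, 1] and symmetrized against floating-point
  asymmetry before ranking; the diagonal is defined as 0.
* Edge-count rounding, tie-breaking and the disconnected-`Lp` convention
  are fixed and documented above; all three are otherwise arbitrary and
  published analyses rarely state them.

## Known limitations

* Networks are group-level; no subject-level network or metric exists, so
  brain-behavior correlations of network metrics are out of scope.
* Binary undirected graphs only — no weighted, directed, rich-club or
  modularity analyses.
* The `full_partial` mode's shrinkage intensity is data-driven
  (Ledoit-Wolf); its null distribution under permutation is valid but its
  interpretation differs from the default mode.
* ANOVA assumes homoscedastic, approximately normal percent volumes;
  strongly skewed regions would need rank-based alternatives.
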