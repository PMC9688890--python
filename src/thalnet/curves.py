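"""Metric curves over the sparsity grid, AUC summaries and group tests.

Each global or nodal metric is evaluated at every density of the grid and
summarized by its average value and its trapezoid-rule area under the curve
(AUC), a threshold-free scalar.  Between-group differences in AUC are tested
with nonparametric permutation tests: subjects of the two groups are pooled
and randomly reassigned to two groups of the original sizes, and the *whole*
pipeline (covariate residualization, correlation matrix, thresholding,
metrics) is re-run on each relabeling, so no group structure leaks through
the residuals.  Nodal families share one permutation stream across the 50
nodes (preserving inter-node dependence) and are corrected with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._kernels import grid_curves as _grid_curves_kernel
from .config import RunConfig
from .io import CohortTable
from .labels import NUCLEUS_COLUMNS
from .metrics import (
    betweenness_centrality,
    local_efficiency,
    normalized_small_world,
)
from .network import (
    BinaryAdjacency,
    binarize_at_density,
    build_correlation_matrix,
    density_grid,
    design_matrix,
    edge_count_at_density,
    ranked_pairs,
    residualize,
)
from .rng import stage_rng

log = logging.getLogger(__name__)

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma")
NODAL_METRICS = ("degree", "nodal_efficiency", "betweenness")

#: metrics the compiled grid kernel provides directly
_KERNEL_GLOBAL = {"Cp": 3, "Lp": 0, "Eglob": 2}
_KERNEL_NODAL = {"degree": 4, "nodal_efficiency": 5}


@dataclass
class MetricCurve:
    """One metric's values over the density grid plus its summaries.

    For nodal metrics ``values`` has shape (G, 50) and ``average``/``auc``
    are per-node vectors.
    """

    metric: str
    group: str
    densities: np.ndarray
    values: np.ndarray
    average: float | np.ndarray = field(init=False)
    auc: float | np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.densities.shape[0]:
            raise ValueError("values and densities lengths differ")
        self.average = np.nanmean(self.values, axis=0)
        self.auc = auc(self.densities, self.values)
        if self.values.ndim == 1:
            self.average = float(self.average)
            self.auc = float(self.auc)

    def to_frame(self) -> pd.DataFrame:
        if self.values.ndim == 1:
            return pd.DataFrame({"density": self.densities,
                                 self.metric: self.values})
        df = pd.DataFrame(self.values, columns=list(NUCLEUS_COLUMNS))
        df.insert(0, "density", self.densities)
        return df


def auc(densities, values) -> float | np.ndarray:
    """Composite trapezoid-rule area under a metric curve.

    Grid points whose value is undefined (NaN, e.g. Lp on a graph with no
    reachable pair) are excluded with a log message.  Requires at least two
    usable points.
    """
    d = np.asarray(densities, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        keep = np.isfinite(v)
        if keep.sum() < 2:
            raise ValueError("fewer than 2 usable curve points")
        if not keep.all():
            log.info("AUC: excluding %d undefined grid points", (~keep).sum())
        return float(np.trapezoid(v[keep], d[keep]))
    if np.isfinite(v).all():
        return np.trapezoid(v, d, axis=0)
    return np.array([auc(d, v[:, j]) for j in range(v.shape[1])])


# -- single-group curves -----------------------------------------------------


def _slow_curve_values(net, grid, metric: str, config: RunConfig,
                       group: str) -> np.ndarray:
    """Per-density values for metrics outside the compiled kernel."""
    vals = []
    for d in grid:
        A = binarize_at_density(net, d)
        if metric == "Eloc":
            vals.append(local_efficiency(A)[1])
        elif metric in ("gamma", "lambda", "sigma"):
            rng = stage_rng(config.rng_seed, "null-networks", group, round(d, 6))
            sw = normalized_small_world(A, n_null=config.n_null_networks, rng=rng)
            vals.append({"gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma}[metric])
        elif metric == "betweenness":
            vals.append(betweenness_centrality(A))
        else:  # pragma: no cover - guarded by callers
            raise ValueError(f"unknown slow metric {metric!r}")
    return np.asarray(vals)


def metric_curve(cohort: CohortTable, group: str, metric: str,
                 config: RunConfig | None = None) -> MetricCurve:
    """Residualize -> correlate -> binarize -> metric, at every grid density."""
    config = config if config is not None else RunConfig()
    if metric not in GLOBAL_METRICS + NODAL_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    res = residualize(cohort, group, covariates=config.covariates,
                      pooled=config.pooled_residualization)
    net = build_correlation_matrix(res, mode=config.correlation_mode)
    grid = density_grid(config)
    n = net.matrix.shape[0]
    if metric in _KERNEL_GLOBAL or metric in _KERNEL_NODAL:
        ei, ej = ranked_pairs(net.matrix)
        ks = np.array([edge_count_at_density(d, n) for d in grid], dtype=np.int64)
        out = _grid_curves_kernel(ei, ej, ks, n, metric == "Cp")
        idx = _KERNEL_GLOBAL.get(metric, _KERNEL_NODAL.get(metric))
        values = out[idx]
    else:
        values = _slow_curve_values(net, grid, metric, config, group)
    return MetricCurve(metric=metric, group=group, densities=grid, values=values)


# -- permutation engine ------------------------------------------------------


class _CurveEngine:
    """Recomputes both groups' curves for arbitrary subject reassignments.

    Used by the permutation tests: holds the pooled volumes and covariates of
    the two groups and replays residualization, correlation, rank
    thresholding and the grid metrics for any index split, via the compiled
    kernel for the distance-based metrics.
    """

    def __init__(self, cohort: CohortTable, groups: tuple[str, str],
                 config: RunConfig):
        self.config = config
        self.groups = groups
        sub = cohort.subset(groups)
        self.volumes = sub.volumes()
        self.covariates = (sub.covariate_matrix(config.covariates)
                           if config.covariates else None)
        self.grid = density_grid(config)
        self.n_nodes = self.volumes.shape[1]
        self._iu, self._ju = np.triu_indices(self.n_nodes, 1)
        self.edge_counts = np.array(
            [edge_count_at_density(d, self.n_nodes) for d in self.grid],
            dtype=np.int64)
        if self.edge_counts[0] == 0:
            raise ValueError("smallest density yields an empty graph")
        group_col = sub.data["group"].to_numpy()
        self.idx_a = np.flatnonzero(group_col == groups[0])
        self.idx_b = np.flatnonzero(group_col == groups[1])
        self.n_a, self.n_b = len(self.idx_a), len(self.idx_b)
        min_needed = max(4, len(config.covariates) + 2)
        if self.n_a < min_needed or self.n_b < min_needed:
            raise ValueError(
                f"groups {groups} need >= {min_needed} subjects each")

    def _residuals(self, idx: np.ndarray) -> np.ndarray:
        V = self.volumes[idx]
        if self.covariates is None:
            return V - V.mean(axis=0)
        X, _, _ = design_matrix(self.covariates[idx], self.config.covariates)
        beta = np.linalg.solve(X.T @ X, X.T @ V)
        return V - X @ beta

    def side_curves(self, idx: np.ndarray, global_metrics, nodal_metrics,
                    n_null: int, rng_key=None) -> dict[str, np.ndarray]:
        """Curves (per grid density) of one reassigned group."""
        R = self._residuals(idx)
        sds = R.std(axis=0)
        if np.any(sds == 0):
            raise ValueError("zero residual variance during permutation")
        C = np.corrcoef(R, rowvar=False)
        iu, ju = self._iu, self._ju
        order = np.argsort(-np.abs(C[iu, ju]), kind="stable")
        ei = iu[order].astype(np.int32)
        ej = ju[order].astype(np.int32)
        want_cp = any(m in ("Cp", "gamma", "sigma") for m in global_metrics)
        out = _grid_curves_kernel(ei, ej, self.edge_counts, self.n_nodes, want_cp)
        curves: dict[str, np.ndarray] = {}
        for m in global_metrics:
            if m in _KERNEL_GLOBAL:
                curves[m] = out[_KERNEL_GLOBAL[m]]
        for m in nodal_metrics:
            if m in _KERNEL_NODAL:
                curves[m] = out[_KERNEL_NODAL[m]]
        slow_globals = [m for m in global_metrics if m not in _KERNEL_GLOBAL]
        slow_nodals = [m for m in nodal_metrics if m not in _KERNEL_NODAL]
        if slow_globals or slow_nodals:
            curves.update(self._slow_side_curves(
                C, slow_globals, slow_nodals, out, n_null, rng_key))
        return curves

    def _slow_side_curves(self, C, slow_globals, slow_nodals, kernel_out,
                          n_null, rng_key) -> dict[str, np.ndarray]:
        from .network import GroupNetwork

        net = GroupNetwork(group="<permuted>", labels=NUCLEUS_COLUMNS, matrix=C)
        curves: dict[str, np.ndarray] = {}
        need_sw = [m for m in slow_globals if m in ("gamma", "lambda", "sigma")]
        if "Eloc" in slow_globals:
            curves["Eloc"] = np.array(
                [local_efficiency(binarize_at_density(net, d))[1]
                 for d in self.grid])
        if "betweenness" in slow_nodals:
            curves["betweenness"] = np.array(
                [betweenness_centrality(binarize_at_density(net, d))
                 for d in self.grid])
        if need_sw:
            gam = np.empty(len(self.grid))
            lam = np.empty(len(self.grid))
            for gi, d in enumerate(self.grid):
                rng = stage_rng(self.config.rng_seed, "perm-null", rng_key,
                                round(float(d), 6))
                sw = normalized_small_world(
                    binarize_at_density(net, d), n_null=n_null, rng=rng)
                gam[gi], lam[gi] = sw.gamma, sw.lam
            if "gamma" in need_sw:
                curves["gamma"] = gam
            if "lambda" in need_sw:
                curves["lambda"] = lam
            if "sigma" in need_sw:
                curves["sigma"] = gam / lam
        return curves

    def auc_difference(self, idx_a, idx_b, global_metrics, nodal_metrics,
                       n_null, rng_key=None) -> dict[str, float | np.ndarray]:
        ca = self.side_curves(idx_a, global_metrics, nodal_metrics, n_null,
                              ("A", rng_key))
        cb = self.side_curves(idx_b, global_metrics, nodal_metrics, n_null,
                              ("B", rng_key))
        return {m: (auc(self.grid, ca[m]), auc(self.grid, cb[m]))
                for m in ca}


@dataclass
class PermutationResult:
    """Observed AUC difference (A - B), permutation null summary and p."""

    metric: str
    groups: tuple[str, str]
    auc_a: float
    auc_b: float
    observed: float
    n_permutations: int
    p_value: float
    null_mean: float
    null_sd: float
    average_a: float | None = None
    average_b: float | None = None


def _pvalue(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (len(null) + 1))


def permutation_tests(cohort: CohortTable, groups: tuple[str, str],
                      config: RunConfig | None = None,
                      global_metrics=(), nodal_metrics=(),
                      rng: np.random.Generator | None = None) -> dict:
    """Between-group AUC permutation tests, global and nodal, sharing one
    set of relabelings.

    Returns ``{"global": {metric: PermutationResult},
    "nodal": {metric: DataFrame}}``; nodal frames carry per-node raw p,
    BH-FDR adjusted p, and flags at ``config.fdr_alpha``.
    """
    config = config if config is not None else RunConfig()
    global_metrics = tuple(global_metrics)
    nodal_metrics = tuple(nodal_metrics)
    for m in global_metrics:
        if m not in GLOBAL_METRICS:
            raise ValueError(f"unknown global metric {m!r}")
    for m in nodal_metrics:
        if m not in NODAL_METRICS:
            raise ValueError(f"unknown nodal metric {m!r}")
    if not global_metrics and not nodal_metrics:
        raise ValueError("no metrics requested")
    engine = _CurveEngine(cohort, groups, config)
    if rng is None:
        # sorted key: swapping group order replays the same relabelings
        rng = stage_rng(config.rng_seed, "permtest", *sorted(groups))

    obs = engine.auc_difference(engine.idx_a, engine.idx_b,
                                global_metrics, nodal_metrics,
                                config.n_null_networks, "observed")
    B = config.n_permutations
    pooled = np.arange(engine.n_a + engine.n_b)
    null: dict[str, list] = {m: [] for m in obs}
    for b in range(B):
        perm = rng.permutation(pooled)
        diffs = engine.auc_difference(perm[:engine.n_a], perm[engine.n_a:],
                                      global_metrics, nodal_metrics,
                                      config.n_null_networks_perm, b)
        for m, (a_auc, b_auc) in diffs.items():
            null[m].append(np.asarray(a_auc) - np.asarray(b_auc))

    results: dict = {"global": {}, "nodal": {}}
    for m in global_metrics:
        a_auc, b_auc = obs[m]
        nd = np.asarray(null[m], dtype=float)
        observed = float(a_auc - b_auc)
        results["global"][m] = PermutationResult(
            metric=m, groups=groups, auc_a=float(a_auc), auc_b=float(b_auc),
            observed=observed, n_permutations=B,
            p_value=_pvalue(nd, observed),
            null_mean=float(nd.mean()), null_sd=float(nd.std(ddof=1)) if B > 1 else 0.0,
        )
    for m in nodal_metrics:
        a_auc, b_auc = obs[m]
        observed = np.asarray(a_auc) - np.asarray(b_auc)
        nd = np.asarray(null[m], dtype=float)  # (B, 50)
        raw = (1 + (np.abs(nd) >= np.abs(observed)[None, :]).sum(axis=0)) / (B + 1)
        adjusted = bh_fdr(raw)
        results["nodal"][m] = pd.DataFrame({
            "region": list(NUCLEUS_COLUMNS),
            "auc_a": np.asarray(a_auc),
            "auc_b": np.asarray(b_auc),
            "observed": observed,
            "p_raw": raw,
            "p_fdr": adjusted,
            "flag": adjusted < config.fdr_alpha,
        })
    return results


def permutation_group_difference(cohort: CohortTable, groups: tuple[str, str],
                                 metric: str,
                                 config: RunConfig | None = None,
                                 rng: np.random.Generator | None = None
                                 ) -> PermutationResult:
    """Two-sided permutation test on one global metric's AUC difference."""
    config = config if config is not None else RunConfig()
    res = permutation_tests(cohort, groups, config,
                            global_metrics=(metric,), rng=rng)
    out = res["global"][metric]
    curve_a = metric_curve(cohort.subset(groups), groups[0], metric, config)
    curve_b = metric_curve(cohort.subset(groups), groups[1], metric, config)
    out.average_a = curve_a.average
    out.average_b = curve_b.average
    return out


def nodal_family_test(cohort: CohortTable, groups: tuple[str, str],
                      metric: str, config: RunConfig | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-node AUC permutation tests with BH-FDR across the 50 nuclei."""
    config = config if config is not None else RunConfig()
    res = permutation_tests(cohort, groups, config,
                            nodal_metrics=(metric,), rng=rng)
    return res["nodal"][metric]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
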