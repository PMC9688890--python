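"""Group structural covariance network construction.

For each group, every nucleus volume is regressed on the retained covariates
(age, sex, lesion load by default) and the residuals replace the raw values.
The group's 50 x 50 inter-regional correlation matrix C_ij is then computed
across subjects and binarized over a sparsity (connection density) grid:
at density d the round(d * N(N-1)/2) node pairs with the largest |C_ij|
become edges of an unweighted, undirected graph.

Rank/density thresholding (rather than a fixed correlation cutoff) guarantees
every group the same edge count at a given grid point, which the AUC
comparison between groups requires.  Edge sets are therefore nested across
the grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .io import CohortTable
from .labels import NUCLEUS_COLUMNS

log = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """A region has zero residual variance, so its correlations are undefined."""


@dataclass
class ResidualTable:
    """Covariate-residualized volumes of one group (subjects x 50)."""

    group: str
    labels: tuple[str, ...]
    residuals: np.ndarray
    covariates_used: tuple[str, ...]
    covariates_dropped: tuple[str, ...]


@dataclass
class GroupNetwork:
    """Symmetric inter-regional correlation matrix of one group; diagonal 0."""

    group: str
    labels: tuple[str, ...]
    matrix: np.ndarray


@dataclass
class BinaryAdjacency:
    """0/1 adjacency at one density of the sparsity grid."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    density: float

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


def design_matrix(covariate_values: np.ndarray, names) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + covariates, dropping columns constant within the sample."""
    names = list(names)
    kept, dropped, cols = [], [], [np.ones(covariate_values.shape[0])]
    for j, name in enumerate(names):
        col = covariate_values[:, j]
        if np.ptp(col) == 0.0:
            dropped.append(name)
        else:
            kept.append(name)
            cols.append(col)
    return np.column_stack(cols), kept, dropped


def residualize(table: CohortTable, group: str,
                covariates=("age", "sex", "lesion_volume"),
                pooled: bool = False) -> ResidualTable:
    """OLS-residualize each nucleus volume on the covariates.

    Regression is run within the group by default (the residuals feed a
    per-group network); ``pooled=True`` fits on all subjects and returns
    the group's rows of the pooled residuals.  Covariates constant within the fitting
    sample (e.g. lesion volume in controls) are dropped and logged.
    """
    covariates = tuple(covariates)
    fit_table = table if pooled else table.subset([group])
    idx = fit_table.group_indices(group)
    n_fit = len(fit_table)
    if n_fit < len(covariates) + 2:
        raise ValueError(
            f"group {group!r} needs >= {len(covariates) + 2} subjects, has {n_fit}"
        )
    V = fit_table.volumes()
    if covariates:
        C = fit_table.covariate_matrix(covariates)
        X, kept, dropped = design_matrix(C, covariates)
        if dropped:
            log.info("group %s: dropped constant covariates %s", group, dropped)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient design for group {group!r}: collinear "
                f"covariates among {kept}"
            )
    else:
        X, kept, dropped = np.ones((n_fit, 1)), [], []
    beta = np.linalg.solve(X.T @ X, X.T @ V)
    resid = V - X @ beta
    resid = resid[idx] if pooled else resid
    return ResidualTable(
        group=group,
        labels=NUCLEUS_COLUMNS,
        residuals=resid,
        covariates_used=tuple(kept),
        covariates_dropped=tuple(dropped),
    )


def build_correlation_matrix(res: ResidualTable,
                             mode: str = "residual_pearson") -> GroupNetwork:
    """Inter-regional correlation matrix of the residualized volumes.

    ``residual_pearson`` (default): product-moment correlation of each pair
    of residual columns - correlation with the regressed covariates
    partialled out.  ``full_partial``: pairwise partial correlations from a
    Ledoit-Wolf shrinkage-regularized precision matrix of the residuals (a
    sensitivity mode; with ~25 subjects and 50 regions an unregularized
    inverse does not exist).  The diagonal is defined as 0.
    """
    R = res.residuals
    if R.shape[0] < 4:
        raise ValueError("need >= 4 subjects to estimate correlations")
    sds = R.std(axis=0)
    if np.any(sds == 0):
        bad = res.labels[int(np.argmax(sds == 0))]
        raise UndefinedCorrelationError(f"zero residual variance in {bad!r}")
    if mode == "residual_pearson":
        C = np.corrcoef(R, rowvar=False)
    elif mode == "full_partial":
        from sklearn.covariance import LedoitWolf

        precision = LedoitWolf().fit(R).get_precision()
        d = np.sqrt(np.diag(precision))
        C = -precision / np.outer(d, d)
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 0.0)
    return GroupNetwork(group=res.group, labels=res.labels, matrix=C)


def density_grid(config: RunConfig | None = None, *,
                 sparsity_min: float | None = None,
                 sparsity_max: float | None = None,
                 sparsity_step: float | None = None) -> np.ndarray:
    """Arithmetic density grid, inclusive of both endpoints.

    If the step does not divide the range exactly the grid is truncated
    below the maximum (logged).  The default 0.05-0.40 by 0.01 grid has 36
    values.
    """
    if config is not None:
        lo, hi, step = config.sparsity_min, config.sparsity_max, config.sparsity_step
    else:
        lo, hi, step = sparsity_min, sparsity_max, sparsity_step
    n_steps = int(math.floor((hi - lo) / step + 1e-9))
    grid = lo + step * np.arange(n_steps + 1)
    grid = np.round(grid, 12)
    if grid[-1] < hi - 1e-9:
        log.info("sparsity_step does not divide the range; grid truncated at %g",
                 grid[-1])
    return grid


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def edge_count_at_density(d: float, n_nodes: int) -> int:
    """round(d * N(N-1)/2), round-half-away-from-zero."""
    return _round_half_away(d * n_nodes * (n_nodes - 1) / 2.0)


def ranked_pairs(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle node pairs ordered by descending |C_ij|.

    Ties are broken by the fixed lexicographic (i, j) pair order via a
    stable sort, making binarization fully deterministic.
    """
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, 1)
    order = np.argsort(-np.abs(matrix[iu, ju]), kind="stable")
    return iu[order].astype(np.int32), ju[order].astype(np.int32)


def binarize_at_density(net: GroupNetwork, d: float) -> BinaryAdjacency:
    """Keep the top-|C_ij| node pairs so exactly round(d*N(N-1)/2) edges remain."""
    if not (0.0 < d < 1.0):
        raise ValueError(f"density must lie in (0, 1), got {d}")
    n = net.matrix.shape[0]
    k = edge_count_at_density(d, n)
    if k == 0:
        raise ValueError(f"density {d} yields an empty graph on {n} nodes")
    ei, ej = ranked_pairs(net.matrix)
    A = np.zeros((n, n), dtype=bool)
    A[ei[:k], ej[:k]] = True
    A |= A.T
    return BinaryAdjacency(labels=net.labels, matrix=A, density=d)
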