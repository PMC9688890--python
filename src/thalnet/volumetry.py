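"""Volume normalization and group volumetry statistics.

Absolute nucleus volumes are expressed as a percentage of estimated total
intracranial volume:

    structural volume (%) = absolute volume / eTIV * 100

Group differences per nucleus use a one-way ANOVA across the three groups
with Bonferroni-adjusted pooled-variance pairwise comparisons; with 50 nuclei
the significance threshold defaults to 0.05/50 = 0.001.  Clinical
correlations (lesion volume, disease duration, age) use Spearman rank
correlation by default, Pearson by flag; lesion volume and disease duration
are evaluated in the patients only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GROUPS
from .io import CohortTable
from .labels import NUCLEUS_COLUMNS, NucleusLabel

PAIRS = (("F-MS", "HC"), ("NF-MS", "HC"), ("F-MS", "NF-MS"))

PATIENT_GROUPS = ("F-MS", "NF-MS")

#: clinical variables restricted to patients (absent / zero in controls)
_PATIENT_ONLY_VARIABLES = ("lesion_volume", "disease_duration")


class UndefinedCorrelationError(ValueError):
    """Raised when either vector of a correlation has zero variance."""


def normalize_volumes(table: CohortTable) -> CohortTable:
    """Convert absolute nucleus volumes to percent of eTIV.

    Covariates are untouched; only the 50 nucleus columns are transformed.
    """
    if table.scale == "percent":
        raise ValueError("table is already on the percent scale")
    df = table.data.copy()
    etiv = df["eTIV"].to_numpy(dtype=float)
    for col in NUCLEUS_COLUMNS:
        df[col] = df[col].to_numpy(dtype=float) / etiv * 100.0
    return CohortTable(df, scale="percent")


@dataclass
class VolumetryStats:
    """One nucleus' group volumetry summary (the per-row layout of a
    three-group volume table)."""

    region: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    f_statistic: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]
    alpha: float
    significant: dict[tuple[str, str], bool] = field(init=False)
    anova_significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = {k: p < self.alpha for k, p in self.pairwise_p.items()}
        self.anova_significant = self.anova_p < self.alpha


def _region_column(region) -> str:
    if isinstance(region, NucleusLabel):
        return str(region)
    label = NucleusLabel.parse(str(region))
    return str(label)


def anova_posthoc(norm: CohortTable, region, alpha: float = 0.001) -> VolumetryStats:
    """One-way ANOVA across the three groups with Bonferroni post hoc tests.

    Pairwise p-values use the pooled within-group variance (mean square
    within, df = N - 3) two-sample t statistic, multiplied by the number of
    pairwise comparisons and capped at 1.  Degenerate inputs with no
    between-group variance report F = 0, p = 1.
    """
    col = _region_column(region)
    df = norm.data
    present = [g for g in GROUPS if (df["group"] == g).any()]
    if len(present) < 3:
        raise ValueError(f"need all three groups, found {present}")
    samples = {g: df.loc[df["group"] == g, col].to_numpy(dtype=float)
               for g in present}
    for g, x in samples.items():
        if len(x) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")

    all_vals = np.concatenate(list(samples.values()))
    n_total = all_vals.size
    k = len(samples)
    grand = all_vals.mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in samples.values())
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in samples.values())
    df_b, df_w = k - 1, n_total - k
    scale = max((all_vals ** 2).sum(), 1.0)
    if ss_between <= 1e-14 * scale:
        f_stat, p_anova = 0.0, 1.0
    elif ss_within <= 1e-14 * scale:
        f_stat, p_anova = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p_anova = float(stats.f.sf(f_stat, df_b, df_w))

    msw = ss_within / df_w
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in PAIRS:
        xa, xb = samples[a], samples[b]
        diff = xa.mean() - xb.mean()
        se = np.sqrt(msw * (1 / len(xa) + 1 / len(xb)))
        if se == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / se
            p = min(1.0, len(PAIRS) * 2.0 * float(stats.t.sf(abs(t), df_w)))
        pairwise[(a, b)] = p

    return VolumetryStats(
        region=col,
        group_means={g: float(x.mean()) for g, x in samples.items()},
        group_sds={g: float(x.std(ddof=1)) for g, x in samples.items()},
        f_statistic=float(f_stat),
        anova_p=float(p_anova),
        pairwise_p=pairwise,
        alpha=alpha,
    )


def volumetry_table(norm: CohortTable, alpha: float = 0.001) -> pd.DataFrame:
    """Per-nucleus volumetry statistics for all 50 regions (group means,
    SDs, ANOVA F/p, pairwise Bonferroni p-values, significance flags)."""
    rows = []
    for col in NUCLEUS_COLUMNS:
        s = anova_posthoc(norm, col, alpha=alpha)
        row = {"region": col, "F": s.f_statistic, "anova_p": s.anova_p}
        for g in GROUPS:
            row[f"mean_{g}"] = s.group_means[g]
            row[f"sd_{g}"] = s.group_sds[g]
        for (a, b), p in s.pairwise_p.items():
            row[f"p_{a}_vs_{b}"] = p
            row[f"sig_{a}_vs_{b}"] = s.significant[(a, b)]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClinicalCorrelation:
    region: str
    variable: str
    method: str
    rho: float
    p: float
    n: int


def correlate_clinical(norm: CohortTable, region, variable: str,
                       method: str = "spearman") -> ClinicalCorrelation:
    """Correlate one nucleus' percent volume with a clinical variable.

    ``lesion_volume`` and ``disease_duration`` are evaluated on patients
    (F-MS and NF-MS) only; ``age`` on all subjects.  Spearman is the default
    (rank transform then product-moment); Pearson available by flag.
    """
    col = _region_column(region)
    df = norm.data
    if variable in _PATIENT_ONLY_VARIABLES:
        df = df[df["group"].isin(PATIENT_GROUPS)]
    x = df[col].to_numpy(dtype=float)
    y = df[variable].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"too few paired observations for {variable!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {col!r} or {variable!r}"
        )
    method = method.lower()
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return ClinicalCorrelation(region=col, variable=variable, method=method,
                               rho=float(rho), p=float(p), n=int(len(x)))
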