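"""Synthetic cohort generator.

The clinical cohort behind this kind of analysis (fatigued and non-fatigued
relapsing-remitting MS patients plus healthy controls, with FreeSurfer
thalamic-nucleus volumes) is not publicly shareable, so this module generates
cohorts with the statistical structure the pipeline assumes:

* three groups (default n = 25 / 25 / 40);
* nucleus volumes drawn on the percent-of-eTIV scale from a multivariate
  Gaussian whose marginal means/SDs are the healthy-control volumetry of the
  reference cohort, with a block correlation structure over the six
  anatomical nucleus groups (anterior, lateral, ventral, intralaminar,
  medial, posterior) spanning both hemispheres;
* group atrophy as fractional mean reductions in the nuclei reported
  atrophied in each patient group;
* linear covariate effects of age, sex and lesion load, plus group-specific
  eTIV distributions that convert percent volumes back to absolute mL.

The block model is a test harness, not a biological claim about the true
covariance of thalamic nuclei.  :func:`plant_network_difference` additionally
rewrites one group's correlation structure into a ring-distance decay
(lattice-like covariance), the canonical construction whose thresholded
graphs have long characteristic path length, and decouples one designated
nucleus so its nodal efficiency drops - giving a known-positive cohort for
effect-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable
from .labels import ALL_LABELS, NUCLEUS_COLUMNS
from .rng import stage_rng

#: Healthy-control percent-of-eTIV volumetry (mean, SD) per nucleus, from the
#: reference cohort's control group; the generator's base scale.
HC_VOLUMETRY = {
    "Left-AV": (0.0103, 0.0019), "Right-AV": (0.0101, 0.0020),
    "Left-LD": (0.0020, 0.0008), "Right-LD": (0.0019, 0.0006),
    "Left-LP": (0.0097, 0.0017), "Right-LP": (0.0093, 0.0018),
    "Left-VA": (0.0330, 0.0050), "Right-VA": (0.0323, 0.0052),
    "Left-VAmc": (0.0026, 0.0004), "Right-VAmc": (0.0026, 0.0004),
    "Left-VLa": (0.0512, 0.0075), "Right-VLa": (0.0484, 0.0073),
    "Left-VLp": (0.0681, 0.0102), "Right-VLp": (0.0631, 0.0095),
    "Left-VPL": (0.0815, 0.0144), "Right-VPL": (0.0698, 0.0119),
    "Left-VM": (0.0022, 0.0004), "Right-VM": (0.0020, 0.0004),
    "Left-CeM": (0.0054, 0.0010), "Right-CeM": (0.0053, 0.0010),
    "Left-CL": (0.0028, 0.0006), "Right-CL": (0.0026, 0.0006),
    "Left-Pc": (0.0003, 0.0001), "Right-Pc": (0.0004, 0.0001),
    "Left-CM": (0.0208, 0.0037), "Right-CM": (0.0192, 0.0032),
    "Left-Pf": (0.0048, 0.0009), "Right-Pf": (0.0047, 0.0008),
    "Left-Pt": (0.0006, 0.0001), "Right-Pt": (0.0005, 0.0001),
    "Left-MV": (0.0011, 0.0002), "Right-MV": (0.0010, 0.0003),
    "Left-MDm": (0.0639, 0.0133), "Right-MDm": (0.0616, 0.0111),
    "Left-MDl": (0.0216, 0.0050), "Right-MDl": (0.0211, 0.0044),
    "Left-LGN": (0.0238, 0.0043), "Right-LGN": (0.0199, 0.0034),
    "Left-MGN": (0.0093, 0.0024), "Right-MGN": (0.0093, 0.0021),
    "Left-L-Sg": (0.0018, 0.0006), "Right-L-Sg": (0.0016, 0.0005),
    "Left-PuA": (0.0191, 0.0037), "Right-PuA": (0.0169, 0.0029),
    "Left-PuM": (0.0951, 0.0162), "Right-PuM": (0.0875, 0.0146),
    "Left-PuL": (0.0154, 0.0029), "Right-PuL": (0.0132, 0.0024),
    "Left-PuI": (0.0222, 0.0040), "Right-PuI": (0.0191, 0.0038),
}

#: Fractional mean reduction (vs the control mean) of the nuclei reported
#: atrophied in each patient group of the reference cohort.
DEFAULT_ATROPHY = {
    "F-MS": {
        "Right-AV": 0.198, "Left-LD": 0.300, "Right-LD": 0.368,
        "Right-CL": 0.192, "Right-LGN": 0.211, "Right-PuA": 0.160,
        "Left-PuM": 0.167, "Right-PuM": 0.202, "Left-PuI": 0.185,
        "Right-PuI": 0.236,
    },
    "NF-MS": {
        "Left-LD": 0.350, "Right-LD": 0.421,
        "Right-PuM": 0.185, "Right-PuI": 0.199,
    },
    "HC": {},
}

#: Group eTIV distributions (mean, SD) in mL, from the reference cohort.
DEFAULT_ETIV = {
    "F-MS": (1336.74, 256.13),
    "NF-MS": (1328.01, 278.80),
    "HC": (1396.01, 282.20),
}

#: Planted-network presets: (ring correlation decay, designated-node
#: attenuation).  Fixed once by the calibration run recorded in the repo.
NETWORK_PRESETS = {
    "none": None,
    "moderate": (0.80, 0.40),
    "strong": (0.90, 0.10),
}

DEFAULT_DESIGNATED_NODE = "Right-MDm"


@dataclass(frozen=True)
class RingStructure:
    """Ring-distance correlation decay planted into one group.

    The designated node's correlations are multiplied by
    ``node_attenuation`` and its idiosyncratic SD by ``1/node_attenuation``.
    The variance inflation matters because absolute volumes share a common
    eTIV factor that induces a baseline correlation between all pairs;
    diluting the node's signal with independent variance pushes its
    absolute-scale correlations toward zero, which pure correlation
    attenuation on the percent scale cannot do.
    """

    decay: float
    node_attenuation: float
    designated_node: str = DEFAULT_DESIGNATED_NODE


@dataclass
class SyntheticCohortSpec:
    """Everything :func:`generate_cohort` needs, with realistic defaults."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"F-MS": 25, "NF-MS": 25, "HC": 40})
    base_means: dict[str, float] = field(
        default_factory=lambda: {k: m for k, (m, _) in HC_VOLUMETRY.items()})
    base_sds: dict[str, float] = field(
        default_factory=lambda: {k: s for k, (_, s) in HC_VOLUMETRY.items()})
    atrophy: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_ATROPHY.items()})
    block_r_in: float = 0.45
    block_r_out: float = 0.12
    #: block assignment of the 50 nuclei; defaults to the six anatomical
    #: groups, each spanning both hemispheres
    blocks: dict[str, str] = field(
        default_factory=lambda: {str(lab): lab.anatomical_group
                                 for lab in ALL_LABELS})
    #: per-group planted correlation structure (None = block model)
    ring_structure: dict[str, RingStructure] = field(default_factory=dict)
    etiv: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ETIV))
    age_range: tuple[float, float] = (18.0, 45.0)
    p_female: float = 0.65
    lesion_gamma: tuple[float, float] = (4.0, 1.6)      # shape, scale (mL)
    duration_gamma: tuple[float, float] = (2.0, 1.2)    # shape, scale (years)
    #: linear covariate effects, as fractions of each region's mean:
    #: per year of age (centered), for male sex, per mL lesion volume
    age_effect: float = -0.002
    sex_effect: float = -0.03
    lesion_effect: float = -0.010
    age_center: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 4:
                raise ValueError(f"group {g} size must be >= 4, got {n}")
        missing = set(NUCLEUS_COLUMNS) - set(self.base_means)
        if missing:
            raise ValueError(f"base_means missing regions: {sorted(missing)}")

    def correlation_matrix(self, group: str) -> np.ndarray:
        """The group's 50 x 50 percent-scale correlation matrix."""
        ring = self.ring_structure.get(group)
        if ring is None:
            block_ids = np.array([self.blocks[c] for c in NUCLEUS_COLUMNS])
            same = block_ids[:, None] == block_ids[None, :]
            R = np.where(same, self.block_r_in, self.block_r_out)
        else:
            n = len(NUCLEUS_COLUMNS)
            pos = np.arange(n)
            d = np.abs(pos[:, None] - pos[None, :])
            ring_d = np.minimum(d, n - d)
            R = ring.decay ** ring_d
            i = NUCLEUS_COLUMNS.index(ring.designated_node)
            R[i, :] *= ring.node_attenuation
            R[:, i] *= ring.node_attenuation
        np.fill_diagonal(R, 1.0)
        return R

    def covariance_matrix(self, group: str) -> np.ndarray:
        """Sigma = D R D on the percent scale; positive definiteness checked."""
        sds = np.array([self.base_sds[c] for c in NUCLEUS_COLUMNS])
        ring = self.ring_structure.get(group)
        if ring is not None and ring.node_attenuation > 0:
            sds = sds.copy()
            i = NUCLEUS_COLUMNS.index(ring.designated_node)
            sds[i] /= ring.node_attenuation
        cov = self.correlation_matrix(group) * np.outer(sds, sds)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"covariance for group {group!r} is not positive definite"
            ) from err
        return cov


def plant_network_difference(spec: SyntheticCohortSpec, target_group: str,
                             preset: str) -> SyntheticCohortSpec:
    """Return a spec whose target group carries a planted network alteration.

    ``"none"`` is the identity.  ``"moderate"`` and ``"strong"`` replace the
    target group's block correlations with a ring-distance decay (so its
    thresholded networks are lattice-like, with systematically longer Lp) and
    attenuate the designated node's correlations (lower nodal efficiency).
    """
    if preset not in NETWORK_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(NETWORK_PRESETS)}")
    if target_group not in spec.group_sizes:
        raise ValueError(f"unknown target group {target_group!r}")
    if preset == "none":
        return spec
    decay, attenuation = NETWORK_PRESETS[preset]
    rings = dict(spec.ring_structure)
    rings[target_group] = RingStructure(decay=decay, node_attenuation=attenuation)
    return dataclasses.replace(spec, ring_structure=rings)


def generate_cohort(spec: SyntheticCohortSpec,
                    seed: int | None = None) -> CohortTable:
    """Draw a cohort table from the spec; fully reproducible from the seed."""
    seed = spec.seed if seed is None else seed
    means = np.array([spec.base_means[c] for c in NUCLEUS_COLUMNS])
    rows = []
    for group, n in spec.group_sizes.items():
        rng = stage_rng(seed, "cohort", group)
        cov = spec.covariance_matrix(group)
        group_means = means.copy()
        for region, frac in spec.atrophy.get(group, {}).items():
            group_means[NUCLEUS_COLUMNS.index(region)] *= 1.0 - frac

        age = rng.uniform(*spec.age_range, size=n)
        sex = (rng.random(n) >= spec.p_female).astype(int)  # 1 = male
        if group == "HC":
            lesion = np.zeros(n)
            duration = np.full(n, np.nan)
        else:
            shape, scale = spec.lesion_gamma
            lesion = rng.gamma(shape, scale, size=n)
            dshape, dscale = spec.duration_gamma
            duration = rng.gamma(dshape, dscale, size=n)
        mean_etiv, sd_etiv = spec.etiv[group]
        etiv = np.clip(rng.normal(mean_etiv, sd_etiv, size=n),
                       0.3 * mean_etiv, None)

        pct = rng.multivariate_normal(group_means, cov, size=n,
                                      method="cholesky")
        shift = (spec.age_effect * (age - spec.age_center)[:, None]
                 + spec.sex_effect * sex[:, None]
                 + spec.lesion_effect * lesion[:, None])
        pct = pct + shift * means[None, :]
        pct = np.maximum(pct, 0.02 * means[None, :])  # volumes must stay > 0
        absolute = pct * etiv[:, None] / 100.0

        for i in range(n):
            row = {
                "subject_id": f"{group}-{i + 1:03d}",
                "group": group,
                "age": age[i],
                "sex": int(sex[i]),
                "lesion_volume": lesion[i],
                "eTIV": etiv[i],
                "disease_duration": duration[i],
            }
            row.update(dict(zip(NUCLEUS_COLUMNS, absolute[i])))
            rows.append(row)
    df = pd.DataFrame(rows)
    return CohortTable(df)
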