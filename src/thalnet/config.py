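"""Run configuration for the network pipeline.

Defaults follow the analysis protocol: sparsity grid 0.05-0.40 in 0.01
increments (36 densities), more than 150 degree-preserving null networks for
the small-world normalization (default 200), 5000 group permutations, FDR at
0.05 for nodal families, and a Bonferroni-style 0.05/50 = 0.001 threshold for
the per-nucleus volumetry ANOVA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

GROUPS = ("F-MS", "NF-MS", "HC")

CORRELATION_MODES = ("residual_pearson", "full_partial")


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of one analysis run.

    Every source of randomness downstream derives from ``rng_seed`` through
    named stage streams (:func:`thalnet.rng.stage_rng`), so the order in which
    pipeline stages execute cannot change results.
    """

    sparsity_min: float = 0.05
    sparsity_max: float = 0.40
    sparsity_step: float = 0.01
    n_null_networks: int = 200
    #: reduced per-permutation null count for gamma/lambda/sigma tests;
    #: the observed statistic always uses the full ``n_null_networks``.
    n_null_networks_perm: int = 50
    n_permutations: int = 5000
    rng_seed: int = 0
    fdr_alpha: float = 0.05
    volumetry_alpha: float = 0.001
    covariates: tuple[str, ...] = ("age", "sex", "lesion_volume")
    correlation_mode: str = "residual_pearson"
    #: residualize per group (default) or pooled across all subjects
    pooled_residualization: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.sparsity_min < self.sparsity_max < 1.0):
            raise ValueError(
                "require 0 < sparsity_min < sparsity_max < 1, got "
                f"[{self.sparsity_min}, {self.sparsity_max}]"
            )
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be > 0")
        if self.n_null_networks < 1:
            raise ValueError("n_null_networks must be >= 1")
        if self.n_null_networks_perm < 1:
            raise ValueError("n_null_networks_perm must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not (0.0 < self.volumetry_alpha < 1.0):
            raise ValueError("volumetry_alpha must lie in (0, 1)")
        if self.correlation_mode not in CORRELATION_MODES:
            raise ValueError(
                f"correlation_mode must be one of {CORRELATION_MODES}"
            )
        object.__setattr__(self, "covariates", tuple(self.covariates))

    def with_options(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON (decided by extension, YAML by default)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_mapping(data)
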