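"""Cohort-table input, result output and the run manifest.

The single pipeline input is a wide per-subject table: id, group
(F-MS / NF-MS / HC), age, sex, lesion volume, disease duration, estimated
total intracranial volume (eTIV), and the 50 absolute thalamic-nucleus
volumes.  Sex is encoded 0 = female, 1 = male for regression.  Healthy
controls carry ``lesion_volume = 0`` (not missing) so one schema serves all
groups; ``disease_duration`` may be missing (NaN) for controls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GROUPS, RunConfig
from .labels import NUCLEUS_COLUMNS, resolve_column

log = logging.getLogger(__name__)

REQUIRED_COVARIATES = ("subject_id", "group", "age", "sex", "lesion_volume", "eTIV")
OPTIONAL_COVARIATES = ("disease_duration",)

_SEX_CODES = {
    "female": 0, "f": 0, "0": 0, "0.0": 0,
    "male": 1, "m": 1, "1": 1, "1.0": 1,
}


class SchemaError(ValueError):
    """The table is missing required columns."""


class ValidationError(ValueError):
    """A row violates the cohort-table invariants."""


@dataclass
class CohortTable:
    """Validated cohort table with canonical columns.

    ``data`` holds the covariates followed by the 50 nucleus columns in
    canonical order.  ``scale`` is ``"absolute"`` (mL) for raw input and
    ``"percent"`` (of eTIV) after :func:`thalnet.volumetry.normalize_volumes`.
    """

    data: pd.DataFrame
    scale: str = "absolute"

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COVARIATES + OPTIONAL_COVARIATES
                   if c not in df.columns]
        missing += [c for c in NUCLEUS_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        order = list(REQUIRED_COVARIATES) + list(OPTIONAL_COVARIATES) + list(NUCLEUS_COLUMNS)
        self.data = df = df[order].reset_index(drop=True)
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels {sorted(bad_group)}")
        if not set(df["sex"].unique()) <= {0, 1}:
            raise ValidationError("sex must be coded 0 (female) / 1 (male)")
        for col in ("eTIV",) + NUCLEUS_COLUMNS:
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                sid = df.loc[~(np.isfinite(vals) & (vals > 0)), "subject_id"].iloc[0]
                raise ValidationError(
                    f"non-positive or missing {col!r} for subject {sid!r}"
                )
        lesion = df["lesion_volume"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lesion)) or np.any(lesion < 0):
            raise ValidationError("lesion_volume must be finite and >= 0")

    # -- accessors -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> tuple[str, ...]:
        present = set(self.data["group"])
        return tuple(g for g in GROUPS if g in present)

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.data["group"] == group).to_numpy())

    def subset(self, groups) -> "CohortTable":
        mask = self.data["group"].isin(list(groups))
        return CohortTable(self.data.loc[mask].copy(), scale=self.scale)

    def volumes(self, group: str | None = None) -> np.ndarray:
        """(n_subjects, 50) volume matrix, canonical column order."""
        df = self.data if group is None else self.data[self.data["group"] == group]
        return df[list(NUCLEUS_COLUMNS)].to_numpy(dtype=float)

    def covariate_matrix(self, covariates) -> np.ndarray:
        return self.data[list(covariates)].to_numpy(dtype=float)


def _coerce_sex(value) -> int:
    key = str(value).strip().lower()
    if key not in _SEX_CODES:
        raise ValidationError(f"cannot interpret sex value {value!r}")
    return _SEX_CODES[key]


def read_cohort_table(path: str | Path, dialect: str | None = None) -> CohortTable:
    """Read a CSV/TSV cohort table.

    Column order is irrelevant; nucleus columns may use either the canonical
    short codes (``"Left-AV"``) or the documented long-name aliases.  Extra
    columns are ignored with a logged warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    raw = pd.read_csv(path, sep=sep)

    rename: dict[str, str] = {}
    for col in raw.columns:
        canon = resolve_column(col)
        if canon is not None:
            rename[col] = canon
        elif col.strip().lower() == "etiv":
            rename[col] = "eTIV"
        elif col.strip() in REQUIRED_COVARIATES + OPTIONAL_COVARIATES:
            rename[col] = col.strip()
    df = raw.rename(columns=rename)

    required = list(REQUIRED_COVARIATES) + list(NUCLEUS_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    extra = [c for c in df.columns
             if c not in required + list(OPTIONAL_COVARIATES)]
    if extra:
        log.warning("ignoring extra columns: %s", extra)
    if "disease_duration" not in df.columns:
        df["disease_duration"] = np.nan
    df = df[required[:2] + ["age", "sex", "lesion_volume", "eTIV",
                            "disease_duration"] + list(NUCLEUS_COLUMNS)]
    df = df.copy()
    df["sex"] = [_coerce_sex(v) for v in df["sex"]]
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.data.to_csv(path, sep=sep, index=False, float_format="%.17g")


# -- result writing ----------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(results: dict, out_dir: str | Path,
                  config: RunConfig | None = None) -> dict:
    """Write pipeline outputs and a replayable run manifest.

    Tabular results (DataFrames, metric curves) go to TSV; everything else is
    serialized as JSON with sorted keys, so identical runs produce
    byte-identical files.  Returns the manifest (also written as
    ``manifest.json``).
    """
    from .curves import MetricCurve  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for key, value in results.items():
        if isinstance(value, MetricCurve):
            fname = f"{key}.tsv"
            value.to_frame().to_csv(out_dir / fname, sep="\t", index=False,
                                     float_format="%.17g")
        elif isinstance(value, pd.DataFrame):
            fname = f"{key}.tsv"
            value.to_csv(out_dir / fname, sep="\t", index=False,
                         float_format="%.17g")
        elif isinstance(value, CohortTable):
            fname = f"{key}.csv"
            write_cohort_table(value, out_dir / fname)
        else:
            fname = f"{key}.json"
            with open(out_dir / fname, "w") as fh:
                json.dump(_jsonable(value), fh, indent=2, sort_keys=True)
                fh.write("\n")
        files[key] = fname
    manifest = {
        "files": files,
        "config": config.to_dict() if config is not None else None,
        "seed": config.rng_seed if config is not None else None,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
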