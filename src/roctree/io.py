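"""Cohort table readers/writers, YAML configuration, run manifests."""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import CLINICAL_COLUMNS, aal_regions, jhu_tracts
from .cohort import (ClinicalModel, CohortConfig, CohortSpec, FeatureModel,
                     GENERATOR_VERSION, PlantedLeaf, PlantedSplit,
                     PlantedTreeSpec)

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "RunManifest",
    "cohort_config_to_dict",
    "cohort_config_from_dict",
    "load_cohort_config",
    "save_cohort_config",
]

REQUIRED_COLUMNS = ("subject_id", "cohort", "remitted")


class CohortValidationError(ValueError):
    """A cohort table violated a schema invariant; message names row/column."""


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV/TSV.

    Checks: required id/cohort/outcome columns; FA values within [0, 1];
    volumes strictly positive; remission consistent with week-8 HRSD17
    (<= 7) where both are present.  Missing cells stay missing (NaN) —
    they are never silently zero-filled.  Unknown columns raise in strict
    mode and warn otherwise.  Row numbers in messages refer to file lines
    (header = line 1).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    known = set(REQUIRED_COLUMNS) | set(aal_regions()) | set(jhu_tracts()) \
        | set(CLINICAL_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        msg = f"unknown columns: {unknown}"
        if strict:
            raise CohortValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    df["remitted"] = df["remitted"].astype(bool)

    def _first_bad(col, bad_mask):
        row = int(np.flatnonzero(bad_mask)[0])
        return f"row {row + 2}, column {col!r}"

    for col in jhu_tracts():
        if col in df.columns:
            x = df[col].astype(float)
            bad = ((x < 0) | (x > 1)) & x.notna()
            if bad.any():
                raise CohortValidationError(
                    f"FA outside [0, 1] at {_first_bad(col, bad.to_numpy())}")
    for col in aal_regions():
        if col in df.columns:
            x = df[col].astype(float)
            bad = (x <= 0) & x.notna()
            if bad.any():
                raise CohortValidationError(
                    f"non-positive volume at {_first_bad(col, bad.to_numpy())}")
    if "hrsd17_week8" in df.columns:
        w8 = df["hrsd17_week8"].astype(float)
        bad = (w8.notna() & (df["remitted"] != (w8 <= 7))).to_numpy()
        if bad.any():
            raise CohortValidationError(
                "remission label inconsistent with week-8 HRSD17 at "
                + _first_bad("hrsd17_week8", bad))
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """What a run needs to be re-executed bit-identically.

    Timestamps are informational; :meth:`equivalent_to` ignores them.
    """

    config: dict
    seed: int | None
    input_hashes: dict = field(default_factory=dict)
    software_version: str = __version__
    generator: str = GENERATOR_VERSION
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def record_input(self, path) -> None:
        self.input_hashes[str(path)] = _sha256(path)

    def to_dict(self) -> dict:
        return {
            "config": self.config, "seed": self.seed,
            "input_hashes": self.input_hashes,
            "software_version": self.software_version,
            "generator": self.generator, "created": self.created,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def equivalent_to(self, other: "RunManifest") -> bool:
        a, b = self.to_dict(), other.to_dict()
        a.pop("created"), b.pop("created")
        return a == b


# --- cohort configuration (de)serialization -------------------------------

def _tree_to_dict(t: PlantedTreeSpec) -> dict:
    return {
        "splits": [{
            "feature": s.feature, "threshold": s.threshold,
            "continue_side": s.continue_side,
            "leaf": {"count": s.leaf.count, "remission_p": s.leaf.remission_p},
        } for s in t.splits],
        "final_leaf": {"count": t.final_leaf.count,
                       "remission_p": t.final_leaf.remission_p},
    }


def _tree_from_dict(d: dict) -> PlantedTreeSpec:
    return PlantedTreeSpec(
        splits=tuple(PlantedSplit(
            feature=s["feature"], threshold=float(s["threshold"]),
            continue_side=s["continue_side"],
            leaf=PlantedLeaf(int(s["leaf"]["count"]),
                             float(s["leaf"]["remission_p"])),
        ) for s in d["splits"]),
        final_leaf=PlantedLeaf(int(d["final_leaf"]["count"]),
                               float(d["final_leaf"]["remission_p"])),
    )


def cohort_config_to_dict(config: CohortConfig) -> dict:
    return {
        "seed": config.seed,
        "label_noise": config.label_noise,
        "exact_counts": config.exact_counts,
        "feature_model": {
            "volume_mean": config.feature_model.volume_mean,
            "volume_sd": config.feature_model.volume_sd,
            "fa_mean": config.feature_model.fa_mean,
            "fa_sd": config.feature_model.fa_sd,
            "overrides": {k: list(v) for k, v in
                          config.feature_model.overrides.items()},
        },
        "cohorts": [{
            "name": c.name, "n": c.n, "remission_rate": c.remission_rate,
            "missing": dict(c.missing),
            "trees": {m: _tree_to_dict(t) for m, t in c.trees.items()},
            "clinical": {k: ({a: list(t) for a, t in v.items()}
                         if isinstance(v, dict) else v)
                         for k, v in vars(c.clinical).items()},
        } for c in config.cohorts],
    }


def cohort_config_from_dict(d: dict) -> CohortConfig:
    fm = d.get("feature_model", {})
    cohorts = []
    for c in d["cohorts"]:
        clin = dict(c.get("clinical") or {})
        if "dose" in clin:
            clin["dose"] = {a: tuple(t) for a, t in clin["dose"].items()}
        clinical = ClinicalModel(**clin) if clin else ClinicalModel()
        cohorts.append(CohortSpec(
            name=c["name"], n=int(c["n"]),
            remission_rate=float(c["remission_rate"]),
            trees={m: _tree_from_dict(t) for m, t in c.get("trees", {}).items()},
            missing={k: int(v) for k, v in c.get("missing", {}).items()},
            clinical=clinical,
        ))
    return CohortConfig(
        cohorts=tuple(cohorts),
        feature_model=FeatureModel(
            volume_mean=float(fm.get("volume_mean", 10.0)),
            volume_sd=float(fm.get("volume_sd", 2.5)),
            fa_mean=float(fm.get("fa_mean", 0.5)),
            fa_sd=float(fm.get("fa_sd", 0.07)),
            overrides={k: tuple(v) for k, v in fm.get("overrides", {}).items()},
        ),
        label_noise=float(d.get("label_noise", 0.0)),
        exact_counts=bool(d.get("exact_counts", False)),
        seed=d.get("seed"),
    )


def load_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        return cohort_config_from_dict(yaml.safe_load(fh))


def save_cohort_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_config_to_dict(config), fh, sort_keys=False)
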