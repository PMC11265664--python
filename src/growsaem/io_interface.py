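"""File formats, GRM computation and configuration.

Everything is plain text: CSV for phenotypes, kinship, genotypes and
predictions; YAML for configuration and estimated parameters; a plain-text
run log carrying the seed and a config hash so every run is reproducible
from its log.

Phenotypes travel in long format, one row per observation, with columns
``plant_id, variety_id, time, value`` plus any number of covariate
columns.  The kinship CSV is square with variety labels as both header and
index; its order must match the phenotype table's variety order (first
appearance) -- a mismatch raises, it is never silently reordered.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .model_core import (
    Dataset,
    DesignSpec,
    Kinship,
    PlantRecord,
    SchemaError,
    Theta,
    design_from_terms,
)

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
    "read_genotypes",
    "write_genotypes",
    "compute_grm",
    "Config",
    "read_config",
    "write_theta",
    "read_theta",
    "write_run_log",
]

REQUIRED_COLUMNS = ("plant_id", "variety_id", "time", "value")


def read_phenotypes(path, transform: Optional[str] = None) -> Dataset:
    """Long-format phenotype CSV -> Dataset.

    Variety order is order of first appearance; per-plant times are sorted.
    Rows with missing values are dropped (count noted in the raised-level
    logger is left to the CLI); duplicate (plant, time) pairs and, under the
    log transform, nonpositive values are errors.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"phenotype file {path} lacks columns: {missing}")
    frame = frame.dropna(subset=["value"])
    dup = frame.duplicated(subset=["plant_id", "time"])
    if dup.any():
        bad = frame.loc[dup, ["plant_id", "time"]].iloc[0]
        raise SchemaError(
            f"duplicate observation for plant {bad['plant_id']} at time {bad['time']}"
        )
    if transform == "log":
        if (frame["value"] <= 0).any():
            rows = frame.index[frame["value"] <= 0].tolist()[:10]
            raise SchemaError(
                f"log transform requires positive values; offending rows: {rows}"
            )
        frame = frame.assign(value=np.log(frame["value"].to_numpy()))
    elif transform not in (None, "none"):
        raise SchemaError(f"unknown transform '{transform}'")

    covariate_cols = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
    variety_index: Dict[str, int] = {}
    plants: List[PlantRecord] = []
    for plant_id, grp in frame.groupby("plant_id", sort=False):
        variety = str(grp["variety_id"].iloc[0])
        variety_index.setdefault(variety, len(variety_index))
        covs = {c: float(grp[c].iloc[0]) for c in covariate_cols}
        plants.append(
            PlantRecord(
                plant_id=str(plant_id),
                variety=variety,
                covariates=covs,
                times=grp["time"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return Dataset(plants, variety_index)


def write_phenotypes(dataset: Dataset, path) -> None:
    rows = []
    for rec in dataset.plants:
        for t, y in zip(rec.times, rec.values):
            row = {"plant_id": rec.plant_id, "variety_id": rec.variety,
                   "time": t, "value": y}
            row.update(rec.covariates)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.15g")


def read_kinship(path, dataset: Optional[Dataset] = None) -> Kinship:
    frame = pd.read_csv(path, index_col=0)
    varieties = [str(v) for v in frame.index]
    if [str(c) for c in frame.columns] != varieties:
        raise SchemaError("kinship CSV row and column labels differ")
    kin = Kinship(frame.to_numpy(dtype=float), varieties)
    if dataset is not None:
        kin.aligned_to(dataset)
    return kin


def write_kinship(kinship: Kinship, path) -> None:
    pd.DataFrame(
        kinship.K, index=kinship.varieties, columns=kinship.varieties
    ).to_csv(path, float_format="%.15g")


def read_genotypes(path) -> pd.DataFrame:
    """Variety-by-marker CSV coded -1/0/1, variety labels in the index."""
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy()
    if not np.isin(values, (-1, 0, 1)).all():
        raise SchemaError("genotypes must be coded -1, 0 or 1 (no missing values)")
    return frame


def write_genotypes(genotypes: np.ndarray, varieties: List[str], path) -> None:
    pd.DataFrame(
        np.asarray(genotypes),
        index=varieties,
        columns=[f"m{j + 1}" for j in range(np.asarray(genotypes).shape[1])],
    ).to_csv(path)


def compute_grm(genotypes, rescale: bool = True) -> np.ndarray:
    """Additive genomic relationship matrix from -1/0/1 genotypes.

    VanRaden method 1: markers centered by their empirical mean,
    ``K = W W' / (2 sum_l p_l (1 - p_l))`` with ``p_l`` the alternative
    allele frequency ``(mean_l + 1) / 2``.  Monomorphic markers contribute
    nothing; an entirely monomorphic panel is an error.  With ``rescale``
    the result is divided by its mean diagonal (unit average inbreeding).
    """
    geno = np.asarray(genotypes, dtype=float)
    if geno.ndim != 2 or geno.shape[1] < 1:
        raise SchemaError("genotypes must be a variety-by-marker matrix")
    if not np.isin(geno, (-1.0, 0.0, 1.0)).all():
        raise SchemaError("genotype entries must be -1, 0 or 1")
    means = geno.mean(axis=0)
    freq = (means + 1.0) / 2.0
    denom = 2.0 * float(np.sum(freq * (1.0 - freq)))
    if denom <= 0:
        raise SchemaError("all markers are monomorphic; GRM is undefined")
    w = geno - means
    k_mat = (w @ w.T) / denom
    if rescale:
        mean_diag = float(np.mean(np.diag(k_mat)))
        if mean_diag > 0:
            k_mat = k_mat / mean_diag
    return 0.5 * (k_mat + k_mat.T)


# ---------------------------------------------------------------------------
# configuration and parameter files


@dataclass
class Config:
    """Structured run configuration (YAML on disk).

    ``fixed_terms``/``genetic_terms`` name the design: ``"1"`` for the
    intercept plus covariate column names, each contributing one effect per
    growth parameter.
    """

    curve: str
    constants: Dict[str, float] = field(default_factory=dict)
    fixed_terms: List[str] = field(default_factory=lambda: ["1"])
    genetic_terms: List[str] = field(default_factory=lambda: ["1"])
    transform: Optional[str] = None
    saem: Dict[str, float] = field(default_factory=dict)
    map: Dict[str, float] = field(default_factory=dict)
    cv: Dict[str, object] = field(default_factory=dict)

    def design_spec(self) -> DesignSpec:
        return design_from_terms(
            self.curve, self.fixed_terms, self.genetic_terms, self.constants
        )

    def to_dict(self) -> dict:
        return {
            "curve": self.curve,
            "constants": dict(self.constants),
            "fixed_terms": list(self.fixed_terms),
            "genetic_terms": list(self.genetic_terms),
            "transform": self.transform,
            "saem": dict(self.saem),
            "map": dict(self.map),
            "cv": dict(self.cv),
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_config(path) -> Config:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if "curve" not in raw:
        raise SchemaError("config must name a growth curve under 'curve'")
    return Config(
        curve=str(raw["curve"]),
        constants={k: float(v) for k, v in (raw.get("constants") or {}).items()},
        fixed_terms=[str(t) for t in raw.get("fixed_terms", ["1"])],
        genetic_terms=[str(t) for t in raw.get("genetic_terms", ["1"])],
        transform=raw.get("transform"),
        saem=dict(raw.get("saem") or {}),
        map=dict(raw.get("map") or {}),
        cv=dict(raw.get("cv") or {}),
    )


def write_theta(theta: Theta, path, spec: Optional[DesignSpec] = None) -> None:
    payload = {
        "beta": [float(b) for b in theta.beta],
        "sigma2": float(theta.sigma2),
        "P": [[float(x) for x in row] for row in theta.P],
        "G": [[float(x) for x in row] for row in theta.G],
    }
    if spec is not None and spec.fixed_names:
        payload["beta_names"] = list(spec.fixed_names)
    if spec is not None and spec.genetic_names:
        payload["genetic_effect_names"] = list(spec.genetic_names)
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def read_theta(path) -> Theta:
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    return Theta(
        beta=np.asarray(raw["beta"], dtype=float),
        sigma2=float(raw["sigma2"]),
        P=np.asarray(raw["P"], dtype=float),
        G=np.asarray(raw["G"], dtype=float),
    )


def write_run_log(path, command: str, seed: int, config: Optional[Config]) -> None:
    """Deterministic run log: command, seed, config hash, library versions."""
    import scipy

    from . import __version__

    lines = [
        f"command: {command}",
        f"seed: {seed}",
        f"config_digest: {config.digest() if config else 'none'}",
        f"growsaem: {__version__}",
        f"numpy: {np.__version__}",
        f"scipy: {scipy.__version__}",
        f"pandas: {pd.__version__}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
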