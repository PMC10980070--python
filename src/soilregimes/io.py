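"""Readers/writers for the pipeline's table formats and run configuration.

All interchange is plain text: CSV for time series, fits, regimes,
boundaries and predictions; TSV for the (wide) ASV count tables; JSON for
summaries and ground truth; YAML for configuration.  Files written by the
CLI begin with a ``# config_hash=...`` comment line; the readers here skip
``#`` comments, so round-trips are exact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .crm import HOURS_PER_DAY
from .fitting import SamplePair

__all__ = [
    "RunConfig",
    "SchemaError",
    "PairingError",
    "read_timeseries",
    "write_timeseries",
    "read_count_table",
    "write_count_table",
    "load_config",
    "config_hash",
    "setup_logging",
]

TIMESERIES_COLUMNS = (
    "soil_id",
    "native_pH",
    "perturbed_pH",
    "replicate",
    "chl",
    "time_hr",
    "nitrate_mM",
)


class SchemaError(ValueError):
    """An input table is missing required columns."""


class PairingError(ValueError):
    """A condition lacks one of the CHL-/CHL+ arms."""


@dataclass
class RunConfig:
    """Declarative settings for a pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    # fitting
    gamma: float = 4.8
    KA: float = 0.01
    KC_tilde: float = 0.01
    n_restarts: int = 8
    fit_model: str = "auto"
    # regimes
    threshold_x: float = 0.05
    threshold_c: float = 1.5
    # abundance
    alpha: float = 0.05
    nmf_seed: int = 0
    nmf_max_iter: int = 500
    # lasso
    presence_threshold: float = 0.0
    n_lambdas: int = 100
    n_perm: int = 200
    # synthetic panel
    n_soils: int = 20
    n_perturbed: int = 13
    replicates: int = 3
    noise_sd: float = 0.05
    n_asv: int = 2000
    # optional input paths
    timeseries_path: Optional[str] = None
    counts_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.threshold_x <= 0 or self.threshold_c <= 0:
            raise ValueError("regime thresholds must be positive")


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    data: Dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = RunConfig.__dataclass_fields__.keys()
    unknown = set(data) - set(known)
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific settings (paths and logging excluded)."""
    data = asdict(cfg)
    for key in ("out_dir", "log_level", "timeseries_path", "counts_path"):
        data.pop(key, None)
    blob = json.dumps(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def setup_logging(level: str = "INFO", logfile: Optional[Path] = None) -> logging.Logger:
    logger = logging.getLogger("soilregimes")
    logger.setLevel(level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


def write_timeseries(df: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_timeseries(path) -> Dict[Tuple, SamplePair]:
    """Load a tidy nitrate time-series CSV into condition-keyed SamplePairs.

    Validates the schema, rejects negative-nitrate rows (with a count in a
    warning), converts hours to days, and pairs the CHL- and CHL+ arms of
    each (soil, perturbed pH, replicate).  A condition missing one arm
    raises :class:`PairingError` naming it.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"time-series file {path} missing column(s): {missing}")
    bad = df["nitrate_mM"] < 0
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} row(s) with negative nitrate",
                      stacklevel=2)
        df = df[~bad]
    pairs: Dict[Tuple, SamplePair] = {}
    for (soil, ph, rep), grp in df.groupby(["soil_id", "perturbed_pH", "replicate"]):
        arms = {}
        for chl, sub in grp.groupby("chl"):
            sub = sub.sort_values("time_hr")
            arms[int(chl)] = (
                sub["time_hr"].to_numpy(float) / HOURS_PER_DAY,
                sub["nitrate_mM"].to_numpy(float),
            )
        if 0 not in arms or 1 not in arms:
            have = "CHL+" if 1 in arms else "CHL-"
            raise PairingError(
                f"condition (soil={soil}, pH={ph}, replicate={rep}) has only the "
                f"{have} arm"
            )
        native = float(grp["native_pH"].iloc[0])
        pairs[(soil, float(ph), int(rep))] = SamplePair(
            times_minus=arms[0][0],
            nitrate_minus=arms[0][1],
            times_plus=arms[1][0],
            nitrate_plus=arms[1][1],
            meta={
                "soil_id": soil,
                "native_pH": native,
                "perturbed_pH": float(ph),
                "replicate": int(rep),
            },
        )
    return pairs


def write_count_table(table, counts_path, meta_path, taxonomy_path) -> None:
    """Write a CountTable as TSV (counts incl. spike_in row) + CSV sidecars."""
    counts_path, meta_path, taxonomy_path = map(Path, (counts_path, meta_path, taxonomy_path))
    counts_path.parent.mkdir(parents=True, exist_ok=True)
    out = table.counts.copy()
    out.loc["__spike_in__"] = table.spike_in
    out.to_csv(counts_path, sep="\t")
    if table.meta is not None:
        table.meta.to_csv(meta_path)
    if table.taxonomy is not None:
        table.taxonomy.to_csv(taxonomy_path)


def read_count_table(counts_path, meta_path=None, taxonomy_path=None):
    """Inverse of :func:`write_count_table`."""
    from .abundance import CountTable

    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    if "__spike_in__" not in counts.index:
        raise SchemaError(f"count table {counts_path} lacks the __spike_in__ row")
    spike = counts.loc["__spike_in__"]
    counts = counts.drop(index="__spike_in__")
    meta = pd.read_csv(meta_path, index_col=0) if meta_path else None
    tax = pd.read_csv(taxonomy_path, index_col=0) if taxonomy_path else None
    return CountTable(counts=counts, spike_in=spike, taxonomy=tax, meta=meta)
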