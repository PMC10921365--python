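"""Run configuration, YAML round-tripping, and table/metadata writers.

The config file format is YAML: a flat mapping whose keys are exactly the
fields of :class:`RunConfig`. Unknown keys are rejected (with the offending
key named) so typos never silently fall back to defaults.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, fields, replace
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .params import CompensationModel, ModelParams, ReplacementMode, SimParams


@dataclass(frozen=True)
class RunConfig:
    """Shared configuration for all subcommands; deterministic subcommands
    simply ignore the simulation-only fields (and vice versa)."""

    s: float = 1.0
    h: float = 0.0
    sigma: float = 0.1
    w_inbred: float = 0.0
    comp_model: str = "backup_embryo"
    C: float = 0.9
    p_A: float = 0.0
    mu: float = 5e-8
    N: int = 10_000
    n_sites: int = 100_000
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0
    replacement_mode: str = "sibling"
    generations: int | None = None
    balance_window: int = 500
    min_generations: int = 2000
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # delegate range validation to the typed parameter containers
        self.model_params()
        self.sim_params()
        CompensationModel(self.comp_model)

    def model_params(self) -> ModelParams:
        return ModelParams(
            s=self.s, h=self.h, sigma=self.sigma, w_inbred=self.w_inbred,
            comp_model=self.comp_model, C=self.C, p_A=self.p_A,
        )

    def sim_params(self) -> SimParams:
        return SimParams(
            s=self.s, h=self.h, sigma=self.sigma, w_inbred=self.w_inbred,
            mu=self.mu, N=self.N, n_sites=self.n_sites,
            n_chromosomes=self.n_chromosomes,
            chrom_length_morgans=self.chrom_length_morgans,
            replacement_mode=self.replacement_mode,
            generations=self.generations,
            balance_window=self.balance_window,
            min_generations=self.min_generations, seed=self.seed,
        )

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.value if isinstance(v, Enum) else v
        return out


def parse_config(path: str | Path | None = None, overrides: dict | None = None
                 ) -> RunConfig:
    """Build a validated :class:`RunConfig` from an optional YAML file plus
    explicit overrides (CLI flags win over file values).

    Raises :class:`ValueError` naming the offending key on unknown keys,
    type mismatches or out-of-range values.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(raw)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_tables(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write each result table as a TSV (tab-delimited, header row, full
    double precision, LF endings) plus a ``metadata.json`` sidecar carrying
    parameters, seed, software version and a timestamp. Returns the paths
    written, keyed like ``results``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in results.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False, lineterminator="\n",
                     float_format="%.17g")
        paths[name] = p
    meta = dict(metadata or {})
    meta.setdefault("software_version", __version__)
    meta.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S"))
    mp = out_dir / "metadata.json"
    mp.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    paths["metadata"] = mp
    return paths
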