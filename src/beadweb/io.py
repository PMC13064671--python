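"""File formats, configuration and the simulate → infer → validate pipeline.

Count tables are plain TSV with columns (experiment_id, type_label,
count_initial, count_final); parameter and posterior outputs are JSON or
flat TSV; configs are YAML or JSON.  Every pipeline run emits a
machine-readable provenance record (config hash, seed, package version)
next to its results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    ExperimentDataset,
    FractionPrior,
    GrowthPrior,
    PriorSpec,
    SamplerConfig,
    fit_posterior,
)
from .simulate import SimulationConfig, make_design, simulate_replicate
from .validate import compare_conditions, replicate_mean_errors, run_validation_sweep

__all__ = [
    "read_dataset",
    "write_dataset",
    "load_config",
    "prior_spec_from_dict",
    "RunConfig",
    "run_pipeline",
    "provenance_record",
]

logger = logging.getLogger("beadweb")

_REQUIRED_COLUMNS = ("experiment_id", "type_label", "count_initial", "count_final")


def read_dataset(
    path: str | Path,
    lambda_rate: float = 0.3,
    intended_proportions: dict[str, np.ndarray] | None = None,
) -> list[ExperimentDataset]:
    """Read experiments from a TSV count table.

    One :class:`ExperimentDataset` per ``experiment_id``, in order of first
    appearance; the cell-type ordering is taken from the first experiment
    and must be consistent across experiments.  ``lambda_rate`` (and
    optionally per-experiment intended inoculum proportions, keyed by
    experiment id) come from the run configuration, not the table.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"experiment_id": str, "type_label": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("count_initial", "count_final"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna() | (vals < 0) | (vals != vals.round())]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: column {col!r} must hold nonnegative integers; "
                f"bad rows (1-based, incl. header): {[int(b) + 2 for b in bad]}"
            )
        table[col] = vals.astype(np.int64)

    ids = list(dict.fromkeys(table["experiment_id"]))
    first = table[table["experiment_id"] == ids[0]]
    type_labels = tuple(dict.fromkeys(first["type_label"]))
    datasets = []
    for eid in ids:
        sub = table[table["experiment_id"] == eid]
        if set(sub["type_label"]) != set(type_labels) or len(sub) != len(type_labels):
            rows = [int(r) + 2 for r in sub.index]
            raise ValueError(
                f"{path}: experiment {eid!r} (rows {rows}) does not list exactly "
                f"the types {list(type_labels)}"
            )
        sub = sub.set_index("type_label").loc[list(type_labels)]
        intended = None
        if intended_proportions is not None and eid in intended_proportions:
            intended = np.asarray(intended_proportions[eid], dtype=float)
        datasets.append(
            ExperimentDataset(
                type_labels=type_labels,
                lambda_rate=lambda_rate,
                counts_initial=sub["count_initial"].to_numpy(),
                counts_final=sub["count_final"].to_numpy(),
                intended_proportions=intended,
                experiment_id=eid,
            )
        )
    return datasets


def write_dataset(datasets: list[ExperimentDataset], path: str | Path) -> None:
    """Write experiments to the TSV count-table format of :func:`read_dataset`."""
    rows = []
    for k, ds in enumerate(datasets):
        eid = ds.experiment_id if ds.experiment_id is not None else f"exp{k}"
        for t, label in enumerate(ds.type_labels):
            rows.append(
                {
                    "experiment_id": eid,
                    "type_label": label,
                    "count_initial": int(ds.counts_initial[t]),
                    "count_final": int(ds.counts_final[t]),
                }
            )
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def _growth_prior_from_dict(d: dict) -> GrowthPrior:
    return GrowthPrior(**d)


def _fraction_prior_from_dict(d: dict) -> FractionPrior:
    return FractionPrior(**d)


def prior_spec_from_dict(d: dict, type_labels: list[str]) -> PriorSpec:
    """Build a :class:`PriorSpec` from a config mapping.

    Recognised keys: ``growth_single``, ``growth_pair``, ``fraction_pair``
    (default prior dicts), ``preparation_precision``, and override maps
    ``growth_single_overrides`` (keyed by type label) plus
    ``growth_pair_overrides`` / ``fraction_pair_overrides`` (keyed by
    "label1,label2").
    """
    known = {
        "growth_single",
        "growth_pair",
        "fraction_pair",
        "preparation_precision",
        "growth_single_overrides",
        "growth_pair_overrides",
        "fraction_pair_overrides",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown prior config keys: {sorted(unknown)}")
    idx = {lab: i for i, lab in enumerate(type_labels)}

    def pair_key(key: str) -> tuple[int, int]:
        a, b = (s.strip() for s in key.split(","))
        i, j = idx[a], idx[b]
        return (min(i, j), max(i, j))

    kwargs: dict = {}
    if "growth_single" in d:
        kwargs["growth_single"] = _growth_prior_from_dict(d["growth_single"])
    if "growth_pair" in d:
        kwargs["growth_pair"] = _growth_prior_from_dict(d["growth_pair"])
    if "fraction_pair" in d:
        kwargs["fraction_pair"] = _fraction_prior_from_dict(d["fraction_pair"])
    if "preparation_precision" in d:
        kwargs["preparation_precision"] = float(d["preparation_precision"])
    if "growth_single_overrides" in d:
        kwargs["growth_single_overrides"] = {
            idx[lab]: _growth_prior_from_dict(v)
            for lab, v in d["growth_single_overrides"].items()
        }
    if "growth_pair_overrides" in d:
        kwargs["growth_pair_overrides"] = {
            pair_key(k): _growth_prior_from_dict(v)
            for k, v in d["growth_pair_overrides"].items()
        }
    if "fraction_pair_overrides" in d:
        kwargs["fraction_pair_overrides"] = {
            pair_key(k): _fraction_prior_from_dict(v)
            for k, v in d["fraction_pair_overrides"].items()
        }
    return PriorSpec(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (simulate → infer → validate)."""

    out_dir: str
    seed: int = 0
    lambda_rate: float = 0.3
    presets: tuple[str, ...] = ("no_isolated",)
    n_types: int = 3
    n_experiments_grid: tuple[int, ...] = (3,)
    colonies_grid: tuple[int, ...] = (96,)
    n_replicates: int = 2
    n_steps: int = 600
    n_starts: int = 4
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("presets", "n_experiments_grid", "colonies_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def provenance_record(config: dict, seed: int) -> dict:
    """Machine-readable provenance: config hash, seed, package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "package_version": __version__,
    }


def run_pipeline(config: RunConfig) -> int:
    """Run the configured validation pipeline and write its outputs.

    Emits, under ``config.out_dir``: ``errors.tsv`` (long-format inference
    errors), ``comparisons.json`` (t-tests between consecutive presets, per
    error family), and ``provenance.json``.  Deterministic under a fixed
    seed.  Returns the process exit status (0 on success).
    """
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline: presets=%s n_types=%d grid=%s colonies=%s",
        config.presets,
        config.n_types,
        config.n_experiments_grid,
        config.colonies_grid,
    )
    table = run_validation_sweep(
        presets=list(config.presets),
        n_types=config.n_types,
        n_experiments_grid=list(config.n_experiments_grid),
        colonies_grid=list(config.colonies_grid),
        n_replicates=config.n_replicates,
        master_seed=config.seed,
        lambda_rate=config.lambda_rate,
        sampler_config=SamplerConfig(
            seed=config.seed, n_steps=config.n_steps, n_starts=config.n_starts
        ),
    )
    table.to_csv(out / "errors.tsv", sep="\t", index=False)

    comparisons = []
    for a, b in zip(config.presets[:-1], config.presets[1:]):
        for error_type in ("growth", "fraction"):
            ea = replicate_mean_errors(table, a, error_type)
            eb = replicate_mean_errors(table, b, error_type)
            if ea.size < 2 or eb.size < 2:
                continue
            res = compare_conditions(eb, ea, sided="one")
            comparisons.append(
                {
                    "comparison": f"{b} > {a}",
                    "error_type": error_type,
                    "statistic": res.statistic,
                    "pvalue": res.pvalue,
                    "sided": res.sided,
                }
            )
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
    (out / "provenance.json").write_text(
        json.dumps(provenance_record(asdict(config), config.seed), indent=2)
    )
    logger.info("pipeline: wrote %s", out)
    return 0
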