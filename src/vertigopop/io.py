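"""Config loading/validation and file writers.

The config dialect is YAML with four top-level blocks::

    parameters:       # ModelParameters fields: d_a1..d_w, a, e1, e2, [e3]
    initial_state:    # J, N1, N2, N3 (month-1 abundances; eggs are derived)
    scenarios:        # list of {name, [t_min], [mortality]|[scp_csv], [d_w_base]}
    run:              # n_seasons, extinction_threshold, bookkeeping, seed, output_dir

Unknown keys anywhere are rejected with the offending path named; every
applied default is logged at INFO level.  All numeric output is written at
full precision — rounding happens only in printed comparisons, never on
disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .cold import DEFAULT_WINTER_SURVIVAL, SCPSample, ScenarioSpec
from .model import MODES, Mode, ModelParameters, MonthlyState, SimulationResult
from .scenarios import (
    DEFAULT_EXTINCTION_THRESHOLD,
    DEFAULT_N_SEASONS,
    ScenarioSummary,
)

__all__ = [
    "RunConfig",
    "load_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_summary_json",
    "write_table_csv",
    "write_manifest",
]

logger = logging.getLogger("vertigopop")

TRAJECTORY_COLUMNS = ["season", "month", "step", "E", "J", "N1", "N2", "N3", "N_total"]
TABLE_COLUMNS = [
    "scenario", "mean_final", "sd_final", "min_final", "max_final",
    "time_to_extinction_months", "lambda_pct",
]

_PARAM_KEYS = {"d_a1", "d_a2", "d_a3", "d_j", "d_e", "d_w", "a", "e1", "e2", "e3"}
_STATE_KEYS = {"J", "N1", "N2", "N3"}
_SCENARIO_KEYS = {"name", "t_min", "mortality", "scp_csv", "d_w_base"}
_RUN_KEYS = {"n_seasons", "extinction_threshold", "bookkeeping", "seed", "output_dir"}
_TOP_KEYS = {"parameters", "initial_state", "scenarios", "run"}


class ConfigError(ValueError):
    """A config file failed schema validation."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    parameters: ModelParameters
    initial_state: MonthlyState
    scenarios: tuple[ScenarioSpec, ...] = ()
    n_seasons: int = DEFAULT_N_SEASONS
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD
    bookkeeping: Mode = "literal"
    seed: int = 0
    output_dir: Path | None = None


def _reject_unknown(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(
            f"unknown key {path}.{key}; allowed keys: {sorted(allowed)}"
        )


def _require_mapping(obj: Any, path: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{path} must be a mapping, got {type(obj).__name__}")
    return obj


def _default(block: dict, key: str, value: Any, path: str) -> Any:
    if key in block:
        return block[key]
    logger.info("config: %s.%s not set, using default %r", path, key, value)
    return value


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending key for schema
    violations; out-of-range parameter values surface the underlying
    validation message with the key named.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    raw = _require_mapping(raw, str(path))
    _reject_unknown(raw, _TOP_KEYS, "config")

    if "parameters" not in raw:
        raise ConfigError("config.parameters block is required")
    pblock = _require_mapping(raw["parameters"], "config.parameters")
    _reject_unknown(pblock, _PARAM_KEYS, "config.parameters")
    missing = {"d_a1", "d_a2", "d_a3", "d_j", "d_e", "d_w", "a", "e1", "e2"} - set(pblock)
    if missing:
        raise ConfigError(f"config.parameters missing keys: {sorted(missing)}")
    try:
        params = ModelParameters(**pblock)
    except ValueError as exc:
        raise ConfigError(f"config.parameters: {exc}") from exc

    sblock = _require_mapping(
        _default(raw, "initial_state", {"J": 100, "N1": 100, "N2": 100, "N3": 100},
                 "config"),
        "config.initial_state",
    )
    _reject_unknown(sblock, _STATE_KEYS, "config.initial_state")
    try:
        initial = MonthlyState(
            season=1, month=1,
            J=float(sblock.get("J", 0.0)),
            N1=float(sblock.get("N1", 0.0)),
            N2=float(sblock.get("N2", 0.0)),
            N3=float(sblock.get("N3", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"config.initial_state: {exc}") from exc

    scenarios: list[ScenarioSpec] = []
    for k, sc in enumerate(raw.get("scenarios") or []):
        spath = f"config.scenarios[{k}]"
        sc = _require_mapping(sc, spath)
        _reject_unknown(sc, _SCENARIO_KEYS, spath)
        if "name" not in sc:
            raise ConfigError(f"{spath}.name is required")
        scp = None
        if "scp_csv" in sc:
            scp = SCPSample.from_csv(Path(path.parent, sc["scp_csv"]))
        try:
            scenarios.append(
                ScenarioSpec(
                    name=str(sc["name"]),
                    t_min=sc.get("t_min"),
                    mortality=sc.get("mortality"),
                    scp=scp,
                    d_w_base=sc.get("d_w_base", DEFAULT_WINTER_SURVIVAL),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"{spath}: {exc}") from exc

    rblock = _require_mapping(raw.get("run") or {}, "config.run")
    _reject_unknown(rblock, _RUN_KEYS, "config.run")
    bookkeeping = _default(rblock, "bookkeeping", "literal", "config.run")
    if bookkeeping not in MODES:
        raise ConfigError(
            f"config.run.bookkeeping must be one of {MODES}, got {bookkeeping!r}"
        )
    n_seasons = int(_default(rblock, "n_seasons", DEFAULT_N_SEASONS, "config.run"))
    if n_seasons < 1:
        raise ConfigError("config.run.n_seasons must be >= 1")
    out = rblock.get("output_dir")
    return RunConfig(
        parameters=params,
        initial_state=initial,
        scenarios=tuple(scenarios),
        n_seasons=n_seasons,
        extinction_threshold=float(
            _default(rblock, "extinction_threshold", DEFAULT_EXTINCTION_THRESHOLD,
                     "config.run")
        ),
        bookkeeping=bookkeeping,
        seed=int(_default(rblock, "seed", 0, "config.run")),
        output_dir=Path(out) if out is not None else None,
    )


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file so failures never leave partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise


def write_trajectory_csv(result: SimulationResult, path: str | Path) -> None:
    """Write the trajectory (one row per active month) at full precision."""
    df = result.to_frame()[TRAJECTORY_COLUMNS]
    # 17 significant digits round-trip float64 exactly
    _atomic_write(Path(path),
                  lambda p: df.to_csv(p, index=False, float_format="%.17g"))


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back, verifying the column contract."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {TRAJECTORY_COLUMNS}, got {list(df.columns)}"
        )
    return df


def write_summary_json(
    summaries: ScenarioSummary | Sequence[ScenarioSummary], path: str | Path
) -> None:
    """Write one or more scenario summaries as JSON."""
    if isinstance(summaries, ScenarioSummary):
        payload: Any = summaries.to_dict()
    else:
        payload = [s.to_dict() for s in summaries]
    _atomic_write(
        Path(path), lambda p: p.write_text(json.dumps(payload, indent=2) + "\n")
    )


def write_table_csv(summaries: Sequence[ScenarioSummary], path: str | Path) -> None:
    """Write the scenario-comparison table (one row per scenario)."""
    rows = [{k: s.to_dict()[k] for k in TABLE_COLUMNS} for s in summaries]
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    _atomic_write(Path(path), lambda p: df.to_csv(p, index=False))


def write_manifest(path: str | Path, config_path: str | Path | None,
                   seed: int, extra: dict | None = None) -> None:
    """Write a reproducibility manifest (config hash, versions, seed)."""
    from . import __version__

    manifest = {
        "package": "vertigopop",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
    }
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        manifest["config"] = str(config_path)
        manifest["config_sha256"] = digest
    if extra:
        manifest.update(extra)
    _atomic_write(
        Path(path), lambda p: p.write_text(json.dumps(manifest, indent=2) + "\n")
    )
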