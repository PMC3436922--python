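"""Configuration files, result serialization, and run manifests.

A single flat YAML file drives every subcommand: the five game parameters
(``b``, ``exploited_payoff``, ``mu``, ``eps``, ``q``) plus numerics settings.
Unknown keys are rejected so that typos fail loudly.  Results are written as
tidy CSV (stable column order) or JSON with an explicit schema version, and
every CLI run emits a manifest recording the configuration snapshot, seed,
package version and output files.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import GameParams

__all__ = [
    "NumericsConfig",
    "RunManifest",
    "load_config",
    "save_config",
    "write_records",
    "read_records",
    "write_manifest",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NumericsConfig:
    """Numerical settings shared by the dynamics and simulation drivers."""

    horizon: float = 1e4  # first classification horizon (time units)
    max_horizon: float = 1e6  # doubling cap before marking an orbit undecided
    delta: float = 1e-3  # attractor classification distance
    rtol: float = 1e-8
    atol: float = 1e-10
    n_samples: int = 2000  # Monte-Carlo basin samples
    rounds: int = 1000  # ABM rounds
    burn_in: int = 100  # ABM burn-in rounds
    n_buyers: int = 200
    n_sellers: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_horizon < self.horizon:
            raise ValueError("max_horizon must be >= horizon")
        if not 0 <= self.burn_in < self.rounds:
            raise ValueError("need rounds > burn_in >= 0")


_PARAM_KEYS = {f.name for f in dataclasses.fields(GameParams)}
_NUMERIC_KEYS = {f.name for f in dataclasses.fields(NumericsConfig)}


def load_config(path: str | Path) -> tuple[GameParams, NumericsConfig]:
    """Read a flat key-value YAML config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    unknown = set(raw) - _PARAM_KEYS - _NUMERIC_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; "
            f"valid keys: {sorted(_PARAM_KEYS | _NUMERIC_KEYS)}"
        )
    params = GameParams(**{k: v for k, v in raw.items() if k in _PARAM_KEYS})
    numerics = NumericsConfig(**{k: v for k, v in raw.items() if k in _NUMERIC_KEYS})
    return params, numerics


def save_config(
    path: str | Path, params: GameParams, numerics: NumericsConfig | None = None
) -> None:
    data = dataclasses.asdict(params)
    if numerics is not None:
        data.update(dataclasses.asdict(numerics))
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_records(records: list[dict], path: str | Path, format: str = "csv") -> Path:
    """Write tidy records as CSV (header always present) or versioned JSON."""
    path = Path(path)
    if format == "csv":
        import pandas as pd

        columns: list[str] = []
        for rec in records:
            columns += [k for k in rec if k not in columns]
        pd.DataFrame(records, columns=columns).to_csv(path, index=False)
    elif format == "json":
        path.write_text(
            json.dumps({"schema_version": SCHEMA_VERSION, "records": records}, indent=2)
        )
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'json')")
    return path


def read_records(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version in {path}")
        return data["records"]
    import pandas as pd

    try:
        return pd.read_csv(path).to_dict(orient="records")
    except pd.errors.EmptyDataError:  # header-only / empty CSV
        return []


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted alongside every CLI run's outputs."""

    config: dict
    seed: int
    version: str
    created: str
    outputs: list[str]


def write_manifest(
    out_dir: str | Path,
    params: GameParams,
    numerics: NumericsConfig,
    seed: int,
    outputs: list[str | Path],
    name: str = "manifest.json",
) -> Path:
    from . import __version__

    manifest = RunManifest(
        config={**dataclasses.asdict(params), **dataclasses.asdict(numerics)},
        seed=seed,
        version=__version__,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=[str(o) for o in outputs],
    )
    path = Path(out_dir) / name
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return path
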