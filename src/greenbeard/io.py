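"""Result tables, run manifests and configuration files.

Tables are RFC-4180 CSV with '.' decimal separator; numeric columns
round-trip at full precision and an undefined correlation (zero
variance) is encoded as an empty field.  Every run directory receives
exactly one JSON manifest recording the fully resolved configuration,
the root seed, timestamp, package version and per-run counters — enough
to reproduce any table exactly.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from greenbeard.simulate import GenerationStats, SimConfig

__all__ = [
    "TRAJECTORY_COLUMNS",
    "RunManifest",
    "write_table",
    "read_table",
    "trajectory_frame",
    "load_config_file",
    "build_sim_config",
]

#: Fixed column order of trajectory tables.
TRAJECTORY_COLUMNS = [
    "generation",
    "mean_a_s",
    "mean_a_a",
    "mean_z_s",
    "mean_z_a",
    "var_a_s",
    "var_a_a",
    "cov_a",
    "corr_a",
    "n_haplotypes",
    "mean_fitness",
    "n_fitness_clamped",
]


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every result table."""

    command: str
    config: dict
    seed: int
    timestamp: str
    version: str
    counters: dict

    @classmethod
    def create(cls, command: str, config: dict, seed: int, version: str, **counters):
        return cls(
            command=command,
            config=config,
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(),
            version=version,
            counters=dict(counters),
        )

    def write(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path: Path | str) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_table(frame: pd.DataFrame, path: Path | str) -> None:
    """Write a result table as CSV (full float precision, NaN as empty)."""
    frame.to_csv(path, index=False)


def read_table(path: Path | str) -> pd.DataFrame:
    """Read a result table back; malformed rows raise with a line number."""
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def trajectory_frame(stats: list[GenerationStats]) -> pd.DataFrame:
    """Trajectory table in the documented fixed column order."""
    frame = pd.DataFrame([s.as_dict() for s in stats])
    return frame[TRAJECTORY_COLUMNS]


def load_config_file(path: Path | str) -> dict:
    """Parse a flat YAML or JSON configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}


def build_sim_config(
    settings: dict, extra_keys: set[str] = frozenset(), defaults: dict | None = None
) -> tuple[SimConfig, dict]:
    """Split flat settings into a :class:`SimConfig` and run-level options.

    Unknown keys are rejected by name so that a typo never silently
    falls back to a default.
    """
    merged = dict(defaults or {})
    merged.update(settings)
    unknown = sorted(set(merged) - _SIM_KEYS - set(extra_keys))
    if unknown:
        raise ValueError(
            "unknown configuration keys: "
            + ", ".join(unknown)
            + f" (known: {', '.join(sorted(_SIM_KEYS | set(extra_keys)))})"
        )
    sim_kwargs = {k: v for k, v in merged.items() if k in _SIM_KEYS}
    run_kwargs = {k: v for k, v in merged.items() if k in extra_keys}
    if "m" not in sim_kwargs or "n" not in sim_kwargs:
        raise ValueError("configuration must set the group structure keys 'm' and 'n'")
    return SimConfig(**sim_kwargs), run_kwargs
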