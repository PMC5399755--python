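"""Pipeline configuration and CSV interchange with provenance headers.

Every output table is CSV with ``#``-prefixed metadata lines (config
hash, seed, software version) so a run can be traced back to the exact
configuration that produced it.  Configuration is a single structured
document whose defaults mirror the package-wide analysis defaults;
unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__


class ConfigError(ValueError):
    """Malformed or unknown configuration keys."""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters in one versioned document.

    Sections mirror the analysis stages; every default equals the
    corresponding function default, so an empty config reproduces the
    stock pipeline.
    """

    simulation: dict = field(default_factory=dict)   # SwimSimParams overrides
    segmentation: dict = field(default_factory=lambda: {
        "policy": "otsu", "threshold": None, "min_area": 10})
    turns: dict = field(default_factory=lambda: {
        "threshold": 0.85, "min_duration_s": 0.2, "merge_gap_s": 0.3,
        "median_filter": False})
    thrash: dict = field(default_factory=lambda: {"hysteresis": 0.2})
    calcium: dict = field(default_factory=lambda: {
        "baseline_s": 60.0, "analysis_s": 120.0, "fit_window": "baseline"})
    seed: int = 0
    config_version: int = 1

    _ALLOWED = {
        "simulation": None,  # free-form: validated by SwimSimParams itself
        "segmentation": {"policy", "threshold", "min_area"},
        "turns": {"threshold", "min_duration_s", "merge_gap_s",
                  "median_filter"},
        "thrash": {"hysteresis"},
        "calcium": {"baseline_s", "analysis_s", "fit_window"},
    }

    def __post_init__(self) -> None:
        for section, allowed in self._ALLOWED.items():
            got = getattr(self, section)
            if not isinstance(got, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            if allowed is not None:
                unknown = set(got) - allowed
                if unknown:
                    raise ConfigError(
                        f"unknown keys in {section!r}: {sorted(unknown)}")
        if self.simulation:
            from .simulate import SwimSimParams

            known = {f.name for f in dataclasses.fields(SwimSimParams)}
            known |= {"turn_rate"}  # serializable rate spec, see pipeline
            unknown = set(self.simulation) - known
            if unknown:
                raise ConfigError(
                    f"unknown keys in 'simulation': {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown top-level config keys: "
                              f"{sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        """Short stable hash of the canonicalized configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                config: PipelineConfig | None = None,
                seed: int | None = None, index: bool = False,
                **extra_meta) -> None:
    """Write a DataFrame as CSV with a ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"osmodrop_version": __version__}
    if config is not None:
        meta["config_hash"] = config.hash
        meta["seed"] = config.seed if seed is None else seed
    elif seed is not None:
        meta["seed"] = seed
    meta.update(extra_meta)
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping the header."""
    return pd.read_csv(path, comment="#")


def read_table_meta(path: str | Path) -> dict[str, str]:
    """Parse the ``#``-prefixed provenance header of a table."""
    meta = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_truth_csv(log, path: str | Path,
                    config: PipelineConfig | None = None,
                    seed: int | None = None) -> None:
    """Ground-truth event CSV (event_type, start_s, end_s) for a sim."""
    rows = [{"event_type": "turn", "start_s": s, "end_s": e}
            for s, e in log.turn_intervals]
    rows += [{"event_type": "thrash_halfcycle", "start_s": t, "end_s": t}
             for t in log.thrash_halfcycle_times]
    write_table(pd.DataFrame(rows, columns=["event_type", "start_s", "end_s"]),
                path, config=config, seed=seed)
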