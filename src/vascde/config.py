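"""Run configuration for the end-to-end pipeline.

A single dataclass holds every tunable the pipeline reads; values can come
from a TOML file with keyword overrides on top (overrides win).  Validation
happens at construction so a bad configuration fails before any stage runs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Parameters of one synthetic end-to-end run.

    Analysis thresholds mirror the published contrast: up to 4 mismatches
    per read, calls at >= 1.9-fold and 5% FDR.  The remaining fields size
    the synthetic dataset.
    """

    seed: int = 0
    # analysis parameters
    max_mismatch: int = 4
    fc_threshold: float = 1.9
    fdr: float = 0.05
    pseudocount: float = 0.5
    unique_scope: str = "location"  # 'location' | 'gene'
    total_def: str = "unique"  # 'unique' | 'all-mapped'
    # synthetic dataset geometry
    n_genes: int = 50
    length_min: int = 500
    length_max: int = 1000
    shared_pairs: int = 2
    shared_segment_len: int = 80
    n_read_pairs: int = 2000  # fragments per condition (split over lanes)
    n_lanes: int = 1
    read_len: int = 76
    insert_len: int = 200
    error_rate: float = 0.0
    # spiked truth: n_spikes genes at spike_fold, the rest null
    n_spikes: int = 10
    spike_fold: float = 32.0
    spike_cpm: float = 5000.0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        if self.max_mismatch < 0:
            raise ConfigError("max_mismatch must be >= 0")
        if self.fc_threshold <= 0:
            raise ConfigError("fc_threshold must be positive")
        if not 0 < self.fdr < 1:
            raise ConfigError("fdr must lie strictly inside (0, 1)")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if self.unique_scope not in ("location", "gene"):
            raise ConfigError("unique_scope must be 'location' or 'gene'")
        if self.total_def not in ("unique", "all-mapped"):
            raise ConfigError("total_def must be 'unique' or 'all-mapped'")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 1 <= self.length_min <= self.length_max:
            raise ConfigError("need 1 <= length_min <= length_max")
        if self.n_read_pairs < 0 or self.n_lanes < 1:
            raise ConfigError("n_read_pairs >= 0 and n_lanes >= 1 required")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must lie in [0, 1)")
        if self.insert_len < self.read_len:
            raise ConfigError("insert_len must be >= read_len")
        if self.insert_len > self.length_min:
            raise ConfigError("insert_len must fit the shortest transcript")
        if self.n_spikes < 0 or self.n_spikes > self.n_genes:
            raise ConfigError("n_spikes must lie in [0, n_genes]")
        if self.spike_fold < 0 or self.spike_cpm <= 0:
            raise ConfigError("spike_fold >= 0 and spike_cpm > 0 required")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Load a TOML config file; keyword overrides win over file values."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
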