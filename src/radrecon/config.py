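"""Pipeline configuration: thresholds, counts, seed, all in one record."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

from .curve import DEFAULT_POWER_SETS

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    max_missing_frac: float = 0.20
    n_noise_normal: int | None = None      # None -> 2x real gene count
    n_noise_uniform: int | None = None     # None -> 1x real gene count
    kmeans_repeats: int = 50
    avg_cluster_size: int = 30
    rho_cutoff: float | None = None   # None -> eligibility by rho=0 significance test
    min_present_frac: float = 0.5
    candidate_power_sets: tuple = DEFAULT_POWER_SETS
    curve_variant: str = "robust"
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "max_missing_frac", "rho_cutoff", "min_present_frac"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("kmeans_repeats", "avg_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("n_noise_normal", "n_noise_uniform"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be a positive integer or None")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "candidate_power_sets" in raw:
            raw["candidate_power_sets"] = tuple(tuple(p) for p in raw["candidate_power_sets"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        rec = asdict(self)
        rec["candidate_power_sets"] = [list(p) for p in self.candidate_power_sets]
        with open(path, "w") as fh:
            yaml.safe_dump(rec, fh, sort_keys=True)

    def log_resolved(self) -> None:
        """Log the seed and the fully resolved configuration (every run)."""
        log.info("resolved configuration (seed=%d): %s", self.seed, asdict(self))
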