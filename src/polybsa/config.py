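"""Run configuration: one object (or YAML file) drives a whole scan."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .plexity import PlexityConfig
from .vcf_io import ConfigurationError, FilterConfig, ROLES


@dataclass
class RunConfig:
    """Every tunable of the scan pipeline, with the defaults of the method.

    ``upstream`` records variant-caller options (e.g. minMQ, adjustMQ) purely
    as provenance; they act at pileup time, before the VCF exists, and are
    not applied here.
    """

    sample_map: Mapping[str, str] = field(
        default_factory=lambda: {r: r for r in ROLES}
    )
    filter: FilterConfig = field(default_factory=FilterConfig)
    plexity: PlexityConfig = field(default_factory=PlexityConfig)
    # null model
    replicates: int = 10_000
    seed: int = 0
    bulk_size_low: int = 10
    bulk_size_high: int = 21
    # window scan
    window_bp: int = 100_000
    step_bp: int = 20_000
    # region calling
    count_threshold: int = 20
    min_span_bp: int = 2_000_000
    zero_min: int = 10
    dominance_ratio: float = 5.0
    confidence: int = 95
    min_run_fraction: float = 1.0
    # marker nomination
    zero_tol: float = 0.02
    simplex_tol: float = 0.05
    top_k: int = 10
    # provenance of the upstream caller invocation (not applied here)
    upstream: Mapping[str, object] = field(
        default_factory=lambda: {"minMQ": 30, "adjustMQ": 70}
    )
    paths: Mapping[str, str] = field(default_factory=dict)
    plot: bool = False

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.sample_map]
        if missing:
            raise ConfigurationError(f"sample_map missing roles: {missing}")
        if self.bulk_size_low < 1 or self.bulk_size_high < 1:
            raise ConfigurationError("bulk sizes must be >= 1")
        if self.confidence not in (95, 99):
            raise ConfigurationError("confidence must be 95 or 99")

    def with_n_plex(self, n_plex: int) -> "RunConfig":
        cfg = RunConfig(**{**self.to_dict(flat=False)})
        cfg.plexity = PlexityConfig(
            ploidy=self.plexity.ploidy, n_plex=n_plex,
            max_other_alt_reads=self.plexity.max_other_alt_reads,
        )
        return cfg

    def to_dict(self, flat: bool = True) -> dict:
        if flat:
            d = asdict(self)
            d["filter"] = asdict(self.filter)
            d["plexity"] = asdict(self.plexity)
            d["sample_map"] = dict(self.sample_map)
            d["upstream"] = dict(self.upstream)
            d["paths"] = dict(self.paths)
            return d
        return {
            "sample_map": dict(self.sample_map),
            "filter": self.filter,
            "plexity": self.plexity,
            "replicates": self.replicates,
            "seed": self.seed,
            "bulk_size_low": self.bulk_size_low,
            "bulk_size_high": self.bulk_size_high,
            "window_bp": self.window_bp,
            "step_bp": self.step_bp,
            "count_threshold": self.count_threshold,
            "min_span_bp": self.min_span_bp,
            "zero_min": self.zero_min,
            "dominance_ratio": self.dominance_ratio,
            "confidence": self.confidence,
            "min_run_fraction": self.min_run_fraction,
            "zero_tol": self.zero_tol,
            "simplex_tol": self.simplex_tol,
            "top_k": self.top_k,
            "upstream": dict(self.upstream),
            "paths": dict(self.paths),
            "plot": self.plot,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        flt = data.get("filter", {})
        if isinstance(flt, Mapping):
            flt = {k: v for k, v in flt.items()
                   if k in ("min_depth", "max_indel_length", "multiallelic_policy",
                            "min_depth_per_role")}
            data["filter"] = FilterConfig(**flt)
        plx = data.get("plexity", {})
        if isinstance(plx, Mapping):
            if plx.get("donor_index_range") is not None:
                plx = {**plx, "donor_index_range": tuple(plx["donor_index_range"])}
            data["plexity"] = PlexityConfig(**plx)
        known = cls.__dataclass_fields__.keys()
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigurationError(f"config file {path} is not a mapping")
        raw = dict(raw)
        raw.pop("simulate", None)  # CrossConfig section, handled by the CLI
        return cls.from_dict(raw)
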